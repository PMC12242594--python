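"""Lump-vs-split decision for two candidate cohorts.

The cohort distance d(C1, C2) is compared with the calibrated threshold c,
and decision uncertainty is quantified by resampling 100 subgroup pairs of
random size from the two cohorts: if more than half of the subgroup
distances exceed c, the evidence favours splitting.  A positive predictive
value — the probability that two cohorts with a distance in the observed
subgroup-distance range are truly distinct — is estimated from the pooled
validation control distributions at a 50% pre-test probability:

    PPV = sens * p / (sens * p + (1 - spec) * (1 - p))

A downsampling analysis draws n patients per cohort (100 draws per n) to
show how decision stability grows with cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, ControlDistributions
from .descriptors import CohortSpec, DescriptorCollection, cohort_distance
from .errors import (
    EmptyCohortError,
    EmptyDistributionError,
    OverlappingCohortsError,
    UndefinedPpvError,
)

__all__ = [
    "PpvInputs",
    "SplitDecision",
    "DownsampleResult",
    "estimate_ppv",
    "range_probabilities",
    "compare_cohorts",
    "downsample",
]


@dataclass(frozen=True)
class PpvInputs:
    """Range-based probabilities feeding the PPV formula."""

    sensitivity: float
    specificity: float
    pretest: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "pretest"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SplitDecision:
    """Outcome of one pairwise cohort comparison."""

    cohort_distance: float
    threshold: float
    subgroup_distances: list[float]
    proportion_above: float
    verdict: str  # "split" | "lump"
    ppv: float
    distance_range: tuple[float, float]
    low_confidence: bool = False  # single-patient cohorts

    def to_dict(self) -> dict:
        return {
            "cohort_distance": self.cohort_distance,
            "threshold": self.threshold,
            "subgroup_distances": self.subgroup_distances,
            "proportion_above": self.proportion_above,
            "verdict": self.verdict,
            "ppv": self.ppv,
            "distance_range": list(self.distance_range),
            "low_confidence": self.low_confidence,
        }


@dataclass
class DownsampleResult:
    """Subgroup distances per downsampled cohort size n (rows of 100 draws)."""

    distances: dict[int, list[float]]
    threshold: float

    def summary(self) -> pd.DataFrame:
        rows = []
        for n, vals in sorted(self.distances.items()):
            arr = np.asarray(vals)
            q1, med, q3 = np.percentile(arr, [25, 50, 75])
            rows.append(
                dict(
                    n=n,
                    median=med,
                    iqr=q3 - q1,
                    std=arr.std(ddof=1) if arr.size > 1 else 0.0,
                    prop_above=float((arr > self.threshold).mean()),
                )
            )
        return pd.DataFrame(rows).set_index("n")


def estimate_ppv(inputs: PpvInputs) -> float:
    """Positive predictive value from sensitivity, specificity and pre-test p."""
    sens, spec, p = inputs.sensitivity, inputs.specificity, inputs.pretest
    denom = sens * p + (1.0 - spec) * (1.0 - p)
    if denom == 0.0:
        raise UndefinedPpvError(
            "PPV undefined: sensitivity*p + (1-specificity)*(1-p) is zero"
        )
    return sens * p / denom


def range_probabilities(
    distance_range: tuple[float, float],
    pooled: ControlDistributions,
    pretest: float = 0.5,
) -> PpvInputs:
    """Empirical range probabilities from the pooled control distributions.

    Sensitivity is the fraction of different-syndrome distances inside the
    closed range; specificity the fraction of same-syndrome distances
    outside it.  Both are clipped to [1/(n+1), n/(n+1)] so a finite sample
    never yields the degenerate probabilities 0 or 1.  A degenerate range
    (min = max) is treated as a point query with the same clipping.
    """
    lo, hi = min(distance_range), max(distance_range)
    diff = np.asarray(pooled.different_syndrome, dtype=float)
    same = np.asarray(pooled.same_syndrome, dtype=float)
    if diff.size == 0 or same.size == 0:
        raise EmptyDistributionError("pooled control distributions must be nonempty")
    sens = float(((diff >= lo) & (diff <= hi)).mean())
    spec = float(((same < lo) | (same > hi)).mean())
    eps_d = 1.0 / (diff.size + 1)
    eps_s = 1.0 / (same.size + 1)
    sens = float(np.clip(sens, eps_d, 1.0 - eps_d))
    spec = float(np.clip(spec, eps_s, 1.0 - eps_s))
    return PpvInputs(sensitivity=sens, specificity=spec, pretest=pretest)


def _patient_groups(c: CohortSpec, coll: DescriptorCollection) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for iid in c.image_ids:
        groups.setdefault(coll[iid].patient_id, []).append(iid)
    return groups


def compare_cohorts(
    c1: CohortSpec,
    c2: CohortSpec,
    coll: DescriptorCollection,
    calib: CalibrationResult,
    n_subgroups: int = 100,
    seed: int | None = None,
    pretest: float = 0.5,
) -> SplitDecision:
    """Run the full lump/split decision for two disjoint cohorts.

    Subgroup sizes are drawn independently and uniformly on [1, |C|] per
    cohort; images within a draw are sampled without replacement.  The
    verdict is "split" when strictly more than half of the subgroup
    distances exceed the threshold; exact equality with the threshold
    counts as lump.
    """
    c1.validate(coll)
    c2.validate(coll)
    overlap = set(c1.image_ids) & set(c2.image_ids)
    if overlap:
        raise OverlappingCohortsError(f"cohorts share images: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    d_full = cohort_distance(c1, c2, coll)
    ids1, ids2 = list(c1.image_ids), list(c2.image_ids)
    dist = coll.distance_matrix()
    r1, r2 = coll.rows(ids1), coll.rows(ids2)
    sub: list[float] = []
    for _ in range(n_subgroups):
        n1 = int(rng.integers(1, len(ids1) + 1))
        n2 = int(rng.integers(1, len(ids2) + 1))
        s1 = rng.choice(r1, size=n1, replace=False)
        s2 = rng.choice(r2, size=n2, replace=False)
        sub.append(float(dist[np.ix_(s1, s2)].mean()))
    sub_arr = np.asarray(sub)
    prop = float((sub_arr > calib.threshold).mean())
    verdict = "split" if prop > 0.5 else "lump"
    d_range = (float(sub_arr.min()), float(sub_arr.max()))
    ppv = estimate_ppv(
        range_probabilities(d_range, calib.pooled_validation_controls, pretest)
    )
    low_conf = (
        len(_patient_groups(c1, coll)) <= 1 or len(_patient_groups(c2, coll)) <= 1
    )
    return SplitDecision(
        cohort_distance=d_full,
        threshold=calib.threshold,
        subgroup_distances=[float(v) for v in sub],
        proportion_above=prop,
        verdict=verdict,
        ppv=ppv,
        distance_range=d_range,
        low_confidence=low_conf,
    )


def downsample(
    c1: CohortSpec,
    c2: CohortSpec,
    coll: DescriptorCollection,
    calib: CalibrationResult,
    draws: int = 100,
    seed: int | None = None,
) -> DownsampleResult:
    """Cohort distances of size-n patient subsamples, 1 <= n <= min cohort size.

    Sampling is at patient level (all of a sampled patient's images enter
    the subgroup); with one image per patient this reduces to image-level
    sampling.
    """
    c1.validate(coll)
    c2.validate(coll)
    rng = np.random.default_rng(seed)
    pats1 = _patient_groups(c1, coll)
    pats2 = _patient_groups(c2, coll)
    keys1, keys2 = sorted(pats1), sorted(pats2)
    if not keys1 or not keys2:
        raise EmptyCohortError("both cohorts must contain at least one patient")
    dist = coll.distance_matrix()
    n_max = min(len(keys1), len(keys2))
    out: dict[int, list[float]] = {}
    for n in range(1, n_max + 1):
        vals: list[float] = []
        for _ in range(draws):
            p1 = [keys1[j] for j in rng.choice(len(keys1), size=n, replace=False)]
            p2 = [keys2[j] for j in rng.choice(len(keys2), size=n, replace=False)]
            g1 = [iid for p in p1 for iid in pats1[p]]
            g2 = [iid for p in p2 for iid in pats2[p]]
            vals.append(
                float(dist[np.ix_(coll.rows(g1), coll.rows(g2))].mean())
            )
        out[n] = vals
    return DownsampleResult(distances=out, threshold=calib.threshold)
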