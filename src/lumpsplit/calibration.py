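"""Split-threshold calibration from sampled control distance distributions.

Two control distributions anchor the lump/split decision:

* *same-syndrome*: each syndrome's images are randomly divided into two
  groups (10 repetitions per syndrome) and the two groups' mean pairwise
  ensemble cosine distance recorded — these are the "lump" controls;
* *different-syndrome*: for every unordered pair of syndromes, a random-size
  group is sampled from each (5 repetitions per pair) — the "split" cases.

Duplicate group-pair comparisons are removed from each distribution.  The
decision threshold c maximises the Youden index (sensitivity + specificity
- 1) over the pooled distances, under syndrome-level five-fold
cross-validation: thresholds are derived on 4/5 of the syndromes and
scored on the held-out 1/5; the fold with the highest validation Youden
index supplies the operational threshold.  Validation-side distributions
from all folds are pooled for downstream predictive-value estimation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .descriptors import CohortSpec, DescriptorCollection, cohort_distance
from .errors import (
    EmptyDatasetError,
    EmptyDistributionError,
    InsufficientSyndromesError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ControlDistributions",
    "CalibrationResult",
    "SplitThresholdCalibrator",
    "filter_dataset",
    "make_syndrome_folds",
    "sample_same_syndrome",
    "sample_different_syndromes",
    "youden_threshold",
    "calibrate",
    "validate_lump_split",
]


@dataclass
class ControlDistributions:
    """Same- and different-syndrome control distance distributions."""

    same_syndrome: list[float] = field(default_factory=list)
    different_syndrome: list[float] = field(default_factory=list)
    fold_ids: list[int] = field(default_factory=list)

    def extend(self, other: "ControlDistributions") -> None:
        self.same_syndrome.extend(other.same_syndrome)
        self.different_syndrome.extend(other.different_syndrome)
        self.fold_ids.extend(other.fold_ids)


@dataclass
class CalibrationResult:
    """Outcome of cross-validated threshold calibration."""

    threshold: float
    selected_fold: int
    train_sensitivity: float
    train_specificity: float
    validation_sensitivity: float
    validation_specificity: float
    auc: float
    youden_per_fold: list[float]
    folds: list[list[str]]
    pooled_validation_controls: ControlDistributions

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            payload = json.load(fh)
        payload["pooled_validation_controls"] = ControlDistributions(
            **payload["pooled_validation_controls"]
        )
        return cls(**payload)


def filter_dataset(coll: DescriptorCollection) -> DescriptorCollection:
    """Keep only syndromes with at least two distinct patients."""
    keep = {
        syn for syn, pats in coll.patients_by_syndrome.items() if len(pats) >= 2
    }
    image_ids = [item.image_id for item in coll if item.syndrome_id in keep]
    if not image_ids:
        raise EmptyDatasetError("no syndrome has two or more distinct patients")
    return coll.subset(image_ids)


def make_syndrome_folds(
    coll: DescriptorCollection, k: int = 5, seed: int | None = None
) -> list[list[str]]:
    """Randomly partition syndrome ids into k folds of near-equal size.

    Splitting at syndrome level guarantees all images of a patient fall in
    one fold, keeping training and validation sets truly distinct.
    """
    syndromes = sorted(coll.syndrome_ids)
    if len(syndromes) < k:
        raise InsufficientSyndromesError(
            f"{len(syndromes)} syndromes cannot fill {k} folds"
        )
    rng = np.random.default_rng(seed)
    order = [syndromes[i] for i in rng.permutation(len(syndromes))]
    return [sorted(part) for part in np.array_split(np.array(order, dtype=object), k)]


def _dedup_key(g1: Sequence[str], g2: Sequence[str]) -> frozenset:
    return frozenset({frozenset(g1), frozenset(g2)})


def sample_same_syndrome(
    coll: DescriptorCollection,
    syndromes: Iterable[str],
    reps: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Sample the same-syndrome control distribution.

    Each syndrome's images are split into two nonempty random groups
    (each image to a side with probability 1/2, resampled if a side is
    empty), `reps` times; duplicate group pairs are dropped.  Syndromes
    with a single image cannot be split and are skipped with a warning.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    by_syndrome = coll.images_by_syndrome
    seen: set[frozenset] = set()
    out: list[float] = []
    for syn in sorted(set(syndromes)):
        images = sorted(by_syndrome.get(syn, []))
        if len(images) < 2:
            warnings.warn(
                f"syndrome {syn!r} has fewer than 2 images; skipped in same-syndrome sampling"
            )
            continue
        for _ in range(reps):
            while True:
                mask = rng.random(len(images)) < 0.5
                if mask.any() and not mask.all():
                    break
            g1 = [im for im, m in zip(images, mask) if m]
            g2 = [im for im, m in zip(images, mask) if not m]
            key = _dedup_key(g1, g2)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                cohort_distance(
                    CohortSpec(f"{syn}/a", tuple(g1)),
                    CohortSpec(f"{syn}/b", tuple(g2)),
                    coll,
                )
            )
    return out


def sample_different_syndromes(
    coll: DescriptorCollection,
    syndromes: Iterable[str],
    reps: int = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Sample the different-syndrome control distribution.

    For each unordered pair of syndromes, draw a group of uniform random
    size (1..n images) without replacement from each side, `reps` times;
    duplicate group-pair comparisons are dropped.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    by_syndrome = coll.images_by_syndrome
    syn_list = sorted(set(syndromes))
    seen: set[frozenset] = set()
    out: list[float] = []
    for i, s1 in enumerate(syn_list):
        for s2 in syn_list[i + 1 :]:
            im1 = sorted(by_syndrome.get(s1, []))
            im2 = sorted(by_syndrome.get(s2, []))
            if not im1 or not im2:
                continue
            for _ in range(reps):
                n1 = int(rng.integers(1, len(im1) + 1))
                n2 = int(rng.integers(1, len(im2) + 1))
                g1 = [im1[j] for j in rng.choice(len(im1), size=n1, replace=False)]
                g2 = [im2[j] for j in rng.choice(len(im2), size=n2, replace=False)]
                key = _dedup_key(g1, g2)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    cohort_distance(
                        CohortSpec(s1, tuple(g1)), CohortSpec(s2, tuple(g2)), coll
                    )
                )
    return out


def youden_threshold(
    controls: Sequence[float], cases: Sequence[float]
) -> tuple[float, float, float, float]:
    """Pick the distance threshold maximising the Youden index.

    Candidate thresholds are midpoints between consecutive distinct pooled
    values plus sentinels below and above all data.  A case counts as
    detected when its distance is strictly above the threshold; a control
    as correctly lumped when at or below it.  Youden ties break toward the
    smallest threshold.  Returns (threshold, sensitivity, specificity,
    auc), with AUC from the Mann-Whitney rank statistic.

    Controls are same-syndrome distances (should fall below c), cases are
    different-syndrome distances (should fall above).
    """
    controls = np.asarray(controls, dtype=float)
    cases = np.asarray(cases, dtype=float)
    if controls.size == 0 or cases.size == 0:
        raise EmptyDistributionError("both distance distributions must be nonempty")
    pooled = np.unique(np.concatenate([controls, cases]))
    span = pooled[-1] - pooled[0]
    if span == 0.0:  # degenerate: all pooled values identical
        span = max(abs(pooled[0]), 1.0)
    candidates = np.concatenate(
        [[pooled[0] - 0.5 * span], (pooled[:-1] + pooled[1:]) / 2.0, [pooled[-1] + 0.5 * span]]
    )
    sens = (cases[None, :] > candidates[:, None]).mean(axis=1)
    spec = (controls[None, :] <= candidates[:, None]).mean(axis=1)
    youden = sens + spec - 1.0
    best = int(np.argmax(youden))  # argmax takes first max: smallest threshold
    # AUC = P(case > control) + 0.5 P(case == control), via joint ranks
    combined = np.concatenate([cases, controls])
    from scipy.stats import rankdata

    ranks = rankdata(combined)
    r_cases = ranks[: cases.size].sum()
    auc = (r_cases - cases.size * (cases.size + 1) / 2.0) / (cases.size * controls.size)
    return float(candidates[best]), float(sens[best]), float(spec[best]), float(auc)


class SplitThresholdCalibrator(BaseEstimator):
    """Cross-validated ensemble-distance threshold calibrator.

    Parameters
    ----------
    k_folds : number of syndrome-level folds (default 5).
    reps_same : same-syndrome partitions sampled per syndrome (default 10).
    reps_diff : comparisons sampled per different-syndrome pair (default 5).
    min_patients : minimum distinct patients for a syndrome to enter
        calibration (default 2).
    random_state : seed for all sampling.

    Attributes (after :meth:`fit`)
    ------------------------------
    threshold_ : selected decision threshold c.
    selected_fold_ : index of the fold with the highest validation Youden.
    train_sensitivity_, train_specificity_ : operating point on the
        selected fold's training distributions.
    validation_sensitivity_, validation_specificity_ : operating point of
        the selected threshold on the held-out distributions.
    auc_ : training ROC AUC of the selected fold.
    youden_per_fold_ : validation Youden index per fold.
    folds_ : syndrome-id partition.
    pooled_validation_controls_ : validation-side distributions pooled over
        all folds.
    result_ : the same information as a :class:`CalibrationResult`.
    """

    def __init__(
        self,
        k_folds: int = 5,
        reps_same: int = 10,
        reps_diff: int = 5,
        min_patients: int = 2,
        random_state: int | None = None,
    ) -> None:
        self.k_folds = k_folds
        self.reps_same = reps_same
        self.reps_diff = reps_diff
        self.min_patients = min_patients
        self.random_state = random_state

    def fit(self, coll: DescriptorCollection, y=None) -> "SplitThresholdCalibrator":
        coll = filter_dataset(coll) if self.min_patients >= 2 else coll
        rng = np.random.default_rng(self.random_state)
        folds = make_syndrome_folds(
            coll, self.k_folds, seed=int(rng.integers(2**31))
        )
        pooled = ControlDistributions()
        per_fold: list[dict] = []
        for f, val_syndromes in enumerate(folds):
            train_syndromes = [
                s for g, fold in enumerate(folds) if g != f for s in fold
            ]
            same_tr = sample_same_syndrome(
                coll, train_syndromes, self.reps_same, rng=rng
            )
            diff_tr = sample_different_syndromes(
                coll, train_syndromes, self.reps_diff, rng=rng
            )
            thr, sens_tr, spec_tr, auc = youden_threshold(same_tr, diff_tr)
            same_va = sample_same_syndrome(coll, val_syndromes, self.reps_same, rng=rng)
            diff_va = sample_different_syndromes(
                coll, val_syndromes, self.reps_diff, rng=rng
            )
            if not same_va or not diff_va:
                raise EmptyDistributionError(
                    f"fold {f} produced an empty validation distribution"
                )
            sens_va = float(np.mean(np.asarray(diff_va) > thr))
            spec_va = float(np.mean(np.asarray(same_va) <= thr))
            per_fold.append(
                dict(
                    threshold=thr,
                    train_sensitivity=sens_tr,
                    train_specificity=spec_tr,
                    auc=auc,
                    validation_sensitivity=sens_va,
                    validation_specificity=spec_va,
                    youden=sens_va + spec_va - 1.0,
                )
            )
            pooled.same_syndrome.extend(same_va)
            pooled.different_syndrome.extend(diff_va)
            pooled.fold_ids.extend([f] * (len(same_va) + len(diff_va)))
        youdens = [d["youden"] for d in per_fold]
        best = int(np.argmax(youdens))
        sel = per_fold[best]
        self.threshold_ = float(sel["threshold"])
        self.selected_fold_ = best
        self.train_sensitivity_ = float(sel["train_sensitivity"])
        self.train_specificity_ = float(sel["train_specificity"])
        self.validation_sensitivity_ = float(sel["validation_sensitivity"])
        self.validation_specificity_ = float(sel["validation_specificity"])
        self.auc_ = float(sel["auc"])
        self.youden_per_fold_ = [float(y) for y in youdens]
        self.folds_ = [list(fold) for fold in folds]
        self.pooled_validation_controls_ = pooled
        self.result_ = CalibrationResult(
            threshold=self.threshold_,
            selected_fold=self.selected_fold_,
            train_sensitivity=self.train_sensitivity_,
            train_specificity=self.train_specificity_,
            validation_sensitivity=self.validation_sensitivity_,
            validation_specificity=self.validation_specificity_,
            auc=self.auc_,
            youden_per_fold=self.youden_per_fold_,
            folds=self.folds_,
            pooled_validation_controls=pooled,
        )
        return self

    def predict(self, distances) -> np.ndarray:
        """Classify distances: True = split (distance strictly above c)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "threshold_")
        return np.asarray(distances, dtype=float) > self.threshold_


def calibrate(
    coll: DescriptorCollection,
    k: int = 5,
    reps_same: int = 10,
    reps_diff: int = 5,
    seed: int | None = None,
) -> CalibrationResult:
    """Functional wrapper over :class:`SplitThresholdCalibrator`."""
    est = SplitThresholdCalibrator(
        k_folds=k, reps_same=reps_same, reps_diff=reps_diff, random_state=seed
    )
    return est.fit(coll).result_


def validate_lump_split(
    coll: DescriptorCollection,
    calib: CalibrationResult,
    n_subgroups: int = 100,
    seed: int | None = None,
) -> tuple[float, float]:
    """Operating characteristics of the full split decision on held-out syndromes.

    Analysis 1: every pair of distinct validation syndromes is compared and
    a "split" verdict counts as a true positive.  Analysis 2: every
    validation syndrome is randomly divided in two and a "lump" verdict
    counts as a true negative.  Returns (sensitivity, specificity).
    """
    from .decision import compare_cohorts  # deferred: decision imports this module

    rng = np.random.default_rng(seed)
    val_syndromes = sorted(calib.folds[calib.selected_fold])
    val_syndromes = [s for s in val_syndromes if s in coll.images_by_syndrome]
    by_syndrome = coll.images_by_syndrome
    tp = total_pairs = 0
    for i, s1 in enumerate(val_syndromes):
        for s2 in val_syndromes[i + 1 :]:
            dec = compare_cohorts(
                CohortSpec(s1, tuple(sorted(by_syndrome[s1]))),
                CohortSpec(s2, tuple(sorted(by_syndrome[s2]))),
                coll,
                calib,
                n_subgroups=n_subgroups,
                seed=int(rng.integers(2**31)),
            )
            total_pairs += 1
            tp += dec.verdict == "split"
    tn = total_splits = 0
    for syn in val_syndromes:
        images = sorted(by_syndrome[syn])
        if len(images) < 2:
            continue
        while True:
            mask = rng.random(len(images)) < 0.5
            if mask.any() and not mask.all():
                break
        g1 = tuple(im for im, m in zip(images, mask) if m)
        g2 = tuple(im for im, m in zip(images, mask) if not m)
        dec = compare_cohorts(
            CohortSpec(f"{syn}/a", g1),
            CohortSpec(f"{syn}/b", g2),
            coll,
            calib,
            n_subgroups=n_subgroups,
            seed=int(rng.integers(2**31)),
        )
        total_splits += 1
        tn += dec.verdict == "lump"
    sensitivity = tp / total_pairs if total_pairs else float("nan")
    specificity = tn / total_splits if total_splits else float("nan")
    return sensitivity, specificity
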