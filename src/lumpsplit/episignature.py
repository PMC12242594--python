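"""Episignature discovery and classification on methylation beta matrices.

A beta matrix holds per-probe methylation levels in [0, 1] (probes x
samples).  Discovery compares case and control samples probe-by-probe with
a linear model (intercept + group + the first two principal components of
the discovery samples as covariates against age, sex and cell-count
structure) and empirical-Bayes moderated t-statistics: probe-wise residual
variances s_g^2 on d degrees of freedom are shrunk toward a prior s0^2
with d0 prior degrees of freedom,

    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),

where (d0, s0^2) are estimated by moment-matching the log residual
variances to a scaled F distribution.  Two-sided p-values on d + d0
degrees of freedom are Benjamini-Hochberg adjusted; the signature is the
probe set with q <= q_max and |delta beta| >= min_abs_delta.

Classification trains a linear support-vector separator on the
signature-site betas and maps its margins to [0, 1] scores through a
Platt-style sigmoid fitted on the training margins; samples score as
case-like above 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigError,
    DegenerateDesignError,
    InsufficientSamplesError,
    MissingProbeError,
)

__all__ = [
    "validate_beta",
    "compute_covariate_pcs",
    "differential_methylation",
    "select_signature",
    "EpisignatureModel",
    "EpisignatureClassifier",
    "train_classifier",
    "score_samples",
    "synth_beta",
]


def validate_beta(beta: pd.DataFrame) -> pd.DataFrame:
    """Check a probes x samples beta matrix: finite values in [0, 1]."""
    values = beta.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ConfigError("beta matrix contains missing or non-finite values")
    if values.min() < 0.0 or values.max() > 1.0:
        raise ConfigError("beta values must lie in [0, 1]")
    if beta.index.has_duplicates or beta.columns.has_duplicates:
        raise ConfigError("duplicate probe or sample ids in beta matrix")
    return beta


def _discovery(sheet: pd.DataFrame) -> pd.DataFrame:
    disc = sheet[sheet["role"] == "discovery"]
    if disc.empty or disc["group"].nunique() < 2:
        raise DegenerateDesignError("discovery set must contain cases and controls")
    return disc


def compute_covariate_pcs(beta: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """First two principal-component scores of the selected samples.

    The sample x probe matrix is probe-centred and decomposed by SVD; the
    sign of each component is fixed so its largest-magnitude score is
    positive.  Returns a DataFrame (PC1, PC2) indexed by sample id.
    """
    samples = list(samples)
    if len(samples) < 3:
        raise InsufficientSamplesError("principal components need at least 3 samples")
    x = beta[samples].to_numpy(dtype=float).T  # samples x probes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :2] * s[:2]
    for j in range(scores.shape[1]):
        if scores[np.argmax(np.abs(scores[:, j])), j] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=samples, columns=["PC1", "PC2"])


def _trigamma(x: np.ndarray | float) -> np.ndarray:
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log variances to s0^2 * F(df, d0); return (d0, s0^2)."""
    ok = s2 > 0
    if not ok.any():
        return np.inf, float(s2.mean() if s2.size else 1.0)
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    if n < 2:
        return np.inf, float(s2[ok].mean())
    e_var = ((e - e_mean) ** 2).sum() / (n - 1) - float(_trigamma(df / 2.0))
    if e_var <= 0:
        # no excess dispersion beyond chi-square sampling noise: variances are
        # effectively exchangeable, so the prior is the plain mean variance
        return np.inf, float(s2[ok].mean())
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def differential_methylation(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-probe moderated-t differential methylation on discovery samples.

    Fits beta ~ intercept + group + covariates (default: PC1 and PC2 of
    the discovery samples) probe-wise, shrinks residual variances with the
    empirical-Bayes prior, and BH-adjusts the two-sided p-values.

    Returns a DataFrame indexed by probe with columns delta_beta,
    moderated_t, p, q; the prior (d0, s0^2) is stored in ``.attrs`` as
    ``df_prior`` and ``s2_prior``.  delta_beta is the raw case-minus-control
    mean difference.
    """
    validate_beta(beta)
    disc = _discovery(sheet)
    samples = list(disc["sample_id"])
    groups = disc.set_index("sample_id").loc[samples, "group"]
    case_ids = [s for s in samples if groups[s] == "case"]
    ctrl_ids = [s for s in samples if groups[s] == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise DegenerateDesignError("each discovery group needs at least 2 samples")
    if covariates is None:
        covariates = compute_covariate_pcs(beta, samples)
    covariates = covariates.loc[samples]

    y = beta[samples].to_numpy(dtype=float)  # probes x n
    n = len(samples)
    g = np.array([1.0 if groups[s] == "case" else 0.0 for s in samples])
    x = np.column_stack([np.ones(n), g, covariates.to_numpy(dtype=float)])
    p_cols = x.shape[1]
    if n <= p_cols:
        raise DegenerateDesignError("more model coefficients than discovery samples")
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = y @ (xtx_inv @ x.T).T  # probes x p
    resid = y - coef @ x.T
    df_resid = n - p_cols
    s2 = (resid**2).sum(axis=1) / df_resid
    v_group = xtx_inv[1, 1]

    d0, s0_2 = _fit_f_dist(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
    # total df capped at the pooled residual df across all probes
    df_total = min(df_resid + d0, len(s2) * df_resid)
    b = coef[:, 1]
    constant = np.ptp(y, axis=1) == 0.0
    denom = np.sqrt(s2_post * v_group)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(denom > 0, b / denom, 0.0)
    t_mod = np.where(constant, 0.0, t_mod)  # constant probes: t = 0 by convention
    pvals = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    delta = y[:, [samples.index(s) for s in case_ids]].mean(axis=1) - y[
        :, [samples.index(s) for s in ctrl_ids]
    ].mean(axis=1)
    out = pd.DataFrame(
        {
            "delta_beta": delta,
            "moderated_t": t_mod,
            "p": pvals,
            "q": qvals,
        },
        index=beta.index.rename("probe_id"),
    )
    out.attrs["df_prior"] = float(d0)
    out.attrs["s2_prior"] = float(s0_2)
    out.attrs["df_residual"] = float(df_resid)
    return out


def select_signature(
    stats: pd.DataFrame, q_max: float = 0.05, min_abs_delta: float = 0.05
) -> list[str]:
    """Signature probes: q <= q_max and |delta beta| >= min_abs_delta.

    Ordered by ascending q, then descending |delta beta|, then probe id.
    An empty selection is returned as-is.
    """
    if stats.empty:
        raise ValueError("probe statistics table is empty")
    mask = (stats["q"] <= q_max) & (stats["delta_beta"].abs() >= min_abs_delta)
    hits = stats[mask].copy()
    hits["_absd"] = hits["delta_beta"].abs()
    hits = hits.sort_values(
        by=["q", "_absd"], ascending=[True, False], kind="mergesort"
    )
    return list(hits.index)


@dataclass
class EpisignatureModel:
    """Serialised linear episignature classifier.

    score(x) = sigmoid(platt_slope * (weights . x + bias) + platt_intercept),
    computed on the signature-site beta vector x in probe order.
    """

    probe_ids: tuple[str, ...]
    weights: np.ndarray
    bias: float
    platt_slope: float
    platt_intercept: float

    def margins(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.weights + self.bias

    def scores(self, x: np.ndarray) -> np.ndarray:
        z = self.platt_slope * self.margins(x) + self.platt_intercept
        return 1.0 / (1.0 + np.exp(-z))

    def to_json_dict(self) -> dict:
        return {
            "probe_ids": list(self.probe_ids),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "platt_slope": self.platt_slope,
            "platt_intercept": self.platt_intercept,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "EpisignatureModel":
        return cls(
            probe_ids=tuple(d["probe_ids"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            platt_slope=float(d["platt_slope"]),
            platt_intercept=float(d["platt_intercept"]),
        )


class EpisignatureClassifier(BaseEstimator, ClassifierMixin):
    """Linear maximum-margin classifier with sigmoid score calibration.

    Fits a linear SVM on signature-site betas (samples x probes) and a
    Platt-style logistic map from training margins to [0, 1] scores;
    scores above 0.5 are case-like.

    Parameters
    ----------
    C : SVM soft-margin penalty (default 1.0).
    """

    def __init__(self, C: float = 1.0) -> None:
        self.C = C

    def fit(self, X, y) -> "EpisignatureClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            y = (y == "case").astype(int)
        else:
            y = y.astype(int)
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateDesignError("training set contains a single class")
        self.classes_ = classes
        svm = SVC(kernel="linear", C=self.C)
        svm.fit(X, y)
        margins = svm.decision_function(X)
        platt = LogisticRegression(C=1e3)
        platt.fit(margins.reshape(-1, 1), y)
        self.model_ = EpisignatureModel(
            probe_ids=tuple(f"f{i}" for i in range(X.shape[1])),
            weights=svm.coef_.ravel().copy(),
            bias=float(svm.intercept_[0]),
            platt_slope=float(platt.coef_[0, 0]),
            platt_intercept=float(platt.intercept_[0]),
        )
        return self

    def decision_function(self, X) -> np.ndarray:
        return self.model_.margins(np.asarray(X, dtype=float))

    def predict_score(self, X) -> np.ndarray:
        """Calibrated scores in [0, 1]; higher = more case-like."""
        return self.model_.scores(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) > 0.5).astype(int)


def train_classifier(
    beta: pd.DataFrame, sheet: pd.DataFrame, signature: Sequence[str], C: float = 1.0
) -> EpisignatureModel:
    """Train the episignature classifier on discovery samples at signature sites."""
    signature = list(signature)
    if not signature:
        raise ValueError("signature is empty")
    missing = [p for p in signature if p not in beta.index]
    if missing:
        raise MissingProbeError(missing)
    disc = _discovery(sheet)
    samples = list(disc["sample_id"])
    X = beta.loc[signature, samples].to_numpy(dtype=float).T
    y = (disc.set_index("sample_id").loc[samples, "group"] == "case").astype(int)
    est = EpisignatureClassifier(C=C).fit(X, y.to_numpy())
    model = est.model_
    model.probe_ids = tuple(signature)
    return model


def score_samples(
    model: EpisignatureModel, beta: pd.DataFrame, samples: Iterable[str] | None = None
) -> pd.DataFrame:
    """Score samples against an episignature model.

    Returns a DataFrame indexed by sample with columns score (in [0, 1])
    and label: "case-like" above 0.5, "not-case" below, "indeterminate"
    at exactly 0.5.
    """
    samples = list(samples) if samples is not None else list(beta.columns)
    missing = [p for p in model.probe_ids if p not in beta.index]
    if missing:
        raise MissingProbeError(missing)
    X = beta.loc[list(model.probe_ids), samples].to_numpy(dtype=float).T
    scores = model.scores(X)
    labels = np.where(
        scores > 0.5, "case-like", np.where(scores < 0.5, "not-case", "indeterminate")
    )
    return pd.DataFrame({"score": scores, "label": labels}, index=pd.Index(samples, name="sample_id"))


def synth_beta(
    n_probes: int = 2000,
    n_signature: int = 30,
    delta_beta: float = 0.10,
    noise_sd: float = 0.03,
    n_cases: int = 9,
    n_controls: int = 41,
    seed: int | None = None,
    n_validation_cases: int = 0,
    n_validation_controls: int = 0,
    n_test_other: int = 0,
    n_confounders: int = 2,
    confounder_sd: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Synthetic beta matrix with a planted differential-methylation signature.

    Background probes draw from probe-specific baselines in (0.1, 0.9) with
    Gaussian noise; at the planted probes, case samples are shifted by
    +delta_beta (baselines kept in (0.15, 0.75) so clipping to [0, 1] is
    negligible).  ``n_confounders`` latent sample-level factors (loading sd
    ``confounder_sd`` per probe) emulate the global age/sex/cell-composition
    structure that the covariate principal components are meant to absorb;
    they affect all samples independently of group.  ``n_test_other``
    generates case-role samples *without* the planted shift, emulating a
    molecularly distinct subgroup that does not carry the signature.
    Returns (beta, sample sheet, planted probe ids).
    """
    if n_signature > n_probes:
        raise ConfigError("n_signature cannot exceed n_probes")
    if delta_beta < 0 or noise_sd < 0:
        raise ConfigError("delta_beta and noise_sd must be >= 0")
    if min(n_cases, n_controls) < 2:
        raise ConfigError("need at least 2 discovery cases and controls")
    rng = np.random.default_rng(seed)
    probe_ids = [f"cg{i:06d}" for i in range(n_probes)]
    planted = [probe_ids[i] for i in rng.choice(n_probes, size=n_signature, replace=False)]
    planted_mask = np.isin(np.array(probe_ids), planted)
    baselines = rng.uniform(0.1, 0.9, size=n_probes)
    baselines[planted_mask] = rng.uniform(0.15, 0.75, size=n_signature)

    cols: list[str] = []
    rows_sheet: list[dict] = []
    shifted: list[bool] = []

    def add(prefix: str, count: int, group: str, role: str, carries: bool) -> None:
        for i in range(count):
            cols.append(f"{prefix}{i:03d}")
            rows_sheet.append(dict(sample_id=cols[-1], group=group, role=role))
            shifted.append(carries)

    add("C", n_cases, "case", "discovery", True)
    add("K", n_controls, "control", "discovery", False)
    add("VC", n_validation_cases, "case", "validation", True)
    add("VK", n_validation_controls, "control", "validation", False)
    add("T", n_test_other, "case", "test", False)

    n_samples = len(cols)
    values = baselines[:, None] + noise_sd * rng.standard_normal((n_probes, n_samples))
    if n_confounders > 0 and confounder_sd > 0:
        loadings = confounder_sd * rng.standard_normal((n_probes, n_confounders))
        factor_scores = rng.standard_normal((n_confounders, n_samples))
        values += loadings @ factor_scores
    shift_cols = np.array(shifted)
    values[np.ix_(planted_mask, shift_cols)] += delta_beta
    values = np.clip(values, 0.0, 1.0)
    beta = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=cols)
    sheet = pd.DataFrame(rows_sheet)
    return beta, sheet, planted
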