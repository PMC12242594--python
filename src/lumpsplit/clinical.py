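"""Exact contingency testing of clinical phenotype frequencies.

Each clinical feature yields a 2x2 table of affected/unaffected counts in
two patient groups (here, the C-terminal vs N-terminal truncation
subgroups of MN1).  Group differences are assessed by a two-tailed
Fisher's exact test — the two-sided p is the sum of hypergeometric point
probabilities, at fixed margins, of every table at most as probable as
the observed one (with a 1e-7 relative tolerance on the comparison) —
with a Bonferroni-adjusted significance level alpha/m across the m
features tested.

A packaged fixture ships the published frequency table of 56 individuals
with MN1 truncating variants; rows whose printed p-value is reproducible
under the convention above are marked ``verified``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import DegenerateTableError, InvalidCountError

__all__ = [
    "ContingencyTable",
    "fisher_two_tailed",
    "bonferroni_alpha",
    "compare_phenotypes",
    "load_mn1_counts",
]

_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (a, b) = group-1 affected/unaffected, (c, d) = group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InvalidCountError(f"count {name} must be a nonnegative integer")
        if self.a + self.b + self.c + self.d == 0:
            raise DegenerateTableError("all four counts are zero")

    @classmethod
    def from_fractions(
        cls, affected_1: int, total_1: int, affected_2: int, total_2: int
    ) -> "ContingencyTable":
        if affected_1 > total_1 or affected_2 > total_2:
            raise InvalidCountError("affected count exceeds its total")
        return cls(affected_1, total_1 - affected_1, affected_2, total_2 - affected_2)


def fisher_two_tailed(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    At fixed margins the table is determined by its top-left cell x; the
    p-value sums P(x) over every x whose point probability does not exceed
    the observed one by more than relative tolerance 1e-7.
    """
    n = t.a + t.b + t.c + t.d
    row1 = t.a + t.b
    col1 = t.a + t.c
    rv = hypergeom(n, row1, col1)
    lo = max(0, col1 - (t.c + t.d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(t.a)
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return min(p, 1.0)


def bonferroni_alpha(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-adjusted significance level alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise InvalidCountError(f"alpha must lie in (0, 1), got {alpha}")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise InvalidCountError(f"m must be a positive integer, got {m}")
    return alpha / m


def _parse_fraction(text: str) -> tuple[int, int]:
    try:
        num, den = str(text).split("/")
        return int(num), int(den)
    except (ValueError, AttributeError):
        raise InvalidCountError(f"malformed fraction {text!r}") from None


def compare_phenotypes(
    rows: pd.DataFrame, m: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Fisher-test every phenotype row and flag Bonferroni significance.

    ``rows`` needs columns feature, affected_1, total_1, affected_2,
    total_2 (or group fractions as "27/36" strings in columns group_1 and
    group_2).  ``m`` defaults to the number of rows.  Returns the table
    with p_value and significant columns appended.
    """
    df = rows.copy()
    if "affected_1" not in df.columns and "group_1" in df.columns:
        for g in ("1", "2"):
            parsed = df[f"group_{g}"].map(_parse_fraction)
            df[f"affected_{g}"] = [p[0] for p in parsed]
            df[f"total_{g}"] = [p[1] for p in parsed]
    m = int(m) if m is not None else len(df)
    cutoff = bonferroni_alpha(alpha, m)
    pvals = []
    for _, row in df.iterrows():
        try:
            table = ContingencyTable.from_fractions(
                int(row["affected_1"]),
                int(row["total_1"]),
                int(row["affected_2"]),
                int(row["total_2"]),
            )
        except (InvalidCountError, DegenerateTableError) as exc:
            raise InvalidCountError(
                f"row {row.get('feature', '?')!r}: {exc}"
            ) from exc
        pvals.append(fisher_two_tailed(table))
    df["p_value"] = pvals
    df["significant"] = df["p_value"] < cutoff
    return df


def load_mn1_counts() -> pd.DataFrame:
    """Packaged phenotype counts for the 56-individual MN1 truncation cohort.

    Columns: feature, affected_1/total_1 (C-terminal truncation group),
    affected_2/total_2 (N-terminal), printed_p (the published value as a
    string; "<0.0001" rows are bounds) and verified (False where the
    printed p is not reproducible under the enumeration convention).
    """
    with resources.files("lumpsplit.data").joinpath("mn1_table1.csv").open() as fh:
        return pd.read_csv(fh, dtype={"printed_p": str})
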