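"""Baseline-characteristics ("Table 1") comparisons between POCD and
NO-POCD patients: mean +/- SD with the two-sample t-test for continuous
variables, n (%) with the Pearson chi-square for categorical ones.

The t-test is computed from summary statistics so the same code path
serves raw cohorts and published summary rows.  The pooled-variance
variant is the default; Welch (Satterthwaite df) is available by flag.
Multi-category variables (e.g. surgery type) get a single r x 2
chi-square across all categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import chi_square_test
from .errors import DataError


def t_test_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample two-sided t-test from group summary statistics.

    ``pooled``: sp^2 = ((n1-1)sd1^2 + (n2-1)sd2^2)/(n1+n2-2) with
    df = n1+n2-2.  ``welch``: unpooled SE with Satterthwaite df.
    Returns (t, df, p).
    """
    if n1 < 2 or n2 < 2:
        raise DataError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise DataError("group SDs must be positive")
    v1, v2 = sd1 * sd1, sd2 * sd2
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        raise DataError(f"unknown t-test variant {variant!r}")
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square_from_counts(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, int, float]:
    """Pearson 2x2 chi-square (df = 1, no continuity correction) on two
    binomial counts k/n per group."""
    if n1 <= 0 or n2 <= 0:
        raise DataError("group totals must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise DataError("counts must satisfy 0 <= k <= n")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    return chi_square_test(obs)


def chi_square_multi(counts1, counts2) -> tuple[float, int, float]:
    """r x 2 chi-square across all categories of a multi-level variable."""
    obs = np.column_stack([counts1, counts2]).astype(float)
    return chi_square_test(obs)


@dataclass(frozen=True)
class VariableDef:
    """One roster entry: a cohort column and how to summarise it.

    kind ``continuous`` -> mean +/- SD + t-test; ``binary`` -> n (%) of
    ``positive_level`` + 2x2 chi-square; ``categorical`` -> per-level
    n (%) rows sharing a single r x 2 chi-square p.
    """

    name: str
    column: str
    kind: str  # continuous | binary | categorical
    positive_level: object = True


DEFAULT_VARIABLES = (
    VariableDef("Age (y)", "age", "continuous"),
    VariableDef("Sex (male)", "sex", "binary", positive_level="male"),
    VariableDef("Education (y)", "education_years", "continuous"),
)


@dataclass(frozen=True)
class GroupSummary:
    """One Table-1 row: formatted per-group summaries and the p-value."""

    variable: str
    kind: str
    group1: str  # formatted "mean +/- sd" or "n (pct)"
    group2: str
    statistic: float
    p: float


def _fmt_cont(x: pd.Series) -> str:
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"


def _fmt_count(k: int, n: int) -> str:
    pct = 100.0 * k / n if n else float("nan")
    return f"{k} ({pct:.1f})"


def table1_report(
    cohort: pd.DataFrame,
    outcomes: pd.DataFrame,
    variables: tuple[VariableDef, ...] = DEFAULT_VARIABLES,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Group-comparison table between POCD and NO-POCD patients.

    ``outcomes`` is the classifier output for one interval; only
    classifiable patients enter.  Returns one row per variable (one per
    level for categorical variables, sharing a joint p).
    """
    if outcomes["interval"].nunique() > 1:
        raise DataError("table1_report expects outcomes from a single interval")
    merged = cohort.merge(
        outcomes[outcomes["classifiable"]][["id", "pocd"]], on="id", how="inner"
    )
    g1 = merged[merged["pocd"]]
    g2 = merged[~merged["pocd"]]
    if len(g1) == 0 or len(g2) == 0:
        raise DataError("both POCD and NO-POCD groups must be non-empty")

    rows = []
    for var in variables:
        if var.column not in merged.columns:
            raise DataError(f"unknown cohort column {var.column!r}")
        x1, x2 = g1[var.column], g2[var.column]
        if var.kind == "continuous":
            if x1.std(ddof=1) == 0 and x2.std(ddof=1) == 0:
                t, p = 0.0, 1.0
            else:
                t, _, p = t_test_from_summary(
                    x1.mean(), x1.std(ddof=1), len(x1),
                    x2.mean(), x2.std(ddof=1), len(x2),
                    variant=variant,
                )
            rows.append(GroupSummary(var.name, var.kind, _fmt_cont(x1),
                                     _fmt_cont(x2), t, p))
        elif var.kind == "binary":
            k1 = int((x1 == var.positive_level).sum())
            k2 = int((x2 == var.positive_level).sum())
            if k1 + k2 == 0 or (len(x1) - k1) + (len(x2) - k2) == 0:
                stat, p = 0.0, 1.0
            else:
                stat, _, p = chi_square_from_counts(k1, len(x1), k2, len(x2))
            rows.append(GroupSummary(var.name, var.kind, _fmt_count(k1, len(x1)),
                                     _fmt_count(k2, len(x2)), stat, p))
        elif var.kind == "categorical":
            levels = sorted(set(x1.dropna()) | set(x2.dropna()))
            c1 = [int((x1 == lv).sum()) for lv in levels]
            c2 = [int((x2 == lv).sum()) for lv in levels]
            stat, _, p = chi_square_multi(c1, c2)
            for lv, a, b in zip(levels, c1, c2):
                rows.append(GroupSummary(f"{var.name}: {lv}", var.kind,
                                         _fmt_count(a, len(x1)),
                                         _fmt_count(b, len(x2)), stat, p))
        else:
            raise DataError(f"unknown variable kind {var.kind!r}")

    df = pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "kind": [r.kind for r in rows],
            f"POCD (n={len(g1)})": [r.group1 for r in rows],
            f"NO-POCD (n={len(g2)})": [r.group2 for r in rows],
            "statistic": [r.statistic for r in rows],
            "p": [r.p for r in rows],
            "p_display": [f"{r.p:.2f}" for r in rows],
        }
    )
    return df
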