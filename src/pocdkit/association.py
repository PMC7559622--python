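"""Single-SNP case-control association models.

Given a 2 (case status) x 3 (genotype AA/AG/GG) count table for a
biallelic SNP with effect allele G, this module computes:

* **allelic** model — 2x2 table of allele counts (each subject
  contributes two alleles) against case status;
* **dominant** model — carriers of at least one G allele vs AA;
* **recessive** model — GG homozygotes vs AA+AG;
* **additive** model — per-allele log-odds trend, a grouped-binomial
  logistic regression of status on G-allele count g in {0, 1, 2}, fit
  by Newton-Raphson; the reported OR is exp(beta) per allele.

For the 2x2 collapses the odds ratio is ad/bc with the Woolf
log-scale confidence interval exp(log OR +/- z * sqrt(1/a+1/b+1/c+1/d)).
When a 2x2 cell is zero the Haldane-Anscombe correction (+0.5 to all
four cells) is applied and flagged; a whole zero row or column leaves
the OR undefined and raises.  P-values come from the Pearson chi-square
test without continuity correction (a Yates-corrected variant is
available by flag).

A Hardy-Weinberg chi-square diagnostic (1 df, allele frequency
estimated from the counts) is provided for genotype quality control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ModelError

GENOTYPES = ("AA", "AG", "GG")
MODELS = ("allelic", "additive", "dominant", "recessive")

Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class GenotypeTable:
    """2 (status) x 3 (genotype) integer counts; the hub of every model.

    ``cases``/``noncases`` are (AA, AG, GG) counts; G is the effect allele.
    """

    cases: tuple[int, int, int]
    noncases: tuple[int, int, int]
    label: str = ""

    def __post_init__(self) -> None:
        for row in (self.cases, self.noncases):
            if len(row) != 3:
                raise DataError("genotype rows must have 3 entries (AA, AG, GG)")
            if any(c < 0 or int(c) != c for c in row):
                raise DataError("genotype counts must be non-negative integers")
        if sum(self.cases) == 0 or sum(self.noncases) == 0:
            raise DataError("both status rows must have positive totals")

    @classmethod
    def from_subjects(cls, genotype, status, label: str = "") -> "GenotypeTable":
        """Cross-tabulate per-subject G-allele counts (0/1/2) against a
        boolean case status; subjects with missing genotype are dropped."""
        g = pd.Series(genotype)
        s = pd.Series(status).astype(bool)
        keep = g.notna()
        g = g[keep].astype(int)
        s = s[keep.to_numpy()]
        if not g.isin([0, 1, 2]).all():
            raise DataError("genotypes must be 0, 1 or 2 G-allele copies")
        cases = tuple(int(((g == k) & s.to_numpy()).sum()) for k in (0, 1, 2))
        nonc = tuple(int(((g == k) & ~s.to_numpy()).sum()) for k in (0, 1, 2))
        return cls(cases=cases, noncases=nonc, label=label)

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.cases, self.noncases], dtype=float)

    @property
    def genotype_totals(self) -> tuple[int, int, int]:
        return tuple(int(a + b) for a, b in zip(self.cases, self.noncases))

    def allele_counts(self, row: tuple[int, int, int]) -> tuple[int, int]:
        """(A count, G count) for one status row."""
        aa, ag, gg = row
        return (2 * aa + ag, ag + 2 * gg)

    @property
    def pooled_genotypes(self) -> tuple[int, int, int]:
        return self.genotype_totals


@dataclass(frozen=True)
class Table2x2:
    """Exposure x status 2x2: a=exposed cases, b=exposed non-cases,
    c=unexposed cases, d=unexposed non-cases."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if any(x < 0 for x in (self.a, self.b, self.c, self.d)):
            raise DataError("2x2 cells must be non-negative")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with Woolf/Wald 95% CI and p-value for one model."""

    model: str
    or_point: float
    log_or: float
    se_log_or: float
    ci95: tuple[float, float]
    p: float
    correction_applied: bool = False

    @property
    def significant(self) -> bool:
        """CI excludes 1 (the no-association value)."""
        return self.ci95[0] > 1.0 or self.ci95[1] < 1.0


@dataclass(frozen=True)
class HWEResult:
    """Hardy-Weinberg chi-square goodness of fit (1 df)."""

    chi2: float
    df: int
    p: float
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    allele_freq_g: float


def collapse(table: GenotypeTable, model: str) -> Table2x2:
    """Collapse a 2x3 genotype table to the 2x2 of a genetic model.

    dominant: exposed = AG+GG carriers; recessive: exposed = GG;
    allelic: exposed = G alleles (two per subject, AG contributing one
    of each), rows remain case status.
    """
    aa_c, ag_c, gg_c = table.cases
    aa_n, ag_n, gg_n = table.noncases
    if model == "dominant":
        return Table2x2(ag_c + gg_c, ag_n + gg_n, aa_c, aa_n)
    if model == "recessive":
        return Table2x2(gg_c, gg_n, aa_c + ag_c, aa_n + ag_n)
    if model == "allelic":
        a_case, g_case = table.allele_counts(table.cases)
        a_non, g_non = table.allele_counts(table.noncases)
        return Table2x2(g_case, g_non, a_case, a_non)
    raise DataError(f"unknown collapsible model {model!r}")


def _haldane(t: Table2x2) -> tuple[Table2x2, bool]:
    """Add 0.5 to all four cells only when some cell is zero."""
    if min(t.cells) > 0:
        return t, False
    a, b, c, d = t.cells
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (
        b == 0 and d == 0
    ):
        raise ModelError("odds ratio undefined: a whole row or column is zero")
    return Table2x2(a + 0.5, b + 0.5, c + 0.5, d + 0.5), True


def chi_square_test(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2x2 or 2x3 table.

    Accepts a :class:`Table2x2`, :class:`GenotypeTable` or array-like.
    No continuity correction by default.  Emits a warning when any
    expected count is below 5.
    """
    if isinstance(table, Table2x2):
        obs = np.array([[table.a, table.c], [table.b, table.d]], dtype=float)
    elif isinstance(table, GenotypeTable):
        obs = table.counts
    else:
        obs = np.asarray(table, dtype=float)
    if obs.sum() == 0 or (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ModelError("chi-square undefined: zero marginal total")
    stat, p, df, expected = stats.chi2_contingency(obs, correction=yates)
    if (expected < 5).any():
        warnings.warn(
            "chi-square approximation dubious: expected cell count below 5",
            stacklevel=2,
        )
    return float(stat), int(df), float(p)


def odds_ratio_2x2(
    t: Table2x2, model: str = "", yates: bool = False
) -> ORResult:
    """Woolf odds ratio for a 2x2 exposure table.

    OR = ad/bc; SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d); 95% CI
    exp(log OR +/- 1.96 SE).  The p-value is the Pearson chi-square on
    the uncorrected counts.  The Haldane-Anscombe +0.5 adjustment is
    applied (and flagged) only when a cell is zero.
    """
    adj, corrected = _haldane(t)
    a, b, c, d = adj.cells
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se))
    _, _, p = chi_square_test(t, yates=yates)
    return ORResult(
        model=model or "2x2",
        or_point=math.exp(log_or),
        log_or=log_or,
        se_log_or=se,
        ci95=ci,
        p=p,
        correction_applied=corrected,
    )


def _grouped_logistic_loglik(beta0: float, beta1: float, g, cases, totals) -> float:
    """Grouped binomial log-likelihood of logit P(case) = beta0 + beta1*g
    (constant terms dropped)."""
    eta = beta0 + beta1 * np.asarray(g, dtype=float)
    cases = np.asarray(cases, dtype=float)
    totals = np.asarray(totals, dtype=float)
    return float(np.sum(cases * eta - totals * np.logaddexp(0.0, eta)))


def additive_trend_or(
    table: GenotypeTable,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> ORResult:
    """Per-allele odds ratio from a grouped-binomial logistic trend fit.

    Fits logit P(case) = b0 + b1*g with g in {0, 1, 2} by
    Newton-Raphson on the grouped likelihood (convergence when the step
    in b1 falls below ``tol``).  Reports exp(b1) with the Wald CI from
    the observed information and the Wald p-value.

    Raises :class:`ModelError` on rank deficiency (a single non-empty
    genotype class) or separation (fitted probabilities collapsing to
    0/1 so the MLE diverges).
    """
    totals = np.array(table.genotype_totals, dtype=float)
    cases = np.array(table.cases, dtype=float)
    nonzero = totals > 0
    if nonzero.sum() < 2:
        raise ModelError("additive fit rank-deficient: one genotype class only")
    g = np.array([0.0, 1.0, 2.0])[nonzero]
    y = cases[nonzero]
    n = totals[nonzero]
    X = np.column_stack([np.ones_like(g), g])

    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1.0 - p)
        if np.all(w < 1e-12):
            raise ModelError("additive fit separated: fitted probabilities at 0/1")
        grad = X.T @ (y - n * p)
        info = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise ModelError("additive fit: singular information matrix") from None
        beta = beta + step
        if abs(step[1]) < tol:
            break
    else:
        raise ModelError(
            "additive fit did not converge in "
            f"{max_iter} iterations (last step {step[1]:.3g}); "
            "possible separation"
        )
    if abs(beta[1]) > 30:
        raise ModelError("additive fit separated: |log OR| diverging")

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = n * p * (1.0 - p)
    info = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(info)
    se = math.sqrt(cov[1, 1])
    b1 = float(beta[1])
    wald = b1 / se
    pval = 2.0 * stats.norm.sf(abs(wald))
    return ORResult(
        model="additive",
        or_point=math.exp(b1),
        log_or=b1,
        se_log_or=se,
        ci95=(math.exp(b1 - Z95 * se), math.exp(b1 + Z95 * se)),
        p=float(pval),
        correction_applied=False,
    )


def hwe_chi_square(genotype_counts) -> HWEResult:
    """Hardy-Weinberg equilibrium chi-square on (AA, AG, GG) counts.

    The G-allele frequency p is estimated from the counts; expected
    counts are n*(q^2, 2pq, p^2); the statistic has 1 df (3 classes
    minus 1 minus 1 estimated frequency).  A monomorphic sample gives
    chi2 = 0 with a warning.
    """
    obs = tuple(int(c) for c in genotype_counts)
    if len(obs) != 3 or any(c < 0 for c in obs):
        raise DataError("genotype counts must be 3 non-negative integers")
    n = sum(obs)
    if n == 0:
        raise DataError("empty genotype sample")
    aa, ag, gg = obs
    p = (ag + 2 * gg) / (2.0 * n)  # G frequency
    q = 1.0 - p
    expected = (n * q * q, n * 2 * p * q, n * p * p)
    if p == 0.0 or p == 1.0:
        warnings.warn("monomorphic sample: HWE test degenerate", stacklevel=2)
        return HWEResult(0.0, 1, 1.0, obs, expected, p)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, expected))
    return HWEResult(
        chi2=float(chi2),
        df=1,
        p=float(stats.chi2.sf(chi2, 1)),
        observed=obs,
        expected=expected,
        allele_freq_g=p,
    )


# --- report formatting -------------------------------------------------------

def format_estimate(x: float) -> str:
    """2 decimals, 3 below 0.1 (so 0.078 keeps its precision)."""
    return f"{x:.3f}" if abs(x) < 0.1 else f"{x:.2f}"


def format_or_ci(r: ORResult) -> str:
    lo, hi = r.ci95
    return f"{format_estimate(r.or_point)} ({format_estimate(lo)}-{format_estimate(hi)})"


def fit_all_models(table: GenotypeTable, yates: bool = False) -> dict[str, ORResult]:
    """All four genetic models on one genotype table.

    A model that cannot be fit is reported as the error, without
    aborting the remaining models.
    """
    results: dict[str, ORResult] = {}
    for model in MODELS:
        try:
            if model == "additive":
                results[model] = additive_trend_or(table)
            else:
                results[model] = odds_ratio_2x2(
                    collapse(table, model), model=model, yates=yates
                )
        except ModelError as exc:
            results[model] = exc  # type: ignore[assignment]
    return results


def association_report(
    table7d: GenotypeTable,
    table3m: GenotypeTable | None = None,
    yates: bool = False,
) -> pd.DataFrame:
    """Full association report: every model at each timepoint, with
    allele/genotype counts, formatted OR (95% CI), p, and a significance
    flag (CI excludes 1), plus an HWE block per timepoint on the pooled
    genotypes."""
    rows = []
    tables = [("7 days", table7d)]
    if table3m is not None:
        tables.append(("3 months", table3m))
    for label, tab in tables:
        lab = tab.label or label
        a_case, g_case = tab.allele_counts(tab.cases)
        a_non, g_non = tab.allele_counts(tab.noncases)
        fits = fit_all_models(tab, yates=yates)
        for model in MODELS:
            r = fits[model]
            row = {
                "timepoint": lab,
                "model": model,
                "cases_AA": tab.cases[0],
                "cases_AG": tab.cases[1],
                "cases_GG": tab.cases[2],
                "noncases_AA": tab.noncases[0],
                "noncases_AG": tab.noncases[1],
                "noncases_GG": tab.noncases[2],
                "cases_A": a_case,
                "cases_G": g_case,
                "noncases_A": a_non,
                "noncases_G": g_non,
            }
            if isinstance(r, ORResult):
                row.update(
                    {
                        "OR": r.or_point,
                        "OR_95CI": format_or_ci(r),
                        "p": r.p,
                        "significant": r.significant,
                        "error": "",
                    }
                )
            else:
                row.update(
                    {"OR": math.nan, "OR_95CI": "", "p": math.nan,
                     "significant": False, "error": str(r)}
                )
            rows.append(row)
        hwe = hwe_chi_square(tab.pooled_genotypes)
        rows.append(
            {
                "timepoint": lab,
                "model": "HWE",
                "cases_AA": tab.pooled_genotypes[0],
                "cases_AG": tab.pooled_genotypes[1],
                "cases_GG": tab.pooled_genotypes[2],
                "OR": math.nan,
                "OR_95CI": f"chi2={hwe.chi2:.3f}, df={hwe.df}, p={hwe.p:.3f}",
                "p": hwe.p,
                "significant": hwe.p < 0.05,
                "error": "",
            }
        )
    return pd.DataFrame(rows)


def write_report_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
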