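"""Bundled example data: published summary counts from an elderly
non-cardiac-surgery cohort genotyped at BDNF rs6265 (A/G).

The study reported POCD incidences of 29/99 at day 7 and 18/99 at
month 3, and genotype/allele counts by POCD status at both follow-ups,
together with odds ratios per genetic model and an HWE statistic.  The
counts are the raw material for every model in
:mod:`pocdkit.association`; the published summary *values* are retained
here solely so that :func:`consistency_report` can audit them against
what the counts actually imply.

Several published summary values are arithmetically inconsistent with
the published counts (see :func:`consistency_report`); this package
always computes from counts and flags, rather than imitates, such
values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .association import (
    GenotypeTable,
    additive_trend_or,
    collapse,
    hwe_chi_square,
    odds_ratio_2x2,
)


def rs6265_day7_table() -> GenotypeTable:
    """Genotype counts (AA, AG, GG) by POCD status at postoperative day 7."""
    return GenotypeTable(cases=(10, 16, 3), noncases=(11, 39, 20), label="7 days")


def rs6265_month3_table() -> GenotypeTable:
    """Genotype counts by POCD status at postoperative month 3.

    Note: these rows sum to 25 and 74 subjects, not the reported month-3
    group sizes of 18 and 81; the published allele totals (50 and 148)
    confirm 25/74.  The table is reproduced as published and the
    inconsistency is surfaced by :func:`consistency_report`.
    """
    return GenotypeTable(cases=(8, 12, 5), noncases=(13, 43, 18), label="3 months")


#: POCD incidence numerators/denominators as published.
INCIDENCE = {"day7": (29, 99), "month3": (18, 99)}

#: Published summary values retained for auditing only.
PUBLISHED = {
    ("7 days", "allelic", "OR"): 0.67,
    ("7 days", "additive", "OR"): 0.41,
    ("7 days", "dominant", "OR"): 0.35,
    ("7 days", "recessive", "OR"): 0.29,
    ("3 months", "allelic", "OR"): 0.69,
    ("3 months", "additive", "OR"): 0.65,
    ("3 months", "dominant", "OR"): 0.45,
    ("3 months", "recessive", "OR"): 0.77,
    ("7 days", "allelic", "CI"): (0.47, 0.96),
    ("7 days", "additive", "CI"): (0.2, 0.84),
    ("7 days", "dominant", "CI"): (0.13, 0.96),
    ("7 days", "recessive", "CI"): (0.078, 1.06),
    ("3 months", "allelic", "CI"): (0.42, 1.13),
    ("3 months", "dominant", "CI"): (0.16, 1.27),
    ("3 months", "recessive", "CI"): (0.25, 2.37),
    ("7 days", "HWE", "chi2"): 4.402,
    ("3 months", "additive", "CI_text"): "0.32-0.302",
    ("3 months", "group_sizes", "n"): (18, 81),
}


@dataclass(frozen=True)
class Discrepancy:
    """One audited mismatch between a published value and the value the
    published counts imply."""

    timepoint: str
    quantity: str
    published: object
    computed: object
    note: str

    def __str__(self) -> str:
        return (
            f"[{self.timepoint}] {self.quantity}: published {self.published!r} "
            f"vs computed-from-counts {self.computed!r} -- {self.note}"
        )


def consistency_report(atol: float = 0.011) -> list[Discrepancy]:
    """Recompute every published summary value from the published counts
    and return the mismatches.

    ``atol`` defaults to one unit in the last printed digit, so that a
    value the source truncated rather than rounded (e.g. 0.7778 printed
    as 0.77) is not flagged as a discrepancy.

    Known findings on the bundled tables:

    * day-7 allelic OR: published 0.67, but the published allele counts
      give ad/bc = (22*61)/(79*36) ~= 0.47 (coincidentally the published
      CI lower bound); the published allelic CIs at both timepoints are
      likewise not the Woolf intervals the counts imply;
    * HWE statistic: published chi2 = 4.402 (p = .11), but the pooled
      day-7 genotype counts (21, 55, 23) give chi2 ~= 1.23, p ~= 0.27,
      and p = .11 at chi2 = 4.402 would require 2 df, which is not the
      standard 1-df HWE test;
    * month-3 additive CI printed as "0.32-0.302", an evident typo (the
      upper bound is below the lower bound and below the point
      estimate);
    * month-3 genotype rows sum to 25/74 subjects, not the stated
      month-3 POCD group sizes 18/81.
    """
    out: list[Discrepancy] = []
    tables = {"7 days": rs6265_day7_table(), "3 months": rs6265_month3_table()}
    for tp, tab in tables.items():
        for model in ("allelic", "dominant", "recessive"):
            pub = PUBLISHED.get((tp, model, "OR"))
            if pub is None:
                continue
            fit = odds_ratio_2x2(collapse(tab, model), model=model)
            if abs(fit.or_point - pub) > atol:
                out.append(
                    Discrepancy(
                        tp,
                        f"{model} OR",
                        pub,
                        round(fit.or_point, 2),
                        "published OR is not reproducible from the published counts",
                    )
                )
            pub_ci = PUBLISHED.get((tp, model, "CI"))
            if pub_ci is not None and any(
                abs(comp - p0) > atol for comp, p0 in zip(fit.ci95, pub_ci)
            ):
                out.append(
                    Discrepancy(
                        tp,
                        f"{model} 95% CI",
                        pub_ci,
                        tuple(round(v, 3) for v in fit.ci95),
                        "published CI is not the Woolf interval the published "
                        "counts imply",
                    )
                )
        pub = PUBLISHED.get((tp, "additive", "OR"))
        add_fit = additive_trend_or(tab)
        if abs(add_fit.or_point - pub) > atol:
            out.append(
                Discrepancy(
                    tp,
                    "additive OR",
                    pub,
                    round(add_fit.or_point, 2),
                    "published OR is not reproducible from the published counts",
                )
            )
        pub_ci = PUBLISHED.get((tp, "additive", "CI"))
        if pub_ci is not None and any(
            abs(comp - p0) > atol for comp, p0 in zip(add_fit.ci95, pub_ci)
        ):
            out.append(
                Discrepancy(
                    tp,
                    "additive 95% CI",
                    pub_ci,
                    tuple(round(v, 3) for v in add_fit.ci95),
                    "published CI is not the Wald interval the published "
                    "counts imply",
                )
            )

    # HWE on pooled day-7 patient genotypes.
    hwe = hwe_chi_square(tables["7 days"].pooled_genotypes)
    pub_chi2 = PUBLISHED[("7 days", "HWE", "chi2")]
    if abs(hwe.chi2 - pub_chi2) > 0.05:
        out.append(
            Discrepancy(
                "7 days",
                "HWE chi2",
                pub_chi2,
                round(hwe.chi2, 3),
                "published HWE statistic cannot be derived from any published "
                "genotype set; its p = .11 would imply 2 df",
            )
        )

    # Month-3 additive CI typo: upper bound below lower bound.
    ci_text = PUBLISHED[("3 months", "additive", "CI_text")]
    lo, hi = (float(x) for x in ci_text.split("-"))
    if hi < lo:
        out.append(
            Discrepancy(
                "3 months",
                "additive 95% CI",
                ci_text,
                tuple(round(v, 2) for v in additive_trend_or(tables["3 months"]).ci95),
                "published CI is malformed (upper < lower); evident typo",
            )
        )

    # Month-3 group-size mismatch.
    sizes = (sum(tables["3 months"].cases), sum(tables["3 months"].noncases))
    pub_sizes = PUBLISHED[("3 months", "group_sizes", "n")]
    if sizes != pub_sizes:
        out.append(
            Discrepancy(
                "3 months",
                "group sizes",
                pub_sizes,
                sizes,
                "month-3 genotype rows sum to fewer subjects than the stated "
                "POCD/NO-POCD group sizes; allele totals confirm the row sums",
            )
        )
    return out
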