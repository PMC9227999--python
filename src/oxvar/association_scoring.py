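"""Association-study category scoring with per-SNP normalization.

Each association-study record labels one (SNP, study) pair as ``strong``
(strongly related to sociality), ``possible`` or ``unrelated``.  Percentages
are computed per SNP first, then averaged unweighted over the SNPs of each
gene -- a SNP backed by 100 studies weighs the same as one backed by a
single study, which removes publication/replication bias toward
heavily-studied SNPs.  Gene pairs are compared with an uncorrected Pearson
chi-squared test on study counts (category vs rest); small expected cells
are flagged rather than continuity-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

CATEGORIES = ("strong", "possible", "unrelated")


def _validate(records: pd.DataFrame) -> None:
    bad = set(records["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    dup = records.duplicated(["snp_id", "study_id"])
    if dup.any():
        raise ValueError("duplicate (snp_id, study_id) records")


def per_snp_percentages(records: pd.DataFrame) -> pd.DataFrame:
    """Category percentage per SNP (rows sum to 100).

    ``records`` columns: snp_id, gene, study_id, category.
    """
    if records.empty:
        raise ValueError("no association records")
    _validate(records)
    counts = (records.groupby("snp_id")["category"]
              .value_counts().unstack(fill_value=0)
              .reindex(columns=list(CATEGORIES), fill_value=0))
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    genes = records.groupby("snp_id")["gene"].first()
    pct.insert(0, "gene", genes)
    return pct.reset_index()


def gene_level_means(per_snp: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of per-SNP percentages over each gene's SNPs."""
    return (per_snp.groupby("gene")[list(CATEGORIES)]
            .mean().reset_index())


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float
    n_a: int
    n_b: int
    small_expected: bool  # some expected cell < 1; no continuity correction applied


def chi_squared_gene_comparison(records: pd.DataFrame, gene_a: str, gene_b: str,
                                category: str = "strong",
                                collapse: bool = True) -> ChiSquaredResult:
    """Pearson chi-squared comparison of two genes' study-category proportions.

    Default is the 2x2 collapse (``category`` vs rest) on study counts,
    df = 1, no Yates correction.  ``collapse=False`` runs the 2x3 test over
    all three categories.
    """
    _validate(records)
    table_rows = []
    ns = []
    for gene in (gene_a, gene_b):
        sub = records[records["gene"] == gene]
        if sub.empty:
            raise ValueError(f"gene {gene!r} has no records")
        ns.append(len(sub))
        if collapse:
            k = int((sub["category"] == category).sum())
            table_rows.append([k, len(sub) - k])
        else:
            table_rows.append([int((sub["category"] == c).sum()) for c in CATEGORIES])
    res = stats.chi2_contingency(table_rows, correction=False)
    small = bool((res.expected_freq < 1).any())
    return ChiSquaredResult(float(res.statistic), int(res.dof), float(res.pvalue),
                            ns[0], ns[1], small)


def all_gene_comparisons(records: pd.DataFrame, category: str = "strong") -> pd.DataFrame:
    """Pairwise chi-squared tests for every gene pair (no multiplicity correction)."""
    genes = sorted(records["gene"].unique())
    rows = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            r = chi_squared_gene_comparison(records, a, b, category)
            rows.append({"gene_a": a, "gene_b": b, "statistic": r.statistic,
                         "df": r.df, "p": r.p_value, "n_a": r.n_a, "n_b": r.n_b,
                         "small_expected": r.small_expected})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "statistic", "df", "p",
                                       "n_a", "n_b", "small_expected"])
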