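"""Concordant/discordant signature calling and enrichment statistics.

A BP is *concordant* when the paired Wilcoxon signed-rank test on its L and
H single-cell expression vectors survives Benjamini-Hochberg correction at
alpha (0.05 by default): the L-H ordering is statistically consistent
across cells.  The same paired engine serves the generic two-group paired
comparison used elsewhere (the paired two-sided Mann-Whitney of figure
captions).  Gene-product (PC/NC) composition per state is scored with an
upper-tail hypergeometric test on the 4x4 state-by-category table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import StateAssignment
from .expression import SwappedBPMatrix

CATEGORIES = ("NC->NC", "NC->PC", "PC->NC", "PC->PC")

#: largest n at which the exact signed-rank null is used
EXACT_N = 25


def signed_rank_test(values_a, values_b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped before ranking.  The exact null is used
    for up to 25 informative pairs (when the absolute differences are
    tie-free); larger samples or tied ranks use the normal approximation
    with continuity correction.  All differences zero gives p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    method = "exact" if len(d) <= EXACT_N and len(np.unique(np.abs(d))) == len(d) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return float(res.pvalue)


#: the paired two-sided comparison used for L-vs-H feature contrasts
paired_compare = signed_rank_test


@dataclass
class ConcordanceCall:
    bp_id: str
    pvalue: float
    excluded: bool  # both genes zero in every cell


def concordance_test(bp_id: str, l_values, h_values) -> ConcordanceCall:
    """Raw (pre-adjustment) signed-rank test for one BP.

    BPs where both genes are zero in all cells are excluded from testing.
    """
    l = np.asarray(l_values, dtype=float)
    h = np.asarray(h_values, dtype=float)
    if not l.any() and not h.any():
        return ConcordanceCall(bp_id, float("nan"), True)
    return ConcordanceCall(bp_id, signed_rank_test(l, h), False)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_concordance(scbp: SwappedBPMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Test every BP, BH-adjust genome-wide, and call concordance.

    Returns a frame indexed by bp_id with columns ``pvalue``, ``padj``,
    ``concordant`` and ``excluded``; excluded BPs carry no call.
    """
    calls = [concordance_test(bp_id, *scbp.row(bp_id)) for bp_id in scbp.bp_ids]
    df = pd.DataFrame(
        {"bp_id": [c.bp_id for c in calls],
         "pvalue": [c.pvalue for c in calls],
         "excluded": [c.excluded for c in calls]}
    ).set_index("bp_id")
    df["padj"] = np.nan
    tested = ~df["excluded"]
    df.loc[tested, "padj"] = bh_adjust(df.loc[tested, "pvalue"].to_numpy())
    df["concordant"] = tested & (df["padj"] <= alpha)
    return df


def concordant_ratio(calls: pd.DataFrame, assignment: StateAssignment) -> pd.Series:
    """Fraction of concordant BPs per state (excluded BPs removed entirely)."""
    states = assignment.to_frame()["state"]
    merged = calls.join(states, how="inner")
    merged = merged[~merged["excluded"]]
    return merged.groupby("state")["concordant"].mean()


def hypergeom_pvalue(x: int, total: int, successes: int, sample: int) -> float:
    """Upper-tail hypergeometric enrichment p-value, P(X >= x).

    Drawing ``sample`` items from a population of ``total`` containing
    ``successes`` marked items.
    """
    return float(stats.hypergeom.sf(x - 1, total, successes, sample))


@dataclass
class GeneProductContingency:
    """4x4 state-by-gene-product counts with per-cell enrichment p-values."""

    counts: pd.DataFrame
    pvalues: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.pvalues <= self.alpha


def gene_product_enrichment(
    assignment: StateAssignment,
    categories: pd.Series,
    alpha: float = 0.05,
) -> GeneProductContingency:
    """Score gene-product composition per transcription state.

    ``categories`` maps bp_id to its L->H biotype category.  Each table
    cell C[i, j] is tested against the hypergeometric law
    h(x; N=grand total, k=column total, n=row total), upper tail.
    """
    states = assignment.to_frame()["state"]
    cat = categories.reindex(states.index)
    if cat.isna().any():
        raise KeyError(f"missing biotype category for {int(cat.isna().sum())} BPs")
    state_order = [s for s in ("BLE", "BWD", "BSD", "BND") if s in set(states)] or sorted(set(states))
    counts = (
        pd.crosstab(states, cat)
        .reindex(index=state_order, columns=list(CATEGORIES), fill_value=0)
    )
    total = int(counts.to_numpy().sum())
    pvals = counts.astype(float).copy()
    for st in counts.index:
        for cj in counts.columns:
            pvals.loc[st, cj] = hypergeom_pvalue(
                int(counts.loc[st, cj]),
                total,
                int(counts[cj].sum()),
                int(counts.loc[st].sum()),
            )
    return GeneProductContingency(counts, pvals, alpha)
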