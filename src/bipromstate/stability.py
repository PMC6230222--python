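"""RNA-stability outlier analysis from promoter histone marks.

A linear (OLS) model predicts a gene's average single-cell expression from
12 histone features: six histone-modification tracks, each summarized as
mean signal in a 2 kb bin upstream and a 2 kb bin downstream of the TSS
(log2(mean + 1) transformed).  Genes whose measured expression exceeds the
prediction (internally studentized residual > 1) are called *stable*,
genes below -1 *unstable*, the rest *neutral*; per-state enrichment of the
stable and unstable categories uses the upper-tail hypergeometric test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from statsmodels.stats.outliers_influence import OLSInfluence

from .annotation import GeneModel
from .concordance import hypergeom_pvalue
from .genomic import Coverage

CATEGORY_ORDER = ("stable", "unstable", "neutral")


def build_features(
    genes: list[GeneModel],
    hm_coverages: dict[str, Coverage],
    flank: int = 2000,
) -> pd.DataFrame:
    """Per-gene histone feature table: one column per track and flank.

    Columns are ordered ``<track>_up, <track>_down`` following the dict
    order of ``hm_coverages``; up/downstream are strand-aware.  Features
    are log2(mean per-base signal + 1).
    """
    rows = []
    for g in genes:
        tss, d = g.anchor_tss, g.direction
        if d == 1:
            up, down = (tss - flank, tss), (tss, tss + flank)
        else:
            up, down = (tss, tss + flank), (tss - flank, tss)
        row = {}
        for track, cov in hm_coverages.items():
            row[f"{track}_up"] = np.log2(cov.interval_mean(g.chrom, *up) + 1.0)
            row[f"{track}_down"] = np.log2(cov.interval_mean(g.chrom, *down) + 1.0)
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index([g.gene_id for g in genes], name="gene_id"))


def mean_expression_response(expression: pd.DataFrame) -> pd.Series:
    """log2(mean TPM over cells + 1) per gene: the regression response."""
    return np.log2(expression.mean(axis=1) + 1.0)


class StabilityModel(RegressorMixin, BaseEstimator):
    """OLS expression model with studentized-residual stability calls.

    Parameters
    ----------
    threshold : |studentized residual| above which a gene is called
        stable (positive residual) or unstable (negative), default 1.0

    Attributes
    ----------
    coef_, intercept_ : fitted OLS parameters
    studentized_residuals_ : internally studentized residuals per gene
    calls_ : "stable" / "unstable" / "neutral" per training gene
    results_ : the underlying statsmodels results object
    """

    def __init__(self, threshold: float = 1.0):
        self.threshold = threshold

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[0] < X.shape[1] + 2:
            raise ValueError(
                f"need at least {X.shape[1] + 2} rows to fit and studentize, got {X.shape[0]}"
            )
        design = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            names = getattr(self, "feature_names_in_", np.arange(X.shape[1]).astype(str))
            # identify columns whose removal restores full rank
            collinear = []
            for j in range(X.shape[1]):
                sub = np.delete(design, j + 1, axis=1)
                if np.linalg.matrix_rank(sub) == rank:
                    collinear.append(str(names[j]))
            raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
        self.results_ = sm.OLS(y, design).fit()
        self.intercept_ = float(self.results_.params[0])
        self.coef_ = np.asarray(self.results_.params[1:])
        scale = np.sqrt(self.results_.mse_resid)
        if scale <= 1e-10 * max(1.0, float(np.std(y))):
            # numerically exact fit: studentizing would divide rounding noise
            # by rounding noise; residuals are zero by definition
            self.studentized_residuals_ = np.zeros(len(y))
        else:
            resid = OLSInfluence(self.results_).resid_studentized_internal
            self.studentized_residuals_ = np.nan_to_num(np.asarray(resid), nan=0.0)
        self.calls_ = np.where(
            self.studentized_residuals_ > self.threshold, "stable",
            np.where(self.studentized_residuals_ < -self.threshold, "unstable", "neutral"),
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "results_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_


def fit_stability(features: pd.DataFrame, response: pd.Series, threshold: float = 1.0):
    """Fit the stability model and tabulate per-gene calls.

    Returns ``(model, calls)`` where ``calls`` is indexed by gene with
    columns ``studentized_residual`` and ``category``.
    """
    response = response.reindex(features.index)
    model = StabilityModel(threshold=threshold).fit(features, response.to_numpy())
    calls = pd.DataFrame(
        {
            "studentized_residual": model.studentized_residuals_,
            "category": model.calls_,
        },
        index=features.index,
    )
    return model, calls


def stability_enrichment(
    calls: pd.DataFrame, gene_states: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of stable/unstable per state.

    Returns one row per state with the category counts, the enrichment
    p-values ``p_stable`` / ``p_unstable``, and significance flags at
    ``alpha``.
    """
    st = gene_states.reindex(calls.index)
    if st.isna().any():
        raise KeyError(f"missing state for {int(st.isna().sum())} genes")
    total = len(calls)
    n_cat = {c: int((calls["category"] == c).sum()) for c in CATEGORY_ORDER}
    rows = []
    for state, sub in calls.groupby(st):
        row = {"state": state, "n_genes": len(sub)}
        for c in CATEGORY_ORDER:
            row[f"n_{c}"] = int((sub["category"] == c).sum())
        for c in ("stable", "unstable"):
            row[f"p_{c}"] = hypergeom_pvalue(row[f"n_{c}"], total, n_cat[c], len(sub))
            row[f"significant_{c}"] = row[f"p_{c}"] <= alpha
        rows.append(row)
    return pd.DataFrame(rows).set_index("state")
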