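"""Clustering BPs into transcription states.

The scBP matrix, log2(TPM + pseudocount) transformed, is clustered by
agglomerative hierarchical clustering with complete linkage and Euclidean
distance; the tree is cut at a fixed number of clusters (four by default).
Clusters are then named BLE / BWD / BSD / BND by a deterministic rule on
their mean low-half and high-half expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .expression import SwappedBPMatrix

logger = logging.getLogger(__name__)

STATE_NAMES = ("BLE", "BWD", "BSD", "BND")


def name_states(labels: np.ndarray, X_log: np.ndarray) -> dict[int, str]:
    """Map the four cluster indices to state names.

    With mL, mH the cluster means of the log-transformed L and H halves:
    the cluster with the lowest mL + mH is BLE; of the rest, the smallest
    mH - mL is BND and the largest is BSD (a tie on mH - mL sends the
    cluster with the higher mH to BSD, and is logged); the remaining
    cluster is BWD.
    """
    uniq = np.unique(labels)
    if len(uniq) != 4:
        raise ValueError("state naming requires exactly 4 clusters")
    n = X_log.shape[1] // 2
    stats = {}
    for k in uniq:
        rows = X_log[labels == k]
        m_l = rows[:, :n].mean()
        m_h = rows[:, n:].mean()
        stats[int(k)] = (m_l, m_h)
    ble = min(stats, key=lambda k: stats[k][0] + stats[k][1])
    rest = [k for k in stats if k != ble]
    diffs = {k: stats[k][1] - stats[k][0] for k in rest}
    srt = sorted(rest, key=lambda k: (diffs[k], stats[k][1]))
    if len({round(diffs[k], 12) for k in rest}) < len(rest):
        logger.info("tie on mH - mL during state naming; broken by higher mH -> BSD")
    bnd, bwd, bsd = srt[0], srt[1], srt[2]
    return {ble: "BLE", bnd: "BND", bwd: "BWD", bsd: "BSD"}


class BPStateClustering(ClusterMixin, BaseEstimator):
    """Hierarchical transcription-state clustering of the scBP matrix.

    Parameters
    ----------
    n_states : number of clusters to cut the dendrogram into (4 = the
        standard BLE/BWD/BSD/BND resolution; names are only assigned at 4)
    pseudocount : added to TPM before the log2 transform
    assign_names : name the four clusters with the deterministic
        mean-expression rule (ignored when ``n_states != 4``)

    Attributes
    ----------
    labels_ : cluster index per row (0-based)
    state_labels_ : state name per row (only when named)
    linkage_ : scipy linkage matrix of the complete-linkage tree
    name_map_ : cluster index -> state name
    """

    def __init__(self, n_states: int = 4, pseudocount: float = 1.0, assign_names: bool = True):
        self.n_states = n_states
        self.pseudocount = pseudocount
        self.assign_names = assign_names

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        if X.shape[0] < self.n_states:
            raise ValueError(f"need at least n_states={self.n_states} rows, got {X.shape[0]}")
        X_log = np.log2(X + self.pseudocount)
        self.linkage_ = linkage(X_log, method="complete", metric="euclidean")
        raw = fcluster(self.linkage_, t=self.n_states, criterion="maxclust")
        self.labels_ = raw - 1
        self.name_map_ = None
        self.state_labels_ = None
        if self.assign_names and self.n_states == 4 and len(np.unique(self.labels_)) == 4:
            self.name_map_ = name_states(self.labels_, X_log)
            self.state_labels_ = np.array([self.name_map_[int(k)] for k in self.labels_])
        elif self.assign_names and self.n_states != 4:
            logger.info("n_states != 4: state naming skipped, numeric labels kept")
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class StateAssignment:
    """Per-BP state labels plus the linkage record that produced them."""

    bp_ids: list[str]
    cluster_index: np.ndarray
    states: list[str]  # state name, or stringified cluster index
    linkage: np.ndarray
    pseudocount: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bp_id": self.bp_ids, "state": self.states, "cluster": self.cluster_index}
        ).set_index("bp_id")

    def state_of(self, bp_id: str) -> str:
        return self.states[self.bp_ids.index(bp_id)]


def cluster_states(
    scbp: SwappedBPMatrix, k: int = 4, pseudocount: float = 1.0
) -> StateAssignment:
    """Functional wrapper over :class:`BPStateClustering` for scBP inputs."""
    est = BPStateClustering(n_states=k, pseudocount=pseudocount).fit(scbp.values)
    if est.state_labels_ is not None:
        states = list(est.state_labels_)
    else:
        states = [str(int(c)) for c in est.labels_]
    return StateAssignment(list(scbp.bp_ids), est.labels_, states, est.linkage_, pseudocount)


def bp_correlation(l_values, h_values) -> float:
    """Pearson r between a BP's L- and H-gene expression across cells.

    Returns NaN (undefined) when either gene has zero variance or there
    are fewer than 3 cells.
    """
    l_values = np.asarray(l_values, dtype=float)
    h_values = np.asarray(h_values, dtype=float)
    if l_values.shape != h_values.shape:
        raise ValueError("L and H vectors must have equal length")
    if len(l_values) < 3:
        raise ValueError("Pearson correlation needs at least 3 cells")
    if np.ptp(l_values) == 0 or np.ptp(h_values) == 0:
        return float("nan")
    return float(pearsonr(l_values, h_values).statistic)


def correlation_table(scbp: SwappedBPMatrix) -> pd.DataFrame:
    """Per-BP L-H Pearson correlation over cells; NaN where undefined."""
    rows = []
    for i, bp_id in enumerate(scbp.bp_ids):
        l, h = scbp.l_half[i], scbp.h_half[i]
        defined = np.ptp(l) > 0 and np.ptp(h) > 0
        rows.append({
            "bp_id": bp_id,
            "pearson_r": bp_correlation(l, h) if defined else float("nan"),
            "defined": defined,
        })
    return pd.DataFrame(rows).set_index("bp_id")
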