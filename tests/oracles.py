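"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct definition (enumeration,
per-base counting, naive agglomeration) without touching the library code
paths it checks.
"""

from itertools import combinations, product

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata


def signed_rank_exact_p(diffs) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n sign
    patterns of the observed absolute differences (zeros dropped)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array([
        sum(r for r, m in zip(ranks, mask) if m) for mask in product((0, 1), repeat=n)
    ])
    p = 2 * min((w_all <= w_obs).mean(), (w_all >= w_obs).mean())
    return min(p, 1.0)


def hypergeom_tail_p(x: int, total: int, successes: int, sample: int) -> float:
    """P(X >= x) by direct summation of the hypergeometric PMF."""
    from math import comb

    denom = comb(total, sample)
    upper = min(successes, sample)
    return sum(
        comb(successes, k) * comb(total - successes, sample - k) for k in range(x, upper + 1)
    ) / denom


def complete_linkage_heights(X) -> list[float]:
    """Merge heights of naive O(n^3) complete-linkage agglomeration."""
    X = np.asarray(X, dtype=float)
    D = squareform(pdist(X))
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(X))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            h = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters.pop(a) + clusters.pop(b)
    return heights


def per_base_chromscore(segments, w_start: int, w_end: int, collapse: dict) -> dict:
    """ChromScore fractions by marking every base of the window."""
    labels = {}
    for s, e, lab in segments:
        for pos in range(max(s, w_start), min(e, w_end)):
            labels[pos] = collapse.get(lab, lab)
    out = {"TSS": 0, "Enhancer": 0, "Repressed": 0, "Others": 0}
    for pos in range(w_start, w_end):
        out[labels.get(pos, "Others")] += 1
    n = w_end - w_start
    return {k: v / n for k, v in out.items()}


def per_base_exon_union_length(exon_sets) -> int:
    """Exonic-union length by marking individual bases."""
    marked: set[int] = set()
    for s, e in exon_sets:
        marked.update(range(s, e))
    return len(marked)


def pearson_direct(x, y) -> float:
    """Pearson r by the textbook summation formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x**2).sum() - sx**2) * np.sqrt(n * (y**2).sum() - sy**2)
    return num / den
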