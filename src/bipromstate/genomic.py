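"""Low-level genomic primitives: interval arithmetic and step-function coverage.

All internal coordinates are 0-based, half-open ``[start, end)``.  bedGraph
files on disk use the same convention; GTF conversion happens in
:mod:`bipromstate.annotation`.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or book-ended half-open intervals.

    Touching intervals (``end == next start``) are coalesced, so the result
    is the minimal sorted set of disjoint intervals with the same union.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"interval end < start: ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[Interval]) -> int:
    """Total number of bases covered by the union of the intervals."""
    return sum(e - s for s, e in merge_intervals(intervals))


class Coverage:
    """Step-function coverage over chromosomes, queryable by interval sum.

    Stores, per chromosome, sorted non-overlapping ``(start, end, value)``
    runs.  ``interval_sum`` returns the integral of the step function over a
    query interval (bases outside any run count as zero), which is the
    read-count analogue used for all spatial binning.
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping bedGraph runs on {chrom}")
            self._runs[chrom] = (starts, ends, values)

    @classmethod
    def from_bedgraph(cls, path) -> "Coverage":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            comment="#",
            dtype={"chrom": str},
        )
        runs = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            runs[str(chrom)] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["value"].to_numpy(),
            )
        return cls(runs)

    @classmethod
    def from_contributions(
        cls, contributions: dict[str, Sequence[tuple[int, int, float]]]
    ) -> "Coverage":
        """Build coverage from possibly-overlapping additive contributions.

        Overlapping pieces sum, as when two nearby genomic windows both
        deposit signal over the same bases.
        """
        runs = {}
        for chrom, pieces in contributions.items():
            pieces = [p for p in pieces if p[1] > p[0]]
            if not pieces:
                continue
            starts = np.array([p[0] for p in pieces], dtype=np.int64)
            ends = np.array([p[1] for p in pieces], dtype=np.int64)
            vals = np.array([p[2] for p in pieces], dtype=np.float64)
            edges = np.unique(np.concatenate([starts, ends]))
            # accumulate value deltas at breakpoints
            delta = np.zeros(len(edges), dtype=np.float64)
            i0 = np.searchsorted(edges, starts)
            i1 = np.searchsorted(edges, ends)
            np.add.at(delta, i0, vals)
            np.subtract.at(delta, i1, vals)
            level = np.cumsum(delta)[:-1]
            keep = level != 0
            runs[chrom] = (edges[:-1][keep], edges[1:][keep], level[keep])
        return cls(runs)

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Integral of coverage over ``[start, end)``."""
        if end <= start:
            return 0.0
        if chrom not in self._runs:
            return 0.0
        starts, ends, values = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        s = starts[lo:hi]
        e = ends[lo:hi]
        v = values[lo:hi]
        overlap = np.minimum(e, end) - np.maximum(s, start)
        overlap = np.clip(overlap, 0, None)
        return float(np.dot(overlap, v))

    def bin_sums(self, chrom: str, edges: Sequence[int]) -> np.ndarray:
        """Coverage integral over the contiguous bins defined by ``edges``."""
        edges = np.asarray(edges, dtype=np.int64)
        return np.array(
            [self.interval_sum(chrom, int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
        )

    def interval_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base coverage over ``[start, end)`` (0 for empty range)."""
        if end <= start:
            return 0.0
        return self.interval_sum(chrom, start, end) / (end - start)

    def total(self) -> float:
        """Genome-wide integral (the library size for depth scaling)."""
        out = 0.0
        for starts, ends, values in self._runs.values():
            out += float(np.dot(ends - starts, values))
        return out

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._runs):
                starts, ends, values = self._runs[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
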