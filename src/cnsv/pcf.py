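"""Piecewise-constant fitting (Potts filter) by exact dynamic programming.

Partitions an ordered numeric series into contiguous segments
minimizing

    sum over segments of within-segment squared deviation from the
    segment mean  +  gamma * (number of segments)

The dynamic program over cut points finds the exact global minimizer in
O(n^2) time using prefix sums; ties are broken toward fewer segments so
the result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PCFSegmentation:
    """Optimal partition of a series into contiguous segments.

    ``boundaries`` holds the start index of every segment (the first is
    always 0); segment i covers ``boundaries[i] .. boundaries[i+1]-1``.
    """

    boundaries: tuple[int, ...]
    n: int
    objective: float
    gamma: float
    kmin: int | None = field(default=None)

    @property
    def n_segments(self) -> int:
        return len(self.boundaries)

    def segments(self) -> list[tuple[int, int]]:
        """(start, stop) half-open index pairs covering the series."""
        edges = list(self.boundaries) + [self.n]
        return [(edges[i], edges[i + 1]) for i in range(len(self.boundaries))]


def segment_cost(values: np.ndarray, start: int, stop: int) -> float:
    """Within-segment sum of squared deviations for values[start:stop]."""
    v = values[start:stop]
    return float(np.sum((v - v.mean()) ** 2))


def pcf_segment(values, gamma: float) -> PCFSegmentation:
    """Exact penalized least-squares segmentation of an ordered series.

    Parameters
    ----------
    values
        Ordered numeric series (for SV clustering: log10(IMD + 1) of the
        breakpoints of one chromosome, in position order).
    gamma
        Penalty added per segment; larger values yield fewer segments.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D series")
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    n = v.size
    s1 = np.concatenate(([0.0], np.cumsum(v)))
    s2 = np.concatenate(([0.0], np.cumsum(v * v)))

    def cost(i: int, j: int) -> float:
        # SSE of v[i:j]
        m = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / m

    # best[j]: minimal objective for v[:j]; nseg[j]: its segment count
    # (fewest among optimal); prev[j]: start index of the last segment.
    best = np.full(n + 1, np.inf)
    nseg = np.zeros(n + 1, dtype=int)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = 0.0
    for j in range(1, n + 1):
        for i in range(j):
            cand = best[i] + cost(i, j) + gamma
            cand_nseg = nseg[i] + 1
            if cand < best[j] or (cand == best[j] and cand_nseg < nseg[j]):
                best[j] = cand
                nseg[j] = cand_nseg
                prev[j] = i
    starts: list[int] = []
    j = n
    while j > 0:
        starts.append(prev[j])
        j = prev[j]
    starts.reverse()
    return PCFSegmentation(
        boundaries=tuple(starts), n=n, objective=float(best[n]), gamma=gamma
    )
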