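"""Shared helpers: an exhaustive PCF oracle and SV set builders."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cnsv.sv import SVRecord


def exhaustive_pcf(values, gamma: float) -> tuple[float, int]:
    """Brute-force global minimum of the penalized least-squares objective.

    Enumerates every one of the 2^(n-1) contiguous segmentations and
    returns (minimal objective, fewest segments among minimizers).
    Independent of the dynamic program it checks; only feasible for
    small n.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    best = (np.inf, n + 1)
    for mask in itertools.product((0, 1), repeat=n - 1):
        starts = [0] + [i + 1 for i, cut in enumerate(mask) if cut]
        edges = starts + [n]
        obj = gamma * len(starts)
        for a, b in zip(edges, edges[1:]):
            seg = v[a:b]
            obj += float(np.sum((seg - seg.mean()) ** 2))
        key = (obj, len(starts))
        if key < best:
            best = key
    return best


def tight_cluster_sv_set(k: int, spacing: int = 1_000) -> list[SVRecord]:
    """k translocation mates `spacing` bp apart on chr1, far mates and
    extra background spaced 10 Mb on other chromosomes."""
    recs = []
    for i in range(k):
        recs.append(SVRecord("S", "1", 1_000_000 + spacing * i,
                             "2", 10_000_000 * (i + 1), "+", "-", "trans"))
    for i in range(6):
        p = 10_000_000 * (i + 1)
        recs.append(SVRecord("S", "3", p, "3", p + 9_000_000, "+", "+", "del"))
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
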