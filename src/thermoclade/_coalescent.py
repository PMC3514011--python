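"""Minimal Kingman coalescent machinery.

Used by the Tajima's D simulated null (which only needs, for each branch
segment, its length and the number of leaves it subtends) and by the synthetic
sequence generator (which needs the full genealogy).  Times are in units of
2N generations, so the expected coalescence time of a pair is 1.
"""

from __future__ import annotations

import numpy as np


def coalescent_segments(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Branch segments of one neutral genealogy for ``n`` samples.

    Returns ``(sizes, lengths)``: for every lineage present during every
    coalescent epoch, the number of leaves it subtends and the epoch duration.
    A mutation falling uniformly on the tree lands on a segment with
    probability proportional to its length and is carried by ``size`` leaves.
    """
    sizes = [1] * n
    seg_sizes: list[int] = []
    seg_lens: list[float] = []
    k = n
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        seg_sizes.extend(sizes)
        seg_lens.extend([t] * k)
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        sizes[i] = sizes[i] + sizes[j]
        del sizes[j]
        k -= 1
    return np.asarray(seg_sizes), np.asarray(seg_lens)


def sample_genealogy(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random-topology Kingman genealogy for ``n`` samples.

    Returns ``(parent, blen)`` over ``2n - 1`` nodes: leaves are ``0..n-1``,
    internal nodes ``n..2n-2`` in coalescence order, the root is the last
    node (parent ``-1``).  ``blen[v]`` is the branch length above ``v`` in
    units of 2N generations.
    """
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=int)
    node_time = np.zeros(total)
    active = list(range(n))
    t = 0.0
    nxt = n
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        a, b = active[i], active[j]
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        active[i] = nxt
        del active[j]
        nxt += 1
        k -= 1
    blen = np.zeros(total)
    for v in range(total - 1):
        blen[v] = node_time[parent[v]] - node_time[v]
    return parent, blen
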