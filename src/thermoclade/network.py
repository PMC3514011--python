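"""Median-joining haplotype networks and the statistical-parsimony limit.

A median-joining network starts from the epsilon-relaxed minimum spanning
network (MSN) on Hamming distances between haplotypes and iteratively adds
median (Steiner) vectors — columnwise consensus sequences of connectable
triplets — whenever doing so reduces the cost of the network, then prunes
median vectors that end up with fewer than three neighbours.  With epsilon=0
and tree-like distances the result contains a minimum spanning tree of the
observed haplotypes and no median vectors are needed.

Edges are annotated with a confidence flag from a statistical-parsimony
connection limit: the largest number of mutational steps for which a
connection is judged free of superimposed substitutions with probability
exceeding a chosen level (95% by convention), computed from the analysed
window length.  See :func:`parsimony_probability` for the finite-sites model
used.

Character states are restricted to A/C/G/T; ambiguous columns must be masked
upstream (see :func:`thermoclade.seq_core.collapse_haplotypes`).
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .errors import AlignmentError, DataError
from .seq_core import HaplotypeTable

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class NetNode:
    node_id: str
    sequence: str
    frequency: int  # 0 for median vectors
    counts_by_population: Mapping[str, int]
    is_median: bool


@dataclass(frozen=True)
class NetEdge:
    source: str
    target: str
    steps: int
    confident: bool = True


@dataclass
class HaploNetwork:
    nodes: list[NetNode]
    edges: list[NetEdge] = field(default_factory=list)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node.node_id,
                sequence=node.sequence,
                frequency=node.frequency,
                is_median=node.is_median,
            )
        for e in self.edges:
            g.add_edge(e.source, e.target, steps=e.steps, confident=e.confident)
        return g

    def total_cost(self) -> int:
        return sum(e.steps for e in self.edges)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))

    def write_edge_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "steps", "confident"])
            for e in self.edges:
                writer.writerow([e.source, e.target, e.steps, e.confident])

    def write_node_csv(self, path: str | Path) -> None:
        pops = sorted(
            {p for n in self.nodes for p in n.counts_by_population}
        )
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["node_id", "is_median", "frequency", *pops])
            for n in self.nodes:
                writer.writerow(
                    [n.node_id, n.is_median, n.frequency]
                    + [n.counts_by_population.get(p, 0) for p in pops]
                )


# ---------------------------------------------------------------------------
# median-joining construction
# ---------------------------------------------------------------------------

def _hamming_matrix(seqs: list[str]) -> np.ndarray:
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2)


def _connection_levels(d: np.ndarray) -> np.ndarray:
    """Single-linkage merge height for every pair (the smallest distance
    threshold at which the two items fall in one connected component)."""
    n = d.shape[0]
    cl = np.zeros((n, n), dtype=d.dtype)
    comp = list(range(n))
    for delta in sorted(set(d[np.triu_indices(n, 1)].tolist())):
        pairs = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if d[i, j] <= delta and comp[i] != comp[j]
        ]
        for i, j in pairs:
            if comp[i] == comp[j]:
                continue
            old, new = comp[j], comp[i]
            for k in range(n):
                if comp[k] == old:
                    comp[k] = new
        for i in range(n):
            for j in range(i + 1, n):
                if cl[i, j] == 0 and i != j and comp[i] == comp[j]:
                    cl[i, j] = cl[j, i] = delta
    return cl


def _msn_links(d: np.ndarray, epsilon: int) -> list[tuple[int, int]]:
    """Feasible links of the epsilon-relaxed minimum spanning network:
    pairs whose distance is within epsilon of their single-linkage
    connection level."""
    n = d.shape[0]
    cl = _connection_levels(d)
    return [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if d[i, j] <= cl[i, j] + epsilon
    ]


def _quasi_medians(u: str, v: str, w: str, max_branch: int = 4) -> list[str]:
    """Columnwise consensus sequences of a triplet.

    Columns where at least two sequences agree take the majority state;
    columns where all three differ branch into one candidate per observed
    state (capped at ``3**max_branch`` candidates; beyond the cap the
    tri-allelic columns keep the first sequence's state)."""
    fixed: list[str] = []
    branching: list[tuple[int, tuple[str, str, str]]] = []
    for pos, (a, b, c) in enumerate(zip(u, v, w)):
        if a == b or a == c:
            fixed.append(a)
        elif b == c:
            fixed.append(b)
        else:
            fixed.append(a)  # placeholder, may branch below
            branching.append((pos, (a, b, c)))
    if not branching or len(branching) > max_branch:
        return ["".join(fixed)]
    out = []
    for states in itertools.product(*(st for _, st in branching)):
        seq = list(fixed)
        for (pos, _), s in zip(branching, states):
            seq[pos] = s
        out.append("".join(seq))
    return out


def _mst_cost(d: np.ndarray) -> int:
    g = nx.Graph()
    n = d.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=int(d[i, j]))
    return int(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
    )


def median_joining(
    haps: HaplotypeTable, epsilon: int = 0, max_rounds: int = 50
) -> HaploNetwork:
    """Build a median-joining network from a haplotype table.

    Tie-breaking is deterministic: candidate links and medians are processed
    in lexicographic order of (steps, smaller node index, larger node index),
    so the output does not depend on input order beyond haplotype identity.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    observed = [h.sequence for h in haps.haplotypes]
    if len({len(s) for s in observed}) != 1:
        raise AlignmentError("haplotype sequences have unequal lengths")
    bad = set("".join(observed)) - _ACGT
    if bad:
        raise DataError(
            f"median computation requires A/C/G/T only; found {sorted(bad)} "
            "(mask ambiguous columns upstream)"
        )

    seqs = list(observed)
    for _ in range(max_rounds):
        d = _hamming_matrix(seqs)
        links = _msn_links(d, epsilon)
        linkset = set(links)
        cur_cost = _mst_cost(d)
        # connectable triplets: at least two of the three pairs are links
        best_cost = None
        best: list[str] = []
        n = len(seqs)
        for i, j, k in itertools.combinations(range(n), 3):
            n_linked = sum(
                p in linkset for p in [(i, j), (i, k), (j, k)]
            )
            if n_linked < 2:
                continue
            for m in _quasi_medians(seqs[i], seqs[j], seqs[k]):
                if m in seqs:
                    continue
                cost = sum(
                    sum(x != y for x, y in zip(m, seqs[t])) for t in (i, j, k)
                )
                if best_cost is None or cost < best_cost or (
                    cost == best_cost and m not in best
                ):
                    if best_cost is None or cost < best_cost:
                        best_cost = cost
                        best = [m]
                    elif m not in best:
                        best.append(m)
        if best_cost is None:
            break
        trial = seqs + sorted(best)
        if _mst_cost(_hamming_matrix(trial)) >= cur_cost:
            break
        seqs = trial

    # prune median vectors with degree < 3 in the final MSN, iteratively
    while True:
        d = _hamming_matrix(seqs)
        links = _msn_links(d, epsilon)
        degree = [0] * len(seqs)
        for i, j in links:
            degree[i] += 1
            degree[j] += 1
        drop = [
            i
            for i, s in enumerate(seqs)
            if s not in observed and degree[i] < 3
        ]
        if not drop:
            break
        seqs = [s for i, s in enumerate(seqs) if i not in drop]

    by_seq = {h.sequence: h for h in haps.haplotypes}
    nodes: list[NetNode] = []
    ids: list[str] = []
    mv = 0
    for s in seqs:
        if s in by_seq:
            h = by_seq[s]
            nodes.append(
                NetNode(h.haplotype_id, s, h.total_count, h.counts_by_population, False)
            )
            ids.append(h.haplotype_id)
        else:
            mv += 1
            nodes.append(NetNode(f"mv{mv}", s, 0, {}, True))
            ids.append(f"mv{mv}")
    edges = [
        NetEdge(ids[i], ids[j], int(d[i, j])) for i, j in _msn_links(d, epsilon)
    ]
    return HaploNetwork(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# statistical-parsimony connection limit
# ---------------------------------------------------------------------------

def parsimony_probability(steps: int, seq_length: int) -> float:
    """Probability that ``steps`` observed differences over ``seq_length``
    sites arose without superimposed substitutions.

    Finite-sites model: the observed proportion of differences p = j/m is
    corrected to a per-site expected number of hits
    lam = -(3/4) ln(1 - 4p/3) (Jukes-Cantor), per-site hit counts are
    Poisson(lam), and parsimony requires every differing site to carry
    exactly one hit and every identical site to carry none:

        P_j = [lam e^-lam / ((3/4)(1 - e^(-4 lam/3)))]^j
              * [e^-lam / (1/4 + (3/4) e^(-4 lam/3))]^(m-j)

    The two bracketed terms are the conditional single-hit and no-hit
    probabilities given an observed difference / identity.  P_0 = 1 and P_j
    decreases monotonically in j.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if steps < 0 or steps > seq_length:
        raise ValueError("steps must lie in [0, seq_length]")
    if steps == 0:
        return 1.0
    p = steps / seq_length
    if p >= 0.75:
        # beyond the saturation point of the Jukes-Cantor correction the
        # divergence is evaluated at a clipped value just inside the domain,
        # keeping the probability finite (and vanishingly small) so the
        # connection limit degrades gracefully to seq_length as the required
        # confidence approaches zero
        p = 0.75 * (1.0 - 1.0 / (2.0 * seq_length))
    lam = -0.75 * math.log1p(-4.0 * p / 3.0)
    e = math.exp(-lam)
    e43 = math.exp(-4.0 * lam / 3.0)
    per_diff = lam * e / (0.75 * (1.0 - e43))
    per_same = e / (0.25 + 0.75 * e43)
    return per_diff**steps * per_same ** (seq_length - steps)


def parsimony_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest number of steps whose parsimony probability exceeds
    ``confidence`` for a window of ``seq_length`` sites."""
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    limit = 0
    for j in range(1, seq_length + 1):
        if parsimony_probability(j, seq_length) > confidence:
            limit = j
        else:
            break
    return limit


def flag_edges(net: HaploNetwork, limit: int) -> HaploNetwork:
    """Mark edges with steps <= limit as confident; others as tentative.

    Idempotent; no edges are removed."""
    if limit < 1:
        raise ValueError("limit must be >= 1")
    return HaploNetwork(
        nodes=list(net.nodes),
        edges=[replace(e, confident=e.steps <= limit) for e in net.edges],
    )
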