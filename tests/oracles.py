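"""Independent brute-force oracles used by the test suite.

Everything here is written from the defining formulas with plain Python
loops, deliberately sharing no code path with the package implementation.
"""

import itertools
import math

import numpy as np

ACGT = set("ACGT")
PURINES = set("AG")


def k2p(a: str, b: str) -> float:
    """Closed-form K2P distance with pairwise deletion, by direct loop."""
    usable = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in ACGT and y in ACGT:
            usable += 1
            if x != y:
                if (x in PURINES) == (y in PURINES):
                    ts += 1
                else:
                    tv += 1
    p, q = ts / usable, tv / usable
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def pi_and_s(seqs: list[str]) -> tuple[int, float, float]:
    """(S, per-site pi, total pi) over columns unambiguous in all records."""
    cols = [
        i
        for i in range(len(seqs[0]))
        if all(s[i] in ACGT for s in seqs)
    ]
    s_count = sum(1 for i in cols if len({s[i] for s in seqs}) > 1)
    n = len(seqs)
    diffs = [
        sum(seqs[i][c] != seqs[j][c] for c in cols)
        for i, j in itertools.combinations(range(n), 2)
    ]
    pi_total = sum(diffs) / len(diffs)
    return s_count, pi_total / len(cols), pi_total


def tajimas_d(pi_total: float, s: int, n: int) -> float:
    """Textbook Tajima formula written out independently."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i / i for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_total - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def amova_one_level(d2: np.ndarray, pops: list[str]):
    """(sigma_among, sigma_within, phi_st) by direct evaluation of the
    squared-distance SS partition."""
    n = len(pops)
    names = sorted(set(pops))
    ss_total = sum(d2[i][j] for i in range(n) for j in range(n)) / (2 * n)
    ss_w = 0.0
    for p in names:
        members = [i for i in range(n) if pops[i] == p]
        ss_w += sum(d2[i][j] for i in members for j in members) / (2 * len(members))
    df_a, df_w = len(names) - 1, n - len(names)
    ms_a = (ss_total - ss_w) / df_a
    sigma_w = ss_w / df_w
    n0 = (n - sum(pops.count(p) ** 2 for p in names) / n) / df_a
    sigma_a = (ms_a - sigma_w) / n0
    return sigma_a, sigma_w, sigma_a / (sigma_a + sigma_w)


def amova_two_level(d2: np.ndarray, pops: list[str], group_of: dict):
    """(sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st) by direct
    evaluation of the nested SS partition and its expected mean squares."""
    n = len(pops)
    pnames = sorted(set(pops))
    gnames = sorted(set(group_of.values()))
    grp = [group_of[p] for p in pops]
    ss_total = sum(d2[i][j] for i in range(n) for j in range(n)) / (2 * n)
    ss_wp = 0.0
    for p in pnames:
        m = [i for i in range(n) if pops[i] == p]
        ss_wp += sum(d2[i][j] for i in m for j in m) / (2 * len(m))
    ss_wg = 0.0
    for g in gnames:
        m = [i for i in range(n) if grp[i] == g]
        ss_wg += sum(d2[i][j] for i in m for j in m) / (2 * len(m))
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp
    df_ag, df_ap, df_wp = len(gnames) - 1, len(pnames) - len(gnames), n - len(pnames)
    ms_ag, ms_ap = ss_ag / df_ag, ss_ap / df_ap
    sigma_c = ss_wp / df_wp
    npop = {p: pops.count(p) for p in pnames}
    ngrp = {g: grp.count(g) for g in gnames}
    term = sum(
        sum(npop[p] ** 2 for p in pnames if group_of[p] == g) / ngrp[g]
        for g in gnames
    )
    n_c = (n - term) / df_ap
    n_cp = (term - sum(v * v for v in npop.values()) / n) / df_ag
    n_cpp = (n - sum(v * v for v in ngrp.values()) / n) / df_ag
    sigma_b = (ms_ap - sigma_c) / n_c
    sigma_a = (ms_ag - sigma_c - n_cp * sigma_b) / n_cpp
    tot = sigma_a + sigma_b + sigma_c
    return (
        sigma_a, sigma_b, sigma_c,
        sigma_a / tot, sigma_b / (sigma_b + sigma_c), (sigma_a + sigma_b) / tot,
    )


def rank(values: list[float]) -> list[float]:
    """Mean ranks with ties, by sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def partial_r(a: list[float], b: list[float], c: list[float], ranked=True) -> float:
    """First-order partial correlation from the defining formula."""
    if ranked:
        a, b, c = rank(a), rank(b), rank(c)

    def corr(x, y):
        mx, my = sum(x) / len(x), sum(y) / len(y)
        num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
        den = math.sqrt(
            sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y)
        )
        return num / den

    r_ab, r_ac, r_bc = corr(a, b), corr(a, c), corr(b, c)
    return (r_ab - r_ac * r_bc) / math.sqrt((1 - r_ac**2) * (1 - r_bc**2))


def lower_triangle(m: np.ndarray) -> list[float]:
    return [m[i][j] for i in range(len(m)) for j in range(i)]


def mst_cost(seqs: list[str]) -> int:
    """Prim's algorithm on Hamming distances, written out."""
    n = len(seqs)
    if n == 1:
        return 0
    d = [
        [sum(x != y for x, y in zip(seqs[i], seqs[j])) for j in range(n)]
        for i in range(n)
    ]
    in_tree = {0}
    cost = 0
    while len(in_tree) < n:
        best = None
        for i in in_tree:
            for j in range(n):
                if j not in in_tree and (best is None or d[i][j] < best[0]):
                    best = (d[i][j], j)
        cost += best[0]
        in_tree.add(best[1])
    return cost


def best_steiner_gain(seqs: list[str]) -> tuple[int, set[str]]:
    """Exhaustively enumerate every candidate Steiner sequence over the
    observed per-column states; return the best achievable single-point MST
    cost and the set of optimal Steiner sequences (empty if no sequence
    improves the MST)."""
    base = mst_cost(seqs)
    cols = [sorted({s[i] for s in seqs}) for i in range(len(seqs[0]))]
    best = base
    winners: set[str] = set()
    for combo in itertools.product(*cols):
        cand = "".join(combo)
        if cand in seqs:
            continue
        c = mst_cost(seqs + [cand])
        if c < best:
            best = c
            winners = {cand}
        elif c == best and c < base:
            winners.add(cand)
    return best, winners


def parsimony_probability(steps: int, m: int) -> float:
    """Independent re-derivation of the finite-sites parsimony probability
    documented in docs/methods.md (Jukes-Cantor corrected per-site Poisson
    hit rate; every differing site exactly one hit, identical sites none)."""
    if steps == 0:
        return 1.0
    p = steps / m
    if p >= 0.75:
        p = 0.75 * (1 - 1 / (2 * m))
    lam = -0.75 * math.log(1 - 4 * p / 3)
    one_hit_given_diff = (lam * math.exp(-lam)) / (
        0.75 * (1 - math.exp(-4 * lam / 3))
    )
    no_hit_given_same = math.exp(-lam) / (0.25 + 0.75 * math.exp(-4 * lam / 3))
    return one_hit_given_diff**steps * no_hit_given_same ** (m - steps)
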