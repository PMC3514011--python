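"""Population-genetic statistics: diversity indices, Tajima's D with a
simulated coalescent null, and hierarchical AMOVA with permutation tests.

Diversity indices follow the conventional per-sample summary: sample size n,
number of haplotypes K, segregating sites S, S/n, nucleotide diversity pi and
Tajima's D.  Columns containing any ambiguity symbol in any record are
excluded from S, pi and D (complete deletion), keeping the three statistics
consistent with one another and with masked haplotype collapsing.

Tajima's D contrasts the pi-based and S-based estimators of the population
mutation rate theta:

    D = (pi_hat - S/a1) / sqrt(e1*S + e2*S*(S-1))

with the Tajima (1989) constants computed from n, and pi_hat the mean
pairwise *count* of differences (not per-site).  Its significance is judged
against neutral coalescent genealogies simulated conditional on the observed
number of segregating sites (fixed-S conditioning), the convention of the
classic tool era: it removes the nuisance parameter theta.

AMOVA partitions squared-distance variance hierarchically (among groups,
among populations within groups, within populations) using the
Excoffier-style sums of squares SS = sum(d^2) / (2N) and reports
Phi_CT, Phi_SC and Phi_ST with permutation p-values.  Negative variance
components are retained, not truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._coalescent import coalescent_segments
from .distances import DistanceMatrix
from .errors import ConfigurationError, DataError, DegenerateDesignError, PartitionError
from .seq_core import AlignedSeqSet, ambiguous_columns, collapse_haplotypes


# ---------------------------------------------------------------------------
# diversity indices and Tajima's D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityIndices:
    """Per-sample diversity summary (n, K, S, S/n, pi +/- sd, D)."""

    n: int
    k: int
    s: int
    pi: float
    pi_sd: float
    d: float | None  # None when S = 0 (statistic undefined)

    @property
    def s_over_n(self) -> float:
        return self.s / self.n


@dataclass(frozen=True)
class TajimaResult:
    d: float
    p_upper: float  # P(D_null >= D_obs)
    p_lower: float  # P(D_null <= D_obs)
    replicates: int


def _complete_columns(seqs: AlignedSeqSet) -> np.ndarray:
    """Alignment restricted to columns unambiguous in every record."""
    mat = seqs.to_matrix()
    return mat[:, ~ambiguous_columns(seqs)]


def _segregating_and_pi(mat: np.ndarray) -> tuple[int, float, float, float]:
    """(S, pi_per_site, pi_sd, pi_total) from an unambiguous matrix."""
    n, length = mat.shape
    if length == 0:
        raise DataError("no unambiguous columns")
    s = int((mat != mat[0]).any(axis=0).sum())
    diffs = []
    for i in range(n):
        d = (mat[i] != mat[i + 1:]).sum(axis=1)
        diffs.extend(d.tolist())
    diffs = np.asarray(diffs, dtype=float)
    pi_total = float(diffs.mean())
    per_site = diffs / length
    return s, float(per_site.mean()), float(per_site.std(ddof=1)) if len(diffs) > 1 else 0.0, pi_total


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalising constants a1, a2, b1, b2, c1, c2, e1, e2."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def _d_from_pi_s(pi_total: float, s: int, n: int) -> float:
    c = tajima_constants(n)
    denom = math.sqrt(c["e1"] * s + c["e2"] * s * (s - 1))
    return (pi_total - s / c["a1"]) / denom


def tajimas_d(seqs: AlignedSeqSet) -> float:
    """Tajima's D for an aligned sample (n >= 4, S >= 1)."""
    if seqs.n < 4:
        raise DataError(f"Tajima's D requires n >= 4, got n = {seqs.n}")
    mat = _complete_columns(seqs)
    s, _, _, pi_total = _segregating_and_pi(mat)
    if s == 0:
        raise DataError("Tajima's D undefined: no segregating sites")
    return _d_from_pi_s(pi_total, s, seqs.n)


def diversity_indices(seqs: AlignedSeqSet) -> DiversityIndices:
    """n, K, S, pi (+/- sd) and Tajima's D for one population sample."""
    if seqs.n < 2:
        raise DataError(f"diversity indices require n >= 2, got n = {seqs.n}")
    mat = _complete_columns(seqs)
    s, pi, pi_sd, pi_total = _segregating_and_pi(mat)
    k = collapse_haplotypes(seqs, ambiguity_policy="mask").k
    d = None
    if s > 0 and seqs.n >= 4:
        d = _d_from_pi_s(pi_total, s, seqs.n)
    return DiversityIndices(n=seqs.n, k=k, s=s, pi=pi, pi_sd=pi_sd, d=d)


def simulate_null_d(n: int, s: int, rng: np.random.Generator) -> float:
    """One draw from the fixed-S neutral coalescent null distribution of D.

    A neutral genealogy is simulated for ``n`` samples and exactly ``s``
    mutations are dropped onto it, each landing on a branch segment with
    probability proportional to segment length (infinite-sites placement).
    """
    sizes, lengths = coalescent_segments(n, rng)
    probs = lengths / lengths.sum()
    hit = rng.choice(len(sizes), size=s, replace=True, p=probs)
    i = sizes[hit].astype(float)
    pi_total = float((i * (n - i)).sum() / (n * (n - 1) / 2.0))
    return _d_from_pi_s(pi_total, s, n)


def tajima_null_test(
    seqs: AlignedSeqSet, replicates: int = 5000, seed: int | None = None
) -> TajimaResult:
    """Test the observed D against the simulated fixed-S coalescent null.

    p_upper = (1 + #{D_sim >= D_obs}) / (replicates + 1); p_lower analogous.
    Ties count toward both tails, so p_upper + p_lower >= 1.
    """
    if replicates < 100:
        raise ConfigurationError(
            f"replicates = {replicates} < 100 gives unstable p-values"
        )
    d_obs = tajimas_d(seqs)
    mat = _complete_columns(seqs)
    s, *_ = _segregating_and_pi(mat)
    rng = np.random.default_rng(seed)
    sims = np.array([simulate_null_d(seqs.n, s, rng) for _ in range(replicates)])
    p_upper = (1 + int((sims >= d_obs).sum())) / (replicates + 1)
    p_lower = (1 + int((sims <= d_obs).sum())) / (replicates + 1)
    return TajimaResult(d=d_obs, p_upper=p_upper, p_lower=p_lower, replicates=replicates)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AMOVAResult:
    phi_st: float
    phi_sc: float | None
    phi_ct: float | None
    #: (among groups, among populations within groups, within populations);
    #: the first entry is None for the one-level design.
    variance_components: tuple[float | None, float, float]
    p_st: float | None
    p_sc: float | None
    p_ct: float | None
    permutations: int


def _check_partition(
    labels: Sequence[str], populations: Mapping[str, str]
) -> np.ndarray:
    missing = [l for l in labels if l not in populations]
    if missing:
        raise PartitionError(f"labels missing from population map: {missing}")
    return np.asarray([populations[l] for l in labels])


def _components_one_level(
    d2: np.ndarray, pop_idx: np.ndarray, n_pops: int
) -> tuple[float, float, float]:
    """(sigma_among, sigma_within, phi_st) for populations with no groups."""
    n = len(pop_idx)
    sizes = np.bincount(pop_idx, minlength=n_pops).astype(float)
    ss_total = d2.sum() / (2.0 * n)
    ss_wp = 0.0
    for p in range(n_pops):
        members = np.flatnonzero(pop_idx == p)
        ss_wp += d2[np.ix_(members, members)].sum() / (2.0 * sizes[p])
    df_ap = n_pops - 1
    df_wp = n - n_pops
    if df_ap == 0 or df_wp == 0:
        raise DegenerateDesignError("need >= 2 populations with > 1 member overall")
    ms_ap = (ss_total - ss_wp) / df_ap
    sigma_c = ss_wp / df_wp
    n0 = (n - (sizes**2).sum() / n) / df_ap
    sigma_b = (ms_ap - sigma_c) / n0
    total = sigma_b + sigma_c
    if total == 0:
        raise DegenerateDesignError("all distances zero: Phi_ST undefined")
    return sigma_b, sigma_c, sigma_b / total


def _components_two_level(
    d2: np.ndarray,
    pop_idx: np.ndarray,
    grp_of_pop: np.ndarray,
) -> tuple[float, float, float, float, float, float]:
    """(sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st)."""
    n = len(pop_idx)
    n_pops = int(pop_idx.max()) + 1
    n_grps = int(grp_of_pop.max()) + 1
    grp_idx = grp_of_pop[pop_idx]
    pop_sizes = np.bincount(pop_idx, minlength=n_pops).astype(float)
    grp_sizes = np.bincount(grp_idx, minlength=n_grps).astype(float)

    ss_total = d2.sum() / (2.0 * n)
    ss_wp = 0.0
    for p in range(n_pops):
        members = np.flatnonzero(pop_idx == p)
        ss_wp += d2[np.ix_(members, members)].sum() / (2.0 * pop_sizes[p])
    ss_wg = 0.0
    for g in range(n_grps):
        members = np.flatnonzero(grp_idx == g)
        ss_wg += d2[np.ix_(members, members)].sum() / (2.0 * grp_sizes[g])
    ss_ag = ss_total - ss_wg
    ss_ap_wg = ss_wg - ss_wp

    df_ag = n_grps - 1
    df_ap = n_pops - n_grps
    df_wp = n - n_pops
    if df_ag == 0:
        raise DegenerateDesignError("grouped AMOVA needs >= 2 groups")
    if df_ap == 0 or df_wp == 0:
        raise DegenerateDesignError(
            "grouped AMOVA needs populations nested in groups with replication"
        )
    ms_ag = ss_ag / df_ag
    ms_ap = ss_ap_wg / df_ap
    sigma_c = ss_wp / df_wp

    sum_np2_by_grp = np.array(
        [(pop_sizes[grp_of_pop == g] ** 2).sum() / grp_sizes[g] for g in range(n_grps)]
    ).sum()
    n_c = (n - sum_np2_by_grp) / df_ap
    n_cp = (sum_np2_by_grp - (pop_sizes**2).sum() / n) / df_ag
    n_cpp = (n - (grp_sizes**2).sum() / n) / df_ag

    sigma_b = (ms_ap - sigma_c) / n_c
    sigma_a = (ms_ag - sigma_c - n_cp * sigma_b) / n_cpp
    total = sigma_a + sigma_b + sigma_c
    if total == 0:
        raise DegenerateDesignError("all distances zero: Phi statistics undefined")
    phi_ct = sigma_a / total
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else float("nan")
    phi_st = (sigma_a + sigma_b) / total
    return sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st


def _perm_p(obs: float, sims: np.ndarray) -> float:
    return (1 + int((sims >= obs).sum())) / (len(sims) + 1)


def amova(
    dist: DistanceMatrix,
    populations: Mapping[str, str],
    groups: Mapping[str, str] | None = None,
    permutations: int = 5000,
    seed: int | None = None,
) -> AMOVAResult:
    """Hierarchical analysis of molecular variance on squared distances.

    ``populations`` maps every matrix label to a population; ``groups`` (may
    be None for the one-level design) maps every population to a group.
    Permutation schemes: individuals among all populations (Phi_ST),
    individuals among populations within groups (Phi_SC), whole populations
    among groups (Phi_CT); add-one p-values.
    """
    if not np.isfinite(dist.values).all():
        raise DataError("non-finite distances")
    pop_labels = _check_partition(dist.labels, populations)
    pop_names = sorted(set(pop_labels))
    if len(pop_names) < 2:
        raise DegenerateDesignError("AMOVA needs >= 2 populations")
    pop_code = {p: i for i, p in enumerate(pop_names)}
    pop_idx = np.asarray([pop_code[p] for p in pop_labels])
    d2 = dist.values**2
    rng = np.random.default_rng(seed)

    if groups is None:
        sigma_b, sigma_c, phi_st = _components_one_level(d2, pop_idx, len(pop_names))
        sims = np.empty(permutations)
        for r in range(permutations):
            perm = rng.permutation(pop_idx)
            try:
                sims[r] = _components_one_level(d2, perm, len(pop_names))[2]
            except DegenerateDesignError:
                sims[r] = np.inf
        return AMOVAResult(
            phi_st=phi_st,
            phi_sc=None,
            phi_ct=None,
            variance_components=(None, sigma_b, sigma_c),
            p_st=_perm_p(phi_st, sims),
            p_sc=None,
            p_ct=None,
            permutations=permutations,
        )

    missing = [p for p in pop_names if p not in groups]
    if missing:
        raise PartitionError(f"populations missing from group map: {missing}")
    grp_names = sorted({groups[p] for p in pop_names})
    if len(grp_names) < 2:
        raise DegenerateDesignError(
            "a group level was supplied but only one group is present"
        )
    grp_code = {g: i for i, g in enumerate(grp_names)}
    grp_of_pop = np.asarray([grp_code[groups[p]] for p in pop_names])

    sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st = _components_two_level(
        d2, pop_idx, grp_of_pop
    )

    def two_level(pidx: np.ndarray, gofp: np.ndarray):
        try:
            return _components_two_level(d2, pidx, gofp)
        except DegenerateDesignError:
            return (np.nan,) * 3 + (np.inf,) * 3

    sims_st = np.empty(permutations)
    sims_sc = np.empty(permutations)
    sims_ct = np.empty(permutations)
    grp_idx = grp_of_pop[pop_idx]
    for r in range(permutations):
        # Phi_ST: individuals among all populations
        sims_st[r] = two_level(rng.permutation(pop_idx), grp_of_pop)[5]
        # Phi_SC: individuals among populations within their group
        perm_sc = pop_idx.copy()
        for g in range(len(grp_names)):
            members = np.flatnonzero(grp_idx == g)
            perm_sc[members] = perm_sc[members][rng.permutation(len(members))]
        sims_sc[r] = two_level(perm_sc, grp_of_pop)[4]
        # Phi_CT: whole populations among groups
        sims_ct[r] = two_level(pop_idx, rng.permutation(grp_of_pop))[3]
    return AMOVAResult(
        phi_st=phi_st,
        phi_sc=phi_sc,
        phi_ct=phi_ct,
        variance_components=(sigma_a, sigma_b, sigma_c),
        p_st=_perm_p(phi_st, sims_st),
        p_sc=_perm_p(phi_sc, sims_sc),
        p_ct=_perm_p(phi_ct, sims_ct),
        permutations=permutations,
    )


def pairwise_phi_st(
    dist: DistanceMatrix,
    populations: Mapping[str, str],
    permutations: int = 5000,
    seed: int | None = None,
) -> list[dict]:
    """One-level AMOVA for every unordered pair of populations.

    Returns one record per pair: ``{"pop_a", "pop_b", "phi_st", "p"}``.
    """
    pop_labels = _check_partition(dist.labels, populations)
    pop_names = sorted(set(pop_labels))
    rng = np.random.default_rng(seed)
    out = []
    for a_i in range(len(pop_names)):
        for b_i in range(a_i + 1, len(pop_names)):
            a, b = pop_names[a_i], pop_names[b_i]
            keep = [
                l for l, p in zip(dist.labels, pop_labels) if p in (a, b)
            ]
            sub = dist.submatrix(keep)
            res = amova(
                sub,
                {l: populations[l] for l in keep},
                groups=None,
                permutations=permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            out.append({"pop_a": a, "pop_b": b, "phi_st": res.phi_st, "p": res.p_st})
    return out
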