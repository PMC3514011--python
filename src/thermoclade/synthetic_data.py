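"""Synthetic data with the statistical structure the pipeline assumes.

Three generators, all pure functions of (config, seed):

* :func:`simulate_sequences` — deeply diverged COI clades with shallow
  within-clade variation.  Clade ancestors sit on a star tree whose branch
  lengths are tuned so the expected between-ancestor K2P distance matches
  the configured net-divergence target; within each clade a neutral Kingman
  coalescent genealogy (theta = within_clade_theta per locus) is simulated
  and sequences evolve site-independently under the Kimura 2-parameter
  substitution process at the configured transition/transversion rate ratio.
* :func:`simulate_occurrence` — sampling sites along an SST gradient, with
  each clade's colony count binomial with a Gaussian thermal-niche occupancy
  probability (bounded by per-site sampling effort, mirroring fixed-effort
  dock surveys).
* :func:`simulate_zooids` — zooid length decreasing linearly with SST plus
  additive Gaussian noise; widths and orifice dimensions scale
  allometrically with multiplicative log-normal noise.

Defaults emulate the magnitudes of the study system: inter-clade divergences
of order 12–24% (default target 15%), within-clade diversity of order
pi ~ 0.01, site SSTs spanning 10–27 degC, niche centres at 12 and 18 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .errors import ConfigurationError
from ._coalescent import sample_genealogy
from .morphometrics import ZooidRecord
from .seq_core import AlignedSeqSet, SeqEntry
from .thermal import SampleTable

import pandas as pd

_BASES = "ACGT"
# rate-matrix state order A, C, G, T; transitions: A<->G, C<->T
_TS_PAIR = {0: 2, 2: 0, 1: 3, 3: 1}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system (defaults are the package's
    reference conditions; see docs/methods.md for rationale)."""

    n_clades: int = 2
    #: target expected K2P distance between clade ancestors (subs/site);
    #: scalar applied to every pair (star topology).
    net_divergence_target: float = 0.15
    #: population mutation parameter per locus (expected pairwise
    #: differences within a clade).
    within_clade_theta: float = 5.0
    seq_length: int = 500
    #: transition/transversion *rate* ratio kappa = alpha/beta.
    ts_tv_ratio: float = 2.0
    samples_per_clade: int = 20
    n_sites_geo: int = 15
    sst_range: tuple[float, float] = (10.0, 27.0)
    niche_centers: tuple[float, ...] = (12.0, 18.0)
    niche_widths: tuple[float, ...] = (2.5, 2.5)
    colonies_per_site: int = 20
    #: zooid length model: l_z = zooid_base + zooid_slope * sst + N(0, sigma)
    zooid_base: float = 1.1
    zooid_slope: float = -0.02
    zooid_sigma: float = 0.05
    #: optional per-clade log10 offset on orifice area (allometric shift)
    orifice_log_offsets: Mapping[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seq_length < 100:
            raise ConfigurationError("seq_length must be >= 100")
        if self.within_clade_theta <= 0 or self.ts_tv_ratio <= 0:
            raise ConfigurationError("rates must be positive")
        if any(w <= 0 for w in self.niche_widths):
            raise ConfigurationError("niche widths must be positive")
        if len(self.niche_centers) < self.n_clades or len(self.niche_widths) < self.n_clades:
            raise ConfigurationError(
                "need a niche center and width per clade"
            )

    def clade_names(self) -> list[str]:
        return [f"clade{i + 1}" for i in range(self.n_clades)]


def _k2p_rate_matrix(kappa: float) -> np.ndarray:
    """K2P rate matrix (states ACGT) normalised to one expected
    substitution per unit branch length."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    q = np.full((4, 4), beta)
    for i in range(4):
        q[i, _TS_PAIR[i]] = alpha
        q[i, i] = 0.0
        q[i, i] = -q[i].sum()
    return q


def _transition_matrix(kappa: float, d: float) -> np.ndarray:
    return expm(_k2p_rate_matrix(kappa) * d)


def _evolve(seq: np.ndarray, pmat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Evolve an integer-coded sequence one branch, sampling per site."""
    cum = pmat.cumsum(axis=1)
    u = rng.random(seq.shape[0])
    return (u[:, None] > cum[seq]).sum(axis=1)


def _expected_k2p_defined(kappa: float, d: float) -> bool:
    p = _transition_matrix(kappa, d)
    # expected P (transitions) and Q (transversions) between two states
    pi = 0.25
    pp = sum(pi * p[i, _TS_PAIR[i]] for i in range(4))
    qq = 1.0 - pp - sum(pi * p[i, i] for i in range(4))
    return (1 - 2 * pp - qq) > 0.05 and (1 - 2 * qq) > 0.05


def simulate_sequences(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[AlignedSeqSet, dict[str, str]]:
    """Simulate clade-structured COI sequences.

    Returns the aligned set (record populations set to the true clade) and a
    label -> clade map.  Same seed, same bytes.
    """
    seed = seed if seed is not None else cfg.seed
    rng = np.random.default_rng(seed)
    if not _expected_k2p_defined(cfg.ts_tv_ratio, cfg.net_divergence_target):
        raise ConfigurationError(
            f"net divergence target {cfg.net_divergence_target} saturates the "
            "K2P distance (unreachable)"
        )
    length = cfg.seq_length
    root = rng.integers(0, 4, size=length)
    # star tree: each ancestor is target/2 from the root
    p_anc = _transition_matrix(cfg.ts_tv_ratio, cfg.net_divergence_target / 2.0)
    records: list[SeqEntry] = []
    truth: dict[str, str] = {}
    for c, clade in enumerate(cfg.clade_names()):
        anc = _evolve(root, p_anc, rng) if cfg.n_clades > 1 else root.copy()
        n = cfg.samples_per_clade
        parent, blen = sample_genealogy(n, rng)
        total = 2 * n - 1
        seqs: dict[int, np.ndarray] = {total - 1: anc}
        # children lists from parent array; evolve root-down
        children: dict[int, list[int]] = {}
        for v in range(total - 1):
            children.setdefault(int(parent[v]), []).append(v)
        stack = [total - 1]
        while stack:
            v = stack.pop()
            for ch in children.get(v, []):
                d = blen[ch] * cfg.within_clade_theta / (2.0 * length)
                seqs[ch] = _evolve(seqs[v], _transition_matrix(cfg.ts_tv_ratio, d), rng)
                stack.append(ch)
        for i in range(n):
            label = f"{clade}_s{i + 1}"
            seq = "".join(_BASES[b] for b in seqs[i])
            records.append(SeqEntry(label, clade, seq))
            truth[label] = clade
    return AlignedSeqSet(records), truth


def simulate_occurrence(
    cfg: SimulationConfig, seed: int | None = None
) -> SampleTable:
    """Simulate a site-by-clade occurrence table along an SST gradient.

    Sites run from cold/high-latitude to warm/low-latitude; clade c's colony
    count at a site is Binomial(colonies_per_site, p) with
    p = exp(-((sst - center_c)^2) / (2 width_c^2)).  Zero-count rows are
    dropped.
    """
    seed = seed if seed is not None else cfg.seed
    rng = np.random.default_rng(seed)
    lo, hi = cfg.sst_range
    sst = np.linspace(lo, hi, cfg.n_sites_geo)
    lat = np.linspace(48.0, 20.0, cfg.n_sites_geo)
    lon = -125.0 + rng.normal(0.0, 1.0, size=cfg.n_sites_geo)
    rows = []
    for s in range(cfg.n_sites_geo):
        for c, clade in enumerate(cfg.clade_names()):
            z = (sst[s] - cfg.niche_centers[c]) / cfg.niche_widths[c]
            p = float(np.exp(-0.5 * z * z))
            count = int(rng.binomial(cfg.colonies_per_site, p))
            if count > 0:
                rows.append(
                    dict(
                        region="synthetic",
                        site=f"S{s + 1:02d}",
                        latitude=float(lat[s]),
                        longitude=float(lon[s]),
                        sst_c=float(sst[s]),
                        phylogroup=clade,
                        count=count,
                        source="simulated",
                    )
                )
    if not rows:
        raise ConfigurationError(
            "no colonies produced: niches do not overlap the SST range"
        )
    return SampleTable(pd.DataFrame(rows))


def simulate_zooids(
    cfg: SimulationConfig, table: SampleTable, seed: int | None = None
) -> list[ZooidRecord]:
    """Simulate one zooid-morphometric record per colony in ``table``."""
    seed = seed if seed is not None else cfg.seed
    rng = np.random.default_rng(seed)
    ssts = table.df.sst_c.to_numpy()
    det = cfg.zooid_base + cfg.zooid_slope * ssts
    if (det <= 0).any():
        raise ConfigurationError(
            "zooid_base + zooid_slope * sst is non-positive at some site"
        )
    offsets = dict(cfg.orifice_log_offsets or {})
    records: list[ZooidRecord] = []
    i = 0
    for _, row in table.df.iterrows():
        mean_l = cfg.zooid_base + cfg.zooid_slope * row.sst_c
        scale = 10.0 ** (offsets.get(row.phylogroup, 0.0) / 2.0)
        for _ in range(int(row["count"])):
            i += 1
            l_z = mean_l + rng.normal(0.0, cfg.zooid_sigma)
            while l_z <= 0:  # truncate at positive lengths
                l_z = mean_l + rng.normal(0.0, cfg.zooid_sigma)
            w_z = 0.55 * l_z * np.exp(rng.normal(0.0, 0.05))
            l_or = 0.28 * l_z * scale * np.exp(rng.normal(0.0, 0.05))
            w_or = 0.33 * w_z * scale * np.exp(rng.normal(0.0, 0.05))
            records.append(
                ZooidRecord(
                    colony_id=f"col{i}",
                    phylogroup=str(row.phylogroup),
                    site=str(row.site),
                    sst=float(row.sst_c),
                    l_z=float(l_z),
                    w_z=float(w_z),
                    l_or=float(l_or),
                    w_or=float(w_or),
                )
            )
    return records
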