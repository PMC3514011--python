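"""Sea-surface-temperature analysis of clade occurrence.

A :class:`SampleTable` holds occurrence rows (region, site, coordinates, mean
annual SST, phylogroup, colony count).  The analyses are:

* colony-count-weighted median SST per phylogroup, with a bootstrap
  percentile confidence interval (resampling 20 units for 1000 replicates by
  default);
* rank-based partial Mantel tests of clade occurrence against SST distance,
  correcting for spatial distance.  Distances are Euclidean on raw decimal
  degrees — deliberately not great-circle, matching the upstream convention
  of the analysis this package reproduces (a haversine mode is available).

The default Mantel analysis unit is one colony (rows expanded by count); a
site-level mode treats each table row as one unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .distances import DistanceMatrix
from .errors import ConfigurationError, DataError, DegenerateDesignError, PartitionError

#: Canonical phylogroup labels of the packaged occurrence table.
CANONICAL_PHYLOGROUPS = ("arcuata", "A", "B", "new_sp", "subovoidea", "edmondsoni")

_SCHEMA = ["region", "site", "latitude", "longitude", "sst_c", "phylogroup", "count", "source"]


@dataclass
class SampleTable:
    """Occurrence rows: site, coordinates, SST, phylogroup, colony count."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _SCHEMA if c not in self.df.columns]
        if missing:
            raise DataError(f"sample table missing columns: {missing}")
        if len(self.df) == 0:
            raise DataError("empty sample table")
        df = self.df.reset_index(drop=True)
        for i, row in df.iterrows():
            if not (abs(row.latitude) <= 90 and abs(row.longitude) <= 180):
                raise DataError(f"row {i}: coordinates out of range")
            if not np.isfinite(row.sst_c):
                raise DataError(f"row {i}: non-finite SST")
            if not (int(row["count"]) == row["count"] and row["count"] >= 1):
                raise DataError(f"row {i}: count must be an integer >= 1")
            if not str(row.phylogroup):
                raise DataError(f"row {i}: empty phylogroup")
        df["count"] = df["count"].astype(int)
        self.df = df

    @property
    def phylogroups(self) -> list[str]:
        return sorted(self.df.phylogroup.unique())

    def total_count(self, phylogroup: str | None = None) -> int:
        df = self.df if phylogroup is None else self.df[self.df.phylogroup == phylogroup]
        return int(df["count"].sum())

    def restrict(self, phylogroups: Sequence[str]) -> "SampleTable":
        sub = self.df[self.df.phylogroup.isin(list(phylogroups))]
        if len(sub) == 0:
            raise DataError(f"no rows for phylogroups {list(phylogroups)}")
        return SampleTable(sub.reset_index(drop=True))

    def expand_colonies(self) -> pd.DataFrame:
        """One row per colony (table rows repeated by count), with unit ids."""
        rep = self.df.loc[self.df.index.repeat(self.df["count"])].reset_index(drop=True)
        rep["unit"] = [f"c{i}" for i in range(len(rep))]
        return rep

    def units(self, unit: str = "colony") -> pd.DataFrame:
        if unit == "colony":
            return self.expand_colonies()
        if unit == "site":
            df = self.df.copy()
            df["unit"] = [f"r{i}" for i in range(len(df))]
            return df
        raise ValueError(f"unknown unit: {unit!r}")


@dataclass(frozen=True)
class CladeSSTSummary:
    phylogroup: str
    n: int
    median_sst: float
    ci_low: float | None = None
    ci_high: float | None = None
    replicates: int | None = None


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    permutations: int
    ranked: bool
    groups: tuple[str, ...] = ()
    unit: str = "colony"


def packaged_table_path() -> Path:
    """Path of the packaged occurrence-table fixture."""
    return Path(resources.files("thermoclade") / "data" / "watersipora_table1.csv")


def load_sample_table(path: str | Path | None = None) -> SampleTable:
    """Load a SampleTable CSV; with no argument, the packaged fixture."""
    path = Path(path) if path is not None else packaged_table_path()
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype={"source": str}, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise DataError(f"cannot parse {path}: {exc}") from exc
    if len(df) == 0:
        raise DataError(f"empty table: {path}")
    return SampleTable(df)


def weighted_median_sst(table: SampleTable, phylogroup: str) -> CladeSSTSummary:
    """Median SST over the multiset in which each row contributes ``count``
    copies of its SST (even size: mean of the two middle values)."""
    rows = table.df[table.df.phylogroup == phylogroup]
    if len(rows) == 0:
        raise KeyError(f"no rows for phylogroup {phylogroup!r}")
    values = np.repeat(rows.sst_c.to_numpy(), rows["count"].to_numpy())
    return CladeSSTSummary(
        phylogroup=phylogroup, n=len(values), median_sst=float(np.median(values))
    )


def bootstrap_median_ci(
    table: SampleTable,
    phylogroup: str,
    resample_size: int = 20,
    replicates: int = 1000,
    unit: str = "colony",
    seed: int | None = None,
) -> CladeSSTSummary:
    """95% percentile bootstrap CI of the median SST for one phylogroup.

    ``unit="colony"`` draws colonies (rows weighted by count);
    ``unit="site"`` draws one value per table row.
    """
    if replicates < 100:
        raise ConfigurationError(f"replicates = {replicates} < 100 is unstable")
    rows = table.df[table.df.phylogroup == phylogroup]
    if len(rows) == 0:
        raise KeyError(f"no rows for phylogroup {phylogroup!r}")
    if unit == "colony":
        pool = np.repeat(rows.sst_c.to_numpy(), rows["count"].to_numpy())
    elif unit == "site":
        pool = rows.sst_c.to_numpy()
    else:
        raise ValueError(f"unknown unit: {unit!r}")
    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=(replicates, resample_size), replace=True)
    medians = np.median(draws, axis=1)
    lo, hi = np.percentile(medians, [2.5, 97.5])
    point = weighted_median_sst(table, phylogroup)
    return CladeSSTSummary(
        phylogroup=phylogroup,
        n=len(pool),
        median_sst=point.median_sst,
        ci_low=float(lo),
        ci_high=float(hi),
        replicates=replicates,
    )


# ---------------------------------------------------------------------------
# distance matrices on analysis units
# ---------------------------------------------------------------------------

def geo_distance_matrix(
    table: SampleTable, unit: str = "colony", great_circle: bool = False
) -> DistanceMatrix:
    """Pairwise spatial distances between analysis units.

    Default: Euclidean distance on raw (latitude, longitude) decimal degrees.
    ``great_circle=True`` switches to haversine distances in kilometres.
    """
    units = table.units(unit)
    lat = units.latitude.to_numpy()
    lon = units.longitude.to_numpy()
    if great_circle:
        rlat, rlon = np.radians(lat), np.radians(lon)
        dlat = rlat[:, None] - rlat[None, :]
        dlon = rlon[:, None] - rlon[None, :]
        a = (
            np.sin(dlat / 2) ** 2
            + np.cos(rlat)[:, None] * np.cos(rlat)[None, :] * np.sin(dlon / 2) ** 2
        )
        vals = 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
        np.fill_diagonal(vals, 0.0)
    else:
        xy = np.column_stack([lat, lon])
        diff = xy[:, None, :] - xy[None, :, :]
        vals = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(units.unit.tolist(), vals)


def sst_distance_matrix(table: SampleTable, unit: str = "colony") -> DistanceMatrix:
    """Pairwise absolute SST differences between analysis units."""
    units = table.units(unit)
    sst = units.sst_c.to_numpy()
    vals = np.abs(sst[:, None] - sst[None, :])
    return DistanceMatrix(units.unit.tolist(), vals)


def clade_indicator_matrix(
    table: SampleTable, phylogroup: str, unit: str = "colony"
) -> DistanceMatrix:
    """0/1 dissimilarity of presence/absence of one phylogroup per unit."""
    units = table.units(unit)
    ind = (units.phylogroup == phylogroup).to_numpy().astype(float)
    vals = np.abs(ind[:, None] - ind[None, :])
    return DistanceMatrix(units.unit.tolist(), vals)


def clade_mismatch_matrix(table: SampleTable, unit: str = "colony") -> DistanceMatrix:
    """Multi-clade mismatch distance: 0 if two units share a phylogroup,
    1 otherwise."""
    units = table.units(unit)
    grp = units.phylogroup.to_numpy()
    vals = (grp[:, None] != grp[None, :]).astype(float)
    return DistanceMatrix(units.unit.tolist(), vals)


# ---------------------------------------------------------------------------
# partial Mantel test
# ---------------------------------------------------------------------------

def _tri(values: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(values.shape[0], k=-1)
    return values[i, j]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / math.sqrt((a @ a) * (b @ b)))


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    permutations: int = 10000,
    ranked: bool = True,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel correlation of A and B controlling for C.

    The strict lower triangles are vectorised (optionally rank-transformed,
    mean ranks for ties) and the first-order partial correlation

        r = (r_AB - r_AC * r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2))

    is computed.  Significance comes from simultaneously permuting the rows
    and columns of A ``permutations`` times (add-one rule).  ``alternative``
    is ``"greater"`` (default) or ``"two-sided"``.
    """
    n = a.n
    if not (a.n == b.n == c.n):
        raise DataError("matrices are not conformable")
    if n < 4:
        raise DataError(f"partial Mantel needs >= 4 units, got {n}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative: {alternative!r}")

    def prep(m: DistanceMatrix, name: str) -> np.ndarray:
        v = _tri(m.values)
        if np.ptp(v) == 0:
            raise DegenerateDesignError(
                f"matrix {name} has a zero-variance lower triangle"
            )
        return rankdata(v) if ranked else v

    va, vb, vc = prep(a, "A"), prep(b, "B"), prep(c, "C")

    def partial_r(x: np.ndarray) -> float:
        r_ab = _pearson(x, vb)
        r_ac = _pearson(x, vc)
        r_bc = _pearson(vb, vc)
        denom = math.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        if denom == 0:
            return math.nan
        return (r_ab - r_ac * r_bc) / denom

    r_obs = partial_r(va)

    # Under permutation the multiset of A's triangle entries is unchanged, so
    # rank-transforming commutes with permuting: permute the (ranked) matrix.
    am = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    am[i, j] = va
    am = am + am.T
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        vp = am[np.ix_(p, p)][i, j]
        r_sim = partial_r(vp)
        if alternative == "greater":
            if r_sim >= r_obs:
                count += 1
        else:
            if abs(r_sim) >= abs(r_obs):
                count += 1
    p_val = (1 + count) / (permutations + 1)
    return MantelResult(r=r_obs, p=p_val, permutations=permutations, ranked=ranked)


def clade_sst_tests(
    table: SampleTable,
    phylogroups: Sequence[str] | None = None,
    permutations: int = 10000,
    ranked: bool = True,
    unit: str = "colony",
    seed: int | None = None,
) -> list[MantelResult]:
    """All-groups and pairwise partial Mantel tests of clade vs SST.

    The all-groups test correlates the multi-clade mismatch matrix with SST
    distance; each pairwise test restricts the table to two phylogroups and
    uses the presence/absence indicator dissimilarity.  All tests correct
    for spatial (Euclidean decimal-degree) distance.
    """
    groups = list(phylogroups) if phylogroups is not None else table.phylogroups
    present = [g for g in groups if g in table.phylogroups]
    if len(present) < 2:
        raise PartitionError(
            f"clade/SST tests need >= 2 phylogroups present, got {present}"
        )
    sub = table.restrict(present)
    rng = np.random.default_rng(seed)
    results: list[MantelResult] = []
    res = partial_mantel(
        clade_mismatch_matrix(sub, unit),
        sst_distance_matrix(sub, unit),
        geo_distance_matrix(sub, unit),
        permutations=permutations,
        ranked=ranked,
        seed=int(rng.integers(2**31 - 1)),
    )
    results.append(
        MantelResult(res.r, res.p, permutations, ranked, tuple(present), unit)
    )
    for x in range(len(present)):
        for y in range(x + 1, len(present)):
            pair = (present[x], present[y])
            pt = sub.restrict(pair)
            res = partial_mantel(
                clade_indicator_matrix(pt, pair[0], unit),
                sst_distance_matrix(pt, unit),
                geo_distance_matrix(pt, unit),
                permutations=permutations,
                ranked=ranked,
                seed=int(rng.integers(2**31 - 1)),
            )
            results.append(MantelResult(res.r, res.p, permutations, ranked, pair, unit))
    return results
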