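"""Zooid-morphometric comparisons.

Bryozoan zooids are approximately elliptical, so zooid and orifice areas are
computed as (pi/4) * length * width by default (a rectangle mode, L * W, is
provided; on the log10 scale used by the ANCOVA a constant factor shifts
intercepts only).  The two analyses are:

* ANCOVA of log10 orifice area on log10 zooid area with a group factor —
  the classic test separating species whose orifice is smaller for a given
  frontal-shield area — plus a slope-heterogeneity (interaction) test;
* ordinary least-squares regression of zooid length on mean annual SST,
  quantifying the decrease of zooid size toward warmer sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import f as f_dist, levene

from .errors import DataError, DegenerateDesignError


@dataclass(frozen=True)
class ZooidRecord:
    """One colony's mean zooid measurements (mm) with site metadata."""

    colony_id: str
    phylogroup: str
    site: str
    sst: float
    l_z: float   # zooid length
    w_z: float   # zooid width at maximum
    l_or: float  # orifice length
    w_or: float  # orifice width

    def __post_init__(self) -> None:
        for name in ("l_z", "w_z", "l_or", "w_or"):
            if getattr(self, name) <= 0:
                raise DataError(f"{self.colony_id}: {name} must be positive")


@dataclass(frozen=True)
class AncovaResult:
    f: float
    df_num: int
    df_den: int
    p: float
    term: str  # "group" or "slope-heterogeneity"
    #: Levene p-value of residual variance homogeneity across groups.
    levene_p: float | None = None


def zooid_areas(
    rec: ZooidRecord, formula: str = "ellipse"
) -> tuple[float, float]:
    """(zooid area, orifice area) in mm^2 for one record."""
    if formula == "ellipse":
        factor = math.pi / 4.0
    elif formula == "rectangle":
        factor = 1.0
    else:
        raise ValueError(f"unknown area formula: {formula!r}")
    return factor * rec.l_z * rec.w_z, factor * rec.l_or * rec.w_or


def records_to_frame(
    records: Sequence[ZooidRecord], area_formula: str = "ellipse"
) -> pd.DataFrame:
    rows = []
    for r in records:
        za, oa = zooid_areas(r, area_formula)
        rows.append(
            dict(
                colony_id=r.colony_id,
                phylogroup=r.phylogroup,
                site=r.site,
                sst=r.sst,
                l_z=r.l_z,
                w_z=r.w_z,
                l_or=r.l_or,
                w_or=r.w_or,
                zooid_area=za,
                orifice_area=oa,
                log_zooid_area=math.log10(za),
                log_orifice_area=math.log10(oa),
            )
        )
    return pd.DataFrame(rows)


def ancova_log_areas(
    records: Sequence[ZooidRecord],
    grouping: Mapping[str, str],
    area_formula: str = "ellipse",
) -> tuple[AncovaResult, AncovaResult]:
    """Group-effect and slope-heterogeneity F-tests on log10 areas.

    ``grouping`` maps each phylogroup to one of two (or more) group labels.
    The group F comes from the nested comparison of
    ``log_orifice_area ~ log_zooid_area`` against the model with the group
    factor added; the slope-heterogeneity F adds the interaction.  A Levene
    test of residual variance across groups is reported as a diagnostic.
    """
    df = records_to_frame(records, area_formula)
    unknown = sorted(set(df.phylogroup) - set(grouping))
    if unknown:
        raise DataError(f"phylogroups missing from grouping: {unknown}")
    df["group"] = df.phylogroup.map(grouping)
    counts = df.group.value_counts()
    if len(counts) < 2:
        raise DegenerateDesignError("ANCOVA needs >= 2 groups")
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise DegenerateDesignError(f"groups with < 3 records: {small}")
    if df.log_zooid_area.nunique() == 1:
        raise DegenerateDesignError("covariate is constant (singular design)")

    base = smf.ols("log_orifice_area ~ log_zooid_area", df).fit()
    with_group = smf.ols("log_orifice_area ~ log_zooid_area + C(group)", df).fit()
    with_inter = smf.ols(
        "log_orifice_area ~ log_zooid_area * C(group)", df
    ).fit()

    def nested_f(small, big, term: str, levene_p=None) -> AncovaResult:
        df_num = int(big.df_model - small.df_model)
        df_den = int(big.df_resid)
        if df_num == 0 or df_den == 0:
            raise DegenerateDesignError("singular design for nested F-test")
        f = ((small.ssr - big.ssr) / df_num) / (big.ssr / df_den)
        p = float(f_dist.sf(f, df_num, df_den))
        return AncovaResult(float(f), df_num, df_den, p, term, levene_p)

    resid_by_group = [
        with_group.resid[df.group == g].to_numpy() for g in counts.index
    ]
    lev_p = float(levene(*resid_by_group).pvalue)
    group_res = nested_f(base, with_group, "group", lev_p)
    slope_res = nested_f(with_group, with_inter, "slope-heterogeneity", lev_p)
    return group_res, slope_res


def length_sst_regression(
    records: Sequence[ZooidRecord],
) -> tuple[float, float, float, float]:
    """OLS of zooid length on SST: (slope, intercept, R^2, slope p-value)."""
    if len(records) < 3:
        raise DataError(f"regression needs >= 3 records, got {len(records)}")
    sst = np.array([r.sst for r in records])
    lz = np.array([r.l_z for r in records])
    if np.ptp(sst) == 0:
        raise DegenerateDesignError("SST is constant across records")
    x = sm.add_constant(sst)
    fit = sm.OLS(lz, x).fit()
    return (
        float(fit.params[1]),
        float(fit.params[0]),
        float(fit.rsquared),
        float(fit.pvalues[1]),
    )
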