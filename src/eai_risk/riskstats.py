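"""Risk accounting: class-area proportions, elevation-band stratification,
scenario trend rates, period means and period-over-period change rates.

Proportion tables are plain pandas DataFrames with class labels as the
index and strata (whole region, or elevation bands) as columns; every
column sums to 100 (percent of unmasked area in that stratum).  Area is
cell count times cell area — no latitude-dependent correction is applied,
since the pipeline is projection-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassScheme
from .gridcore import Grid, GridError, _mask_union

#: The four 20-year forecast windows used throughout the future analysis.
PERIODS: dict[str, tuple[int, int]] = {
    "2021-2040": (2021, 2040),
    "2041-2060": (2041, 2060),
    "2061-2080": (2061, 2080),
    "2081-2100": (2081, 2100),
}

SCENARIOS = ("SSP126", "SSP245", "SSP370", "SSP585")


@dataclass
class ElevationBands:
    """Altitude band edges; the defaults cut the plateau at 2300, 3600,
    4400 and 5000 m into five bands."""

    edges: list[float] = field(
        default_factory=lambda: [2300.0, 3600.0, 4400.0, 5000.0])
    labels: list[str] = field(default_factory=lambda: [
        "<2300m", "2300-3600m", "3600-4400m", "4400-5000m", ">5000m"])

    def __post_init__(self) -> None:
        if sorted(self.edges) != list(self.edges) or \
                len(set(self.edges)) != len(self.edges):
            raise ValueError("band edges must be strictly increasing")
        if len(self.labels) != len(self.edges) + 1:
            raise ValueError("need one more label than edges")

    def band_index(self, altitude: np.ndarray) -> np.ndarray:
        return np.searchsorted(np.asarray(self.edges), altitude,
                               side="right")


@dataclass
class ScenarioSeries:
    """Per-year regional means of one variable for one scenario member."""

    scenario_id: str
    member_id: str
    years: np.ndarray
    values: np.ndarray
    variable: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must have the same length")
        if len(self.years) > 1 and not (np.diff(self.years) > 0).all():
            raise ValueError("years must be strictly increasing")


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def class_proportions(class_raster: Grid, scheme: ClassScheme,
                      stratum: str = "region") -> pd.DataFrame:
    """Percentage of unmasked cells in each class of the scheme."""
    valid = ~class_raster.nodata_mask
    n = int(valid.sum())
    codes = np.rint(class_raster.values[valid]).astype(np.int64)
    col = []
    for code in range(scheme.n_classes):
        col.append(100.0 * (codes == code).sum() / n if n else np.nan)
    return pd.DataFrame({stratum: col}, index=scheme.labels)


def band_proportions(class_raster: Grid, dem: Grid, scheme: ClassScheme,
                     bands: ElevationBands | None = None
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-elevation-band class percentages and each band's share of the
    total unmasked area.

    Returns ``(props, band_share)``: props has one column per band, each
    summing to 100; a band with no cells is reported as an all-NaN column
    (empty, not 0/0).  band_share sums to 100 over non-empty bands.
    """
    if bands is None:
        bands = ElevationBands()
    if not class_raster.same_geometry(dem):
        raise GridError("class raster and DEM are not aligned")
    valid = (~class_raster.nodata_mask) & (~dem.nodata_mask)
    codes = np.rint(class_raster.values[valid]).astype(np.int64)
    band_idx = bands.band_index(dem.values[valid])
    n_total = int(valid.sum())
    props = pd.DataFrame(index=scheme.labels, dtype=np.float64)
    shares = []
    for b, label in enumerate(bands.labels):
        in_band = band_idx == b
        nb = int(in_band.sum())
        shares.append(100.0 * nb / n_total if n_total else np.nan)
        if nb == 0:
            props[label] = np.nan
            continue
        props[label] = [100.0 * (codes[in_band] == c).sum() / nb
                        for c in range(scheme.n_classes)]
    return props, pd.Series(shares, index=bands.labels, name="band_share")


def change_rates(prop_t1: pd.DataFrame,
                 prop_t2: pd.DataFrame) -> pd.DataFrame:
    """Per-class percentage-point differences prop_t2 - prop_t1.

    Within each stratum the differences sum to 0 (both inputs sum to 100).
    """
    if list(prop_t1.index) != list(prop_t2.index) or \
            list(prop_t1.columns) != list(prop_t2.columns):
        raise ValueError("proportion tables have mismatched classes/strata")
    return prop_t2 - prop_t1


# ---------------------------------------------------------------------------
# Scenario series
# ---------------------------------------------------------------------------

def ensemble_mean(members: list[ScenarioSeries]) -> ScenarioSeries:
    """Unweighted per-year mean across ensemble members."""
    if not members:
        raise ValueError("no members supplied")
    ref = members[0]
    for m in members[1:]:
        if m.scenario_id != ref.scenario_id:
            raise ValueError("members span different scenarios")
        if not np.array_equal(m.years, ref.years):
            raise ValueError("members have mismatched year grids")
        if m.units != ref.units or m.variable != ref.variable:
            raise ValueError("members have mismatched variable/units")
    values = np.mean([m.values for m in members], axis=0)
    return ScenarioSeries(ref.scenario_id, "ensemble_mean", ref.years.copy(),
                          values, ref.variable, ref.units)


def trend_rate(series: ScenarioSeries) -> tuple[float, float]:
    """OLS trend of the series on calendar year, as (rate per decade, R^2).

    A perfectly constant series is reported as (0.0, 0.0) — no trend, and
    no explained variance by convention.
    """
    if len(series.years) < 3:
        raise ValueError("need at least 3 years for a trend")
    if len(np.unique(series.years)) < 2:
        raise ValueError("constant year vector")
    y = series.values
    if np.allclose(y, y[0]):
        return 0.0, 0.0
    res = stats.linregress(series.years.astype(np.float64), y)
    return float(res.slope * 10.0), float(res.rvalue ** 2)


def period_mean_stack(per_year_rasters: dict[int, Grid],
                      period: str | tuple[int, int]) -> Grid:
    """Cell-wise mean raster over one forecast period's years.

    A cell masked in any year is masked in the mean (mask union).
    """
    if isinstance(period, str):
        if period not in PERIODS:
            raise ValueError(f"unknown period {period!r}; "
                             f"known: {list(PERIODS)}")
        start, end = PERIODS[period]
    else:
        start, end = period
    years = list(range(start, end + 1))
    missing = [y for y in years if y not in per_year_rasters]
    if missing:
        raise ValueError(f"missing years for period {start}-{end}: "
                         f"{missing}")
    grids = [per_year_rasters[y] for y in years]
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise GridError("per-year rasters are not aligned")
    mask = _mask_union(grids)
    vals = np.mean([g.values for g in grids], axis=0)
    vals = np.where(mask, 0.0, vals)
    return Grid(vals, mask, ref.cell_size, ref.origin, ref.crs_tag)


# ---------------------------------------------------------------------------
# Series CSV I/O (columns: scenario, member, year, variable, value, units)
# ---------------------------------------------------------------------------

def series_to_frame(series_list: list[ScenarioSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for yr, v in zip(s.years, s.values):
            rows.append({"scenario": s.scenario_id, "member": s.member_id,
                         "year": int(yr), "variable": s.variable,
                         "value": float(v), "units": s.units})
    return pd.DataFrame(rows)


def frame_to_series(df: pd.DataFrame) -> list[ScenarioSeries]:
    out = []
    for (scen, member, var), sub in df.groupby(
            ["scenario", "member", "variable"], sort=False):
        sub = sub.sort_values("year")
        units = str(sub["units"].iloc[0]) if "units" in sub else ""
        out.append(ScenarioSeries(str(scen), str(member),
                                  sub["year"].to_numpy(),
                                  sub["value"].to_numpy(), str(var), units))
    return out
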