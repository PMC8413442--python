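"""Self-contained synthetic inputs with the spatial structure the analysis
assumes: a plateau-like base scene and future climate-scenario series.

The base scene emulates three features of the Qinghai-Tibet Plateau setting:

* a northwest -> southeast gradient in every quality factor (quality, and
  hence the EAI, improves towards the southeast; ecological risk decreases),
* terrain that is highest in the northwest, with the five altitude bands
  (<2300, 2300-3600, 3600-4400, 4400-5000, >5000 m) occupying prescribed
  area shares (defaults 1.97 / 16.11 / 21.52 / 37.75 / 22.65 percent),
* per-factor spatially coherent noise (moving-average smoothed), so
  natural-breaks classes are nontrivial.

Scenario series are linear-in-time trends on precipitation and temperature
at per-decade rates of 7.2/10.5/12.3/16.6 mm and 0.07/0.28/0.56/0.62 degC
for SSP126/245/370/585, with interannual noise and a spatial rate pattern
in which precipitation rises fastest in the southeast and temperature
fastest in the northwest.

Everything is a pure function of its seed: one shared seed expands into
fixed, named sub-streams (one per factor / member), so adding a factor
never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .classify import classify_by_breaks, reference_schemes
from .gridcore import FactorStack, Grid
from .indices import (IndexWeights, compute_cqi, compute_sqi, compute_vqi,
                      compute_eai)
from .riskstats import ScenarioSeries
from .scoring import default_tables

YEARS = np.arange(2021, 2101)

#: (precipitation mm/decade, temperature degC/decade) per SSP scenario.
SCENARIO_RATES: dict[str, tuple[float, float]] = {
    "SSP126": (7.2, 0.07),
    "SSP245": (10.5, 0.28),
    "SSP370": (12.3, 0.56),
    "SSP585": (16.6, 0.62),
}

#: Fixed sub-stream indices: the counter scheme that expands one scene seed
#: into independent per-factor streams.  Append-only.
_STREAMS = {
    "DEM": 0, "Pr": 1, "T": 2, "Di": 3, "Par": 4, "At": 5,
    "Sd": 6, "St": 7, "Sei": 8, "Som": 9, "Sm": 10,
    "Vc": 11, "Vr": 12, "Vrr": 13, "NPP": 14, "A": 15,
    "sampling": 16, "scenario": 17,
}

#: Raw-value ranges: each factor is an affine map of its latent quality
#: field q' in [0, 1], spanning (a little beyond) all bins of its score
#: table.  Categorical factors quantise q' into their class codes.
_FACTOR_RANGES: dict[str, tuple[float, float]] = {
    "Pr": (30.0, 1030.0),     # mm / yr
    "T": (-8.0, 14.0),        # degC
    "Di": (0.02, 0.82),       # P / PET
    "Par": (3200.0, 4000.0),  # MJ / m2
    "At": (200.0, 7000.0),    # degree-days
    "Sd": (0.0, 160.0),       # cm
    "St": (0.05, 0.95),       # texture index
    "Som": (0.2, 12.2),       # percent
    "Sm": (0.03, 0.16),       # m3 / m3
    "Vc": (0.0, 170.0),       # coverage (table bins run past 100)
    "Vr": (0.001, 0.301),     # richness index
    "NPP": (10.0, 1410.0),    # gC / m2 / yr
}
_FACTOR_NCODES = {"Sei": 6, "Vrr": 4, "A": 4}


@dataclass
class SceneSpec:
    """Conditions for the synthetic base scene."""

    shape: tuple[int, int] = (200, 200)
    seed: int = 0
    band_shares: tuple[float, ...] = (0.0197, 0.1611, 0.2152, 0.3775, 0.2265)
    noise_sd: float = 0.10       # latent-quality units, after smoothing
    cell_size: float = 500.0     # m
    origin: tuple[float, float] = (0.0, 0.0)
    band_edges: tuple[float, ...] = (2300.0, 3600.0, 4400.0, 5000.0)
    dem_range: tuple[float, float] = (1200.0, 6500.0)

    def __post_init__(self) -> None:
        if abs(sum(self.band_shares) - 1.0) > 1e-9:
            raise ValueError(
                f"band_shares must sum to 1, got {sum(self.band_shares)!r}")
        if len(self.band_shares) != len(self.band_edges) + 1:
            raise ValueError("need one band share per altitude band")


@dataclass
class ScenarioSpec:
    """Conditions for one future scenario's synthetic series.

    Interannual noise is split into a yearly anomaly shared by all ensemble
    members plus smaller member-specific deviations; the shared part sets
    the variability of the ensemble-mean series.
    """

    scenario_id: str = "SSP126"
    pr_rate: float | None = None   # mm / decade; None -> scenario default
    t_rate: float | None = None    # degC / decade
    spatial_rate_pattern: str = "pr_fast_SE_t_fast_NW"  # or 'uniform'
    pr_noise_sd: float = 38.0      # shared yearly anomaly, mm
    t_noise_sd: float = 0.40       # shared yearly anomaly, degC
    pr_member_sd: float = 15.0     # member deviation, mm
    t_member_sd: float = 0.15      # member deviation, degC
    n_members: int = 9
    seed: int = 0
    years: np.ndarray = field(default_factory=lambda: YEARS.copy())

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        if self.years.min() < 2021 or self.years.max() > 2100:
            raise ValueError("scenario years must lie within 2021-2100")
        if self.spatial_rate_pattern not in ("uniform",
                                             "pr_fast_SE_t_fast_NW"):
            raise ValueError(
                f"unknown pattern {self.spatial_rate_pattern!r}")
        if self.pr_rate is None or self.t_rate is None:
            if self.scenario_id not in SCENARIO_RATES:
                raise ValueError(
                    f"no default rates for scenario {self.scenario_id!r}; "
                    "supply pr_rate and t_rate")
            pr, t = SCENARIO_RATES[self.scenario_id]
            if self.pr_rate is None:
                self.pr_rate = pr
            if self.t_rate is None:
                self.t_rate = t


def _rng(seed: int, stream: str, extra: tuple[int, ...] = ()) -> \
        np.random.Generator:
    key = (_STREAMS[stream], *extra)
    return np.random.default_rng(np.random.SeedSequence(seed,
                                                        spawn_key=key))


def _ramp(shape: tuple[int, int]) -> np.ndarray:
    """NW -> SE ramp in [0, 1]: 0 at the northwest corner (row 0, col 0)."""
    r = np.linspace(0.0, 1.0, shape[0])[:, None]
    c = np.linspace(0.0, 1.0, shape[1])[None, :]
    return (r + c) / 2.0


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator,
                  sd: float, kernel: int = 5) -> np.ndarray:
    """Zero-mean spatially coherent noise with the requested pointwise sd."""
    if sd == 0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    sm = ndimage.uniform_filter(raw, size=kernel, mode="nearest")
    sm -= sm.mean()
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def _latent(spec: SceneSpec, factor: str) -> np.ndarray:
    noise = _smooth_noise(spec.shape, _rng(spec.seed, factor), spec.noise_sd)
    return np.clip(_ramp(spec.shape) + noise, 0.0, 1.0)


def _dem_values(spec: SceneSpec) -> np.ndarray:
    """Terrain highest in the NW, with band area shares met by rank
    mapping: cells are ranked on a NW-high latent field and the sorted
    ranks are carved into the five altitude bands at the prescribed
    cumulative shares."""
    d = 1.0 - _ramp(spec.shape) + _smooth_noise(
        spec.shape, _rng(spec.seed, "DEM"), spec.noise_sd)
    flat = d.ravel()
    order = np.argsort(flat, kind="stable")
    n = flat.size
    lo_alt, hi_alt = spec.dem_range
    alt_edges = [lo_alt, *spec.band_edges, hi_alt]
    cum = np.concatenate([[0.0], np.cumsum(spec.band_shares)])
    counts = np.diff(np.rint(cum * n).astype(int))
    dem = np.empty(n)
    pos = 0
    for b, cnt in enumerate(counts):
        if cnt <= 0:
            continue
        # low ranks of d = low altitude; spread linearly inside the band,
        # keeping strictly inside [edge_lo, edge_hi)
        frac = (np.arange(cnt) + 0.5) / cnt
        dem[order[pos:pos + cnt]] = (alt_edges[b]
                                     + frac * (alt_edges[b + 1]
                                               - alt_edges[b]))
        pos += cnt
    return dem.reshape(spec.shape)


def generate_base_scene(spec: SceneSpec | None = None) -> FactorStack:
    """Generate the 16 factor rasters plus DEM as an aligned FactorStack.

    Deterministic for a fixed seed; every raw value lies in the domain of
    its score table; quality rises NW -> SE while the terrain falls.
    """
    if spec is None:
        spec = SceneSpec()

    def grid(vals: np.ndarray) -> Grid:
        return Grid(vals, None, spec.cell_size, spec.origin, "synthetic")

    stack = FactorStack()
    dem = _dem_values(spec)
    stack["DEM"] = grid(dem)
    stack["Al"] = grid(dem.copy())
    for name, (lo, hi) in _FACTOR_RANGES.items():
        stack[name] = grid(lo + (hi - lo) * _latent(spec, name))
    for name, ncodes in _FACTOR_NCODES.items():
        q = _latent(spec, name)
        codes = np.minimum((q * ncodes).astype(np.int64), ncodes - 1) + 1
        stack[name] = grid(codes.astype(np.float64))
    return stack


def generate_scenario_series(
        base: FactorStack, spec: ScenarioSpec
) -> tuple[dict[int, dict[str, Grid]], list[ScenarioSeries]]:
    """Yearly Pr and T fields for one scenario plus per-member regional
    series.

    Fields: base field + (rate/10) * (year - 2021) * spatial pattern
    + the shared yearly anomaly.  The pattern has regional mean 1, so the
    regional-mean trend equals the spec rate; under
    ``pr_fast_SE_t_fast_NW`` the per-cell precipitation slope grows towards
    the southeast and the temperature slope towards the northwest.  Static
    factors are untouched (soil properties are assumed unchanged).

    Series: one :class:`ScenarioSeries` per member and variable — the base
    regional mean plus the trend, the shared anomaly and the member's own
    deviation.
    """
    base.require(["Pr", "T"], context="scenario generation")
    pr0, t0 = base["Pr"], base["T"]
    shape = pr0.shape
    ramp = _ramp(shape)
    if spec.spatial_rate_pattern == "uniform":
        pat_pr = pat_t = np.ones(shape)
    else:
        pat_pr = 2.0 * ramp          # mean 1, largest in the SE
        pat_t = 2.0 * (1.0 - ramp)   # mean 1, largest in the NW
    pat_pr = pat_pr / pat_pr.mean()
    pat_t = pat_t / pat_t.mean()

    rng = _rng(spec.seed, "scenario",
               (zlib.crc32(spec.scenario_id.encode()),))
    ny = len(spec.years)
    shared_pr = rng.normal(0.0, spec.pr_noise_sd, ny)
    shared_t = rng.normal(0.0, spec.t_noise_sd, ny)
    member_pr = rng.normal(0.0, spec.pr_member_sd, (spec.n_members, ny))
    member_t = rng.normal(0.0, spec.t_member_sd, (spec.n_members, ny))

    dy = (spec.years - 2021).astype(np.float64)
    fields: dict[int, dict[str, Grid]] = {}
    for i, year in enumerate(spec.years):
        pr_vals = (pr0.values + (spec.pr_rate / 10.0) * dy[i] * pat_pr
                   + shared_pr[i])
        t_vals = (t0.values + (spec.t_rate / 10.0) * dy[i] * pat_t
                  + shared_t[i])
        fields[int(year)] = {
            "Pr": pr0.with_values(np.maximum(pr_vals, 0.0)),
            "T": t0.with_values(t_vals),
        }

    pr_mean0 = float(pr0.unmasked_values().mean())
    t_mean0 = float(t0.unmasked_values().mean())
    series: list[ScenarioSeries] = []
    for m in range(spec.n_members):
        mid = f"member_{m + 1:02d}"
        series.append(ScenarioSeries(
            spec.scenario_id, mid, spec.years.copy(),
            pr_mean0 + (spec.pr_rate / 10.0) * dy + shared_pr + member_pr[m],
            "Pr", "mm"))
        series.append(ScenarioSeries(
            spec.scenario_id, mid, spec.years.copy(),
            t_mean0 + (spec.t_rate / 10.0) * dy + shared_t + member_t[m],
            "T", "degC"))
    return fields, series


def generate_weight_training_samples(
        stack: FactorStack, n: int, seed: int = 0,
        true_weights: IndexWeights = IndexWeights(0.6, 0.2, 0.2),
) -> pd.DataFrame:
    """Labelled (CQI, SQI, VQI) samples for weight-recovery experiments.

    The label is the five-class risk grade of a hidden ground-truth EAI
    built with ``true_weights``; estimating weights from these samples and
    comparing against ``true_weights`` closes the loop.
    """
    tables = default_tables()
    cqi = compute_cqi(stack, tables)
    sqi = compute_sqi(stack, tables)
    vqi = compute_vqi(stack, tables)
    eai = compute_eai(cqi, sqi, vqi, true_weights)
    risk = classify_by_breaks(eai.grid, reference_schemes()["eai_risk"])

    valid = ~eai.grid.nodata_mask
    idx = np.flatnonzero(valid.ravel())
    if n > len(idx):
        raise ValueError(f"n={n} exceeds the {len(idx)} unmasked cells")
    rng = _rng(seed, "sampling")
    chosen = rng.choice(idx, size=n, replace=False)
    labels = risk.values.ravel()[chosen].astype(int)
    scheme = reference_schemes()["eai_risk"]
    return pd.DataFrame({
        "CQI": cqi.grid.values.ravel()[chosen],
        "SQI": sqi.grid.values.ravel()[chosen],
        "VQI": vqi.grid.values.ravel()[chosen],
        "reference_label": [scheme.labels[c] for c in labels],
    })
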