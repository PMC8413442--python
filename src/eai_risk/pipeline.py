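"""End-to-end orchestration: base-period and future scenario runs.

A run is fully described by a :class:`RunConfig` (loadable from YAML) and
is reproducible from it: all randomness flows from the config seed, and a
provenance JSON (config hash, seed, versions) is written next to the
outputs.

Base run: factors -> scores -> CQI/SQI/VQI -> EAI -> five-class risk ->
region and elevation-band proportion tables.

Future run, per scenario x 20-year period: period-mean dynamic factors
(precipitation and temperature; soil held static) -> rescored -> indices ->
EAI -> classification with the base break scheme (fixed by default, for
cross-period comparability) -> band proportions -> change vs the base
period; plus an OLS rate/R^2 table from the ensemble-mean regional series.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (ClassScheme, classify_by_breaks, reference_schemes,
                       scheme_from_jenks)
from .gridcore import (FACTOR_KINDS, FactorStack, Grid, GridError,
                       read_grid, write_grid)
from .indices import (IndexWeights, compute_cqi, compute_eai, compute_sqi,
                      compute_vqi, estimate_weights)
from .riskstats import (ElevationBands, PERIODS, band_proportions,
                        change_rates, class_proportions, ensemble_mean,
                        period_mean_stack, trend_rate)
from .scoring import default_tables, load_tables
from .synthetic import (SceneSpec, ScenarioSpec, generate_base_scene,
                        generate_scenario_series,
                        generate_weight_training_samples)

logger = logging.getLogger("eai_risk")

ALL_INDEX_FACTORS = ("Pr", "T", "Di", "Al", "Par", "At",
                     "Sd", "St", "Sei", "Som", "Sm",
                     "Vc", "Vr", "Vrr", "NPP", "A")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """One pipeline run.  Exactly one of ``factor_paths`` (real rasters) or
    ``synthetic`` (generator spec) must be supplied."""

    out_dir: str = "eai_run"
    seed: int = 0
    synthetic: dict | None = None          # SceneSpec kwargs
    factor_paths: dict[str, str] | None = None
    tables_path: str | None = None         # None -> shipped defaults
    weights: tuple[float, float, float] = (0.6, 0.2, 0.2)
    estimate_weights_from_samples: bool = False
    n_weight_samples: int = 2000
    classification: str = "reference"      # 'reference' | 'jenks'
    band_edges: tuple[float, ...] = (2300.0, 3600.0, 4400.0, 5000.0)
    scenarios: tuple[str, ...] = ("SSP126", "SSP245", "SSP370", "SSP585")
    periods: tuple[str, ...] = tuple(PERIODS)
    scenario_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.factor_paths is None):
            raise ConfigError(
                "exactly one of 'synthetic' or 'factor_paths' must be set")
        if self.classification not in ("reference", "jenks"):
            raise ConfigError(
                f"classification must be 'reference' or 'jenks', "
                f"got {self.classification!r}")
        for p in self.periods:
            if p not in PERIODS:
                raise ConfigError(f"unknown period {p!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("weights", "band_edges", "scenarios", "periods"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------

def _load_stack(config: RunConfig) -> FactorStack:
    if config.synthetic is not None:
        spec = SceneSpec(seed=config.seed, **config.synthetic)
        return generate_base_scene(spec)
    paths = config.factor_paths or {}
    missing = [f for f in (*ALL_INDEX_FACTORS, "DEM") if f not in paths]
    unreadable = [f"{f} ({paths[f]})" for f in paths
                  if not Path(paths[f]).exists()]
    problems = []
    if missing:
        problems.append(f"factors without a path: {', '.join(missing)}")
    if unreadable:
        problems.append(f"missing raster files: {', '.join(unreadable)}")
    if problems:
        raise ConfigError("; ".join(problems))
    stack = FactorStack()
    for name, path in paths.items():
        stack[name] = read_grid(path)
    return stack


def _tables(config: RunConfig):
    if config.tables_path:
        return load_tables(config.tables_path)
    return default_tables()


def _risk_scheme(config: RunConfig, eai_grid: Grid) -> ClassScheme:
    if config.classification == "jenks":
        scheme = scheme_from_jenks(
            eai_grid, 5, ["HeERA", "HERA", "LERA", "LeERA", "PERA"],
            scheme_id="eai_risk_jenks", orientation="risk")
        logger.info("Jenks risk breaks: %s",
                    [round(b, 4) for b in scheme.breaks])
        return scheme
    return reference_schemes()["eai_risk"]


def _write_provenance(config: RunConfig, out: Path, extra: dict) -> None:
    record = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "conventions": {
            "bin_endpoints": "lower-closed [a, b); break belongs to upper "
                             "class",
            "eai_form": "three-term: w_cqi*CQI + w_sqi*SQI + w_vqi*VQI",
            "classification_mode": config.classification,
        },
        **extra,
    }
    (out / "provenance.json").write_text(json.dumps(record, indent=2,
                                                    default=str))


def run_base_period(config: RunConfig) -> dict:
    """Run the base-period assessment and write all artifacts to
    ``config.out_dir``.  Validates the full factor set before writing
    anything; idempotent for a fixed config."""
    logger.info("base run: conventions: lower-closed bins, three-term EAI, "
                "%s classification", config.classification)
    stack = _load_stack(config)
    stack.require((*ALL_INDEX_FACTORS, "DEM"), context="base run")
    tables = _tables(config)

    cqi = compute_cqi(stack, tables)
    sqi = compute_sqi(stack, tables)
    vqi = compute_vqi(stack, tables)

    weight_info: dict = {}
    if config.estimate_weights_from_samples:
        samples = generate_weight_training_samples(
            stack, config.n_weight_samples, seed=config.seed)
        weights, goodness = estimate_weights(samples, seed=config.seed)
        weight_info = {"estimated_weights": weights.as_tuple(),
                       "oob_goodness": goodness}
        logger.info("estimated weights %s (OOB goodness %.4f)",
                    weights.as_tuple(), goodness)
    else:
        weights = IndexWeights(*config.weights)

    eai = compute_eai(cqi, sqi, vqi, weights)
    scheme = _risk_scheme(config, eai.grid)
    risk = classify_by_breaks(eai.grid, scheme)

    bands = ElevationBands(list(config.band_edges))
    props = class_proportions(risk, scheme)
    band_props, band_share = band_proportions(risk, stack["DEM"], scheme,
                                              bands)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, idx in (("cqi", cqi), ("sqi", sqi), ("vqi", vqi),
                      ("eai", eai)):
        write_grid(idx.grid, out / f"{name}.tif")
    write_grid(risk, out / "risk.tif")
    pd.DataFrame(scheme.legend()).to_csv(out / "risk_legend.csv",
                                         index=False)
    props.to_csv(out / "proportions.csv")
    band_props.to_csv(out / "band_proportions.csv")
    band_share.to_csv(out / "band_shares.csv")
    _write_provenance(config, out, weight_info)

    return {"stack": stack, "cqi": cqi, "sqi": sqi, "vqi": vqi, "eai": eai,
            "risk": risk, "scheme": scheme, "weights": weights,
            "proportions": props, "band_proportions": band_props,
            "band_share": band_share, "bands": bands, **weight_info}


def run_future(config: RunConfig, base: dict | None = None) -> dict:
    """Per-scenario, per-period future risk: rasters, band proportions,
    change-vs-base tables and the trend-rate table."""
    if base is None:
        base = run_base_period(config)
    if config.synthetic is None:
        raise ConfigError(
            "future runs need synthetic scenario series (real per-year "
            "rasters are driven through the library API)")
    stack: FactorStack = base["stack"]
    tables = _tables(config)
    weights: IndexWeights = base["weights"]
    scheme: ClassScheme = base["scheme"]
    bands: ElevationBands = base["bands"]
    dem = stack["DEM"]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rate_rows = []
    results: dict[str, dict] = {}
    for scen in config.scenarios:
        spec = ScenarioSpec(scenario_id=scen, seed=config.seed,
                            **config.scenario_overrides.get(scen, {}))
        fields, series = generate_scenario_series(stack, spec)
        for var, units in (("Pr", "mm"), ("T", "degC")):
            members = [s for s in series if s.variable == var]
            rate, r2 = trend_rate(ensemble_mean(members))
            rate_rows.append({"scenario": scen, "variable": var,
                              "rate_per_decade": rate, "r_squared": r2,
                              "units": f"{units}/10a"})
        scen_out: dict[str, dict] = {}
        for period in config.periods:
            dyn = {}
            for var in ("Pr", "T"):
                per_year = {y: fields[y][var] for y in fields}
                dyn[var] = period_mean_stack(per_year, period)
            future_stack = FactorStack(
                {**{k: g for k, g in stack.grids.items()}, **dyn})
            cqi = compute_cqi(future_stack, tables)
            sqi = base["sqi"]  # soil static by assumption
            vqi = base["vqi"]
            eai = compute_eai(cqi, sqi, vqi, weights)
            risk = classify_by_breaks(eai.grid, scheme)
            props, _ = band_proportions(risk, dem, scheme, bands)
            change = change_rates(base["band_proportions"], props)
            tag = f"{scen}_{period}"
            write_grid(risk, out / f"risk_{tag}.tif")
            props.to_csv(out / f"band_props_{tag}.csv")
            change.to_csv(out / f"change_{tag}.csv")
            scen_out[period] = {"risk": risk, "eai": eai,
                                "band_proportions": props, "change": change}
        results[scen] = scen_out

    rates = pd.DataFrame(rate_rows)
    rates.to_csv(out / "trend_rates.csv", index=False)
    return {"scenarios": results, "trend_rates": rates}
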