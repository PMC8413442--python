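# eai-risk

Ecological-risk assessment with the **Environmental Area Index (EAI)** — a
raster pipeline for high-mountain regions such as the Qinghai-Tibet
Plateau, where climate change reshapes risk differently along the
elevation gradient.

The package is for landscape ecologists and climate-impact analysts who
want to (a) turn environmental factor rasters into a five-class ecological
risk map, (b) stratify that risk by elevation band, and (c) project it
forward under CMIP6 SSP scenario trends. Everything runs on fully
synthetic inputs out of the box, so the whole pipeline is testable without
any data downloads.

## The model

Sixteen environmental factors are scored on a 1.25–10 scale through
published lookup tables and combined into three quality indices by
cell-wise geometric mean:

```
CQI = (Pr · T · Di · Al · Par · At)^(1/6)        climate quality
SQI = (Sd · St · Sei · Som · Sm)^(1/5)           soil quality
VQI = (Vc · Vr · Vrr · NPP · A)^(1/5)            vegetation quality
```

(Pr precipitation, T temperature, Di drought index, Al altitude, Par
photosynthetically active radiation, At accumulated temperature ≥ 10 °C;
Sd soil depth, St texture, Sei erosion class, Som organic matter, Sm
moisture; Vc vegetation cover, Vr richness, Vrr resistance class, NPP net
primary productivity, A aspect class.)

The Environmental Area Index is their weighted sum

```
EAI = α·CQI + β·SQI + γ·VQI,   (α, β, γ) = (0.6, 0.2, 0.2) by default,
```

with weights obtainable from random-forest variable importance on labelled
samples (`estimate_weights`, mtry = 2, ntree = 1000). **Low EAI means high
ecological risk.** The EAI is graded into five risk classes — HeERA, HERA,
LERA, LeERA, PERA from higher risk to potential risk only — either with
the published fixed breaks (2.66 / 3.66 / 4.86 / 6.18) or with exact
Fisher–Jenks natural breaks. Risk shares are then tabulated per elevation
band (< 2300, 2300–3600, 3600–4400, 4400–5000, > 5000 m) and, for the four
SSP scenarios over 2021–2100, per 20-year period, together with OLS trend
rates (units per decade) of the scenario ensembles.

## Worked example

```python
import eai_risk as er

tables = er.default_tables()                     # the 16 score tables
scene = er.generate_base_scene(er.SceneSpec(shape=(200, 200), seed=42))

cqi = er.compute_cqi(scene, tables)
sqi = er.compute_sqi(scene, tables)
vqi = er.compute_vqi(scene, tables)
eai = er.compute_eai(cqi, sqi, vqi)              # weights 0.6/0.2/0.2

scheme = er.reference_schemes()["eai_risk"]
risk = er.classify_by_breaks(eai.grid, scheme)
props, share = er.band_proportions(risk, scene["DEM"], scheme)
print(props.round(2))
```

```
       <2300m  2300-3600m  3600-4400m  4400-5000m  >5000m
HeERA     0.0        0.00        0.00        0.01    5.62
HERA      0.0        0.00        0.00        0.68   26.03
LERA      0.0        0.00        0.00        6.50   41.83
LeERA     0.0        0.12        3.14       44.91   25.81
PERA    100.0       99.88       96.86       47.89    0.72
```

Each column is one elevation band and sums to 100 % of that band's area.
The synthetic scene is built with quality improving from northwest to
southeast and terrain falling the same way, so the table shows the
expected vertical structure: the lowlands are entirely potential-risk
(PERA), while the share of the high-risk classes (HERA + HeERA) grows
with altitude. Scenario series recover their construction too:

```python
fields, series = er.generate_scenario_series(
    scene, er.ScenarioSpec("SSP585", seed=42))
pr = er.ensemble_mean([s for s in series if s.variable == "Pr"])
rate, r2 = er.trend_rate(pr)
# SSP585 precipitation trend: 16.4 mm/decade (R^2 = 0.48)
```

i.e. an 80-year ensemble built with a 16.6 mm/decade trend is estimated at
16.4 mm/decade by the OLS trend fit.

The same pipeline is scriptable from the shell:

```sh
eai-risk simulate scene --shape 200x200 --seed 42 --out-dir scene/
eai-risk run --config config.yaml
eai-risk classify --input eai.tif --scheme eai_risk --output risk.tif
```

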