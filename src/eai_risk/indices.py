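"""Quality indices and the Environmental Area Index (EAI).

The three quality indices are geometric means of scored factors:

    CQI = (Pr * T * Di * Al * Par * At)^(1/6)
    SQI = (Sd * St * Sei * Som * Sm)^(1/5)
    VQI = (Vc * Vr * Vrr * NPP * A)^(1/5)

where each symbol stands for the *score* raster of that factor.  The EAI is
their convex combination

    EAI = w_cqi * CQI + w_sqi * SQI + w_vqi * VQI

with default weights (0.6, 0.2, 0.2) derived from random-forest variable
importance.  Low EAI means high ecological risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .gridcore import (CLIMATE_FACTORS, FactorStack, Grid, GridError,
                       SOIL_FACTORS, VEGETATION_FACTORS, _mask_union)
from .scoring import ScoreTable, score_factor


@dataclass
class IndexRaster:
    """A computed quality/risk index with its identity tag."""

    index_id: str  # CQI | SQI | VQI | EAI
    grid: Grid


@dataclass(frozen=True)
class IndexWeights:
    """Weights of CQI, SQI, VQI in the EAI; non-negative, summing to 1."""

    w_cqi: float = 0.6
    w_sqi: float = 0.2
    w_vqi: float = 0.2

    def __post_init__(self) -> None:
        w = (self.w_cqi, self.w_sqi, self.w_vqi)
        if any(x < 0 for x in w):
            raise ValueError(f"weights must be non-negative: {w}")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(w)!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_cqi, self.w_sqi, self.w_vqi)


def geometric_mean_index(scores: list[Grid], index_id: str) -> IndexRaster:
    """Cell-wise n-th root of the product of n score grids.

    All inputs must be aligned and strictly positive at unmasked cells
    (score tables guarantee positivity; a zero or negative score signals a
    corrupted table).  The output mask is the union of input masks.
    """
    if not scores:
        raise GridError("geometric_mean_index: no score grids")
    ref = scores[0]
    for g in scores[1:]:
        if not ref.same_geometry(g):
            raise GridError(f"{index_id}: score grids are not aligned")
    mask = _mask_union(scores)
    log_sum = np.zeros(ref.shape, dtype=np.float64)
    for g in scores:
        bad = (~g.nodata_mask) & (g.values <= 0)
        if bad.any():
            raise ValueError(
                f"{index_id}: {int(bad.sum())} unmasked cell(s) carry a "
                "non-positive score; check the score tables")
        log_sum += np.where(g.nodata_mask, 0.0, np.log(g.values))
    vals = np.where(mask, 0.0, np.exp(log_sum / len(scores)))
    return IndexRaster(index_id, Grid(vals, mask, ref.cell_size, ref.origin,
                                      ref.crs_tag))


def _scored_stack(stack: FactorStack, tables: dict[str, ScoreTable],
                  factors: tuple[str, ...], index_id: str) -> list[Grid]:
    stack.require(factors, context=index_id)
    missing_tables = [f for f in factors if f not in tables]
    if missing_tables:
        raise KeyError(f"{index_id}: no score table for "
                       f"{', '.join(missing_tables)}")
    return [score_factor(stack[f], tables[f]) for f in factors]


def compute_cqi(stack: FactorStack,
                tables: dict[str, ScoreTable]) -> IndexRaster:
    """Climate quality: geometric mean of the six scored climate factors."""
    return geometric_mean_index(
        _scored_stack(stack, tables, CLIMATE_FACTORS, "CQI"), "CQI")


def compute_sqi(stack: FactorStack,
                tables: dict[str, ScoreTable]) -> IndexRaster:
    """Soil quality: geometric mean of the five scored soil factors."""
    return geometric_mean_index(
        _scored_stack(stack, tables, SOIL_FACTORS, "SQI"), "SQI")


def compute_vqi(stack: FactorStack,
                tables: dict[str, ScoreTable]) -> IndexRaster:
    """Vegetation quality: geometric mean of the five scored vegetation
    factors."""
    return geometric_mean_index(
        _scored_stack(stack, tables, VEGETATION_FACTORS, "VQI"), "VQI")


def compute_eai(cqi: IndexRaster, sqi: IndexRaster, vqi: IndexRaster,
                weights: IndexWeights = IndexWeights()) -> IndexRaster:
    """Weighted EAI; a convex combination, so cell-wise
    min(CQI,SQI,VQI) <= EAI <= max(CQI,SQI,VQI)."""
    grids = [cqi.grid, sqi.grid, vqi.grid]
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise GridError("EAI: index rasters are not aligned")
    w = weights.as_tuple()
    mask = _mask_union(grids)
    vals = sum(wi * g.values for wi, g in zip(w, grids))
    vals = np.where(mask, 0.0, vals)
    return IndexRaster("EAI", Grid(vals, mask, ref.cell_size, ref.origin,
                                   ref.crs_tag))


def estimate_weights(samples: pd.DataFrame, n_trees: int = 1000,
                     mtry: int = 2, seed: int = 0,
                     round_weights: bool = False
                     ) -> tuple[IndexWeights, float]:
    """Estimate EAI weights from labelled (CQI, SQI, VQI) samples.

    Fits a random-forest classifier of ``reference_label`` on the three
    index columns, normalises the mean-decrease-in-impurity importances to
    sum 1 and reports the out-of-bag accuracy as the goodness of fit
    (a fraction in [0, 1]).  Fully deterministic for a fixed seed.

    Parameters
    ----------
    samples:
        DataFrame with columns ``CQI``, ``SQI``, ``VQI`` and
        ``reference_label``; at least 100 rows.
    n_trees, mtry:
        Forest size and features tried per split (mtry in {1, 2, 3}).
    round_weights:
        If True, round the normalised importances to one decimal and
        renormalise (the convention behind headline weights like
        0.6/0.2/0.2); off by default.
    """
    required = ["CQI", "SQI", "VQI", "reference_label"]
    missing = [c for c in required if c not in samples.columns]
    if missing:
        raise ValueError(f"samples missing column(s): {', '.join(missing)}")
    if len(samples) < 100:
        raise ValueError(f"need >= 100 samples, got {len(samples)}")
    if mtry not in (1, 2, 3):
        raise ValueError(f"mtry must be 1, 2 or 3, got {mtry}")
    y = samples["reference_label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("reference_label has a single class; "
                         "cannot fit a classifier")
    X = samples[["CQI", "SQI", "VQI"]].to_numpy(dtype=np.float64)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, oob_score=True,
        random_state=seed, n_jobs=1)
    forest.fit(X, y)
    imp = forest.feature_importances_
    w = imp / imp.sum()
    if round_weights:
        w = np.round(w, 1)
        w = w / w.sum()
    return IndexWeights(*map(float, w)), float(forest.oob_score_)
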