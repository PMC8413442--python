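"""Factor scoring: raw environmental rasters -> quality scores in (0, 10].

Each of the 16 factors entering the climate, soil and vegetation quality
indices has a lookup table mapping raw values (or class codes) to scores.
The default tables ship as an editable CSV
(``eai_risk/data/score_tables.csv``) so every cell can be inspected and
overridden without touching code.

Bin convention: every binned table is a step function over contiguous
lower-closed half-open intervals ``[a, b)``; the lowest interval is open
below, the highest closed above, so a value equal to a printed bound falls
in the *upper* bin.  Scores decrease with altitude (high ground is harsher)
and increase with every other continuous factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .gridcore import Grid

logger = logging.getLogger("eai_risk")

INF = float("inf")


class ScoreTableError(ValueError):
    """Malformed score table or value outside a categorical table's domain."""


@dataclass
class ScoreTable:
    """Lookup table for one factor.

    For ``kind == 'binned'``: ``bins`` is an ordered list of
    ``(lower, upper, score)`` with ``lower``/``upper`` possibly infinite;
    bins are contiguous, non-overlapping and cover the whole real line.

    For ``kind == 'categorical'``: ``categories`` maps integer class codes
    to scores and ``category_names`` maps human-readable class names to
    codes.
    """

    table_id: str
    kind: str  # 'binned' | 'categorical'
    bins: list[tuple[float, float, float]] = field(default_factory=list)
    categories: dict[int, float] = field(default_factory=dict)
    category_names: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("binned", "categorical"):
            raise ScoreTableError(f"{self.table_id}: unknown kind {self.kind!r}")
        if self.kind == "binned":
            if not self.bins:
                raise ScoreTableError(f"{self.table_id}: no bins")
            if self.bins[0][0] != -INF or self.bins[-1][1] != INF:
                raise ScoreTableError(
                    f"{self.table_id}: bins must cover (-inf, +inf)")
            for (_, hi, _), (lo2, _, _) in zip(self.bins, self.bins[1:]):
                if hi != lo2:
                    raise ScoreTableError(
                        f"{self.table_id}: bins not contiguous at {hi}/{lo2}")
            scores = [s for _, _, s in self.bins]
        else:
            if not self.categories:
                raise ScoreTableError(f"{self.table_id}: no categories")
            scores = list(self.categories.values())
        if any(not (0 < s <= 10) for s in scores):
            raise ScoreTableError(
                f"{self.table_id}: scores must lie in (0, 10]")

    # -- direction --------------------------------------------------------
    @property
    def direction(self) -> str:
        """'ascending', 'descending' (scores vs raw value) or 'categorical'."""
        if self.kind == "categorical":
            return "categorical"
        s = [b[2] for b in self.bins]
        return "ascending" if s[-1] >= s[0] else "descending"

    @property
    def score_set(self) -> set[float]:
        if self.kind == "binned":
            return {s for _, _, s in self.bins}
        return set(self.categories.values())

    # -- scalar lookup ----------------------------------------------------
    def lookup(self, value: float | str) -> float:
        """Score a single raw value, class code, or class name."""
        if self.kind == "categorical":
            if isinstance(value, str):
                if value not in self.category_names:
                    raise ScoreTableError(
                        f"{self.table_id}: unknown category {value!r}")
                value = self.category_names[value]
            code = int(value)
            if code not in self.categories:
                raise ScoreTableError(
                    f"{self.table_id}: unknown class code {code}")
            return self.categories[code]
        v = float(value)
        for lo, hi, s in self.bins:
            if lo <= v < hi or (hi == INF and v >= lo):
                return s
        raise ScoreTableError(f"{self.table_id}: no bin matches {v}")

    def _edges_scores(self) -> tuple[np.ndarray, np.ndarray]:
        edges = np.array([b[0] for b in self.bins[1:]], dtype=np.float64)
        scores = np.array([b[2] for b in self.bins], dtype=np.float64)
        return edges, scores


def score_factor(raster: Grid, table: ScoreTable) -> Grid:
    """Score every unmasked cell of a raster through a lookup table.

    The mask is unchanged; masked cells never touch the table.  For
    categorical tables, any unmasked cell whose code is not registered
    raises, listing the offending codes and their cell counts.
    """
    out = np.zeros(raster.shape, dtype=np.float64)
    valid = ~raster.nodata_mask
    vals = raster.values[valid]
    if table.kind == "binned":
        edges, scores = table._edges_scores()
        idx = np.searchsorted(edges, vals, side="right")
        out[valid] = scores[idx]
    else:
        codes = np.rint(vals).astype(np.int64)
        known = np.array(sorted(table.categories), dtype=np.int64)
        ok = np.isin(codes, known)
        if not ok.all():
            bad, counts = np.unique(codes[~ok], return_counts=True)
            listing = ", ".join(f"code {b} ({c} cells)"
                                for b, c in zip(bad, counts))
            raise ScoreTableError(
                f"{table.table_id}: unregistered class codes: {listing}")
        lut = {c: s for c, s in table.categories.items()}
        out[valid] = np.vectorize(lut.__getitem__, otypes=[np.float64])(codes)
    return raster.with_values(out)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _tables_from_frame(df: pd.DataFrame) -> dict[str, ScoreTable]:
    tables: dict[str, ScoreTable] = {}
    for tid, sub in df.groupby("table_id", sort=False):
        kind = sub["kind"].iloc[0]
        if kind == "binned":
            bins = []
            for _, row in sub.iterrows():
                lo = -INF if pd.isna(row["lower"]) else float(row["lower"])
                hi = INF if pd.isna(row["upper"]) else float(row["upper"])
                bins.append((lo, hi, float(row["score"])))
            bins.sort(key=lambda b: b[0])
            tables[tid] = ScoreTable(tid, "binned", bins=bins)
        else:
            cats = {int(r["code"]): float(r["score"])
                    for _, r in sub.iterrows()}
            names = {str(r["category"]): int(r["code"])
                     for _, r in sub.iterrows()}
            tables[tid] = ScoreTable(tid, "categorical", categories=cats,
                                     category_names=names)
    return tables


def load_tables(path: str | Path) -> dict[str, ScoreTable]:
    """Load score tables from a CSV with columns
    table_id, kind, lower, upper, category, code, score."""
    return _tables_from_frame(pd.read_csv(path))


def default_tables() -> dict[str, ScoreTable]:
    """The 16 shipped factor score tables (one per factor of the three
    quality indices), loaded from the packaged CSV."""
    with resources.files("eai_risk.data").joinpath(
            "score_tables.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    tables = _tables_from_frame(df)
    assert len(tables) == 16
    return tables


def save_tables(tables: dict[str, ScoreTable], path: str | Path) -> None:
    """Write tables back to the editable CSV format."""
    rows = []
    for tid, t in tables.items():
        if t.kind == "binned":
            for lo, hi, s in t.bins:
                rows.append({"table_id": tid, "kind": "binned",
                             "lower": None if lo == -INF else lo,
                             "upper": None if hi == INF else hi,
                             "category": None, "code": None, "score": s})
        else:
            code_to_name = {c: n for n, c in t.category_names.items()}
            for code, s in t.categories.items():
                rows.append({"table_id": tid, "kind": "categorical",
                             "lower": None, "upper": None,
                             "category": code_to_name.get(code),
                             "code": code, "score": s})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Aspect helper
# ---------------------------------------------------------------------------

def aspect_classes_from_dem(dem: Grid) -> Grid:
    """Derive 4-class aspect codes (1 sunny .. 4 shady) from a DEM.

    Slope azimuth comes from the 2-D elevation gradient (8-neighbour
    central differences); in the northern hemisphere south-facing slopes
    are sunny and north-facing shady.  Flat cells (no gradient) are coded
    half sunny as a neutral default.
    """
    dz_dr, dz_dc = np.gradient(dem.values, dem.cell_size)
    # downslope direction: east component = -dz/dx, north component = +dz/dr
    # (row index increases southwards, so +dz_dr points the fall line north)
    east, north = -dz_dc, dz_dr
    flat = (np.hypot(east, north) < 1e-12)
    # cosine of the angle between the fall line and due south
    denom = np.hypot(east, north)
    denom[flat] = 1.0
    cos_south = -north / denom
    codes = np.full(dem.shape, 2, dtype=np.float64)  # half sunny default
    codes[cos_south > np.cos(np.pi / 4)] = 1          # sunny
    codes[(cos_south <= np.cos(np.pi / 4)) & (cos_south > 0)] = 2
    codes[(cos_south <= 0) & (cos_south > -np.cos(np.pi / 4))] = 3
    codes[cos_south <= -np.cos(np.pi / 4)] = 4        # shady
    codes[flat] = 2
    return dem.with_values(codes)
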