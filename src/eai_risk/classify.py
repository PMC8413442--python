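"""Five-class grading of index rasters.

Two routes: the fixed break values published for the Qinghai-Tibet Plateau
gradings of CQI, SQI, VQI and the EAI risk classes, or data-driven Jenks
natural breaks (exact Fisher-Jenks dynamic programming, deterministic).

Interval convention: with interior breaks b1 < ... < b_{k-1}, class i is
[b_i, b_{i+1}); the lowest class is open below and the highest closed
above, so a value exactly on a break belongs to the upper class.

Note the EAI risk scheme's orientation: LOW EAI means HIGH ecological risk,
so its labels run from HeERA (higher risk) at low values to PERA (potential
risk only) at high values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gridcore import Grid


class ClassifyError(ValueError):
    pass


@dataclass
class ClassScheme:
    """Ordered breaks + labels for a k-class grading.

    labels are listed from low index value to high; ``orientation`` records
    whether a higher index value means better quality ('quality') or lower
    risk ('risk') — it does not change the arithmetic, only how results
    should be read.
    """

    scheme_id: str
    breaks: list[float]
    labels: list[str]
    orientation: str = "quality"  # 'quality' | 'risk'

    def __post_init__(self) -> None:
        if sorted(self.breaks) != list(self.breaks) or \
                len(set(self.breaks)) != len(self.breaks):
            raise ClassifyError(f"{self.scheme_id}: breaks must be strictly "
                                "increasing")
        if len(self.labels) != len(self.breaks) + 1:
            raise ClassifyError(
                f"{self.scheme_id}: need {len(self.breaks) + 1} labels, "
                f"got {len(self.labels)}")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def classify_value(self, v: float) -> str:
        return self.labels[int(np.searchsorted(self.breaks, v,
                                               side="right"))]

    def legend(self) -> list[dict]:
        """Rows of (code, label, lower, upper) for the sidecar legend CSV."""
        edges = [-np.inf, *self.breaks, np.inf]
        return [{"code": i, "label": lab, "lower": edges[i],
                 "upper": edges[i + 1]}
                for i, lab in enumerate(self.labels)]


def reference_schemes() -> dict[str, ClassScheme]:
    """The four published QTP grading schemes (fixed break values).

    Keys: ``cqi``, ``sqi``, ``vqi``, ``eai_risk``.
    """
    return {
        "cqi": ClassScheme("cqi", [2.89, 3.82, 4.85, 6.21],
                           ["LeCQ", "LCQ", "GCQ", "HCQ", "HeCQ"], "quality"),
        "sqi": ClassScheme("sqi", [3.88, 5.14, 6.36, 7.41],
                           ["LeSQ", "LSQ", "GSQ", "HSQ", "HeSQ"], "quality"),
        "vqi": ClassScheme("vqi", [3.53, 5.02, 6.55, 7.80],
                           ["LeVQ", "LVQ", "GVQ", "HVQ", "HeVQ"], "quality"),
        "eai_risk": ClassScheme("eai_risk", [2.66, 3.66, 4.86, 6.18],
                                ["HeERA", "HERA", "LERA", "LeERA", "PERA"],
                                "risk"),
    }


def classify_by_breaks(raster: Grid, scheme: ClassScheme) -> Grid:
    """Assign each unmasked cell its class code (0-based, low to high).

    Masked cells stay masked; their stored code is meaningless.
    """
    codes = np.searchsorted(np.asarray(scheme.breaks), raster.values,
                            side="right").astype(np.float64)
    codes[raster.nodata_mask] = 0.0
    return raster.with_values(codes)


# ---------------------------------------------------------------------------
# Jenks natural breaks (exact Fisher-Jenks dynamic programming)
# ---------------------------------------------------------------------------

def _weighted_unique(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals = np.asarray(values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    return np.unique(vals, return_counts=True)


def within_class_ssd(values, breaks) -> float:
    """Total within-class sum of squared deviations from class means under
    the package's break convention ([b_i, b_{i+1}), upper class owns the
    break).  The Jenks objective."""
    vals = np.asarray(values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    idx = np.searchsorted(np.asarray(breaks), vals, side="right")
    total = 0.0
    for k in np.unique(idx):
        grp = vals[idx == k]
        total += float(((grp - grp.mean()) ** 2).sum())
    return total


def jenks_breaks(values, k: int) -> list[float]:
    """Interior break values minimising within-class SSD for k classes.

    Exact dynamic programming on the sorted unique values with frequency
    weights — deterministic, no sampling.  Returns k-1 breaks, each the
    lowest member of its upper class (consistent with the lower-closed
    interval convention).  Requires at least k distinct finite values.
    """
    if k < 1:
        raise ClassifyError(f"k must be >= 1, got {k}")
    u, w = _weighted_unique(values)
    n = len(u)
    if n < k:
        raise ClassifyError(
            f"need at least {k} distinct finite values, got {n}")
    if k == 1:
        return []

    # prefix sums for O(1) weighted SSD of any contiguous run u[i..j]
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cs = np.concatenate([[0.0], np.cumsum(w * u)])
    csq = np.concatenate([[0.0], np.cumsum(w * u * u)])

    def seg_cost_vec(i_arr: np.ndarray, j: int) -> np.ndarray:
        """SSD of runs u[i..j] for a vector of i (inclusive indices)."""
        W = cw[j + 1] - cw[i_arr]
        S = cs[j + 1] - cs[i_arr]
        Q = csq[j + 1] - csq[i_arr]
        return Q - S * S / W

    # D[c][j]: optimal cost of splitting u[0..j] into c+1 classes
    prev = csq[1:] - cs[1:] ** 2 / cw[1:]  # one class covering u[0..j]
    # back[c][j]: start index of the last class in the optimum
    backs = []
    for c in range(1, k):
        cur = np.full(n, np.inf)
        back = np.zeros(n, dtype=np.intp)
        for j in range(c, n):
            i = np.arange(c, j + 1)  # last class starts at u[i]
            cand = prev[i - 1] + seg_cost_vec(i, j)
            best = int(np.argmin(cand))
            cur[j] = cand[best]
            back[j] = i[best]
        backs.append(back)
        prev = cur

    # backtrack: break value = lowest member of each upper class
    breaks: list[float] = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        i = int(backs[c - 1][j])
        breaks.append(float(u[i]))
        j = i - 1
    breaks.reverse()
    return breaks


def equal_interval_breaks(values, k: int) -> list[float]:
    vals = np.asarray(values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    lo, hi = vals.min(), vals.max()
    return list(lo + (hi - lo) * np.arange(1, k) / k)


def quantile_breaks(values, k: int) -> list[float]:
    vals = np.asarray(values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    return list(np.quantile(vals, np.arange(1, k) / k))


def scheme_from_jenks(raster: Grid, k: int, labels: list[str] | None = None,
                      scheme_id: str = "jenks",
                      orientation: str = "quality") -> ClassScheme:
    """Build a ClassScheme from natural breaks of a raster's unmasked cells."""
    breaks = jenks_breaks(raster.unmasked_values(), k)
    if labels is None:
        labels = [f"class_{i + 1}" for i in range(k)]
    return ClassScheme(scheme_id, breaks, labels, orientation)
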