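"""Habitat-suitability estimation from presence and land-use rasters.

The suitability of a land-use class is scored by how often that class
occurs in the neighbourhood of cells where the species was detected: the
more a class appears near an occurrence, the more suitable it is taken to
be.  Scores are relative frequencies over all classes (they sum to 1), so
a single score is bounded by 1 and the projected raster is a valid
suitability function rho(x) in [0, 1].

Because the plant favours edges (wood margins, roadsides, field borders),
selected classes can first be split into an interior class and a derived
"edge" class before scoring (:func:`add_edge_classes`).

A spatial k-fold subsample (contiguous strips) yields a mean and standard
deviation per class; the mean is projected over the land-use map to give
the HSI raster used by the dynamical model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import correlate, maximum_filter

from .grids import Grid, LandUseMap, PresenceMap

__all__ = [
    "ClassScores",
    "add_edge_classes",
    "class_frequencies",
    "scores_from_frequencies",
    "kfold_scores",
    "project_scores",
    "holdout_split",
]


@dataclass
class ClassScores:
    """Per-class suitability estimates: mean and fold-to-fold sd."""

    mean: dict[int, float]
    sd: dict[int, float] = field(default_factory=dict)
    n_folds: int = 1

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.mean.values()):
            raise ValueError("scores must be non-negative")
        if sum(self.mean.values()) > 1 + 1e-9:
            raise ValueError("relative-frequency scores must sum to <= 1")
        if not self.sd:
            self.sd = {c: 0.0 for c in self.mean}

    def to_frame(self, class_table: Mapping[int, str] | None = None):
        import pandas as pd

        codes = sorted(self.mean)
        return pd.DataFrame(
            {
                "code": codes,
                "label": [class_table.get(c, str(c)) if class_table else str(c) for c in codes],
                "mean": [self.mean[c] for c in codes],
                "sd": [self.sd.get(c, 0.0) for c in codes],
            }
        )


def add_edge_classes(
    lu: LandUseMap, edge_source_classes: set[int] | list[int], width: int = 1
) -> LandUseMap:
    """Split each source class into interior and edge sub-classes.

    A cell of a source class ``c`` lying within ``width`` cells (Chebyshev
    distance) of a cell of a *different* class is relabelled to a new code
    ``edge_of(c)``; interior cells keep ``c``.  Derived edge codes are
    recorded in ``edge_origin`` and, for the purpose of repeated
    application, count as their source class — applying the operation to
    its own output is therefore a no-op.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    sources = {int(c) for c in edge_source_classes}
    unknown = sources - set(lu.class_table)
    if unknown:
        raise ValueError(f"edge source classes not in class table: {sorted(unknown)}")

    values = lu.values.copy()
    table = dict(lu.class_table)
    origin = dict(lu.edge_origin)
    next_code = max(table) + 1
    size = 2 * width + 1
    valid = lu.mask()

    for c in sorted(sources):
        same = np.isin(values, [c] + [e for e, o in origin.items() if o == c])
        other = valid & ~same
        # dilate "other" by the Chebyshev ball of radius `width`
        near_other = maximum_filter(other.astype(np.uint8), size=size, mode="constant", cval=0) > 0
        edge = (values == c) & near_other
        if not edge.any():
            continue
        code = next_code
        next_code += 1
        values[edge] = code
        table[code] = f"edge of {table[c]}"
        origin[code] = c

    return LandUseMap(values=values, cellsize=lu.cellsize, nodata=lu.nodata,
                      xllcorner=lu.xllcorner, yllcorner=lu.yllcorner,
                      class_table=table, edge_origin=origin)


def class_frequencies(
    lu: LandUseMap, presence: PresenceMap, radius: int = 1
) -> dict[int, int]:
    """Count land-use classes in windows around every presence cell.

    For each presence cell, every non-nodata cell of the (2*radius+1)^2
    Chebyshev window centred on it (centre included, truncated at the map
    border) is tallied by its class; counts are summed over all presence
    cells.
    """
    lu.require_aligned(presence, "land-use and presence maps")
    pres = (presence.values == 1) & presence.mask() & lu.mask()
    if not pres.any():
        raise ValueError("no presence cells")
    size = 2 * radius + 1
    kernel = np.ones((size, size))
    counts: dict[int, int] = {}
    for c in lu.codes():
        indicator = ((lu.values == c) & lu.mask()).astype(float)
        # windowed count of class c around every cell; borders truncate
        windowed = correlate(indicator, kernel, mode="constant", cval=0.0)
        n = int(round(windowed[pres].sum()))
        if n:
            counts[c] = n
    return counts


def scores_from_frequencies(counts: Mapping[int, int]) -> ClassScores:
    """Normalize neighbourhood counts to relative frequencies (sum to 1)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all-zero counts")
    return ClassScores(mean={int(c): n / total for c, n in counts.items() if n > 0})


def _fold_slices(n: int, k: int) -> list[slice]:
    """k contiguous strips over n rows/cols; the last absorbs the remainder."""
    step = n // k
    bounds = [i * step for i in range(k)] + [n]
    return [slice(bounds[i], bounds[i + 1]) for i in range(k)]


def kfold_scores(
    lu: LandUseMap,
    presence: PresenceMap,
    k: int = 5,
    radius: int = 1,
    axis: str = "rows",
) -> ClassScores:
    """Spatially subsampled class scores: mean and sd over k fold estimates.

    The map is cut into k contiguous strips along ``axis``; each fold holds
    one strip out (its presence cells are ignored) and scores on the rest.
    Classes never observed in a fold contribute 0 to that fold.  Folds
    whose retained strips contain no presence cell are skipped with a
    warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    n = lu.nrows if axis == "rows" else lu.ncols
    slices = _fold_slices(n, k)
    classes = sorted(lu.class_table)
    fold_scores: list[dict[int, float]] = []
    for held_out in slices:
        pres = presence.values.copy()
        if axis == "rows":
            pres[held_out, :] = 0
        else:
            pres[:, held_out] = 0
        masked = PresenceMap(values=np.where(presence.mask(), pres, presence.values),
                             cellsize=presence.cellsize, nodata=presence.nodata,
                             xllcorner=presence.xllcorner, yllcorner=presence.yllcorner)
        try:
            counts = class_frequencies(lu, masked, radius=radius)
        except ValueError:
            warnings.warn("fold with zero presence cells skipped", stacklevel=2)
            continue
        s = scores_from_frequencies(counts)
        fold_scores.append({c: s.mean.get(c, 0.0) for c in classes})
    if not fold_scores:
        raise ValueError("every fold was empty of presence cells")
    arr = np.array([[f[c] for c in classes] for f in fold_scores])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(fold_scores) > 1 else np.zeros(len(classes))
    return ClassScores(
        mean={c: float(m) for c, m in zip(classes, mean)},
        sd={c: float(s) for c, s in zip(classes, sd)},
        n_folds=len(fold_scores),
    )


def project_scores(lu: LandUseMap, scores: ClassScores | Mapping[int, float]) -> Grid:
    """Project per-class mean scores over the land-use map -> HSI raster.

    Classes without a score map to 0 (with a warning); nodata is preserved.
    """
    mean = scores.mean if isinstance(scores, ClassScores) else dict(scores)
    missing = set(lu.codes()) - set(int(c) for c in mean)
    if missing:
        warnings.warn(f"classes without a score mapped to 0: {sorted(missing)}", stacklevel=2)
    out = np.zeros(lu.shape, dtype=float)
    for c, s in mean.items():
        out[lu.values == int(c)] = s
    if lu.nodata is not None:
        out[~lu.mask()] = lu.nodata
    return Grid(values=out, cellsize=lu.cellsize, nodata=lu.nodata,
                xllcorner=lu.xllcorner, yllcorner=lu.yllcorner)


def holdout_split(grid: Grid, fraction: float, axis: str = "rows") -> tuple[Grid, Grid]:
    """Split into two contiguous strips; the first gets ceil(fraction*n) rows.

    For ``axis="rows"`` the first part is the upper (northern) strip — the
    estimation strip of the evaluation protocol — and the second the lower.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0,1)")
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    n = grid.nrows if axis == "rows" else grid.ncols
    n1 = int(np.ceil(fraction * n))
    if n1 == 0 or n1 == n:
        raise ValueError("degenerate split")

    def _take(sl: slice) -> Grid:
        vals = grid.values[sl, :] if axis == "rows" else grid.values[:, sl]
        if isinstance(grid, LandUseMap):
            return LandUseMap(values=vals.copy(), cellsize=grid.cellsize, nodata=grid.nodata,
                              xllcorner=grid.xllcorner, yllcorner=grid.yllcorner,
                              class_table=dict(grid.class_table),
                              edge_origin=dict(grid.edge_origin))
        if isinstance(grid, PresenceMap):
            return PresenceMap(values=vals.copy(), cellsize=grid.cellsize, nodata=grid.nodata,
                               xllcorner=grid.xllcorner, yllcorner=grid.yllcorner)
        return Grid(values=vals.copy(), cellsize=grid.cellsize, nodata=grid.nodata,
                    xllcorner=grid.xllcorner, yllcorner=grid.yllcorner)

    return _take(slice(0, n1)), _take(slice(n1, n))
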