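"""Raster data model and I/O.

Every layer in the workflow (land-use codes, species presence, habitat
suitability, population density, control effort) lives on a common
georeferenced rectangular grid of square cells.  The interchange format is
the ESRI ASCII grid (``.asc``) — plain text, self-describing header, no
binary dependencies.  GeoTIFF is supported when the optional ``rasterio``
dependency is installed.

Conventions
-----------
* row 0 is the northernmost row; the origin (``xllcorner``/``yllcorner``)
  is the lower-left corner of the lower-left cell;
* cells are square with edge length ``cellsize`` in metres;
* ``nodata`` is a sentinel value excluded from all statistics, and it
  propagates: operations combining layers yield nodata wherever any input
  is nodata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Grid",
    "LandUseMap",
    "PresenceMap",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "read_class_table",
    "write_class_table",
    "degrade_resolution",
]

#: Default nodata sentinel used when padding requires one.
DEFAULT_NODATA = -9999.0

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


class GridFormatError(ValueError):
    """Raised when a raster file cannot be parsed."""


@dataclass
class Grid:
    """A single-band raster: 2-D value array plus header metadata.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, row 0 = north.
    cellsize : float
        Cell edge length in metres (> 0).
    nodata : float or None
        Sentinel value marking missing cells, or None if the layer is
        complete.
    xllcorner, yllcorner : float
        Coordinates of the lower-left corner of the grid.
    """

    values: np.ndarray
    cellsize: float
    nodata: float | None = None
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2-D array")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        return self.values != self.nodata

    def valid_values(self) -> np.ndarray:
        """1-D array of the non-nodata cell values."""
        return self.values[self.mask()]

    def with_values(self, values: np.ndarray) -> "Grid":
        """Copy of this grid carrying ``values`` and the same header."""
        out = replace(self, values=np.asarray(values))
        return out

    def copy(self) -> "Grid":
        return self.with_values(self.values.copy())

    def same_geometry(self, other: "Grid") -> bool:
        return self.shape == other.shape and np.isclose(self.cellsize, other.cellsize)

    def require_aligned(self, other: "Grid", what: str = "layers") -> None:
        if not self.same_geometry(other):
            raise ValueError(
                f"{what} are not aligned: {self.shape}@{self.cellsize} vs "
                f"{other.shape}@{other.cellsize}"
            )


@dataclass
class LandUseMap(Grid):
    """Categorical raster of integer land-use/land-cover class codes.

    ``class_table`` maps every code occurring in the raster to a label.
    ``edge_origin`` maps derived edge-class codes back to the code they
    were split from (see :func:`invasim.hsi.add_edge_classes`).
    """

    class_table: dict[int, str] = field(default_factory=dict)
    edge_origin: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.asarray(self.values)
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("land-use codes must be integers")
        self.values = np.round(vals).astype(np.int64)
        if self.nodata is not None:
            self.nodata = int(self.nodata)
        if not self.class_table:
            self.class_table = {int(c): str(int(c)) for c in np.unique(self.valid_values())}
        else:
            present = set(int(c) for c in np.unique(self.valid_values()))
            missing = present - set(self.class_table)
            if missing:
                raise ValueError(f"codes missing from class_table: {sorted(missing)}")

    def codes(self) -> list[int]:
        """Sorted list of class codes present in the raster."""
        return sorted(int(c) for c in np.unique(self.valid_values()))


@dataclass
class PresenceMap(Grid):
    """Binary raster: 1 where the species was detected, 0 elsewhere."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.asarray(self.values, dtype=float)
        ok = self.values if self.nodata is None else vals[vals != self.nodata]
        if not np.all(np.isin(ok, (0.0, 1.0))):
            raise ValueError("presence map must be binary (0/1) apart from nodata")
        self.values = vals

    def n_presences(self) -> int:
        return int(np.sum(self.valid_values() == 1))


# ---------------------------------------------------------------------------
# I/O


def _parse_ascii(path: Path) -> Grid:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            if len(parts) != 2:
                raise GridFormatError(f"malformed header line for key '{key}'")
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"non-numeric header value for key '{key}'") from exc
        else:
            body_start = i
            break
    else:
        raise GridFormatError("no data rows found")
    for key in _HEADER_KEYS:
        if key not in header:
            raise GridFormatError(f"missing required header key '{key}'")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    rows = []
    for line in lines[body_start:]:
        parts = line.split()
        if not parts:
            continue
        try:
            rows.append([float(v) for v in parts])
        except ValueError as exc:
            raise GridFormatError(f"non-numeric cell value in row {len(rows)}") from exc
    if len(rows) != nrows or any(len(r) != ncols for r in rows):
        raise GridFormatError(
            f"body is not a {nrows}x{ncols} rectangle as declared in the header"
        )
    return Grid(
        values=np.array(rows, dtype=float),
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value"),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
    )


def read_grid(path: str | Path, format: str = "ascii") -> Grid:
    """Read a single-band raster.

    Parameters
    ----------
    path : path to an ESRI ASCII grid (``format="ascii"``) or a GeoTIFF
        (``format="geotiff"``, requires the optional ``rasterio`` extra).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "ascii":
        return _parse_ascii(path)
    if format == "geotiff":
        try:
            import rasterio  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "GeoTIFF support requires the optional 'rasterio' dependency "
                "(pip install invasim[tiff]); ESRI ASCII needs none"
            ) from exc
        with rasterio.open(path) as src:  # pragma: no cover
            values = src.read(1)
            tr = src.transform
            return Grid(
                values=np.asarray(values, dtype=float),
                cellsize=abs(tr.a),
                nodata=src.nodata,
                xllcorner=tr.c,
                yllcorner=tr.f + tr.e * src.height,
            )
    raise ValueError(f"unknown format '{format}'")


def write_grid(grid: Grid, path: str | Path) -> None:
    """Write ``grid`` as an ESRI ASCII file, re-readable losslessly.

    Floating values are serialized with 17 significant digits (shortest
    exact float64 representation), so a write/read round trip is lossless.
    """
    path = Path(path)
    ints = np.issubdtype(np.asarray(grid.values).dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.12g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.12g}\n")
        fh.write(f"cellsize {grid.cellsize:.12g}\n")
        if grid.nodata is not None:
            fh.write(f"NODATA_value {grid.nodata:.12g}\n")
        fmt = "%d" if ints else "%.17g"
        np.savetxt(fh, np.asarray(grid.values), fmt=fmt)


def read_class_table(path: str | Path) -> dict[int, str]:
    """Read a ``code,label`` CSV into a class table."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "code" not in cols or "label" not in cols:
        raise GridFormatError("class table CSV needs 'code' and 'label' columns")
    return {int(c): str(l) for c, l in zip(df[cols["code"]], df[cols["label"]])}


def write_class_table(table: Mapping[int, str], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"code": list(table.keys()), "label": list(table.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Resolution degradation


def _pad_to_multiple(values: np.ndarray, factor: int, fill: float) -> np.ndarray:
    nr, nc = values.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    if pr == 0 and pc == 0:
        return values
    logger.info("degrade_resolution: padding %dx%d with nodata to fit factor %d", pr, pc, factor)
    return np.pad(values, ((0, pr), (0, pc)), constant_values=fill)


def degrade_resolution(grid: Grid, factor: int, mode: str) -> Grid:
    """Aggregate ``factor``×``factor`` blocks of cells into one coarse cell.

    Modes
    -----
    ``majority``
        Most frequent value per block (categorical layers); ties broken to
        the lowest class code.
    ``mean``
        Mean of the non-nodata values per block (continuous layers).
    ``any_presence``
        1 if any constituent cell equals 1 (binary layers).

    The output ``cellsize`` is the input's times ``factor``.  Dimensions
    not divisible by ``factor`` are padded with nodata (recorded in the
    log); an all-nodata block yields nodata.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if mode not in ("majority", "mean", "any_presence"):
        raise ValueError(f"unknown mode '{mode}'")
    nodata = grid.nodata if grid.nodata is not None else DEFAULT_NODATA
    vals = _pad_to_multiple(np.asarray(grid.values, dtype=float), factor, nodata)
    nr, nc = vals.shape
    blocks = vals.reshape(nr // factor, factor, nc // factor, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(nr // factor, nc // factor, factor * factor)
    valid = blocks != nodata

    out = np.full(blocks.shape[:2], nodata, dtype=float)
    any_valid = valid.any(axis=-1)
    if mode == "mean":
        with np.errstate(invalid="ignore"):
            masked = np.where(valid, blocks, np.nan)
            means = np.nanmean(masked, axis=-1)
        out[any_valid] = means[any_valid]
    elif mode == "any_presence":
        out[any_valid] = np.where((blocks == 1) & valid, 1.0, 0.0).any(axis=-1)[any_valid]
    else:  # majority, ties -> lowest code
        it = np.ndindex(blocks.shape[:2])
        for idx in it:
            if not any_valid[idx]:
                continue
            vals_here = blocks[idx][valid[idx]].astype(np.int64)
            codes, counts = np.unique(vals_here, return_counts=True)
            out[idx] = codes[np.argmax(counts)]  # np.unique sorts: first max = lowest

    header = dict(
        cellsize=grid.cellsize * factor,
        nodata=grid.nodata if (grid.nodata is not None or (out == nodata).any()) else None,
        xllcorner=grid.xllcorner,
        yllcorner=grid.yllcorner,
    )
    if header["nodata"] is None and (out == nodata).any():
        header["nodata"] = nodata
    if isinstance(grid, LandUseMap) and mode == "majority":
        return LandUseMap(values=out.astype(np.int64), class_table=dict(grid.class_table),
                          edge_origin=dict(grid.edge_origin), **header)
    if isinstance(grid, PresenceMap) and mode == "any_presence":
        return PresenceMap(values=out, **header)
    return Grid(values=out, **header)
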