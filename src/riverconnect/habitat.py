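"""Habitat rasters and patch labeling.

A riverscape is represented as a binary habitat-suitability raster on a
square metric grid: suitable cells are coded 1, unsuitable cells 0, and
cells outside the active river corridor are nodata.  A *patch* is a
maximal contiguous group of suitable cells separated from other patches
by unsuitable (or nodata) cells.

Grid convention: row 0 is the top (northern) row and cell (0, 0) the
top-left corner; offsets are (row, col).  Geo-referencing is carried by
``origin`` (the x/y map coordinates of the lower-left raster corner) and
``cell_size``.  Supported file formats are single-band GeoTIFF (nodata
from the GDAL_NODATA tag, cell size from the pixel-scale tag) and the
ESRI ASCII grid.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "HabitatRaster",
    "PatchMap",
    "read_habitat_raster",
    "label_patches",
    "write_raster",
]

SUITABLE, UNSUITABLE, NODATA = 1, 0, -1

# GeoTIFF tag codes (GeoTIFF spec / GDAL convention)
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_DEFAULT_ASCII_NODATA = -9999.0


@dataclass
class HabitatRaster:
    """Binary suitability grid with a nodata mask.

    ``grid`` holds one of three states per cell: 1 (suitable),
    0 (unsuitable) or -1 (nodata, outside the active river channel).
    """

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.size == 0:
            raise ValueError("habitat grid must be a non-empty 2-D array")
        bad = ~np.isin(g, (SUITABLE, UNSUITABLE, NODATA))
        if bad.any():
            raise ValueError("habitat grid cells must be 1, 0 or -1 (nodata)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.grid = g.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def suitable_mask(self) -> np.ndarray:
        return self.grid == SUITABLE

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.grid == NODATA

    @property
    def n_suitable(self) -> int:
        return int(self.suitable_mask.sum())


@dataclass
class PatchMap:
    """Connected-component labeling of the suitable cells.

    ``labels`` is 0 on non-patch cells and 1..P on patch cells; ids are
    consecutive and assigned in row-major order of first occurrence, so
    the labeling is deterministic for a given raster and adjacency rule.
    """

    labels: np.ndarray
    connectivity_rule: int = 8
    cell_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.connectivity_rule not in (4, 8):
            raise ValueError("connectivity_rule must be 4 or 8")
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.cell_counts = np.bincount(
            self.labels[self.labels > 0].ravel(),
            minlength=self.n_patches + 1,
        )[1:]

    @property
    def n_patches(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def patch_ids(self) -> list[int]:
        return list(range(1, self.n_patches + 1))


def label_patches(habitat: HabitatRaster, connectivity_rule: int = 8) -> PatchMap:
    """Label contiguous groups of suitable cells as patches.

    Parameters
    ----------
    habitat : HabitatRaster
    connectivity_rule : {4, 8}
        Whether diagonal neighbours belong to the same patch (8, the
        default) or only orthogonal neighbours do (4).  The choice
        changes patch counts and therefore every per-patch metric.
    """
    if connectivity_rule == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    elif connectivity_rule == 8:
        structure = ndimage.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity_rule must be 4 or 8")
    raw, n = ndimage.label(habitat.suitable_mask, structure=structure)
    labels = _relabel_row_major(raw, n)
    return PatchMap(labels=labels, connectivity_rule=connectivity_rule)


def _relabel_row_major(raw: np.ndarray, n: int) -> np.ndarray:
    """Remap labels to row-major order of first occurrence."""
    if n == 0:
        return raw.astype(np.int32)
    flat = raw.ravel()
    nz = np.flatnonzero(flat)
    # first occurrence index per label
    first = np.full(n + 1, flat.size, dtype=np.int64)
    np.minimum.at(first, flat[nz], nz)
    order = np.argsort(first[1:], kind="stable") + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, n + 1, dtype=np.int32)
    return remap[raw]


# ---------------------------------------------------------------------------
# File I/O


def read_habitat_raster(
    path: str | Path,
    suitable_value: float = 1,
    nodata_value: float | None = None,
) -> HabitatRaster:
    """Read a habitat raster from GeoTIFF or ESRI ASCII grid.

    Cells equal to ``suitable_value`` become suitable; cells equal to the
    nodata value (from file metadata, or ``nodata_value`` if given)
    become nodata; everything else is unsuitable.  Non-square pixels are
    rejected — all metrics assume a square metric grid.
    """
    values, file_nodata, cell_size, origin, crs = _read_grid(Path(path))
    nd = nodata_value if nodata_value is not None else file_nodata
    grid = np.full(values.shape, UNSUITABLE, dtype=np.int8)
    grid[values == suitable_value] = SUITABLE
    if nd is not None:
        if np.isnan(nd):
            grid[np.isnan(values)] = NODATA
        else:
            grid[values == nd] = NODATA
    grid[np.isnan(values)] = NODATA
    if np.all(grid == NODATA):
        raise ValueError(f"{path}: raster contains only nodata cells")
    return HabitatRaster(grid=grid, cell_size=cell_size, origin=origin, crs=crs)


def write_raster(
    grid: np.ndarray,
    template: HabitatRaster,
    path: str | Path,
    nodata_value: float = _DEFAULT_ASCII_NODATA,
) -> None:
    """Write a value grid with the template's geo-referencing.

    The output format follows the file extension: ``.asc``/``.agr`` for
    ESRI ASCII grid, anything else GeoTIFF.  Nodata cells of the
    template (and NaNs in ``grid``) are written as ``nodata_value``.
    """
    path = Path(path)
    grid = np.asarray(grid, dtype=np.float64)
    if grid.shape != template.shape:
        raise ValueError(
            f"grid shape {grid.shape} does not match template {template.shape}"
        )
    out = grid.copy()
    out[template.nodata_mask] = nodata_value
    out[np.isnan(out)] = nodata_value
    if path.suffix.lower() in (".asc", ".agr", ".txt"):
        _write_ascii(out, template, path, nodata_value)
    else:
        _write_geotiff(out.astype(np.float32), template, path, nodata_value)


def _read_grid(path: Path):
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".asc", ".agr", ".txt"):
        return _read_ascii(path)
    return _read_geotiff(path)


# -- ESRI ASCII grid --------------------------------------------------------

_ASCII_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
               "yllcenter", "cellsize", "nodata_value"}


def _read_ascii(path: Path):
    header: dict[str, float] = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        m = re.match(r"^\s*([A-Za-z_]+)\s+(\S+)\s*$", line)
        if m and m.group(1).lower() in _ASCII_KEYS:
            header[m.group(1).lower()] = float(m.group(2))
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    values = np.loadtxt(lines[data_start:], dtype=np.float64, ndmin=2)
    if values.shape != (nrows, ncols):
        values = values.reshape(nrows, ncols)
    if "xllcorner" in header:
        xll = header["xllcorner"]
    else:
        xll = header.get("xllcenter", 0.0) - cell / 2
    if "yllcorner" in header:
        yll = header["yllcorner"]
    else:
        yll = header.get("yllcenter", 0.0) - cell / 2
    nodata = header.get("nodata_value")
    return values, nodata, cell, (xll, yll), None


def _write_ascii(values, template, path: Path, nodata_value: float) -> None:
    nrows, ncols = values.shape
    xll, yll = template.origin
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {template.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata_value:.10g}\n")
        for row in values:
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


# -- GeoTIFF ---------------------------------------------------------------


def _read_geotiff(path: Path):
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster")
        tags = page.tags
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        if _TAG_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
            if abs(sx - sy) > 1e-9 * max(sx, sy):
                raise ValueError(
                    f"{path}: non-square pixels ({sx} x {sy} m); "
                    "resample to a square grid first"
                )
            cell = float(sx)
        else:
            raise ValueError(f"{path}: GeoTIFF lacks a pixel-scale tag")
        origin = (0.0, 0.0)
        if _TAG_TIEPOINT in tags:
            tp = tags[_TAG_TIEPOINT].value
            # tiepoint maps raster (0,0) top-left to map (x, y)
            x_top_left, y_top_left = tp[3], tp[4]
            origin = (x_top_left, y_top_left - values.shape[0] * cell)
    return values, nodata, cell, origin, None


def _write_geotiff(values, template, path: Path, nodata_value: float) -> None:
    import tifffile

    nrows = values.shape[0]
    xll, yll = template.origin
    y_top = yll + nrows * template.cell_size
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (template.cell_size, template.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, xll, y_top, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{nodata_value:.10g}"),
    ]
    tifffile.imwrite(str(path), values, extratags=extratags)
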