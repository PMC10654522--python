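"""Synthetic riverscapes and the brute-force connectivity oracle.

The habitat rasters the metrics were designed for are braided-river
corridors: mosaics of gravel-bar patches inside an active channel,
surrounded by nodata.  This module generates stand-in landscapes with
controllable patch geometry — deterministic two-patch and shape-series
fixtures, and seeded random landscapes built from rectangle/ellipse
primitives — plus a direct, unoptimised transcription of the seed-rain
definition (an explicit loop over receiver/donor cell pairs) that serves
as ground truth for the convolution fast path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .habitat import HabitatRaster, PatchMap, SUITABLE, UNSUITABLE, NODATA
from .kernel import DispersalKernel
from .metrics import SeedRainMap, PairwiseConnectivity, DEFAULT_THRESHOLD

__all__ = [
    "Primitive",
    "LandscapeSpec",
    "two_patch_landscape",
    "shape_series",
    "random_blob_landscape",
    "brute_force_seed_rain",
]

ORACLE_CELL_LIMIT = 10_000


@dataclass(frozen=True)
class Primitive:
    """A habitat primitive: an axis-aligned rectangle or ellipse.

    ``row``/``col`` give the top-left corner of the bounding box;
    ``height``/``width`` its extent in cells.
    """

    kind: str  # "rect" or "ellipse"
    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.kind not in ("rect", "ellipse"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if self.height < 1 or self.width < 1:
            raise ValueError("primitive height and width must be >= 1")


@dataclass
class LandscapeSpec:
    """Specification of a synthetic landscape.

    Overlapping primitives merge into a single patch.  ``nodata_margin``
    rings the grid with nodata cells, emulating the boundary of the
    active river channel.  ``seed`` only matters for randomly generated
    specs (see :meth:`random`); for a fixed primitive list the output is
    fully determined by the fields.
    """

    shape: tuple[int, int]
    cell_size: float = 5.0
    patches: list[Primitive] = field(default_factory=list)
    nodata_margin: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def random(
        cls,
        shape: tuple[int, int],
        n_primitives: int,
        seed: int,
        cell_size: float = 5.0,
        size_range: tuple[int, int] = (1, 6),
        nodata_margin: int = 0,
    ) -> "LandscapeSpec":
        """Draw a seeded random primitive list within the grid."""
        rng = np.random.default_rng(seed)
        lo, hi = size_range
        prims = []
        inner = (shape[0] - 2 * nodata_margin, shape[1] - 2 * nodata_margin)
        for _ in range(n_primitives):
            h = int(rng.integers(lo, hi + 1))
            w = int(rng.integers(lo, hi + 1))
            h = min(h, inner[0])
            w = min(w, inner[1])
            r = nodata_margin + int(rng.integers(0, inner[0] - h + 1))
            c = nodata_margin + int(rng.integers(0, inner[1] - w + 1))
            kind = "ellipse" if rng.random() < 0.3 else "rect"
            prims.append(Primitive(kind, r, c, h, w))
        return cls(
            shape=shape,
            cell_size=cell_size,
            patches=prims,
            nodata_margin=nodata_margin,
            seed=seed,
        )


def random_blob_landscape(spec: LandscapeSpec) -> HabitatRaster:
    """Rasterise a LandscapeSpec into a HabitatRaster.

    Deterministic for a given spec: the primitive list fully determines
    the raster, so the same seed yields bit-identical output.
    """
    nrows, ncols = spec.shape
    grid = np.full((nrows, ncols), UNSUITABLE, dtype=np.int8)
    for p in spec.patches:
        if p.row < 0 or p.col < 0 or p.row + p.height > nrows or p.col + p.width > ncols:
            raise ValueError(f"primitive {p} exceeds grid {spec.shape}")
        if p.kind == "rect":
            grid[p.row : p.row + p.height, p.col : p.col + p.width] = SUITABLE
        else:
            rr, cc = np.mgrid[0 : p.height, 0 : p.width]
            cy, cx = (p.height - 1) / 2, (p.width - 1) / 2
            ry, rx = max(p.height / 2, 0.5), max(p.width / 2, 0.5)
            inside = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
            grid[p.row : p.row + p.height, p.col : p.col + p.width][inside] = SUITABLE
    m = spec.nodata_margin
    if m > 0:
        grid[:m, :] = NODATA
        grid[-m:, :] = NODATA
        grid[:, :m] = NODATA
        grid[:, -m:] = NODATA
    return HabitatRaster(grid=grid, cell_size=spec.cell_size)


def two_patch_landscape(
    patch_size: int, gap: int, cell_size: float = 5.0, margin: int = 1
) -> HabitatRaster:
    """Two identical square patches separated by a horizontal gap.

    The patches are ``patch_size`` cells on a side with ``gap`` columns
    of unsuitable cells between their facing edges, so two single-cell
    patches have a centre-to-centre distance of ``(gap + 1) * cell_size``
    metres.  A one-cell unsuitable margin (by default) keeps patches off
    the raster edge.
    """
    if gap < 1:
        raise ValueError("gap must be >= 1 (otherwise the patches merge)")
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    nrows = patch_size + 2 * margin
    ncols = 2 * patch_size + gap + 2 * margin
    grid = np.full((nrows, ncols), UNSUITABLE, dtype=np.int8)
    grid[margin : margin + patch_size, margin : margin + patch_size] = SUITABLE
    c1 = margin + patch_size + gap
    grid[margin : margin + patch_size, c1 : c1 + patch_size] = SUITABLE
    return HabitatRaster(grid=grid, cell_size=cell_size)


def shape_series(
    area_cells: int,
    aspect_ratios: list[tuple[int, int]],
    gap: int,
    cell_size: float = 5.0,
) -> list[HabitatRaster]:
    """Equal-area donor rectangles of varying elongation facing a
    fixed receiver strip.

    Each aspect ratio ``(height, width)`` must factorise ``area_cells``
    exactly.  The donor rectangle is placed ``gap`` unsuitable rows above
    a one-cell-wide receiver strip spanning the full raster width, with
    the donor's long side parallel to the strip, so donors differ only in
    the length of the interface they present to the receiver.
    """
    for h, w in aspect_ratios:
        if h * w != area_cells:
            raise ValueError(
                f"aspect ratio {h}x{w} does not factorise area {area_cells}"
            )
    if gap < 1:
        raise ValueError("gap must be >= 1")
    max_w = max(w for _, w in aspect_ratios)
    max_h = max(h for h, _ in aspect_ratios)
    ncols = max_w + 2
    landscapes = []
    for h, w in aspect_ratios:
        nrows = max_h + gap + 1 + 2
        grid = np.full((nrows, ncols), UNSUITABLE, dtype=np.int8)
        receiver_row = 1 + max_h + gap
        grid[receiver_row, :] = SUITABLE  # receiver strip
        r0 = receiver_row - gap - h
        c0 = (ncols - w) // 2
        grid[r0 : r0 + h, c0 : c0 + w] = SUITABLE
        landscapes.append(HabitatRaster(grid=grid, cell_size=cell_size))
    return landscapes


def brute_force_seed_rain(
    habitat: HabitatRaster,
    patch_map: PatchMap,
    kernel: DispersalKernel,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[SeedRainMap, PairwiseConnectivity]:
    """Definitional effective seed rain: sum the kernel over every
    (receiver, donor) suitable-cell pair on different patches.

    This is the ground-truth transcription of the metric — no
    convolution, just the per-pair accumulation — and the reference all
    fast-path results are tested against.  Guarded to rasters with at
    most 10,000 suitable cells.
    """
    n_suit = habitat.n_suitable
    if n_suit > ORACLE_CELL_LIMIT:
        raise ValueError(
            f"brute-force oracle limited to {ORACLE_CELL_LIMIT} suitable "
            f"cells (got {n_suit}); use riverconnect.metrics for large rasters"
        )
    labels = patch_map.labels
    R = kernel.radius_cells
    K = kernel.matrix
    rows, cols = np.nonzero(habitat.suitable_mask)
    pids = labels[rows, cols]
    n_patches = patch_map.n_patches
    es = np.zeros(habitat.shape, dtype=np.float64)
    pair = np.zeros((n_patches, n_patches), dtype=np.float64)
    for r, c, pid in zip(rows, cols, pids):
        # donors relative to this receiver
        dr = rows - r
        dc = cols - c
        in_window = (
            (np.abs(dr) <= R) & (np.abs(dc) <= R) & (pids != pid)
        )
        contrib = K[dr[in_window] + R, dc[in_window] + R]
        es[r, c] = contrib.sum()
        np.add.at(pair[pid - 1], pids[in_window] - 1, contrib)
    es[~habitat.suitable_mask] = 0.0
    es[habitat.nodata_mask] = np.nan
    seed_rain = SeedRainMap(
        values=es, kernel=kernel, patch_map=patch_map, habitat=habitat
    )
    return seed_rain, PairwiseConnectivity(matrix=pair, threshold=threshold)
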