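"""Colonization-potential metrics for riverscape habitat rasters.

Given a binary habitat raster, its patch labeling and a species dispersal
kernel, this module computes:

- **effective seed rain (eS)** — per suitable cell, the fraction of an
  ideal source's seed output reaching the cell from the suitable cells of
  *other* patches (same-patch cells are never donors); 1 corresponds to a
  cell whose whole kernel footprint lies on donor cells.
- **effective connectivity (eC)** — the sum of eS over a patch's cells;
  linear in seed exchange, may exceed 1.  Also available per patch pair.
- **colonization potential (cP)** — the mean patch eC of a riverscape.
- **effective distance (eD)** — eC re-expressed as the single-source
  distance (metres) that would yield that seed fraction,
  ``log_(1-decay)(eC)``; clamped at 0, infinite for unconnected patches.
- **number of connections (nC)** and **connection capacity (cC)** —
  how many other patches exchange at least a threshold seed fraction
  (default 0.01) with a patch, and the patch's eC divided by that count.

The fast path computes eS as a full-raster focal correlation minus each
patch's self-contribution; its semantics are defined by the brute-force
per-cell-pair sum (see :mod:`riverconnect.synthetic`), which it must match
to 1e-9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .habitat import HabitatRaster, PatchMap
from .kernel import DispersalKernel

__all__ = [
    "SeedRainMap",
    "PairwiseConnectivity",
    "RiverscapeSummary",
    "effective_seed_rain",
    "patch_effective_connectivity",
    "pairwise_effective_connectivity",
    "effective_distance",
    "count_connections",
    "connection_capacity",
    "compute_patch_metrics",
    "riverscape_summary",
    "weighted_seed_rain",
]

DEFAULT_THRESHOLD = 0.01


@dataclass
class SeedRainMap:
    """Per-cell effective seed rain on the habitat grid.

    ``values`` is 0 on unsuitable cells, NaN on nodata cells (outside
    the active river channel) and the eS fraction on suitable cells.
    """

    values: np.ndarray
    kernel: DispersalKernel
    patch_map: PatchMap
    habitat: HabitatRaster


@dataclass
class PairwiseConnectivity:
    """Patch-by-patch effective connectivity matrix.

    ``matrix[a - 1, b - 1]`` is the seed fraction patch ``a`` receives
    from patch ``b``; the diagonal is 0.  For isotropic kernels seed
    reachability is bidirectional, so the matrix is symmetric.
    """

    matrix: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    @property
    def n_patches(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RiverscapeSummary:
    """Riverscape-level aggregates of the per-patch metrics.

    Means are over all patches except ``eDm``, which averages the
    effective distance of *connected* patches only (unconnected patches
    have infinite eD) and must be read together with ``pct_connected``.
    ``sd`` entries are sample standard deviations and ``rsd`` the ratio
    sd/mean (NaN where the mean is 0 or fewer than two values exist).
    """

    n_patches: int
    cP: float
    eDm: float
    nCm: float
    cCm: float
    pct_connected: float
    sd: dict[str, float]
    rsd: dict[str, float]


def _check_cell_size(habitat: HabitatRaster, kernel: DispersalKernel) -> None:
    if not math.isclose(habitat.cell_size, kernel.cell_size, rel_tol=1e-9):
        raise ValueError(
            f"kernel cell size ({kernel.cell_size} m) does not match "
            f"habitat cell size ({habitat.cell_size} m)"
        )


def _patch_windows(patch_map: PatchMap, radius: int):
    """Per-patch bounding boxes expanded by the kernel radius."""
    shape = patch_map.labels.shape
    for pid, sl in enumerate(ndimage.find_objects(patch_map.labels), start=1):
        if sl is None:  # pragma: no cover - labels are consecutive
            continue
        r0 = max(sl[0].start - radius, 0)
        r1 = min(sl[0].stop + radius, shape[0])
        c0 = max(sl[1].start - radius, 0)
        c1 = min(sl[1].stop + radius, shape[1])
        yield pid, (slice(r0, r1), slice(c0, c1))


def effective_seed_rain(
    habitat: HabitatRaster, patch_map: PatchMap, kernel: DispersalKernel
) -> SeedRainMap:
    """Effective seed rain for every cell of the habitat raster.

    For each suitable cell the kernel is applied as a focal window over
    the suitable cells of *other* patches; contributions from the cell's
    own patch are excluded, cells outside the raster contribute nothing,
    and nodata cells neither donate nor receive.

    Implemented as one correlation of the full suitability mask with the
    kernel, minus a per-patch correlation of the patch's own mask
    (restricted to the patch's kernel-padded bounding box).
    """
    _check_cell_size(habitat, kernel)
    if patch_map.labels.shape != habitat.shape:
        raise ValueError("patch map shape does not match habitat raster")
    K = kernel.matrix
    suitable = habitat.suitable_mask.astype(np.float64)
    total = ndimage.correlate(suitable, K, mode="constant", cval=0.0)
    es = np.zeros(habitat.shape, dtype=np.float64)
    labels = patch_map.labels
    for pid, win in _patch_windows(patch_map, kernel.radius_cells):
        own = (labels[win] == pid).astype(np.float64)
        self_rain = ndimage.correlate(own, K, mode="constant", cval=0.0)
        cells = labels[win] == pid
        es_win = total[win] - self_rain
        es[win][cells] = es_win[cells]
    np.maximum(es, 0.0, out=es)  # guard rounding at the 1e-16 level
    es[~habitat.suitable_mask] = 0.0
    es[habitat.nodata_mask] = np.nan
    return SeedRainMap(values=es, kernel=kernel, patch_map=patch_map, habitat=habitat)


def patch_effective_connectivity(seed_rain: SeedRainMap) -> np.ndarray:
    """Per-patch effective connectivity: the sum of eS over each patch.

    Returns an array indexed by patch id - 1.  Values above 1 are
    possible for large, well-connected patches.
    """
    labels = seed_rain.patch_map.labels
    vals = np.where(labels > 0, seed_rain.values, 0.0)
    n = seed_rain.patch_map.n_patches
    return np.bincount(labels.ravel(), weights=vals.ravel(), minlength=n + 1)[1:]


def pairwise_effective_connectivity(
    habitat: HabitatRaster,
    patch_map: PatchMap,
    kernel: DispersalKernel,
    threshold: float = DEFAULT_THRESHOLD,
) -> PairwiseConnectivity:
    """Effective connectivity for every patch pair.

    ``eC(A, B)`` sums the kernel over all (receiver in A, donor in B)
    cell pairs; it characterises the strength of the individual
    connection.  Each patch's row sum equals its patch-level eC.
    """
    _check_cell_size(habitat, kernel)
    n = patch_map.n_patches
    K = kernel.matrix
    labels = patch_map.labels
    matrix = np.zeros((n, n), dtype=np.float64)
    for pid, win in _patch_windows(patch_map, kernel.radius_cells):
        donors = (labels[win] == pid).astype(np.float64)
        rain = ndimage.correlate(donors, K, mode="constant", cval=0.0)
        lab_w = labels[win]
        receivers = (lab_w > 0) & (lab_w != pid)
        np.add.at(matrix[:, pid - 1], lab_w[receivers] - 1, rain[receivers])
    return PairwiseConnectivity(matrix=matrix, threshold=threshold)


def effective_distance(eC, decay: float):
    """Effective distance in metres from an effective connectivity.

    ``eD = log_(1-decay)(eC)``: the distance at which a single ideal
    source would deliver the seed fraction ``eC``.  Values below zero
    (eC >= 1) are set to 0; eC = 0 gives an infinite distance
    (unconnected).  Accepts scalars or arrays.
    """
    if not 0 < decay < 1:
        raise ValueError(f"decay must be in (0, 1), got {decay!r}")
    arr = np.asarray(eC, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("eC must be non-negative")
    with np.errstate(divide="ignore"):
        ed = np.log(arr) / np.log(1.0 - decay)
    ed = np.where(arr == 0.0, np.inf, np.maximum(ed, 0.0))
    return float(ed) if np.isscalar(eC) else ed


def count_connections(
    pairwise: PairwiseConnectivity, threshold: float | None = None
) -> np.ndarray:
    """Number of other patches each patch exchanges at least ``threshold``
    seed fraction with (default: the pairwise matrix's threshold, 0.01)."""
    t = pairwise.threshold if threshold is None else threshold
    if t < 0:
        raise ValueError("threshold must be >= 0")
    m = pairwise.matrix
    connected = m >= t
    np.fill_diagonal(connected, False)
    return connected.sum(axis=1).astype(np.int64)


def connection_capacity(eC, nC):
    """Average connection capacity: patch eC divided by its number of
    connections; 0 for unconnected patches.

    The division uses the patch's *total* eC — sub-threshold exchanges
    count toward the capacity even though they do not add a connection.
    """
    eC_arr = np.asarray(eC, dtype=np.float64)
    nC_arr = np.asarray(nC, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(nC_arr > 0, eC_arr / np.where(nC_arr > 0, nC_arr, 1.0), 0.0)
    return float(cc) if np.isscalar(eC) else cc


def compute_patch_metrics(
    habitat: HabitatRaster,
    patch_map: PatchMap,
    kernel: DispersalKernel,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-patch metrics table: eC, eD, nC and cC for every patch.

    Returns a DataFrame with columns ``patch_id, cells, area_m2, eC,
    eD, nC, cC``.  eD requires a decay rate on the kernel; for
    user-supplied kernels without one, eD is NaN.
    """
    seed_rain = effective_seed_rain(habitat, patch_map, kernel)
    eC = patch_effective_connectivity(seed_rain)
    pairwise = pairwise_effective_connectivity(habitat, patch_map, kernel, threshold)
    nC = count_connections(pairwise)
    cC = connection_capacity(eC, nC)
    if kernel.decay is not None:
        eD = effective_distance(eC, kernel.decay)
    else:
        eD = np.full_like(eC, np.nan)
    counts = patch_map.cell_counts
    return pd.DataFrame(
        {
            "patch_id": patch_map.patch_ids,
            "cells": counts,
            "area_m2": counts * habitat.cell_size**2,
            "eC": eC,
            "eD": eD,
            "nC": nC,
            "cC": cC,
        }
    )


def riverscape_summary(patch_table: pd.DataFrame) -> RiverscapeSummary:
    """Aggregate a per-patch metrics table to the riverscape level.

    cP is the mean patch eC (the riverscape's colonization potential);
    eDm averages eD over connected patches only (finite values; clamped
    zeros for eC >= 1 are included); nCm and cCm are means over all
    patches; pct_connected is the percentage of patches with at least
    one connection.
    """
    if len(patch_table) == 0:
        raise ValueError("riverscape summary requires at least one patch")
    eC = patch_table["eC"].to_numpy(dtype=float)
    eD = patch_table["eD"].to_numpy(dtype=float)
    nC = patch_table["nC"].to_numpy(dtype=float)
    cC = patch_table["cC"].to_numpy(dtype=float)
    eD_fin = eD[np.isfinite(eD)]

    def _stats(x: np.ndarray) -> tuple[float, float, float]:
        if x.size == 0:
            return math.nan, math.nan, math.nan
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if x.size > 1 else math.nan
        rsd = sd / mean if mean != 0 and not math.isnan(sd) else math.nan
        return mean, sd, rsd

    cP, eC_sd, eC_rsd = _stats(eC)
    eDm, eD_sd, eD_rsd = _stats(eD_fin)
    nCm, nC_sd, nC_rsd = _stats(nC)
    cCm, cC_sd, cC_rsd = _stats(cC)
    pct = 100.0 * float(np.count_nonzero(nC >= 1)) / len(patch_table)
    return RiverscapeSummary(
        n_patches=len(patch_table),
        cP=cP,
        eDm=eDm,
        nCm=nCm,
        cCm=cCm,
        pct_connected=pct,
        sd={"eC": eC_sd, "eD": eD_sd, "nC": nC_sd, "cC": cC_sd},
        rsd={"eC": eC_rsd, "eD": eD_rsd, "nC": nC_rsd, "cC": cC_rsd},
    )


def weighted_seed_rain(seed_rain: SeedRainMap, weights: np.ndarray) -> SeedRainMap:
    """Multiply eS cell-wise by a non-negative weight grid.

    The hook for occupancy, plant density or graded habitat quality:
    ``eS * weights`` with nodata preserved.  To restrict *donors* (e.g.
    to occupied cells) mask the habitat raster before computing eS
    instead — receiver-side weighting cannot express that.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != seed_rain.values.shape:
        raise ValueError(
            f"weights shape {w.shape} does not match seed rain "
            f"{seed_rain.values.shape}"
        )
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return SeedRainMap(
        values=seed_rain.values * w,
        kernel=seed_rain.kernel,
        patch_map=seed_rain.patch_map,
        habitat=seed_rain.habitat,
    )
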