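"""Seed-rain and connectivity metrics: definitional anchors, structural
invariants and agreement with the brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest

import riverconnect as rc
from conftest import random_landscape, unnormalized_kernel_sum

TOL = 1e-9


def test_single_patch_zero_everything(kernel_019):
    """With no other patch there are no donors: eS and eC are zero,
    eD infinite, the riverscape unconnected."""
    grid = np.zeros((9, 9), dtype=np.int8)
    grid[3:6, 3:6] = 1
    h = rc.HabitatRaster(grid=grid, cell_size=5)
    pm = rc.label_patches(h)
    sr = rc.effective_seed_rain(h, pm, kernel_019)
    assert np.all(sr.values == 0)
    table = rc.compute_patch_metrics(h, pm, kernel_019)
    assert table["eC"].iloc[0] == 0
    assert math.isinf(table["eD"].iloc[0])
    assert table["nC"].iloc[0] == 0
    summary = rc.riverscape_summary(table)
    assert summary.cP == 0
    assert summary.pct_connected == 0
    assert math.isnan(summary.eDm)


def test_ideal_cell_receives_exactly_one(kernel_019):
    """A suitable cell whose whole 7x7 kernel footprint lies on other
    patches' suitable cells receives the full ideal seed rain (eS = 1)."""
    grid = np.ones((7, 7), dtype=np.int8)
    h = rc.HabitatRaster(grid=grid, cell_size=5)
    labels = np.full((7, 7), 2, dtype=np.int32)
    labels[3, 3] = 1  # focal cell as its own patch
    pm = rc.PatchMap(labels=labels, connectivity_rule=8)
    sr = rc.effective_seed_rain(h, pm, kernel_019)
    assert sr.values[3, 3] == pytest.approx(1.0, abs=1e-12)


def test_two_single_cell_patches_exact_value(two_singles, kernel_019):
    """Centres 10 m apart: eS = 0.81^10 / pre-normalisation sum, in both
    cells (symmetry), matching the closed form and the oracle."""
    h, pm = two_singles
    sigma = unnormalized_kernel_sum(0.19, 5, 3)
    expected = 0.81**10 / sigma
    sr = rc.effective_seed_rain(h, pm, kernel_019)
    cells = sr.values[h.suitable_mask]
    assert cells == pytest.approx([expected, expected], abs=1e-12)
    oracle_sr, oracle_pc = rc.brute_force_seed_rain(h, pm, kernel_019)
    assert np.nanmax(np.abs(oracle_sr.values - sr.values)) < TOL
    assert oracle_pc.matrix[0, 1] == pytest.approx(expected, abs=1e-12)


def test_cell_size_mismatch_rejected(two_singles):
    h, pm = two_singles
    k = rc.build_kernel(0.19, 10, 3)
    with pytest.raises(ValueError, match="cell size"):
        rc.effective_seed_rain(h, pm, k)


def test_kernel_larger_than_raster_allowed():
    h = rc.two_patch_landscape(1, 1, 5)  # 3x4 raster
    k = rc.build_kernel(0.19, 5, 6)  # 13x13 window
    pm = rc.label_patches(h)
    sr = rc.effective_seed_rain(h, pm, k)
    oracle, _ = rc.brute_force_seed_rain(h, pm, k)
    assert np.nanmax(np.abs(sr.values - oracle.values)) < TOL


@pytest.mark.parametrize("seed", range(6))
def test_fast_path_matches_oracle(seed, kernel_14m):
    """Convolution fast path equals the definitional per-pair sum for
    eS, patch eC and the pairwise matrix on random landscapes."""
    h = random_landscape(seed)
    pm = rc.label_patches(h)
    sr = rc.effective_seed_rain(h, pm, kernel_14m)
    pc = rc.pairwise_effective_connectivity(h, pm, kernel_14m)
    osr, opc = rc.brute_force_seed_rain(h, pm, kernel_14m)
    assert np.nanmax(np.abs(sr.values - osr.values)) < TOL
    assert np.max(np.abs(pc.matrix - opc.matrix)) < TOL
    eC = rc.patch_effective_connectivity(sr)
    assert np.max(np.abs(eC - opc.matrix.sum(axis=1))) < TOL


def test_pairwise_symmetry_and_conservation(kernel_14m):
    h = random_landscape(42, shape=(35, 45), n=10)
    pm = rc.label_patches(h)
    sr = rc.effective_seed_rain(h, pm, kernel_14m)
    pc = rc.pairwise_effective_connectivity(h, pm, kernel_14m)
    m = pc.matrix
    assert np.max(np.abs(m - m.T)) < TOL
    assert np.all(np.diag(m) == 0)
    eC = rc.patch_effective_connectivity(sr)
    # each patch eC equals its pairwise row sum ...
    assert np.max(np.abs(eC - m.sum(axis=1))) < TOL
    # ... and the total eC equals total eS over suitable cells
    assert eC.sum() == pytest.approx(np.nansum(sr.values), abs=TOL)


def test_patches_beyond_kernel_radius_disconnected(kernel_019):
    h = rc.two_patch_landscape(1, 5, 5)  # centres 6 cells apart, radius 3
    pm = rc.label_patches(h)
    pc = rc.pairwise_effective_connectivity(h, pm, kernel_019)
    assert np.all(pc.matrix == 0)
    table = rc.compute_patch_metrics(h, pm, kernel_019)
    assert np.all(np.isinf(table["eD"]))


def test_monotone_distance_response():
    """eS/eC fall and eD rises strictly with separation, until the gap
    exceeds the kernel radius where eC = 0 and eD = inf."""
    kernel = rc.build_kernel(0.19, 5, 5)  # 11x11 window
    eCs, eDs = [], []
    for gap in range(1, 5):  # centre distances 2..5 cells (radius 5)
        h = rc.two_patch_landscape(1, gap, 5)
        pm = rc.label_patches(h)
        eC = rc.patch_effective_connectivity(
            rc.effective_seed_rain(h, pm, kernel)
        )[0]
        eCs.append(eC)
        eDs.append(rc.effective_distance(eC, 0.19))
    assert eCs[0] > eCs[1] > eCs[2] > eCs[3] > 0
    assert eDs[0] < eDs[1] < eDs[2] < eDs[3]
    h = rc.two_patch_landscape(1, 5, 5)  # centres 6 cells apart: beyond
    pm = rc.label_patches(h)
    eC = rc.patch_effective_connectivity(
        rc.effective_seed_rain(h, pm, kernel)
    )[0]
    assert eC == 0
    assert math.isinf(rc.effective_distance(eC, 0.19))


@pytest.mark.parametrize(
    "eC, decay, expected",
    [
        (1.0, 0.19, 0.0),
        (2.5, 0.19, 0.0),  # clamped: eC above 1 would give negative eD
        (0.81**10, 0.19, 10.0),
        (0.0, 0.19, math.inf),
    ],
)
def test_effective_distance_values(eC, decay, expected):
    assert rc.effective_distance(eC, decay) == pytest.approx(expected, abs=1e-9)


def test_effective_distance_validation():
    with pytest.raises(ValueError):
        rc.effective_distance(0.5, 1.5)
    with pytest.raises(ValueError):
        rc.effective_distance(-0.1, 0.19)


def test_count_connections_and_capacity_worked_example():
    """A patch exchanging 0.5 and 0.1 with two neighbours has nC = 2 and
    cC = (0.5 + 0.1) / 2 = 0.3."""
    m = np.array([[0.0, 0.5, 0.1], [0.5, 0.0, 0.0], [0.1, 0.0, 0.0]])
    pc = rc.PairwiseConnectivity(matrix=m, threshold=0.01)
    nC = rc.count_connections(pc)
    assert nC.tolist() == [2, 1, 1]
    eC = m.sum(axis=1)
    cC = rc.connection_capacity(eC, nC)
    assert cC[0] == pytest.approx(0.3, abs=1e-12)
    assert rc.connection_capacity(0.38, 1) == pytest.approx(0.38)
    assert rc.connection_capacity(0.004, 0) == 0.0


def test_threshold_excludes_weak_connections_but_not_eC():
    """The 0.01 threshold applies only to counting connections; the
    patch eC and cC keep sub-threshold seed rain."""
    m = np.array([[0.0, 0.5, 0.005], [0.5, 0.0, 0.0], [0.005, 0.0, 0.0]])
    pc = rc.PairwiseConnectivity(matrix=m, threshold=0.01)
    nC = rc.count_connections(pc)
    assert nC.tolist() == [1, 1, 0]
    cC = rc.connection_capacity(m.sum(axis=1), nC)
    assert cC[0] == pytest.approx(0.505, abs=1e-12)


def test_linearity_of_capacity():
    m = np.array([[0.0, 0.5, 0.1], [0.5, 0.0, 0.0], [0.1, 0.0, 0.0]])
    pc = rc.PairwiseConnectivity(matrix=m)
    nC = rc.count_connections(pc)
    cC = rc.connection_capacity(m.sum(axis=1), nC)
    cC2 = rc.connection_capacity(2 * m.sum(axis=1), rc.count_connections(
        rc.PairwiseConnectivity(matrix=2 * m)
    ))
    assert cC2 == pytest.approx(2 * cC, abs=1e-12)


def test_translation_invariance(kernel_14m):
    h = random_landscape(3, shape=(25, 30), n=6)
    pm = rc.label_patches(h)
    t1 = rc.compute_patch_metrics(h, pm, kernel_14m)
    padded = np.pad(h.grid, ((4, 2), (3, 5)))
    h2 = rc.HabitatRaster(grid=padded, cell_size=5)
    t2 = rc.compute_patch_metrics(h2, rc.label_patches(h2), kernel_14m)
    for col in ("eC", "eD", "nC", "cC", "cells"):
        np.testing.assert_allclose(t1[col], t2[col], atol=TOL)


def test_riverscape_summary_statistics(kernel_14m):
    """Summary equals statistics computed directly from the per-patch
    oracle table."""
    h = random_landscape(11, shape=(30, 30), n=6)
    pm = rc.label_patches(h)
    _, opc = rc.brute_force_seed_rain(h, pm, kernel_14m)
    eC = opc.matrix.sum(axis=1)
    nC = rc.count_connections(opc)
    table = rc.compute_patch_metrics(h, pm, kernel_14m)
    summary = rc.riverscape_summary(table)
    assert summary.cP == pytest.approx(eC.mean(), abs=TOL)
    assert summary.nCm == pytest.approx(nC.mean(), abs=TOL)
    eD = rc.effective_distance(eC, kernel_14m.decay)
    finite = eD[np.isfinite(eD)]
    if finite.size:
        assert summary.eDm == pytest.approx(finite.mean(), abs=TOL)
    assert summary.pct_connected == pytest.approx(100 * (nC >= 1).mean(), abs=TOL)
    assert summary.sd["eC"] == pytest.approx(np.std(eC, ddof=1), abs=TOL)
    assert summary.rsd["eC"] == pytest.approx(
        np.std(eC, ddof=1) / eC.mean(), abs=TOL
    )


def test_summary_duplication_symmetry(kernel_019):
    """Two identical, mutually unreachable patch pairs give the same cP
    as a single pair: the mean is configuration-local, not area-weighted."""
    h1 = rc.two_patch_landscape(2, 1, 5)
    pm1 = rc.label_patches(h1)
    s1 = rc.riverscape_summary(rc.compute_patch_metrics(h1, pm1, kernel_019))
    # stack two copies far apart vertically (>> kernel radius 3)
    g = h1.grid
    spacer = np.zeros((10, g.shape[1]), dtype=np.int8)
    h2 = rc.HabitatRaster(grid=np.vstack([g, spacer, g]), cell_size=5)
    s2 = rc.riverscape_summary(
        rc.compute_patch_metrics(h2, rc.label_patches(h2), kernel_019)
    )
    assert s2.cP == pytest.approx(s1.cP, abs=TOL)
    assert s2.eDm == pytest.approx(s1.eDm, abs=TOL)
    assert s2.pct_connected == pytest.approx(s1.pct_connected, abs=TOL)


def test_summary_requires_patches():
    with pytest.raises(ValueError):
        rc.riverscape_summary(pd.DataFrame(columns=["eC", "eD", "nC", "cC"]))


def test_shape_effect_longer_interface_receives_more(kernel_019):
    """Equal-area donors at the same edge gap: the more elongated the
    donor (longer interface to the receiver), the higher the receiver's
    total seed rain."""
    ratios = [(4, 4), (2, 8), (1, 16)]
    landscapes = rc.shape_series(16, ratios, gap=1)
    totals = []
    for h in landscapes:
        pm = rc.label_patches(h)
        assert pm.n_patches == 2
        sr = rc.effective_seed_rain(h, pm, kernel_019)
        receiver_id = pm.labels[-2, 0]  # the full-width strip
        totals.append(float(np.nansum(sr.values[pm.labels == receiver_id])))
    assert totals[0] < totals[1] < totals[2]


def test_weighted_seed_rain(two_singles, kernel_019):
    h, pm = two_singles
    sr = rc.effective_seed_rain(h, pm, kernel_019)
    same = rc.weighted_seed_rain(sr, np.ones(h.shape))
    assert np.array_equal(
        same.values[~h.nodata_mask], sr.values[~h.nodata_mask]
    )
    zero = rc.weighted_seed_rain(sr, np.zeros(h.shape))
    assert np.all(zero.values[~h.nodata_mask] == 0)
    doubled = rc.weighted_seed_rain(sr, np.full(h.shape, 2.0))
    assert rc.patch_effective_connectivity(doubled) == pytest.approx(
        2 * rc.patch_effective_connectivity(sr), abs=TOL
    )
    with pytest.raises(ValueError, match="shape"):
        rc.weighted_seed_rain(sr, np.ones((2, 2)))
    with pytest.raises(ValueError, match="non-negative"):
        rc.weighted_seed_rain(sr, -np.ones(h.shape))


def test_donor_side_masking_equals_masked_habitat_run(kernel_019):
    """Restricting donors (e.g. to occupied cells) must be done by
    masking the habitat input; the oracle run on the masked raster is
    the reference."""
    h = rc.two_patch_landscape(2, 1, 5)
    masked = h.grid.copy()
    masked[1, 1] = 0  # one donor cell unoccupied
    h_masked = rc.HabitatRaster(grid=masked, cell_size=5)
    pm = rc.label_patches(h_masked)
    sr = rc.effective_seed_rain(h_masked, pm, kernel_019)
    oracle, _ = rc.brute_force_seed_rain(h_masked, pm, kernel_019)
    assert np.nanmax(np.abs(sr.values - oracle.values)) < TOL


def test_nodata_cells_neither_donate_nor_receive(kernel_019):
    g = rc.two_patch_landscape(2, 1, 5).grid.copy()
    g[0, :] = -1  # nodata stripe outside the active channel
    h = rc.HabitatRaster(grid=g, cell_size=5)
    pm = rc.label_patches(h)
    sr = rc.effective_seed_rain(h, pm, kernel_019)
    assert np.all(np.isnan(sr.values[h.nodata_mask]))
    oracle, _ = rc.brute_force_seed_rain(h, pm, kernel_019)
    assert np.nanmax(np.abs(sr.values - oracle.values)) < TOL
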