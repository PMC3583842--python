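"""Voronoi domains, ICDs, distance maps and diffusion-limited fractions."""

import numpy as np
import pytest

from vasomet import (
    NoVesselError,
    PixelMask,
    ValidationError,
    corrected_domain_areas,
    diffusion_limited_fraction,
    distance_map,
    domain_table,
    icd_distribution,
    icd_from_area,
    label_components,
    mean_distance_in_region,
    quantize_distance_map,
    voronoi_domains,
)

from .conftest import nonempty_random_mask


def full_roi(shape, px=1.0):
    return PixelMask(np.ones(shape, dtype=bool), px)


def point_vessels(shape, points, px=1.0):
    grid = np.zeros(shape, dtype=bool)
    for r, c in points:
        grid[r, c] = True
    return label_components(PixelMask(grid, px))


def brute_nearest(labels: np.ndarray):
    """Exhaustive nearest-vessel search with the smallest-label tie rule.

    Returns (assignment, sqrt of integer squared distance) per pixel.
    """
    vr, vc = np.nonzero(labels)
    vlab = labels[vr, vc]
    rows, cols = np.indices(labels.shape)
    d2 = (rows[..., None] - vr) ** 2 + (cols[..., None] - vc) ** 2  # int arithmetic
    best = d2.min(axis=-1)
    assign = np.zeros(labels.shape, dtype=int)
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            ties = vlab[d2[r, c] == best[r, c]]
            assign[r, c] = ties.min()
    return assign, np.sqrt(best.astype(float))


# ---------------------------------------------------------------- Voronoi


def test_single_component_owns_everything():
    vessels = point_vessels((9, 9), [(4, 4)])
    roi = full_roi((9, 9))
    dom = voronoi_domains(vessels, roi)
    assert (dom.assignment == 1).all()


def test_two_point_assignment_and_tie_rule():
    vessels = point_vessels((1, 11), [(0, 0), (0, 10)])
    dom = voronoi_domains(vessels, full_roi((1, 11)))
    assert dom.assignment[0, 4] == 1
    assert dom.assignment[0, 6] == 2
    assert dom.assignment[0, 5] == 1  # equidistant: lowest label wins


def test_voronoi_requires_vessels():
    empty = label_components(PixelMask(np.zeros((5, 5), dtype=bool), 1.0))
    with pytest.raises(NoVesselError):
        voronoi_domains(empty, full_roi((5, 5)))


def test_voronoi_outside_roi_is_zero(rng):
    vessels = label_components(nonempty_random_mask(rng, (20, 20), 0.05))
    roi = PixelMask(rng.random((20, 20)) < 0.5, 1.0)
    if not roi.grid.any():
        roi = full_roi((20, 20))
    dom = voronoi_domains(vessels, roi)
    assert (dom.assignment[~roi.grid] == 0).all()
    assert (dom.assignment[roi.grid] > 0).all()


@pytest.mark.parametrize("seed", range(10))
def test_voronoi_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    vessels = label_components(nonempty_random_mask(rng, (25, 25), 0.04))
    dom = voronoi_domains(vessels, full_roi((25, 25)))
    expected, _ = brute_nearest(vessels.labels)
    assert np.array_equal(dom.assignment, expected)


# ---------------------------------------------------------------- areas & ICD


def test_corrected_areas_direct_arithmetic():
    # one vessel blob of 4 px in a 10x10 ROI: its domain is everything
    grid = np.zeros((10, 10), dtype=bool)
    grid[4:6, 4:6] = True
    vessels = label_components(PixelMask(grid, 1.0))
    roi = full_roi((10, 10))
    dom = voronoi_domains(vessels, roi)
    areas = corrected_domain_areas(dom, vessels, roi)
    assert areas.tolist() == [96.0]  # 100 assigned - 4 vessel px


def test_corrected_areas_scale_with_calibration_squared():
    grid = np.zeros((10, 10), dtype=bool)
    grid[4:6, 4:6] = True
    for px, expected in [(1.0, 96.0), (2.0, 384.0)]:
        vessels = label_components(PixelMask(grid, px))
        roi = full_roi((10, 10), px)
        dom = voronoi_domains(vessels, roi)
        assert corrected_domain_areas(dom, vessels, roi).tolist() == [expected]


def test_vessel_filling_domain_gives_zero_area():
    vessels = label_components(PixelMask(np.ones((4, 4), dtype=bool), 1.0))
    roi = full_roi((4, 4))
    dom = voronoi_domains(vessels, roi)
    assert corrected_domain_areas(dom, vessels, roi).tolist() == [0.0]
    dist = icd_distribution(dom, vessels, roi)
    assert dist.icd_um.tolist() == [0.0]  # kept with ICD 0


def test_icd_from_area_closed_forms():
    assert icd_from_area(100 * np.pi) == pytest.approx(20.0)
    assert icd_from_area(0.0) == 0.0
    assert icd_from_area(5026.55) == pytest.approx(80.0, abs=1e-3)
    with pytest.raises(ValidationError):
        icd_from_area(-1.0)


def test_icd_distribution_mean_of_two_domains():
    # two point vessels splitting a 1x20 strip into equal halves
    vessels = point_vessels((1, 20), [(0, 4), (0, 15)])
    roi = full_roi((1, 20))
    dom = voronoi_domains(vessels, roi)
    dist = icd_distribution(dom, vessels, roi)
    assert dist.n_domains == 2
    expected = 2 * np.sqrt(9 / np.pi)
    assert dist.mean_um == pytest.approx(expected)
    assert dist.sd_um == pytest.approx(0.0)


def test_icd_distribution_translation_invariant(rng):
    """Translating vessels and ROI together leaves the ICD distribution unchanged."""
    grid = np.zeros((30, 30), dtype=bool)
    grid[[3, 20, 11], [4, 22, 15]] = True
    roi_grid = np.zeros((30, 30), dtype=bool)
    roi_grid[0:26, 0:25] = True
    out = []
    for shift in ((0, 0), (2, 3)):
        g = np.roll(grid, shift, axis=(0, 1))
        r = np.roll(roi_grid, shift, axis=(0, 1))
        vessels = label_components(PixelMask(g, 1.5))
        roi = PixelMask(r, 1.5)
        dom = voronoi_domains(vessels, roi)
        out.append(np.sort(icd_distribution(dom, vessels, roi).icd_um))
    np.testing.assert_allclose(out[0], out[1])


def test_conservation_of_domain_areas(rng):
    """Corrected areas plus in-ROI vessel area reproduce the ROI area exactly."""
    for _ in range(10):
        vessels = label_components(nonempty_random_mask(rng, (30, 30), 0.05, 2.0))
        roi = PixelMask(rng.random((30, 30)) < 0.8, 2.0)
        if not roi.grid.any():
            continue
        dom = voronoi_domains(vessels, roi)
        areas = corrected_domain_areas(dom, vessels, roi)
        vessel_in_roi = ((vessels.labels > 0) & roi.grid).sum()
        assert areas.sum() + vessel_in_roi * 4.0 == pytest.approx(roi.n_true * 4.0)


def test_regular_lattice_icd_limit():
    """Domains of an odd-spacing lattice tile exactly: ICD -> 2 s / sqrt(pi).

    Odd spacing keeps cell boundaries off the half-integer midlines, so no
    tie-broken pixels distort individual cells.
    """
    s, n = 9, 8
    shape = (s * n, s * n)
    pts = [(s // 2 + i * s, s // 2 + j * s) for i in range(n) for j in range(n)]
    vessels = point_vessels(shape, pts)
    roi = full_roi(shape)
    dom = voronoi_domains(vessels, roi)
    areas = corrected_domain_areas(dom, vessels, roi)
    icds = icd_from_area(areas)
    expected = 2 * np.sqrt((s * s - 1) / np.pi)  # one vessel pixel subtracted
    np.testing.assert_allclose(icds, expected, rtol=1e-12)


# ---------------------------------------------------------------- distance map


def test_distance_three_four_five():
    grid = np.zeros((5, 6), dtype=bool)
    grid[0, 0] = True
    dmap = distance_map(PixelMask(grid, 1.0))
    assert dmap.dist_um[3, 4] == pytest.approx(5.0)


def test_distance_zero_on_vessels_and_all_vessel_roi():
    full = PixelMask(np.ones((6, 6), dtype=bool), 1.0)
    assert (distance_map(full).dist_um == 0).all()
    with pytest.raises(NoVesselError):
        distance_map(PixelMask(np.zeros((6, 6), dtype=bool), 1.0))


@pytest.mark.parametrize("seed", range(10))
def test_distance_matches_brute_force(seed):
    rng = np.random.default_rng(200 + seed)
    vessels = nonempty_random_mask(rng, (30, 30), 0.03, 1.7)
    dmap = distance_map(vessels)
    _, brute = brute_nearest(label_components(vessels).labels)
    np.testing.assert_allclose(dmap.dist_um, brute * 1.7, atol=1e-9)


def test_distance_lipschitz(rng):
    vessels = nonempty_random_mask(rng, (40, 40), 0.02, 2.0)
    d = distance_map(vessels).dist_um
    step = 2.0 * np.sqrt(2) + 1e-9
    assert np.abs(np.diff(d, axis=0)).max() <= step
    assert np.abs(np.diff(d, axis=1)).max() <= step


# ---------------------------------------------------------------- DLF


def test_dlf_trivial_cases():
    full = PixelMask(np.ones((6, 6), dtype=bool), 1.0)
    roi = full_roi((6, 6))
    assert diffusion_limited_fraction(distance_map(full), roi, 80).fraction == 0.0
    grid = np.zeros((6, 6), dtype=bool)
    grid[0, 0] = True
    res = diffusion_limited_fraction(distance_map(PixelMask(grid, 1.0)), roi, 0.0)
    assert res.fraction == 35 / 36  # strict inequality: vessel pixel excluded


def test_dlf_central_vessel_brute_count():
    shape = (101, 101)
    grid = np.zeros(shape, dtype=bool)
    grid[50, 50] = True
    dmap = distance_map(PixelMask(grid, 1.0))
    res = diffusion_limited_fraction(dmap, full_roi(shape), 40.0)
    rows, cols = np.indices(shape)
    expected = ((rows - 50) ** 2 + (cols - 50) ** 2 > 1600).sum() / (101 * 101)
    assert res.fraction == expected


def test_dlf_monotone_in_cutoff_and_vessels(rng):
    for _ in range(10):
        vessels = nonempty_random_mask(rng, (40, 40), 0.02)
        roi = full_roi((40, 40))
        dmap = distance_map(vessels)
        fracs = [diffusion_limited_fraction(dmap, roi, c).fraction for c in (0, 5, 10, 20, 40)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        # adding a vessel pixel can only shrink distances and DLFs
        grid = vessels.grid.copy()
        grid[tuple(rng.integers(0, 40, 2))] = True
        dmap2 = distance_map(PixelMask(grid, 1.0))
        assert (dmap2.dist_um <= dmap.dist_um + 1e-12).all()
        for c in (5, 10, 20):
            assert (
                diffusion_limited_fraction(dmap2, roi, c).fraction
                <= diffusion_limited_fraction(dmap, roi, c).fraction
            )


def test_scaling_invariance(rng):
    """Scaling the calibration by s scales distances by s and maps DLF cutoffs."""
    grid = nonempty_random_mask(rng, (30, 30), 0.04).grid
    roi_grid = np.ones((30, 30), dtype=bool)
    d1 = distance_map(PixelMask(grid, 1.0))
    d3 = distance_map(PixelMask(grid, 3.0))
    np.testing.assert_allclose(d3.dist_um, 3 * d1.dist_um)
    f1 = diffusion_limited_fraction(d1, PixelMask(roi_grid, 1.0), 7.0).fraction
    f3 = diffusion_limited_fraction(d3, PixelMask(roi_grid, 3.0), 21.0).fraction
    assert f1 == f3


# ---------------------------------------------------------------- regions, tables


def test_mean_distance_in_region_arithmetic():
    dist = np.arange(25, dtype=float).reshape(5, 5)
    from vasomet import DistanceMap

    dmap = DistanceMap(dist, 1.0)
    region = np.zeros((5, 5), dtype=bool)
    region[0, 0] = region[1, 1] = region[2, 2] = True
    roi = full_roi((5, 5))
    mean_in, mean_out = mean_distance_in_region(dmap, PixelMask(region, 1.0), roi)
    assert mean_in == pytest.approx(np.mean([0, 6, 12]))
    assert mean_out == pytest.approx(dist[~region].mean())


def test_mean_distance_empty_side_is_nan():
    from vasomet import DistanceMap

    dmap = DistanceMap(np.full((4, 4), 3.0), 1.0)
    roi = full_roi((4, 4))
    mean_in, mean_out = mean_distance_in_region(dmap, roi, roi)
    assert mean_in == pytest.approx(3.0)
    assert np.isnan(mean_out)


def test_domain_table_columns(rng):
    vessels = label_components(nonempty_random_mask(rng, (20, 20), 0.05))
    roi = full_roi((20, 20))
    dom = voronoi_domains(vessels, roi)
    table = domain_table(dom, vessels, roi)
    assert list(table.columns) == ["label", "domain_px", "vessel_px_in_roi", "corrected_area_um2", "icd_um"]
    assert len(table) == vessels.n_components


def test_quantize_distance_map(rng):
    vessels = nonempty_random_mask(rng, (20, 20), 0.05)
    dmap = distance_map(vessels)
    q = quantize_distance_map(dmap, 256)
    step = dmap.dist_um.max() / 255
    assert np.abs(q.dist_um - dmap.dist_um).max() <= step / 2 + 1e-12
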