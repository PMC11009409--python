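"""Peak/valley detection and the CTC / VPDR / FWHM metrics."""

import numpy as np
import pytest

from moirebeam.metrics import (
    LateralProfile,
    PeaksValleys,
    UndefinedMetricError,
    average_beamlet_profile,
    compare_to_analytic,
    ctc,
    find_peaks_valleys,
    fwhm,
    lateral_profile,
    vpdr,
)
from moirebeam.transport import DoseGrid, Phantom


def make_profile(positions, values):
    return LateralProfile(
        axis="x",
        positions=positions,
        values=values,
        depth_window=(0.0, 4.0),
        band_halfwidth=10.0,
    )


def gaussian_comb(spacing=3.86, sigma=0.5, n_teeth=11, dx=0.02, floor=0.0):
    half = (n_teeth // 2) * spacing + 2 * spacing
    x = np.arange(-half, half + dx / 2, dx)
    centers = spacing * (np.arange(n_teeth) - n_teeth // 2)
    y = floor + sum(np.exp(-0.5 * ((x - c) / sigma) ** 2) for c in centers)
    return make_profile(x, y), centers


def test_cos_squared_comb_peaks_and_valleys():
    x = np.arange(-20, 20.001, 0.05)
    y = np.cos(np.pi * x / 4.0) ** 2  # period 4 mm, peaks at multiples of 4
    pv = find_peaks_valleys(make_profile(x, y))
    assert ctc(pv) == pytest.approx(4.0, abs=0.01)
    dist_to_tooth = np.abs((pv.peak_positions + 2.0) % 4.0 - 2.0)
    assert np.allclose(dist_to_tooth, 0.0, atol=0.02)
    assert np.all(pv.valley_values < 1e-3)


def test_monotone_ramp_has_no_peaks():
    x = np.arange(0, 10, 0.1)
    pv = find_peaks_valleys(make_profile(x, x * 2.0))
    assert pv.n_peaks == 0


def test_gaussian_comb_centers_recovered_subvoxel():
    prof, centers = gaussian_comb()
    pv = find_peaks_valleys(prof)
    # all 11 teeth lie inside the central 80% of this field
    assert pv.n_peaks == 11
    assert np.max(np.abs(np.sort(pv.peak_positions) - centers)) < 0.02
    assert ctc(pv) == pytest.approx(3.86, abs=0.01)


def test_ctc_of_explicit_peaks():
    pv = PeaksValleys(np.array([0.0, 4.0, 8.0]), np.ones(3),
                      np.array([2.0, 6.0]), np.zeros(2))
    assert ctc(pv) == pytest.approx(4.0)
    with pytest.raises(UndefinedMetricError):
        ctc(PeaksValleys(np.array([1.0]), np.ones(1), np.array([]), np.array([])))


def test_vpdr_limits():
    flat = PeaksValleys(np.array([0.0, 4.0]), np.array([5.0, 5.0]),
                        np.array([2.0]), np.array([5.0]))
    assert vpdr(flat) == pytest.approx(1.0)
    # an ideal binary comb has zero-dose valleys
    x = np.arange(-10, 10, 0.05)
    y = ((x % 4.0) < 1.0).astype(float)
    pv = find_peaks_valleys(make_profile(x, y))
    assert vpdr(pv) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(UndefinedMetricError):
        vpdr(PeaksValleys(np.array([0.0]), np.ones(1), np.array([]), np.array([])))


def test_vpdr_matches_closed_form_mixture_oracle():
    spacing, sigma = 3.86, 0.8
    prof, centers = gaussian_comb(spacing=spacing, sigma=sigma)
    pv = find_peaks_valleys(prof)

    def mixture(x):
        return sum(np.exp(-0.5 * ((x - c) / sigma) ** 2) for c in centers)

    inner = centers[1:-1]  # oracle over teeth with both neighbours present
    oracle = np.mean(mixture(inner + spacing / 2)) / np.mean(mixture(inner))
    assert vpdr(pv) == pytest.approx(oracle, abs=5e-3)


def test_fwhm_rectangle_triangle_gaussian():
    dx = 0.01
    x = np.arange(-5, 5, dx)
    rect = (np.abs(x) <= 0.5).astype(float)
    assert fwhm(make_profile(x, rect)) == pytest.approx(1.0, abs=2 * dx)

    tri = np.clip(1.0 - np.abs(x), 0.0, None)  # base 2 mm
    assert fwhm(make_profile(x, tri)) == pytest.approx(1.0, abs=2 * dx)

    sigma = 0.7
    gauss = np.exp(-0.5 * (x / sigma) ** 2)
    assert fwhm(make_profile(x, gauss)) == pytest.approx(2.3548 * sigma, rel=0.01)


def test_fwhm_undefined_when_no_peak():
    x = np.arange(0, 10, 0.1)
    with pytest.raises(UndefinedMetricError):
        fwhm(make_profile(x, x))


@pytest.mark.parametrize("scale", [0.1, 3.0, 1e4])
def test_metrics_scale_invariance(scale):
    prof, _ = gaussian_comb(floor=0.1)
    scaled = make_profile(prof.positions, prof.values * scale)
    pv1, pv2 = find_peaks_valleys(prof), find_peaks_valleys(scaled)
    assert ctc(pv1) == pytest.approx(ctc(pv2), rel=1e-12)
    assert vpdr(pv1) == pytest.approx(vpdr(pv2), rel=1e-9)
    assert fwhm(prof, pv1) == pytest.approx(fwhm(scaled, pv2), rel=1e-9)


def test_metrics_translation_invariance():
    prof, _ = gaussian_comb()
    shifted = make_profile(prof.positions + 1.7, prof.values)
    pv1, pv2 = find_peaks_valleys(prof), find_peaks_valleys(shifted)
    np.testing.assert_allclose(
        pv2.peak_positions, pv1.peak_positions + 1.7, atol=1e-9
    )
    assert ctc(pv2) == pytest.approx(ctc(pv1), rel=1e-12)
    assert vpdr(pv2) == pytest.approx(vpdr(pv1), rel=1e-12)


def test_ctc_converges_with_resolution():
    coarse, _ = gaussian_comb(dx=0.1)
    fine, _ = gaussian_comb(dx=0.05)
    c1 = ctc(find_peaks_valleys(coarse))
    c2 = ctc(find_peaks_valleys(fine))
    assert abs(c1 - c2) < 0.5 * 0.1


def test_average_beamlet_profile_preserves_shape():
    prof, _ = gaussian_comb(sigma=0.6)
    pv = find_peaks_valleys(prof)
    avg = average_beamlet_profile(prof, pv, halfwidth=1.9)
    assert fwhm(avg) == pytest.approx(2.3548 * 0.6, rel=0.02)


def test_compare_to_analytic_examples():
    assert compare_to_analytic(3.95, 3.86) == pytest.approx(2.33, abs=0.01)
    assert compare_to_analytic(2.42, 2.37) == pytest.approx(2.11, abs=0.01)
    assert compare_to_analytic(5.0, 5.0) == 0.0
    assert compare_to_analytic(3.80, 3.86) < 0  # signed
    with pytest.raises(ValueError):
        compare_to_analytic(-1.0, 3.86)


def filled_grid(fill):
    grid = DoseGrid(nx=100, ny=60, nz=5, dx=0.5, dy=0.5, dz=4.0,
                    x0=-25, y0=-15, phantom=Phantom())
    grid.edep[...] = fill
    return grid


def test_lateral_profile_uniform_grid_is_constant():
    grid = filled_grid(2.0)
    prof = lateral_profile(grid, (4.0, 12.0), axis="x", band_halfwidth=5.0)
    assert np.ptp(prof.values) == pytest.approx(0.0, abs=1e-12)
    assert prof.positions.size == 100


def test_lateral_profile_band_and_window_selection():
    grid = filled_grid(1.0)
    # mark one y-row: zero-halfwidth extraction picks exactly that row
    iy = 30
    grid.edep[:, iy, :] *= 7.0
    prof = lateral_profile(grid, (0.0, 4.0), axis="x", band_halfwidth=0.0,
                           band_center=grid.y_centers[iy])
    assert np.all(prof.values == prof.values[0])
    ref = lateral_profile(grid, (0.0, 4.0), axis="x", band_halfwidth=0.0,
                          band_center=grid.y_centers[iy - 5])
    assert prof.values[0] == pytest.approx(7.0 * ref.values[0])


def test_lateral_profile_window_validation():
    grid = filled_grid(1.0)
    with pytest.raises(ValueError):
        lateral_profile(grid, (4.0, 4.0), axis="x")
    with pytest.raises(ValueError):
        lateral_profile(grid, (0.0, 100.0), axis="x")
    with pytest.raises(ValueError):
        lateral_profile(grid, (0.0, 4.0), axis="q")
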