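"""The five QA metrics: closed forms, oracles and error paths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from us3dqa.metrics import (
    LineProfile,
    NoMarkerError,
    PeakClippedError,
    ROISpec,
    SurfaceNotFoundError,
    SurfaceProfile,
    contrast_resolution,
    distance_error,
    find_marker_peak,
    fwhm,
    line_profile,
    run_qa,
    stability,
    surface_profile,
)
from us3dqa.phantom import default_phantom
from us3dqa.reconstruct import Volume

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _volume(data, spacing=(0.1, 0.1, 0.1), origin=(0.0, 0.0, 0.0)):
    return Volume(np.asarray(data, np.uint8), spacing, origin)


class TestContrastResolution:
    levels = (-9.0, -6.0, -3.0, 3.0, 6.0)

    def _cyl_volume(self, values):
        data = np.zeros((20, 100, 10), np.uint8)
        rois = []
        for m, v in enumerate(values):
            j = 10 + 20 * m
            data[5:15, j - 5: j + 5, :] = v
            rois.append(ROISpec((10, j, 5), "box", (0.3, 0.3, 0.3)))
        return _volume(data), rois

    def test_exact_linear_means_recover_slope(self):
        # integer grays exactly linear in dB with slope 2
        vol, rois = self._cyl_volume([128 + 2 * int(d) for d in self.levels])
        res = contrast_resolution(vol, rois, self.levels)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_means_give_zero_slope(self):
        vol, rois = self._cyl_volume([100] * 5)
        res = contrast_resolution(vol, rois, self.levels)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_requires_five_rois(self):
        vol, rois = self._cyl_volume([100] * 5)
        with pytest.raises(ValueError):
            contrast_resolution(vol, rois[:3], self.levels[:3])


class TestFindMarkerPeak:
    def test_single_hot_voxel(self):
        data = np.zeros((9, 9, 9), np.uint8)
        data[3, 4, 5] = 200
        assert find_marker_peak(_volume(data), ROISpec((4, 4, 4))) == (3, 4, 5)

    def test_collinear_tie_takes_center(self):
        data = np.zeros((9, 9, 9), np.uint8)
        data[4, 4, 3] = data[4, 4, 4] = data[4, 4, 5] = 200
        assert find_marker_peak(_volume(data), ROISpec((4, 4, 4))) == (4, 4, 4)

    def test_flat_roi_raises(self):
        data = np.full((9, 9, 9), 90, np.uint8)
        with pytest.raises(NoMarkerError):
            find_marker_peak(_volume(data), ROISpec((4, 4, 4)))


class TestDistanceError:
    def test_zero_when_equal(self):
        res = distance_error((0, 0, 0), (0, 0, 60), (0.1, 0.1, 0.5), 30.0)
        assert res.measured_mm == pytest.approx(30.0)
        assert res.error_mm == pytest.approx(0.0)

    def test_printed_example(self):
        # measured 45.78 mm against an actual 50 mm spacing
        res = distance_error((0, 0, 0), (0, 0, 4578), (0.1, 0.1, 0.01), 50.0)
        assert res.error_mm == pytest.approx(4.22, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 400), st.floats(0.05, 0.5), st.floats(1.0, 60.0))
    def test_symmetry_and_scale(self, dz, spacing, actual):
        p1, p2 = (0, 0, 0), (0, 0, dz)
        sp = (0.1, 0.1, spacing)
        a = distance_error(p1, p2, sp, actual)
        b = distance_error(p2, p1, sp, actual)
        assert a.error_mm == b.error_mm >= 0.0
        assert a.error_mm == pytest.approx(abs(actual - dz * spacing), abs=1e-9)


class TestLineProfile:
    def test_length_and_peak_membership(self):
        data = np.zeros((30, 5, 12), np.uint8)
        data[20, 2, 7] = 250
        vol = _volume(data)
        ax = line_profile(vol, (20, 2, 7), "axial")
        el = line_profile(vol, (20, 2, 7), "elevation")
        assert ax.values.size == 30 and el.values.size == 12
        assert ax.values.max() == 250 and el.values.max() == 250

    def test_uniform_volume_constant_profile(self):
        vol = _volume(np.full((30, 5, 12), 77, np.uint8))
        assert np.all(line_profile(vol, (0, 2, 0), "axial").values == 77)

    def test_lateral_axis_unsupported(self):
        vol = _volume(np.zeros((4, 4, 4), np.uint8))
        with pytest.raises(ValueError, match="axial and elevation"):
            line_profile(vol, (1, 1, 1), "lateral")


class TestFWHM:
    @pytest.mark.parametrize("sigma", np.round(np.arange(0.1, 1.01, 0.1), 2))
    def test_gaussian_closed_form_ladder(self, sigma):
        """Noise-free Gaussian profiles recover 2·sqrt(2 ln 2)·σ within
        half a sample spacing (on- and off-grid centers)."""
        x = np.arange(0.0, 12.0, 0.1)
        for center in (6.0, 6.05):
            v = 200.0 * np.exp(-((x - center) ** 2) / (2 * sigma**2))
            res = fwhm(LineProfile(x, v, "axial"))
            assert res.fwhm_mm == pytest.approx(FWHM_FACTOR * sigma, abs=0.05)

    def test_gaussian_sigma_02(self):
        x = np.arange(0.0, 8.0, 0.1)
        v = 200.0 * np.exp(-((x - 4.0) ** 2) / (2 * 0.2**2))
        assert fwhm(LineProfile(x, v, "axial")).fwhm_mm == pytest.approx(
            0.471, abs=0.01)

    def test_triangle_exact(self):
        x = np.arange(0.0, 4.05, 0.05)
        v = np.clip(200.0 * (1.0 - np.abs(x - 2.0)), 0.0, None)
        res = fwhm(LineProfile(x, v, "axial"))
        assert res.fwhm_mm == pytest.approx(1.0, abs=1e-9)

    def test_nonzero_floor_subtracted(self):
        x = np.arange(0.0, 8.0, 0.1)
        v = 50.0 + 150.0 * np.exp(-((x - 4.0) ** 2) / (2 * 0.3**2))
        res = fwhm(LineProfile(x, v, "axial"))
        assert res.half_level_gray == pytest.approx(125.0, abs=0.5)
        assert res.fwhm_mm == pytest.approx(FWHM_FACTOR * 0.3, abs=0.02)

    def test_clipped_peak_raises(self):
        x = np.arange(0.0, 4.0, 0.1)
        v = 200.0 * np.exp(-((x - 0.1) ** 2) / (2 * 0.5**2))
        with pytest.raises(PeakClippedError):
            fwhm(LineProfile(x, v, "axial"))


class TestSurfaceProfile:
    @staticmethod
    def _plane_volume(surface_rows, rows=60):
        """Volume whose mid-lateral plane has the surface at the given
        row per elevation column."""
        n = len(surface_rows)
        data = np.zeros((rows, 3, n), np.uint8)
        for k, r in enumerate(surface_rows):
            data[r:, 1, k] = 200
        return _volume(data, spacing=(0.1, 0.1, 0.5))

    def test_flat_surface_zero_df(self):
        vol = self._plane_volume([30] * 40)
        prof = surface_profile(vol)
        assert prof.f_px.size == 10  # ceil(0.25 × 40)
        assert np.all(prof.df_px == 0)

    def test_ramp_unit_df(self):
        rows = np.arange(20, 60)  # 1 px per column
        vol = self._plane_volume(list(rows), rows=80)
        prof = surface_profile(vol)
        assert np.all(prof.df_px == 1)

    def test_known_heights_recovered(self):
        rng = np.random.default_rng(0)
        rows = 30 + rng.integers(-3, 4, 40)
        vol = self._plane_volume(list(rows))
        prof = surface_profile(vol)
        inner = rows[prof.columns]
        assert np.array_equal(prof.f_px, inner - (inner.min() - 10))

    def test_missing_surface_lists_columns(self):
        vol = self._plane_volume([30] * 40)
        vol.data[:, :, 20] = 0  # kill one baseline column
        with pytest.raises(SurfaceNotFoundError, match="20"):
            surface_profile(vol)


class TestStability:
    def test_zero_df(self):
        prof = SurfaceProfile(np.arange(5), np.full(5, 7.0), np.zeros(4), 0.1, 0)
        res = stability(prof)
        assert res.rms_mm == res.min_df_mm == res.max_df_mm == 0.0

    def test_alternating_unit_df(self):
        df = np.array([1.0, -1.0, 1.0, -1.0])
        prof = SurfaceProfile(np.arange(5), np.zeros(5), df, 0.1, 0)
        res = stability(prof)
        assert res.rms_mm == pytest.approx(0.1)
        assert res.min_df_mm == pytest.approx(-0.1)
        assert res.max_df_mm == pytest.approx(0.1)

    def test_linear_ramp_closed_form(self):
        for slope in (0.5, 2.0, -1.5):
            f = np.arange(30) * slope
            prof = SurfaceProfile(np.arange(30), f, np.diff(f), 0.12, 0)
            res = stability(prof)
            assert res.rms_mm == pytest.approx(abs(slope) * 0.12)
            assert res.min_df_mm == pytest.approx(slope * 0.12)
            assert res.max_df_mm == pytest.approx(slope * 0.12)

    def test_gaussian_jitter_recovered(self):
        """i.i.d. Gaussian per-slice increments: RMS recovers the
        injected std within 15% at n >= 150 (Monte-Carlo)."""
        sigma_px = 1.3
        spacing = 0.12
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            f = 40.0 + np.cumsum(rng.normal(0.0, sigma_px, 150))
            prof = SurfaceProfile(np.arange(150), f, np.diff(f), spacing, 0)
            vals.append(stability(prof).rms_mm)
        assert np.median(vals) == pytest.approx(sigma_px * spacing, rel=0.15)


class TestRunQA:
    def test_ideal_volume_reports_all_metrics(self, ideal_ma_volume):
        vol, phantom = ideal_ma_volume
        row = run_qa(vol, phantom)
        assert row.absent == {}
        d = row.as_dict()
        for name in ("contrast_resolution", "resolution_axial",
                     "resolution_elevation",
                     "distance_calibration_error_axial",
                     "distance_calibration_error_elevation", "stability_rms"):
            assert np.isfinite(d[name])
        # noise-free defaults: contrast slope is the generator's own
        assert d["contrast_resolution"] == pytest.approx(6.3, rel=0.02)

    def test_missing_targets_recorded_with_reason(self):
        """A sweep that never reaches the elevation filaments reports
        that metric as absent, not silently dropped."""
        from conftest import geometry
        from us3dqa.acquisition import AcquisitionConfig, acquire
        from us3dqa.imaging import BeamProfile, ImageGeometry
        from us3dqa.reconstruct import stack_volume

        phantom = default_phantom(speckle_sigma=0.0)
        cfg = AcquisitionConfig(method="motorized", movement="stepwise",
                                step_size_mm=0.5, sweep_start_mm=18.0,
                                sweep_length_mm=24.0)
        frames, _ = acquire(phantom, cfg, BeamProfile(), ImageGeometry(), seed=0)
        vol = stack_volume(frames, 0.5)
        row = run_qa(vol, phantom)
        assert "distance_calibration_error_elevation" in row.absent
        assert "outside volume" in row.absent["distance_calibration_error_elevation"]
        assert np.isfinite(row.metrics["distance_calibration_error_axial"])

    def test_deterministic(self, ideal_ma_volume):
        vol, phantom = ideal_ma_volume
        assert run_qa(vol, phantom).as_dict() == run_qa(vol, phantom).as_dict()
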