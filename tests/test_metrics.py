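"""Image-quality metrics: oracle agreement, formulas, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phantomqa import SimulationParams, VolumeGrid, simulate_scan
from phantomqa.localize import RoiSpec
from phantomqa.metrics import (
    MetricError,
    RoiStats,
    compute_cnr,
    measure_hu_accuracy,
    measure_resolution,
    measure_scaling,
    measure_uniformity,
    roi_stats,
)
from phantomqa.phantom import nominal_roi_layout

from conftest import coarse_params


def _flat_volume(value: float, shape=(3, 40, 40), spacing=(3.0, 1.0, 1.0)) -> VolumeGrid:
    vol = VolumeGrid(np.full(shape, value, dtype=np.float32), spacing)
    # center the in-plane axes on 0 for convenient ROI placement
    ny, nx = shape[1:]
    vol.origin = (0.0, -(ny - 1) / 2 * spacing[1], -(nx - 1) / 2 * spacing[2])
    return vol


class TestRoiStats:
    def test_constant_region(self):
        vol = _flat_volume(100.0)
        st_ = roi_stats(vol, RoiSpec("r", (0, 0), 16.0, 3.0))
        assert st_.mean == 100.0
        assert st_.sd == 0.0

    def test_gaussian_noise_sd_estimate(self):
        rng = np.random.default_rng(1)
        vol = _flat_volume(0.0, shape=(5, 120, 120))
        vol.values += rng.normal(0, 10.0, vol.shape).astype(np.float32)
        st_ = roi_stats(vol, RoiSpec("r", (0, 0), 100.0, 6.0, z_thickness=15.0))
        assert st_.n > 10_000
        assert st_.sd == pytest.approx(10.0, abs=0.5)

    def test_agreement_with_per_voxel_oracle(self):
        """Brute-force loop over a small crop gives identical mean/sd/n."""
        rng = np.random.default_rng(2)
        vol = _flat_volume(0.0, shape=(1, 20, 20))
        vol.values += rng.normal(0, 5.0, vol.shape).astype(np.float32)
        roi = RoiSpec("r", (1.0, -2.0), 11.0, 0.0, z_thickness=3.0)
        picked = []
        for j in range(20):
            for i in range(20):
                x = vol.x_coords()[i]
                y = vol.y_coords()[j]
                if (x - 1.0) ** 2 + (y + 2.0) ** 2 <= 5.5**2:
                    picked.append(vol.values[0, j, i])
        st_ = roi_stats(vol, roi)
        assert st_.n == len(picked)
        assert st_.mean == pytest.approx(np.mean(picked), abs=1e-6)
        assert st_.sd == pytest.approx(np.std(picked, ddof=1), abs=1e-6)

    def test_empty_roi_errors(self):
        vol = _flat_volume(0.0)
        with pytest.raises(MetricError, match="no voxel centers"):
            roi_stats(vol, RoiSpec("r", (500.0, 0.0), 1e-3, 0.0))


class TestCnr:
    def test_direct_formula(self):
        r = compute_cnr(RoiStats(120.0, 4.0, 100), RoiStats(100.0, 10.0, 100))
        assert r.cnr == 2.0

    def test_equal_means_give_zero(self):
        assert compute_cnr(RoiStats(5.0, 1.0, 10), RoiStats(5.0, 2.0, 10)).cnr == 0.0

    def test_zero_noise_undefined(self):
        with pytest.raises(MetricError, match="zero standard deviation"):
            compute_cnr(RoiStats(1.0, 0.0, 10), RoiStats(0.0, 0.0, 10))

    @settings(max_examples=50, deadline=None)
    @given(
        offset=st.floats(-500, 500),
        gain=st.floats(0.1, 10),
        mean_a=st.floats(-100, 100),
        mean_b=st.floats(-100, 100),
        sd_b=st.floats(0.5, 50),
    )
    def test_offset_invariance_and_contrast_linearity(self, offset, gain, mean_a, mean_b, sd_b):
        """Adding a constant leaves CNR unchanged; scaling the contrast
        (noise fixed) scales CNR by the same factor."""
        base = compute_cnr(RoiStats(mean_a, 1.0, 10), RoiStats(mean_b, sd_b, 10)).cnr
        shifted = compute_cnr(
            RoiStats(mean_a + offset, 1.0, 10), RoiStats(mean_b + offset, sd_b, 10)
        ).cnr
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        scaled = compute_cnr(
            RoiStats(mean_b + gain * (mean_a - mean_b), 1.0, 10), RoiStats(mean_b, sd_b, 10)
        ).cnr
        assert scaled == pytest.approx(gain * base, rel=1e-6, abs=1e-6)

    def test_simulated_cnr_monte_carlo(self, spec):
        """6 HU rod contrast over 3 HU noise gives CNR 2.0 on average."""
        vals = []
        for seed in range(50):
            vol = simulate_scan(spec, coarse_params(noise_sd=3.0, seed=seed), z_range=(40, 80))
            rois = {r.label: r for r in nominal_roi_layout(spec, 1)}
            vals.append(
                compute_cnr(roi_stats(vol, rois["A"]), roi_stats(vol, rois["B"])).cnr
            )
        assert np.mean(vals) == pytest.approx(2.0, abs=0.3)


class TestUniformity:
    def test_noiseless_uniform_slab_is_exactly_zero(self, spec, coarse_noiseless_scan):
        u = measure_uniformity(coarse_noiseless_scan, nominal_roi_layout(spec, 3))
        assert u.max_abs_diff == 0.0

    def test_hand_computed_diffs(self):
        vol = _flat_volume(0.0, shape=(3, 120, 120))
        # paint four peripheral patches with known offsets
        offsets = {"12": 1.0, "3": 2.0, "6": -3.0, "9": 4.0}
        centers = {"12": (0, 40), "3": (40, 0), "6": (0, -40), "9": (-40, 0)}
        for label, (cx, cy) in centers.items():
            xs, ys = vol.x_coords(), vol.y_coords()
            mask = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= 11.28**2
            vol.values[:, mask] += offsets[label]
        rois = [RoiSpec("center", (0, 0), 22.0, 3.0)] + [
            RoiSpec(lab, centers[lab], 22.0, 3.0) for lab in offsets
        ]
        u = measure_uniformity(vol, rois)
        assert u.max_abs_diff == pytest.approx(4.0, abs=1e-5)
        assert sorted(u.diffs) == pytest.approx([-3.0, 1.0, 2.0, 4.0], abs=1e-5)

    def test_cupping_six_hu_classifies_minor(self, spec):
        from phantomqa.criteria import Level, classify_uniformity

        vol = simulate_scan(spec, coarse_params(cupping_amplitude=6.0), z_range=(120, 160))
        u = measure_uniformity(vol, nominal_roi_layout(spec, 3))
        assert u.max_abs_diff == pytest.approx(6.0, abs=1.0)
        assert classify_uniformity(u.max_abs_diff).level is Level.MINOR

    def test_wrong_roi_count_rejected(self, coarse_noiseless_scan, spec):
        with pytest.raises(MetricError, match="exactly 5"):
            measure_uniformity(coarse_noiseless_scan, nominal_roi_layout(spec, 3)[:4])


class TestScaling:
    def test_unit_scale_error_near_zero(self, coarse_noiseless_scan):
        sc = measure_scaling(coarse_noiseless_scan)
        assert sc.percent_error < 0.2

    def test_simulated_magnification(self, spec):
        vol = simulate_scan(spec, coarse_params(scale_factor=1.005), z_range=(120, 160))
        sc = measure_scaling(vol)
        assert sc.percent_error == pytest.approx(0.5, abs=0.5)  # half-voxel equivalent


@pytest.fixture(scope="module")
def fine(spec):
    cache = {}

    def make(blur):
        if blur not in cache:
            p = SimulationParams(in_plane_spacing=0.3, blur_fwhm=blur)
            cache[blur] = simulate_scan(spec, p, z_range=(80, 120))
        return cache[blur]

    return make


class TestResolution:
    def _measure(self, spec, vol):
        mod = spec.module(2)
        return measure_resolution(vol, mod.bar_patterns, contrast_hu=910.0, z=mod.z_center)

    def test_ideal_system_resolves_all_patterns(self, spec, fine):
        r = self._measure(spec, fine(0.0))
        assert r.resolvable_lp == 12.0
        assert all(0.0 <= m <= 1.0 for m in r.modulations)

    def test_heavy_blur_drops_below_five(self, spec, fine):
        r = self._measure(spec, fine(2.0))
        assert r.resolvable_lp <= 5.0

    def test_resolvable_lp_non_increasing_in_blur(self, spec, fine):
        values = [self._measure(spec, fine(b)).resolvable_lp for b in (0.0, 0.8, 1.6, 2.4)]
        assert values == sorted(values, reverse=True)

    def test_modulation_tracks_gaussian_mtf(self, spec, fine):
        """Measured modulation falls with frequency like the analytic MTF of
        the applied Gaussian blur (loose agreement; the strip estimator sees
        the square-wave fundamental through the sampling chain)."""
        blur = 1.0
        r = self._measure(spec, fine(blur))
        sigma = blur / 2.3548
        f = np.array(r.frequencies) / 10.0  # lp/mm
        mtf = np.exp(-2 * np.pi**2 * sigma**2 * f**2)
        measured = np.array(r.modulations)
        # normalize both at the coarsest pattern and compare decay
        ratio = measured / measured[0]
        expected = mtf / mtf[0]
        assert np.all(np.abs(ratio[:4] - expected[:4]) < 0.25)


class TestHuAccuracy:
    def test_noiseless_render_matches_nominal(self, spec, coarse_noiseless_scan):
        res = measure_hu_accuracy(coarse_noiseless_scan, nominal_roi_layout(spec, 0))
        for mat, mean in res.means.items():
            assert mean == pytest.approx(spec.material_table()[mat], abs=0.5)

    def test_missing_material_rejected(self, spec, coarse_noiseless_scan):
        rois = [r for r in nominal_roi_layout(spec, 0) if r.label != "bone"]
        with pytest.raises(MetricError, match="bone"):
            measure_hu_accuracy(coarse_noiseless_scan, rois)
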