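"""Simulator: rendering accuracy, degradation semantics, determinism."""

import numpy as np
import pytest

from phantomqa import (
    SimulationParams,
    default_head_phantom,
    degrade,
    render_volume,
    simulate_scan,
    with_body_ring,
)
from phantomqa.metrics import roi_stats
from phantomqa.phantom import nominal_roi_layout

from conftest import COARSE, coarse_params


def _roi(spec, module, label):
    return {r.label: r for r in nominal_roi_layout(spec, module)}[label]


class TestRender:
    def test_uniformity_center_is_water(self, coarse_noiseless_scan, spec):
        st = roi_stats(coarse_noiseless_scan, _roi(spec, 3, "center"))
        assert st.mean == pytest.approx(0.0, abs=0.5)
        assert st.sd == 0.0

    @pytest.mark.parametrize("material", ["acrylic", "air", "bone", "polyethylene", "water"])
    def test_insert_means_match_nominal(self, coarse_noiseless_scan, spec, material):
        nominal = spec.material_table()[material]
        st = roi_stats(coarse_noiseless_scan, _roi(spec, 0, material))
        assert st.mean == pytest.approx(nominal, abs=0.5)

    def test_area_weighted_edge_voxels_against_oracle(self, spec):
        """Voxels straddling an insert boundary carry area-weighted HU.

        Oracle: analytic disc-coverage fraction of each voxel computed by a
        much finer independent sub-grid (32x) over a small crop around the
        acrylic insert boundary.
        """
        params = coarse_params(supersample=8)
        vol = render_volume(spec, params, z_range=(18, 22))
        ins = next(i for i in spec.module(0).inserts if i.material.name == "acrylic")
        cx, cy = ins.center
        r = ins.diameter / 2
        xs, ys = vol.x_coords(), vol.y_coords()
        jx = np.nonzero(np.abs(xs - cx) <= r + 2)[0]
        jy = np.nonzero(np.abs(ys - cy) <= r + 2)[0]
        fine = 32
        for j in jy[::4]:
            for i in jx[::4]:
                subx = xs[i] + (np.arange(fine) + 0.5) / fine * COARSE - COARSE / 2
                suby = ys[j] + (np.arange(fine) + 0.5) / fine * COARSE - COARSE / 2
                cover = (
                    ((subx[None, :] - cx) ** 2 + (suby[:, None] - cy) ** 2) <= r**2
                ).mean()
                expected = cover * ins.material.nominal_hu
                assert vol.values[0, j, i] == pytest.approx(expected, abs=4.0)

    def test_body_ring_fills_radius_160(self, spec):
        ringed = with_body_ring(spec)
        vol = render_volume(ringed, coarse_params(), z_range=(118, 122))
        j = vol.slice_index_near(120.0)
        ix = int(round((160.0 - vol.origin[2]) / vol.spacing[2]))
        iy = int(round((0.0 - vol.origin[1]) / vol.spacing[1]))
        assert vol.values[j, iy, ix] > -300.0

    def test_nyquist_warning_recorded(self, spec):
        vol = render_volume(spec, SimulationParams(in_plane_spacing=0.6), z_range=(98, 102))
        assert any("Nyquist" in w for w in vol.meta["warnings"])

    def test_fine_default_spacing_has_no_warning(self, spec):
        vol = render_volume(spec, SimulationParams(), z_range=(98, 102))
        assert "warnings" not in vol.meta


class TestDegrade:
    def test_all_zero_params_identity(self, coarse_noiseless_scan):
        out = degrade(coarse_noiseless_scan, coarse_params())
        np.testing.assert_array_equal(out.values, coarse_noiseless_scan.values)

    def test_cupping_center_to_edge_amplitude(self, spec):
        amp = 8.0
        vol = simulate_scan(spec, coarse_params(cupping_amplitude=amp), z_range=(120, 160))
        rois = nominal_roi_layout(spec, 3)
        center = roi_stats(vol, _roi(spec, 3, "center")).mean
        edge = roi_stats(vol, _roi(spec, 3, "12")).mean
        assert center - edge == pytest.approx(amp, abs=0.5)

    def test_noise_sd_recovered_in_large_roi(self, spec):
        from phantomqa.localize import RoiSpec

        vol = simulate_scan(spec, coarse_params(noise_sd=10.0, seed=3), z_range=(120, 160))
        big = RoiSpec("big", (0.0, 0.0), 80.0, 140.0, 9.0)
        st = roi_stats(vol, big)
        assert st.n > 10_000
        assert st.sd == pytest.approx(10.0, rel=0.05)

    def test_material_bias_recovered(self, spec):
        bias = {"water": 7.0, "polyethylene": -12.0}
        vol = simulate_scan(
            spec, coarse_params(material_bias=bias, noise_sd=2.0, seed=5), z_range=(0, 40)
        )
        for mat, b in bias.items():
            st = roi_stats(vol, _roi(spec, 0, mat))
            nominal = spec.material_table()[mat]
            assert st.mean - nominal == pytest.approx(b, abs=3 * 2.0 / np.sqrt(st.n) + 0.2)

    def test_determinism_same_seed(self, spec):
        p = coarse_params(noise_sd=12.0, seed=42, cupping_amplitude=3.0)
        a = simulate_scan(spec, p, z_range=(120, 160))
        b = simulate_scan(spec, p, z_range=(120, 160))
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seeds_differ(self, spec):
        a = simulate_scan(spec, coarse_params(noise_sd=12.0, seed=1), z_range=(120, 160))
        b = simulate_scan(spec, coarse_params(noise_sd=12.0, seed=2), z_range=(120, 160))
        assert not np.array_equal(a.values, b.values)

    def test_scaling_magnifies_bearing_separation(self, spec):
        from phantomqa.metrics import measure_scaling

        vol = simulate_scan(spec, coarse_params(scale_factor=1.01), z_range=(120, 160))
        sc = measure_scaling(vol)
        assert sc.measured_mm == pytest.approx(101.0, abs=COARSE / 2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(noise_sd=-1.0)
        with pytest.raises(ValueError):
            SimulationParams(scale_factor=0.0)
        with pytest.raises(ValueError):
            SimulationParams(in_plane_spacing=-0.4)
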