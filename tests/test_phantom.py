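"""Forward-model correctness: thickness field, refraction ray trace,
determinism, cohort plumbing."""

import math

import numpy as np
import pytest

from epioct import (NoiseModel, PhantomSpec, ScanGeometry, SessionSpec,
                    build_thickness_field, plan_cohort, render_bscan,
                    simulate_cohort)
from epioct.phantom import CorneaModel

N_TISSUE = 1.389


class TestThicknessField:
    def test_apex_value_and_monotonicity(self):
        T = build_thickness_field(CorneaModel())
        assert T(np.array([0.0]), "horizontal")[0] == 52.0
        for meridian in ("horizontal", "vertical"):
            d = np.linspace(0, 5, 200)
            for sign in (1, -1):
                t = T(sign * d, meridian)
                assert np.all(np.diff(t) >= 0)

    def test_zone_means_match_printed_ranges(self):
        # oracle: dense average of T over each annular zone, pooled over
        # all four directions (temporal, nasal, superior, inferior)
        T = build_thickness_field(CorneaModel())
        for (lo, hi), (want_lo, want_hi) in [((0.0, 1.5), (51, 53)),
                                             ((1.5, 3.0), (52, 57)),
                                             ((3.0, 5.0), (58, 72))]:
            d = np.linspace(lo, hi, 2001)
            vals = [T(s * d, m).mean() for m in ("horizontal", "vertical")
                    for s in (1, -1)]
            zone_mean = np.mean(vals)
            assert want_lo <= zone_mean <= want_hi

    def test_uniform_when_coeffs_zero(self):
        model = CorneaModel(coeff_temporal=0, coeff_nasal=0,
                            coeff_superior=0, coeff_inferior=0)
        T = build_thickness_field(model)
        d = np.linspace(-5, 5, 101)
        assert np.allclose(T(d, "horizontal"), 52.0)
        assert np.allclose(T(d, "vertical"), 52.0)

    def test_inferior_thicker_than_superior_at_2p5(self):
        T = build_thickness_field(CorneaModel())
        assert T(np.array([-2.5]), "vertical")[0] > T(np.array([2.5]), "vertical")[0]

    def test_five_mm_endpoints(self):
        T = build_thickness_field(CorneaModel())
        assert T(np.array([5.0]), "horizontal")[0] == pytest.approx(63.0)
        assert T(np.array([-5.0]), "horizontal")[0] == pytest.approx(63.0)
        assert T(np.array([5.0]), "vertical")[0] == pytest.approx(58.0)
        assert T(np.array([-5.0]), "vertical")[0] == pytest.approx(72.0)


class TestGeometry:
    def test_pitches(self):
        g = ScanGeometry()
        assert g.lateral_pitch_mm == pytest.approx(13.465 / 2048)
        assert g.axial_pitch_mm == pytest.approx(7.281 / 4096)

    def test_scaled_keeps_field_of_view(self):
        g = ScanGeometry().scaled(4)
        assert g.n_ascans == 512 and g.n_samples == 1024
        assert g.lateral_width_mm == 13.465
        assert g.axial_psf_fwhm_um == pytest.approx(4.6 * 4)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            ScanGeometry(lateral_width_mm=-1)
        with pytest.raises(ValueError):
            CorneaModel(group_index=0.9)


class TestRenderBScan:
    def test_flat_layer_back_echo_at_optical_depth(self, flat_spec):
        # normal incidence: optical separation = n * T = 52 * 1.389 µm
        b = render_bscan(flat_spec, SessionSpec(), seed=0)
        t = b.truth
        sep_um = (t.back_optical_z_mm - t.front_z_mm)[t.valid] * 1000
        assert np.allclose(sep_um, 52.0 * N_TISSUE, atol=1e-9)

    def test_determinism_bit_identical(self, noisy_spec):
        a = render_bscan(noisy_spec, SessionSpec(), seed=5)
        b = render_bscan(noisy_spec, SessionSpec(), seed=5)
        assert np.array_equal(a.intensity, b.intensity)

    def test_optical_path_ratio_is_group_index(self, noiseless_bscan):
        t = noiseless_bscan.truth
        ok = t.valid
        ratio = (t.back_optical_z_mm[ok] - t.front_z_mm[ok]) / t.path_length_mm[ok]
        assert np.allclose(ratio, N_TISSUE, atol=1e-9)

    def test_snell_conservation_in_forward_model(self, noiseless_bscan):
        t = noiseless_bscan.truth
        ok = t.valid
        nrm, refr = t.surface_normal[ok], t.refracted_dir[ok]
        incident = np.array([0.0, 1.0])
        sin1 = np.abs(incident[0] * nrm[:, 1] - incident[1] * nrm[:, 0])
        sin2 = np.abs(refr[:, 0] * nrm[:, 1] - refr[:, 1] * nrm[:, 0])
        assert np.allclose(sin1, N_TISSUE * sin2, atol=1e-9)

    def test_index_one_renders_true_geometry(self, reduced_geometry):
        # with n = 1 rays do not bend and optical depth equals physical depth
        spec = PhantomSpec(geometry=reduced_geometry,
                           cornea=CorneaModel(group_index=1.0),
                           noise=NoiseModel().silent())
        b = render_bscan(spec, SessionSpec(), seed=0)
        t = b.truth
        ok = t.valid
        assert np.allclose(t.back_point_mm[ok, 0], t.x_mm[ok], atol=1e-12)
        assert np.allclose(t.back_optical_z_mm[ok], t.back_point_mm[ok, 1], atol=1e-12)

    def test_back_echo_matches_independent_ray_trace_oracle(self, noiseless_spec):
        """Brute-force oracle: closed-form entry/normal/Snell plus an
        ultra-dense back-surface polyline intersection, at x = 3 mm."""
        b = render_bscan(noiseless_spec, SessionSpec(), seed=0)
        geo, cornea = noiseless_spec.geometry, noiseless_spec.cornea
        i = int(np.argmin(np.abs(geo.x_mm - 3.0)))
        x = geo.x_mm[i]
        R = cornea.anterior_radius_mm
        ox, oz = cornea.apex_offset_mm
        cx, cz = ox, oz + R
        zf = cz - math.sqrt(R * R - (x - cx) ** 2)
        # closed-form Snell by rotation angles
        theta_n = math.atan2(x - cx, cz - zf)  # surface tilt at entry
        theta1 = abs(theta_n)
        theta2 = math.asin(math.sin(theta1) / N_TISSUE)
        bend = math.copysign(theta1 - theta2, theta_n)
        refr = np.array([math.sin(-bend), math.cos(bend)])
        # ultra-dense independent back surface around the entry point
        T = build_thickness_field(cornea)
        u = np.linspace(x - 0.4, x + 0.4, 200001)
        fz = cz - np.sqrt(R * R - (u - cx) ** 2)
        nrm = np.stack([cx - u, cz - fz], axis=1)
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        t_mm = T(u - cx, "horizontal") / 1000.0
        bx = u + t_mm * nrm[:, 0]
        bz = fz + t_mm * nrm[:, 1]
        def vertical_miss(s):
            px = x + s * refr[0]
            pz = zf + s * refr[1]
            return np.abs(pz - np.interp(px, bx, bz))

        s_grid = np.linspace(0.01, 0.2, 100000)
        s0 = s_grid[np.argmin(vertical_miss(s_grid))]
        s_fine = np.linspace(s0 - 5e-6, s0 + 5e-6, 20001)
        s_oracle = s_fine[np.argmin(vertical_miss(s_fine))]
        z_oracle = zf + N_TISSUE * s_oracle
        assert b.truth.back_optical_z_mm[i] == pytest.approx(z_oracle, abs=1e-6)

    def test_occluded_ascans_are_background_only(self, noiseless_spec):
        b = render_bscan(noiseless_spec, SessionSpec(meridian="vertical"), seed=0)
        occ = b.geometry.x_mm > 4.5
        assert occ.any()
        assert np.all(b.intensity[occ] == 0)
        assert not b.truth.valid[occ].any()

    def test_intensity_nonnegative_finite(self, noisy_bscan):
        assert np.all(np.isfinite(noisy_bscan.intensity))
        assert np.all(noisy_bscan.intensity >= 0)


class TestCohort:
    def test_scan_count_21_subjects(self):
        plan = plan_cohort(n_subjects=21, seed=0)
        assert len(plan) == 21 * 2 * 2 * 2
        assert set(plan["test"]) == {1, 2}
        assert set(plan["eye"]) == {"OD", "OS"}

    def test_shared_t0_within_subject(self):
        plan = plan_cohort(n_subjects=5, seed=1)
        assert (plan.groupby("subject")["t0_um"].nunique() == 1).all()

    def test_t0_population_sd(self):
        plan = plan_cohort(n_subjects=21, seed=3)
        t0 = plan.groupby("subject")["t0_um"].first()
        assert abs(t0.std(ddof=1) - 3.2) < 1.5

    def test_zero_jitter_zero_noise_tests_identical(self):
        small = ScanGeometry().scaled(8)
        spec = PhantomSpec(geometry=small, noise=NoiseModel().silent())
        plan, scans = simulate_cohort(n_subjects=2, spec=spec, seed=0,
                                      jitter=(0.0, 0.0),
                                      meridians=("horizontal",), eyes=("OD",))
        imgs = {(r["subject"], r["test"]): b.intensity for r, b in scans}
        for s in (1, 2):
            assert np.array_equal(imgs[(s, 1)], imgs[(s, 2)])

    def test_invalid_population_rejected(self):
        with pytest.raises(ValueError):
            plan_cohort(n_subjects=1)
        with pytest.raises(ValueError):
            plan_cohort(n_subjects=5, t0_sd_um=-1.0)
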