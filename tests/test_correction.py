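"""Phase unwrap and background-offset correction."""

import numpy as np
import pytest

from flowcomp4d.correction import (
    apply_correction,
    compute_static_weights,
    fit_background,
    polynomial_exponents,
    unwrap_phase,
)
from flowcomp4d.io import MagnitudeField4D, ValidationError, VelocityField4D
from flowcomp4d.phantom import make_polynomial_offset_field


def field_from(vel, venc=100.0, spacing=(3.0, 3.0, 3.0)):
    return VelocityField4D(vel, spacing, 1000.0, venc)


class TestUnwrap:
    def test_wrap_free_field_unchanged(self):
        # wrap-free: all values within VENC and no consecutive-frame jump
        # exceeding VENC
        rng = np.random.default_rng(0)
        vel = rng.uniform(-49, 49, size=(6, 4, 4, 4, 3))
        f = field_from(vel)
        np.testing.assert_array_equal(unwrap_phase(f).velocity, vel)

    def test_single_wrapped_sample_restored(self):
        # true velocity +110 cm/s aliases at VENC 100 to 110 - 2*100 = -90;
        # temporal neighbors at +95 reveal the wrap
        vel = np.zeros((3, 2, 2, 2, 3))
        vel[:, 0, 0, 0, 0] = [95.0, -90.0, 95.0]
        out = unwrap_phase(field_from(vel))
        np.testing.assert_allclose(out.velocity[:, 0, 0, 0, 0], [95.0, 110.0, 95.0])

    def test_constant_wrap_everywhere_undetectable(self):
        # -150 at all frames has no temporal jump: unchanged by contract
        vel = np.full((4, 2, 2, 2, 3), -150.0)
        out = unwrap_phase(field_from(vel))
        np.testing.assert_array_equal(out.velocity, vel)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        true = rng.uniform(-150, 150, size=(8, 3, 3, 3, 3))
        wrapped = (true + 100.0) % 200.0 - 100.0
        once = unwrap_phase(field_from(wrapped))
        twice = unwrap_phase(once)
        np.testing.assert_array_equal(once.velocity, twice.velocity)


class TestStaticWeights:
    def make_pair(self, vel, mag):
        f = field_from(vel)
        m = MagnitudeField4D(mag, f.spacing_mm, f.cycle_ms, f.origin_mm)
        return f, m

    def test_static_bright_voxel_gets_weight_one(self):
        vel = np.zeros((4, 3, 3, 3, 3))
        mag = np.ones((4, 3, 3, 3))
        f, m = self.make_pair(vel, mag)
        w = compute_static_weights(f, m)
        assert w.weights[1, 1, 1] == pytest.approx(1.0)

    def test_half_weight_at_characteristic_speed_spread(self):
        # speed alternates 0 / 2s so its temporal std is exactly s;
        # s = sigma0*sqrt(2 ln 2) makes the Gaussian factor exactly 1/2
        sigma0 = 2.0
        s = sigma0 * np.sqrt(2 * np.log(2))
        vel = np.zeros((4, 3, 3, 3, 3))
        vel[:, 1, 1, 1, 0] = [0.0, 2 * s, 0.0, 2 * s]
        mag = np.ones((4, 3, 3, 3))
        f, m = self.make_pair(vel, mag)
        w = compute_static_weights(f, m, sigma0_cm_s=sigma0)
        assert w.weights[1, 1, 1] == pytest.approx(0.5, rel=1e-12)

    def test_zero_magnitude_voxel_gets_zero_weight(self):
        vel = np.zeros((4, 3, 3, 3, 3))
        vel[:, 0, 0, 0, 0] = 50.0  # moving, but irrelevant: magnitude 0
        mag = np.ones((4, 3, 3, 3))
        mag[:, 0, 0, 0] = 0.0
        f, m = self.make_pair(vel, mag)
        assert compute_static_weights(f, m).weights[0, 0, 0] == 0.0

    def test_all_zero_magnitude_rejected(self):
        f, m = self.make_pair(np.zeros((4, 3, 3, 3, 3)), np.zeros((4, 3, 3, 3)))
        with pytest.raises(ValidationError):
            compute_static_weights(f, m)


def uniform_weights(field):
    from flowcomp4d.correction import StaticTissueWeights

    return StaticTissueWeights(np.ones(field.dims))


class TestBackgroundFit:
    def test_degree4_inject_and_recover(self):
        rng = np.random.default_rng(42)
        coeffs = rng.normal(0, 2, size=(3, 35))
        field = make_polynomial_offset_field(coeffs, 4, dims=(10, 11, 9), n_frames=2)
        model = fit_background(field, uniform_weights(field), degree=4)
        for k in range(2):
            np.testing.assert_allclose(model.coeffs[k], coeffs, rtol=1e-8, atol=1e-10)

    def test_constant_offset_recovered_as_constant_term(self):
        field = make_polynomial_offset_field(
            np.c_[[5.0, 0.0, 0.0], np.zeros((3, 34))], 4, dims=(8, 8, 8)
        )
        model = fit_background(field, uniform_weights(field), degree=0)
        np.testing.assert_allclose(model.coeffs[0, 0], [5.0], atol=1e-10)
        np.testing.assert_allclose(model.coeffs[0, 1:], 0.0, atol=1e-10)

    def test_recovery_from_thin_static_shell(self):
        # offset recoverable from a static shell even when interior voxels
        # carry unrelated "blood" velocities at zero weight
        rng = np.random.default_rng(7)
        coeffs = rng.normal(0, 1, size=(3, 35))
        field = make_polynomial_offset_field(coeffs, 4, dims=(12, 12, 12), n_frames=2)
        vel = field.velocity.copy()
        interior = np.zeros(field.dims, dtype=bool)
        interior[3:-3, 3:-3, 3:-3] = True
        vel[:, interior] += rng.normal(0, 40, size=(2, int(interior.sum()), 3))
        noisy = field.with_velocity(vel)
        from flowcomp4d.correction import StaticTissueWeights

        w = StaticTissueWeights((~interior).astype(float))
        model = fit_background(noisy, w, degree=4)
        np.testing.assert_allclose(model.coeffs[0], coeffs, rtol=1e-6, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        field = make_polynomial_offset_field(np.zeros((3, 35)), 4, dims=(8, 8, 8))
        from flowcomp4d.correction import StaticTissueWeights

        w = np.zeros(field.dims)
        w[:, :, 4] = 1.0  # all weighted voxels coplanar
        with pytest.raises(ValidationError, match="[Rr]ank"):
            fit_background(field, StaticTissueWeights(w), degree=4)

    def test_too_few_weighted_voxels_rejected(self):
        field = make_polynomial_offset_field(np.zeros((3, 35)), 4, dims=(8, 8, 8))
        from flowcomp4d.correction import StaticTissueWeights

        w = np.zeros(field.dims)
        w[0, 0, :5] = 1.0
        with pytest.raises(ValidationError, match="35"):
            fit_background(field, StaticTissueWeights(w), degree=4)


class TestApplyCorrection:
    def test_pure_polynomial_field_zeroed(self):
        rng = np.random.default_rng(5)
        coeffs = rng.normal(0, 3, size=(3, 35))
        field = make_polynomial_offset_field(coeffs, 4, dims=(9, 9, 9))
        model = fit_background(field, uniform_weights(field), degree=4)
        residual = apply_correction(field, model)
        np.testing.assert_allclose(residual.velocity, 0.0, atol=1e-8)

    def test_refit_after_correction_is_null_model(self):
        rng = np.random.default_rng(6)
        vel = rng.normal(0, 20, size=(2, 9, 9, 9, 3))
        field = field_from(vel)
        model = fit_background(field, uniform_weights(field), degree=3)
        corrected = apply_correction(field, model)
        remodel = fit_background(corrected, uniform_weights(field), degree=3)
        np.testing.assert_allclose(remodel.coeffs, 0.0, atol=1e-8)

    def test_zero_model_is_identity(self):
        field = field_from(np.random.default_rng(8).normal(size=(2, 6, 6, 6, 3)))
        from flowcomp4d.correction import BackgroundModel

        model = BackgroundModel(
            degree=4,
            coeffs=np.zeros((2, 3, 35)),
            center_mm=(field.bbox_min_mm + field.bbox_max_mm) / 2,
            halfwidth_mm=(field.bbox_max_mm - field.bbox_min_mm) / 2,
        )
        out = apply_correction(field, model)
        np.testing.assert_array_equal(out.velocity, field.velocity)


def test_term_count_is_35_for_degree_4():
    assert len(polynomial_exponents(4)) == 35
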