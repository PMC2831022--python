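"""Velocity sampling and Runge-Kutta pathline integration."""

import numpy as np
import pytest

from flowcomp4d.geometry import rasterize_mask
from flowcomp4d.io import ValidationError, VelocityField4D
from flowcomp4d.phantom import make_rotation_field, make_uniform_field
from flowcomp4d.tracing import (
    TraceSettings,
    full_cycle_span,
    sample_velocity,
    seed_from_mask,
    trace,
    trace_batch,
    trace_full_cycle,
)


class TestSampler:
    def test_exact_at_voxel_center_and_frame_time(self):
        rng = np.random.default_rng(0)
        vel = rng.normal(0, 30, size=(4, 5, 5, 5, 3))
        f = VelocityField4D(vel, (3, 3, 3), 1000.0, 100.0, (0, 0, 0))
        v = sample_velocity(f, np.array([6.0, 9.0, 3.0]), 250.0)  # voxel (2,3,1), frame 1
        np.testing.assert_allclose(v, vel[1, 2, 3, 1] * 0.01, rtol=1e-12)

    def test_spatial_midpoint_linearity(self):
        vel = np.zeros((2, 2, 2, 2, 3))
        vel[:, 0, :, :, 0] = 2.0
        vel[:, 1, :, :, 0] = 4.0
        f = VelocityField4D(vel, (3, 3, 3), 1000.0, 100.0, (0, 0, 0))
        v = sample_velocity(f, np.array([1.5, 0.0, 0.0]), 0.0)
        assert v[0] == pytest.approx(3.0 * 0.01)

    def test_periodic_time_wrap_midpoint(self):
        # t = cycle - dt/2 interpolates between the last and first frames
        vel = np.zeros((4, 2, 2, 2, 3))
        vel[0, ..., 1] = 10.0
        vel[3, ..., 1] = 30.0
        f = VelocityField4D(vel, (3, 3, 3), 1000.0, 100.0, (0, 0, 0))
        v = sample_velocity(f, np.array([0.0, 0.0, 0.0]), 1000.0 - 125.0)
        assert v[1] == pytest.approx(20.0 * 0.01)

    def test_outside_domain_is_zero_with_flag(self):
        f = make_uniform_field((10.0, 0, 0))
        v, out = sample_velocity(f, np.array([-50.0, 0.0, 0.0]), 0.0, return_domain_flag=True)
        assert out
        np.testing.assert_array_equal(v, 0.0)


class TestTrace:
    def test_uniform_field_exact_displacement(self):
        f = make_uniform_field((1.0, 0, 0), dims=(12, 4, 4))  # 1 cm/s = 0.01 mm/ms
        br = trace(f, np.array([3.0, 4.5, 4.5]), 0.0, 1000.0)
        np.testing.assert_allclose(
            br.positions_mm[-1] - br.positions_mm[0], [10.0, 0, 0], atol=1e-9
        )

    def test_backward_trace_sign_symmetry(self):
        f = make_uniform_field((1.0, 0, 0), dims=(12, 4, 4))
        br = trace(f, np.array([9.0, 4.5, 4.5]), 500.0, 0.0)
        np.testing.assert_allclose(
            br.positions_mm[-1] - br.positions_mm[0], [-5.0, 0, 0], atol=1e-9
        )
        assert br.times_ms[0] == 500.0 and br.times_ms[-1] == 0.0

    def test_rotation_closure_and_radius_preserved(self):
        omega = 2 * np.pi / 1000.0
        f = make_rotation_field(omega, (30.0, 30.0, 6.0), n_frames=40)
        seed = np.array([30.0 + 15.0, 30.0, 6.0])
        br = trace(f, seed, 0.0, 1000.0)
        assert np.linalg.norm(br.positions_mm[-1] - seed) < 1e-3 * 15.0
        radii = np.linalg.norm(br.positions_mm[:, :2] - [30.0, 30.0], axis=1)
        np.testing.assert_allclose(radii, 15.0, rtol=1e-4)

    def test_fourth_order_convergence_on_rotation(self):
        omega = 2 * np.pi / 1000.0
        f = make_rotation_field(omega, (30.0, 30.0, 6.0), n_frames=40)
        seed = np.array([30.0 + 18.0, 30.0, 6.0])
        errs = []
        for h in (25.0, 12.5, 6.25):
            br = trace(f, seed, 0.0, 1000.0, TraceSettings(fixed_step_ms=h))
            errs.append(np.linalg.norm(br.positions_mm[-1] - seed))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert (orders >= 3.7).all()

    def test_time_reversal_returns_to_seed(self):
        omega = 2 * np.pi / 1000.0
        f = make_rotation_field(omega, (30.0, 30.0, 6.0), n_frames=40)
        seed = np.array([30.0 + 12.0, 30.0, 6.0])
        settings = TraceSettings()
        fwd = trace(f, seed, 0.0, 500.0, settings)
        back = trace(f, fwd.positions_mm[-1], 500.0, 0.0, settings)
        n_steps = len(fwd.times_ms) + len(back.times_ms)
        assert np.linalg.norm(back.positions_mm[-1] - seed) <= 2 * settings.rel_tol_mm * n_steps

    def test_trace_leaves_domain_is_truncated_frozen(self):
        f = make_uniform_field((50.0, 0, 0), dims=(6, 4, 4))  # 0.5 mm/ms
        br = trace(f, np.array([12.0, 4.5, 4.5]), 0.0, 1000.0)
        assert br.truncated
        assert br.positions_mm[-1, 0] > f.bbox_max_mm[0]

    def test_determinism_bit_identical(self):
        omega = 2 * np.pi / 1000.0
        f = make_rotation_field(omega, (30.0, 30.0, 6.0), n_frames=40)
        seeds = np.array([[42.0, 30.0, 6.0], [30.0, 18.0, 6.0]])
        a = trace_batch(f, seeds, 0.0, 730.0)
        b = trace_batch(f, seeds, 0.0, 730.0)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.positions_mm, y.positions_mm)
            np.testing.assert_array_equal(x.times_ms, y.times_ms)

    def test_max_steps_guard(self):
        f = make_rotation_field(2 * np.pi / 1000.0, (30.0, 30.0, 6.0), n_frames=40)
        with pytest.raises(RuntimeError, match="max_steps"):
            trace(f, np.array([40.0, 30.0, 6.0]), 0.0, 1000.0, TraceSettings(max_steps=3))


class TestFullCycle:
    def test_span_arithmetic(self):
        assert full_cycle_span(0.0, 300.0, 1000.0) == (-700.0, 300.0)
        assert full_cycle_span(500.0, 300.0, 1000.0) == (300.0, 1300.0)

    def test_static_field_pathlines_are_points(self, small_phantom):
        f = make_uniform_field((0.0, 0, 0), dims=(8, 8, 8))
        fgm = rasterize_mask(small_phantom.mask_ivc, small_phantom.field)
        seeds = seed_from_mask(fgm)
        # use a zero field on the phantom grid
        zero = small_phantom.field.with_velocity(np.zeros_like(small_phantom.field.velocity))
        pathlines = trace_full_cycle(zero, seeds, 0.0, 350.0)
        assert len(pathlines) == len(seeds)
        for p in pathlines[:25]:
            np.testing.assert_array_equal(p.start_position, p.seed_position_mm)
            np.testing.assert_array_equal(p.end_position, p.seed_position_mm)
            assert p.times_ms[0] == -650.0 and p.times_ms[-1] == 350.0

    def test_count_conserved_and_seed_interior(self, small_phantom):
        ph = small_phantom
        fgm = rasterize_mask(ph.mask_ivc, ph.field)
        seeds = seed_from_mask(fgm)
        pathlines = trace_full_cycle(ph.field, seeds, 0.0, 350.0)
        assert len(pathlines) == len(seeds)
        for p in pathlines[::50]:
            i = np.searchsorted(p.times_ms, 0.0)
            assert p.times_ms[i] == 0.0
            np.testing.assert_array_equal(p.positions_mm[i], p.seed_position_mm)

    def test_invalid_times_rejected(self, small_phantom):
        fgm = rasterize_mask(small_phantom.mask_ivc, small_phantom.field)
        seeds = seed_from_mask(fgm)
        with pytest.raises(ValidationError):
            trace_full_cycle(small_phantom.field, seeds, 100.0, 100.0)
        with pytest.raises(ValidationError):
            trace_full_cycle(small_phantom.field, seeds, -5.0, 300.0)


class TestSeeding:
    def test_seed_count_and_edv(self, small_phantom):
        fgm = rasterize_mask(small_phantom.mask_ivc, small_phantom.field)
        seeds = seed_from_mask(fgm)
        assert len(seeds) == fgm.n_inside
        # flow-derived EDV = seed count x voxel volume
        assert seeds.edv_ml == pytest.approx(len(seeds) * 27.0 / 1000.0)

    def test_empty_mask_rejected(self):
        from flowcomp4d.geometry import FlowGridMask

        with pytest.raises(ValidationError):
            FlowGridMask(np.zeros((3, 3, 3), dtype=bool), (3, 3, 3), (0, 0, 0))
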