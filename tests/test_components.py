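"""Flow-component classification, quantification, balance, KE and QC."""

import numpy as np
import pytest

from flowcomp4d.components import (
    ComponentLabel,
    classify,
    classify_all,
    first_basal_crossing,
    flow_balance,
    kinetic_energy,
    qc_leak_fraction,
    quantify,
    suggest_isovolumetric_times,
)
from flowcomp4d.geometry import BasalPlane, FlowGridMask, basal_plane_from_mask, rasterize_mask
from flowcomp4d.io import Pathline, ValidationError
from flowcomp4d.phantom import make_uniform_field


def make_setup():
    """A 10-voxel-cube LV below a basal plane at z = 31.5 mm."""
    inside = np.zeros((12, 12, 12), dtype=bool)
    inside[1:11, 1:11, 1:11] = True
    fgm = FlowGridMask(inside, (3.0, 3.0, 3.0), (1.5, 1.5, 1.5))
    plane = BasalPlane(point_mm=(0, 0, 31.5), normal_mm=(0, 0, 1.0))
    return fgm, plane


def two_point_pathline(B, F, seed=None, trunc_b=False, trunc_f=False):
    seed = np.array([15.0, 15.0, 15.0]) if seed is None else np.asarray(seed)
    return Pathline(
        seed_id=0,
        seed_position_mm=seed,
        times_ms=np.array([-650.0, 0.0, 350.0]),
        positions_mm=np.vstack([B, seed, F]),
        truncated_backward=trunc_b,
        truncated_forward=trunc_f,
    )


INSIDE = np.array([15.0, 15.0, 15.0])  # voxel center well within the LV
BASAL = np.array([15.0, 15.0, 41.5])  # 10 mm basal of the plane
OUTSIDE = np.array([100.0, 15.0, 15.0])  # apical of plane, outside the LV


class TestClassify:
    @pytest.mark.parametrize(
        "B,F,expected",
        [
            (BASAL, BASAL, ComponentLabel.DIRECT_FLOW),
            (BASAL, INSIDE, ComponentLabel.RETAINED_INFLOW),
            (INSIDE, BASAL, ComponentLabel.DELAYED_EJECTION),
            (INSIDE, INSIDE, ComponentLabel.RESIDUAL_VOLUME),
            (INSIDE, OUTSIDE, ComponentLabel.EXCLUDED),
            (OUTSIDE, BASAL, ComponentLabel.EXCLUDED),
            (OUTSIDE, OUTSIDE, ComponentLabel.EXCLUDED),
        ],
        ids=[
            "enters-and-leaves",
            "enters-and-stays",
            "stays-then-leaves",
            "stays-both-cycles",
            "leaves-apically",
            "emitted-from-myocardium",
            "out-both-ends",
        ],
    )
    def test_endpoint_rule(self, B, F, expected):
        fgm, plane = make_setup()
        assert classify(two_point_pathline(B, F), fgm, plane) == expected

    def test_truncated_pathline_excluded(self):
        fgm, plane = make_setup()
        p = two_point_pathline(BASAL, BASAL, trunc_f=True)
        assert classify(p, fgm, plane) == ComponentLabel.EXCLUDED

    def test_on_plane_endpoint_counts_as_apical(self):
        fgm, plane = make_setup()
        # exactly on the plane = not basal (ties break apically); the point
        # sits inside the most basal inside voxel, so it stayed in the LV
        on_plane = np.array([15.0, 15.0, 31.5])
        label = classify(two_point_pathline(INSIDE, on_plane), fgm, plane)
        assert label == ComponentLabel.RESIDUAL_VOLUME
        # one voxel further out the point is on-plane but outside the LV
        plane_hi = BasalPlane(point_mm=(0, 0, 34.5), normal_mm=(0, 0, 1.0))
        label = classify(
            two_point_pathline(INSIDE, np.array([15.0, 15.0, 34.5])), fgm, plane_hi
        )
        assert label == ComponentLabel.EXCLUDED

    def test_vectorized_matches_scalar(self):
        fgm, plane = make_setup()
        rng = np.random.default_rng(11)
        pls = []
        for _ in range(200):
            B = rng.uniform(-5, 50, 3)
            F = rng.uniform(-5, 50, 3)
            pls.append(two_point_pathline(B, F))
        vec = classify_all(pls, fgm, plane)
        scalar = np.array([int(classify(p, fgm, plane)) for p in pls])
        np.testing.assert_array_equal(vec, scalar)

    def test_enlarging_ivr_mask_only_rescues_excluded(self):
        """Monotonicity: a larger IVR volume can only move pathlines from
        EXCLUDED to a non-excluded label, never the reverse."""
        fgm, plane = make_setup()
        bigger = FlowGridMask(
            np.ones((12, 12, 12), dtype=bool), (3.0, 3.0, 3.0), (1.5, 1.5, 1.5)
        )
        rng = np.random.default_rng(12)
        pls = [
            two_point_pathline(rng.uniform(-5, 50, 3), rng.uniform(-5, 50, 3))
            for _ in range(300)
        ]
        small = classify_all(pls, fgm, plane)
        large = classify_all(pls, bigger, plane)
        changed = small != large
        assert (small[changed] == int(ComponentLabel.EXCLUDED)).all()

    def test_first_basal_crossing_time(self):
        _, plane = make_setup()
        p = Pathline(
            0,
            np.array([0.0, 0.0, 30.0]),
            np.array([0.0, 100.0, 200.0]),
            np.array([[0, 0, 30.0], [0, 0, 30.5], [0, 0, 33.5]]),
        )
        # crossing z=31.5 between t=100 (z=30.5) and t=200 (z=33.5)
        assert first_basal_crossing(p, plane) == pytest.approx(100 + 100 / 3)
        below = Pathline(
            0,
            np.array([0.0, 0.0, 10.0]),
            np.array([0.0, 100.0]),
            np.array([[0, 0, 10.0], [0, 0, 12.0]]),
        )
        assert first_basal_crossing(below, plane) is None


class TestQuantify:
    def test_volume_arithmetic(self):
        labels = np.repeat([0, 1, 2, 3], [300, 180, 170, 350])
        res = quantify(labels, 27.0, 1000)
        assert res.volume_ml(ComponentLabel.DIRECT_FLOW) == pytest.approx(8.1)
        assert res.edv_ml == pytest.approx(27.0)
        assert res.inflow_ml == pytest.approx(12.96)
        assert res.outflow_ml == pytest.approx(12.69)
        assert res.percent_of_edv(ComponentLabel.DIRECT_FLOW) == pytest.approx(30.0)

    def test_partition_invariant_enforced(self):
        with pytest.raises(ValidationError):
            quantify(np.zeros(5, dtype=int), 27.0, 6)

    def test_empty_label_zero_volume(self):
        res = quantify(np.zeros(10, dtype=int), 27.0, 10)
        assert res.volume_ml(ComponentLabel.RESIDUAL_VOLUME) == 0.0
        assert res.percent_of_edv(ComponentLabel.RESIDUAL_VOLUME) == 0.0

    def test_conservation_identity(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 5, size=777)
        res = quantify(labels, 27.0, 777)
        four = sum(res.volume_ml(ComponentLabel(c)) for c in range(4))
        assert four == pytest.approx(res.edv_ml - res.volume_ml(ComponentLabel.EXCLUDED))


class TestFlowBalance:
    def test_equal_volumes_zero_rel_diff(self):
        labels = np.repeat([0, 1, 2, 3], [30, 20, 20, 30])
        res = quantify(labels, 1000.0, 100)
        rep = flow_balance(res)
        assert rep["rel_diff"] == 0.0 and not rep["flagged"]

    def test_group_mean_style_imbalance(self):
        # inflow 68 mL vs outflow 67 mL -> ~1.48% relative difference
        labels = np.repeat([0, 1, 2, 3], [50, 18, 17, 15])
        res = quantify(labels, 1000.0 * 1000.0 / 1000.0, 100)  # 1 mL voxels
        rep = flow_balance(res)
        assert rep["inflow_ml"] == pytest.approx(68.0)
        assert rep["outflow_ml"] == pytest.approx(67.0)
        assert rep["rel_diff"] == pytest.approx(1.0 / 67.5, rel=1e-12)
        assert not rep["flagged"]

    def test_both_zero_flagged_undefined(self):
        res = quantify(np.full(10, 3), 27.0, 10)
        rep = flow_balance(res)
        assert rep["rel_diff"] is None and rep["flagged"]


class TestKineticEnergy:
    def test_zero_field_zero_curves(self):
        f = make_uniform_field((0.0, 0, 0), n_frames=5)
        p = Pathline(0, [10.5, 10.5, 10.5], np.array([-650.0, 350.0]),
                     np.array([[10.5] * 3, [10.5] * 3]))
        ke = kinetic_energy([p], [0], f)
        np.testing.assert_array_equal(ke.ke_microjoule, 0.0)

    def test_unit_speed_voxel_energy(self):
        # 1 m/s in a 27 uL voxel: KE = 0.5*1060*1^2*27e-9 J = 14.31 uJ/frame
        f = make_uniform_field((100.0, 0, 0), venc_cm_s=150.0, n_frames=4)
        p = Pathline(0, [10.5, 10.5, 10.5], np.array([-650.0, 350.0]),
                     np.array([[10.5] * 3, [10.5] * 3]))
        ke = kinetic_energy([p], [int(ComponentLabel.DIRECT_FLOW)], f)
        np.testing.assert_allclose(
            ke.for_label(ComponentLabel.DIRECT_FLOW), 14.31, rtol=1e-12
        )

    def test_additivity(self):
        f = make_uniform_field((60.0, 0, 0), n_frames=4)
        p = Pathline(0, [10.5, 10.5, 10.5], np.array([-650.0, 350.0]),
                     np.array([[10.5] * 3, [10.5] * 3]))
        one = kinetic_energy([p], [0], f)
        two = kinetic_energy([p, p], [0, 0], f)
        np.testing.assert_allclose(two.ke_microjoule, 2 * one.ke_microjoule)


class TestQC:
    def test_clean_phantom_no_leaks(self, small_phantom):
        ph = small_phantom
        plane = basal_plane_from_mask(ph.mask_ivr)
        rep = qc_leak_fraction(ph.field, plane, ph.pool_mask, 0.0, ph.field.cycle_ms)
        assert rep.leak_fraction == 0.0
        assert not rep.cluster_warning

    def test_offset_field_leaks_with_cluster_warning(self, small_phantom):
        ph = small_phantom
        plane = basal_plane_from_mask(ph.mask_ivr)
        shifted = ph.field.with_velocity(ph.field.velocity + np.array([3.0, 0.0, 0.0]))
        rep = qc_leak_fraction(shifted, plane, ph.pool_mask, 0.0, ph.field.cycle_ms)
        assert rep.leak_fraction > 0
        assert rep.cluster_warning
        assert rep.dominant_exit_direction == "+x"

    def test_degenerate_window_zero_fraction(self, small_phantom):
        ph = small_phantom
        plane = basal_plane_from_mask(ph.mask_ivr)
        rep = qc_leak_fraction(ph.field, plane, ph.pool_mask, 100.0, 100.0)
        assert rep.leak_fraction == 0.0


class TestSuggestTimes:
    def test_phantom_quiet_windows_recovered(self, small_phantom):
        ph = small_phantom
        plane = basal_plane_from_mask(ph.mask_ivr)
        fgm = rasterize_mask(ph.mask_ivc, ph.field)
        out = suggest_isovolumetric_times(ph.field, plane, fgm)
        dt = ph.field.dt_ms
        assert abs(out["t_ivc_ms"] - ph.spec.t_ivc_ms) % ph.field.cycle_ms <= dt
        assert abs(out["t_ivr_ms"] - ph.spec.t_ivr_ms) <= dt

    def test_constant_flux_is_error(self, small_phantom):
        ph = small_phantom
        plane = basal_plane_from_mask(ph.mask_ivr)
        fgm = rasterize_mask(ph.mask_ivc, ph.field)
        const = ph.field.with_velocity(
            np.broadcast_to(np.array([0.0, 0.0, 10.0]), ph.field.velocity.shape).copy()
        )
        with pytest.raises(ValidationError):
            suggest_isovolumetric_times(const, plane, fgm)
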