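"""Synthetic-data generation: closed-form test fields and a kinematic LV
phantom with programmable flow-component fractions and ground-truth labels.

The LV phantom is a prescribed-velocity (kinematic) flow program, not a
fluid simulation: ground truth must be exact by construction, and the
method under test consumes velocity fields regardless of their physical
origin.  The chamber is a box with its basal face at the top; the
cross-section is partitioned into z-columns, each assigned to one flow
component.  Flow is purely axial, ``v = (0, 0, vz(x, y, t))``, hence
exactly divergence-free.  During "diastole" an inflow pulse runs down the
direct-flow and retained-inflow columns (entering through the basal
apertures); during "systole" an ejection pulse runs up the direct-flow and
delayed-ejection columns.  Pulse amplitudes are set so that, over one
cycle, inflow columns are flushed over the full chamber depth and ejection
columns are emptied past the basal plane:

* direct columns carry both pulses (filled this diastole, drained this
  systole),
* retained columns only the inflow pulse,
* delayed columns only the ejection pulse,
* residual columns are quiescent (their blood stays at least two cycles).

Pulse windows are aligned to frame times and shaped as sin^2, so the
frame-sampled, linearly-interpolated field integrates to the programmed
displacements exactly; classification margins are therefore deterministic,
not statistical.  Truth labels come from an independent fixed-step RK4
oracle (scipy grid interpolation, step = frame spacing / 100) — a separate
code path from the adaptive tracer under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .correction import BackgroundModel, polynomial_exponents
from .geometry import FlowGridMask
from .io import (
    CM_S_TO_MM_MS,
    MagnitudeField4D,
    SegmentationMask,
    ValidationError,
    VelocityField4D,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "LVPhantom",
    "make_uniform_field",
    "make_rotation_field",
    "make_polynomial_offset_field",
    "make_lv_phantom",
    "reference_trace",
    "reference_trace_batch",
]

# Component codes used in truth labels (match components.ComponentLabel
# values, but defined independently here so the oracle does not import the
# module under test).
DIRECT, RETAINED, DELAYED, RESIDUAL, EXCLUDED = 0, 1, 2, 3, 4


# ---------------------------------------------------------------------------
# Closed-form fields
# ---------------------------------------------------------------------------


def _grid_coords(dims, spacing_mm, origin_mm):
    return tuple(
        origin_mm[a] + spacing_mm[a] * np.arange(dims[a]) for a in range(3)
    )


def make_uniform_field(
    v_cm_s,
    dims=(8, 8, 8),
    spacing_mm=(3.0, 3.0, 3.0),
    origin_mm=(0.0, 0.0, 0.0),
    n_frames=4,
    cycle_ms=1000.0,
    venc_cm_s=100.0,
) -> VelocityField4D:
    """Constant-in-space-and-time field; pathlines are straight lines."""
    vel = np.broadcast_to(
        np.asarray(v_cm_s, dtype=float), (n_frames, *dims, 3)
    ).copy()
    return VelocityField4D(vel, spacing_mm, cycle_ms, venc_cm_s, origin_mm)


def make_rotation_field(
    omega_rad_per_ms: float,
    center_mm,
    dims=(21, 21, 5),
    spacing_mm=(3.0, 3.0, 3.0),
    origin_mm=(0.0, 0.0, 0.0),
    n_frames=4,
    cycle_ms=1000.0,
    venc_cm_s=100.0,
) -> VelocityField4D:
    """Steady solid-body rotation about the z axis through ``center_mm``.

    ``v = omega x (x - c)``; trajectories are circles with period
    2*pi/omega.  The field is linear in space, so trilinear interpolation
    reproduces it exactly — the closed-form oracle for integrator tests.
    """
    xs, ys, zs = _grid_coords(dims, spacing_mm, origin_mm)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    vx = -omega_rad_per_ms * (Y - center_mm[1]) / CM_S_TO_MM_MS
    vy = omega_rad_per_ms * (X - center_mm[0]) / CM_S_TO_MM_MS
    vel = np.zeros((n_frames, *dims, 3))
    vel[..., 0] = vx[None, :, :, None]
    vel[..., 1] = vy[None, :, :, None]
    return VelocityField4D(vel, spacing_mm, cycle_ms, venc_cm_s, origin_mm)


def make_polynomial_offset_field(
    coeffs: np.ndarray,
    degree: int,
    dims=(12, 12, 12),
    spacing_mm=(3.0, 3.0, 3.0),
    origin_mm=(0.0, 0.0, 0.0),
    n_frames=2,
    cycle_ms=1000.0,
    venc_cm_s=100.0,
) -> VelocityField4D:
    """Field equal to a trivariate polynomial offset at every voxel, all frames.

    ``coeffs`` has shape (3, n_terms) (or (n_frames, 3, n_terms)) in the
    normalized [-1, 1]^3 coordinates of the grid bounding box, with terms
    ordered as :func:`flowcomp4d.correction.polynomial_exponents` — the same
    convention the background-correction fit reports, so inject-and-recover
    comparisons are direct.
    """
    if degree > 4:
        raise ValidationError("polynomial degree > 4 not supported")
    n_terms = len(polynomial_exponents(degree))
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape == (3, n_terms):
        coeffs = np.broadcast_to(coeffs, (n_frames, 3, n_terms)).copy()
    if coeffs.shape != (n_frames, 3, n_terms):
        raise ValidationError(
            f"coeffs must have shape (3, {n_terms}) or ({n_frames}, 3, {n_terms})"
        )
    lo = np.asarray(origin_mm, dtype=float)
    hi = lo + (np.asarray(dims) - 1) * np.asarray(spacing_mm)
    model = BackgroundModel(
        degree=degree,
        coeffs=coeffs,
        center_mm=0.5 * (lo + hi),
        halfwidth_mm=np.maximum(0.5 * (hi - lo), 1e-12),
    )
    xs, ys, zs = _grid_coords(dims, spacing_mm, origin_mm)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.c_[X.ravel(), Y.ravel(), Z.ravel()]
    vel = np.empty((n_frames, *dims, 3))
    for k in range(n_frames):
        vel[k] = model.evaluate(pts, k).reshape(*dims, 3)
    return VelocityField4D(vel, spacing_mm, cycle_ms, venc_cm_s, origin_mm)


# ---------------------------------------------------------------------------
# Independent reference tracer (the brute-force oracle)
# ---------------------------------------------------------------------------


def _oracle_sampler(field: VelocityField4D):
    """Space-time interpolator built on scipy, periodic in time."""
    dt = field.dt_ms
    tgrid = np.arange(field.n_frames + 1) * dt
    Vp = np.concatenate([field.velocity, field.velocity[:1]], axis=0)
    axes = (tgrid,) + _grid_coords(field.dims, field.spacing_mm, field.origin_mm)
    rgi = RegularGridInterpolator(
        axes, Vp, method="linear", bounds_error=False, fill_value=0.0
    )
    cycle = field.cycle_ms

    def sample(pos: np.ndarray, t: float) -> np.ndarray:
        tw = np.mod(t, cycle)
        pts = np.c_[np.full(len(pos), tw), pos]
        return rgi(pts) * CM_S_TO_MM_MS

    return sample


def reference_trace_batch(
    field: VelocityField4D,
    seeds: np.ndarray,
    t0: float,
    t1: float,
    step_divisor: int = 100,
    record_stride: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step classical RK4 for many seeds; no adaptivity.

    Step size is the field's frame spacing divided by ``step_divisor``.
    Returns ``(times, positions)`` with positions of shape
    (n_recorded, n_seeds, 3); by default only start and end are recorded
    (``record_stride=None``), which is what truth generation needs.
    Used only in tests and ground-truth generation; independent of the
    adaptive tracer.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if t0 == t1:
        return np.array([t0]), seeds[None, :, :].copy()
    h0 = field.dt_ms / step_divisor
    n_steps = max(1, int(np.ceil(abs(t1 - t0) / h0 - 1e-12)))
    h = (t1 - t0) / n_steps
    sample = _oracle_sampler(field)
    x = seeds.copy()
    rec_t = [t0]
    rec_x = [x.copy()]
    t = t0
    for i in range(n_steps):
        k1 = sample(x, t)
        k2 = sample(x + 0.5 * h * k1, t + 0.5 * h)
        k3 = sample(x + 0.5 * h * k2, t + 0.5 * h)
        k4 = sample(x + h * k3, t + h)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t0 + (i + 1) * h
        if record_stride is not None and (i + 1) % record_stride == 0 and i + 1 < n_steps:
            rec_t.append(t)
            rec_x.append(x.copy())
    rec_t.append(t1)
    rec_x.append(x.copy())
    return np.array(rec_t), np.stack(rec_x)


def reference_trace(
    field: VelocityField4D,
    seed,
    t0: float,
    t1: float,
    step_divisor: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-seed fixed-step reference trajectory (all steps recorded)."""
    times, pos = reference_trace_batch(
        field, np.asarray(seed, dtype=float).reshape(1, 3), t0, t1,
        step_divisor=step_divisor, record_stride=1,
    )
    return times, pos[:, 0, :]


# ---------------------------------------------------------------------------
# The LV phantom
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Study conditions of the synthetic LV dataset.

    Defaults mirror the acquisition regime the method targets: 3 mm
    isotropic voxels, 40 frames over a 1000 ms cycle, VENC 100 cm/s, and a
    healthy-heart operating point — EDV near 146 mL with component
    fractions (30, 18, 17, 35)% for direct flow, retained inflow, delayed
    ejection flow and residual volume.
    """

    spacing_mm: float = 3.0
    n_frames: int = 40
    cycle_ms: float = 1000.0
    venc_cm_s: float = 100.0
    chamber_width_mm: float = 48.0
    edv_target_ml: float = 146.0
    fractions: tuple[float, float, float, float] = (0.30, 0.18, 0.17, 0.35)
    t_ivc_ms: float = 0.0
    t_ivr_ms: float = 350.0
    quiet_ms: float = 25.0
    noise_cm_s: float = 0.0
    seed: int = 0

    # base in-plane/slab lattice everything is aligned to (mm)
    _lattice: float = 3.0
    _slice_thickness: float = 9.0

    def validate(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError("fractions must be nonnegative and sum to 1")
        if self.spacing_mm <= 0 or self.n_frames < 2 or self.cycle_ms <= 0:
            raise ValidationError("invalid grid parameters")
        if not (0 <= self.t_ivc_ms < self.cycle_ms and 0 <= self.t_ivr_ms < self.cycle_ms):
            raise ValidationError("t_ivc/t_ivr must lie in [0, cycle_ms)")
        if self.t_ivc_ms >= self.t_ivr_ms:
            raise ValidationError("phantom requires t_ivc < t_ivr")
        if self.chamber_width_mm % self._lattice:
            raise ValidationError("chamber_width_mm must be a multiple of 3 mm")
        for v in self.peak_speeds_cm_s():
            if v >= self.venc_cm_s:
                raise ValidationError(
                    f"programmed peak speed {v:.1f} cm/s reaches VENC {self.venc_cm_s}"
                )

    # -- derived geometry (world mm, independent of grid spacing) ----------
    @property
    def wall_mm(self) -> float:
        return 2 * self._lattice

    @property
    def chamber_lo(self) -> float:
        """x/y coordinate of the chamber footprint lower face."""
        return self.wall_mm

    @property
    def chamber_hi(self) -> float:
        return self.wall_mm + self.chamber_width_mm

    @property
    def chamber_height_mm(self) -> float:
        """Chamber depth snapped to whole mask slices so EDV ~ target."""
        w2 = self.chamber_width_mm**2
        n_slices = max(1, round(self.edv_target_ml * 1000.0 / (w2 * self._slice_thickness)))
        return n_slices * self._slice_thickness

    @property
    def z_apex(self) -> float:
        return self.wall_mm

    @property
    def z_base(self) -> float:
        """Basal plane position (chamber top face)."""
        return self.z_apex + self.chamber_height_mm

    @property
    def sys_displacement_mm(self) -> float:
        return self.chamber_height_mm + self._lattice

    @property
    def dia_displacement_mm(self) -> float:
        return self.chamber_height_mm

    @property
    def grid_extent_mm(self) -> tuple[float, float, float]:
        xy = self.chamber_width_mm + 2 * self.wall_mm
        z = self.z_base + self.sys_displacement_mm + 2 * self._lattice
        return (xy, xy, z)

    @property
    def dims(self) -> tuple[int, int, int]:
        ext = self.grid_extent_mm
        return tuple(int(round(e / self.spacing_mm)) for e in ext)

    def pulse_windows(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(systolic window, diastolic window) in ms; frame-aligned by default."""
        sys_w = (self.t_ivc_ms + self.quiet_ms, self.t_ivr_ms - self.quiet_ms)
        dia_w = (self.t_ivr_ms + self.quiet_ms, self.cycle_ms - self.quiet_ms)
        return sys_w, dia_w

    def peak_speeds_cm_s(self) -> tuple[float, float]:
        """Peak systolic and diastolic plug speeds (sin^2 pulse integral =
        peak * window / 2 = programmed displacement)."""
        (s0, s1), (d0, d1) = self.pulse_windows()
        vp_sys = 2.0 * self.sys_displacement_mm / (s1 - s0) / CM_S_TO_MM_MS
        vp_dia = 2.0 * self.dia_displacement_mm / (d1 - d0) / CM_S_TO_MM_MS
        return vp_sys, vp_dia


@dataclass
class PhantomTruth:
    """Ground truth for one phantom realization."""

    labels: np.ndarray  # per-seed component code
    seed_positions_mm: np.ndarray
    backward_end_mm: np.ndarray  # oracle position at previous IVR
    forward_end_mm: np.ndarray  # oracle position at IVR
    edv_ml: float
    inflow_ml: float
    outflow_ml: float
    source: str  # "oracle" | "programmed"

    @property
    def fractions(self) -> dict[int, float]:
        n = len(self.labels)
        return {c: float((self.labels == c).sum()) / n for c in range(5)}


@dataclass
class LVPhantom:
    spec: PhantomSpec
    field: VelocityField4D
    magnitude: MagnitudeField4D
    mask_ivc: SegmentationMask
    mask_ivr: SegmentationMask
    truth: PhantomTruth
    pool_mask: FlowGridMask
    programmed_labels: np.ndarray = dataclass_field(repr=False, default=None)
    column_component: np.ndarray = dataclass_field(repr=False, default=None)


def _allocate_columns(spec: PhantomSpec, xs: np.ndarray, ys: np.ndarray):
    """Assign each chamber cross-section cell to a component.

    Cells are ordered by distance from the footprint center (direct flow
    innermost, like the transmitral jet core; residual volume at the
    periphery) and counts follow the programmed fractions by largest
    remainder, so the realized fractions deviate from programmed ones by at
    most half a cell.
    """
    in_x = (xs >= spec.chamber_lo) & (xs < spec.chamber_hi)
    in_y = (ys >= spec.chamber_lo) & (ys < spec.chamber_hi)
    ii, jj = np.nonzero(np.outer(in_x, in_y))
    n_cells = len(ii)
    if n_cells < 4:
        raise ValidationError("chamber cross-section too small for four components")
    cx = 0.5 * (spec.chamber_lo + spec.chamber_hi)
    d2 = (xs[ii] - cx) ** 2 + (ys[jj] - cx) ** 2
    order = np.lexsort((jj, ii, d2))
    f = np.asarray(spec.fractions, dtype=float)
    raw = f * n_cells
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for _ in range(n_cells - counts.sum()):
        k = int(np.argmax(remainder))
        counts[k] += 1
        remainder[k] = -1
    comp_of_cell = np.empty(n_cells, dtype=np.int64)
    start = 0
    for comp, c in enumerate(counts):
        comp_of_cell[order[start : start + c]] = comp
        start += c
    column_component = np.full((len(xs), len(ys)), -1, dtype=np.int64)
    column_component[ii, jj] = comp_of_cell
    return column_component


def _sin2_pulse(frame_times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    u = (frame_times - t0) / (t1 - t0)
    inside = (u > 0) & (u < 1)
    out = np.zeros_like(frame_times)
    out[inside] = np.sin(np.pi * u[inside]) ** 2
    return out


def make_lv_phantom(spec: PhantomSpec | None = None, truth: str = "oracle") -> LVPhantom:
    """Build the kinematic LV phantom: velocity + magnitude fields, IVC/IVR
    masks, QC blood-pool mask, and ground-truth component labels.

    ``truth="oracle"`` (default) labels seeds from independent fixed-step
    RK4 trajectories; ``truth="programmed"`` uses the analytic column
    assignment directly (cheap; the two agree on noiseless phantoms).
    """
    if spec is None:
        spec = PhantomSpec()
    spec.validate()
    s = spec.spacing_mm
    dims = spec.dims
    xs = s / 2.0 + s * np.arange(dims[0])
    ys = s / 2.0 + s * np.arange(dims[1])
    zs = s / 2.0 + s * np.arange(dims[2])
    origin = (s / 2.0, s / 2.0, s / 2.0)
    frame_times = np.arange(spec.n_frames) * (spec.cycle_ms / spec.n_frames)

    column_component = _allocate_columns(spec, xs, ys)
    sys_cols = (column_component == DIRECT) | (column_component == DELAYED)
    dia_cols = (column_component == DIRECT) | (column_component == RETAINED)

    vp_sys, vp_dia = spec.peak_speeds_cm_s()
    sys_win, dia_win = spec.pulse_windows()
    sys_pulse = vp_sys * _sin2_pulse(frame_times, sys_win)  # cm/s, +z (ejection)
    dia_pulse = -vp_dia * _sin2_pulse(frame_times, dia_win)  # cm/s, -z (inflow)

    # flow channels span z >= sump bottom (one lattice layer below the apex)
    z_flow_lo = spec.z_apex - spec._lattice
    z_active = zs >= z_flow_lo

    vel = np.zeros((spec.n_frames, *dims, 3))
    vz = (
        sys_pulse[:, None, None] * sys_cols[None, :, :]
        + dia_pulse[:, None, None] * dia_cols[None, :, :]
    )  # (nt, nx, ny)
    vel[..., 2] = vz[:, :, :, None] * z_active[None, None, None, :]

    if spec.noise_cm_s > 0:
        rng = np.random.default_rng(spec.seed)
        vel = vel + rng.normal(0.0, spec.noise_cm_s, size=vel.shape)

    field = VelocityField4D(vel, (s, s, s), spec.cycle_ms, spec.venc_cm_s, origin)

    # magnitude: bright blood + bright static tissue below the base, dim air
    in_foot = np.zeros(dims[:2], dtype=bool)
    in_foot[
        np.ix_(
            (xs >= spec.chamber_lo) & (xs < spec.chamber_hi),
            (ys >= spec.chamber_lo) & (ys < spec.chamber_hi),
        )
    ] = True
    mag3d = np.full(dims, 0.05)
    mag3d[:, :, zs < spec.z_base] = 1.0  # myocardium/tissue slab
    mag3d[in_foot] = 1.0  # blood columns, full height
    magnitude = MagnitudeField4D(
        np.broadcast_to(mag3d, (spec.n_frames, *dims)).copy(),
        (s, s, s),
        spec.cycle_ms,
        origin,
    )

    # masks: slice stack over the chamber, slice index increasing apex->base
    lat = spec._lattice
    n_ip = int(round(spec.chamber_width_mm / lat))
    n_slices = int(round(spec.chamber_height_mm / spec._slice_thickness))
    affine = np.diag([lat, lat, spec._slice_thickness, 1.0])
    affine[:3, 3] = (
        spec.chamber_lo + lat / 2.0,
        spec.chamber_lo + lat / 2.0,
        spec.z_apex + spec._slice_thickness / 2.0,
    )
    mask_kwargs = dict(
        voxels=np.ones((n_ip, n_ip, n_slices), dtype=bool),
        in_plane_spacing_mm=(lat, lat),
        slice_thickness_mm=spec._slice_thickness,
        affine=affine,
        basal_slice_index=n_slices - 1,
        slice_direction="apex_to_base",
    )
    mask_ivc = SegmentationMask(phase_label="IVC", **mask_kwargs)
    mask_ivr = SegmentationMask(phase_label="IVR", **mask_kwargs)

    # QC blood pool: chamber footprint columns from the sump layer upward,
    # leaving the one-voxel grid margin outside the pool
    pool = np.zeros(dims, dtype=bool)
    pool[in_foot] = True
    pool[:, :, ~(z_active & (zs <= spec.z_base + spec.sys_displacement_mm + lat))] = False
    pool_mask = FlowGridMask(inside=pool, spacing_mm=(s, s, s), origin_mm=origin)

    # seeds: chamber voxel centers, lexicographic (identical to rasterizing
    # the IVC mask on the flow grid and seeding each inside voxel)
    in_ch_z = (zs >= spec.z_apex) & (zs < spec.z_base)
    chamber = np.zeros(dims, dtype=bool)
    chamber[in_foot] = True
    chamber[:, :, ~in_ch_z] = False
    seed_idx = np.argwhere(chamber)
    seeds = np.asarray(origin) + seed_idx * s
    prog_labels = column_component[seed_idx[:, 0], seed_idx[:, 1]]

    edv_ml = len(seeds) * field.voxel_volume_mm3 / 1000.0
    voxel_ml = field.voxel_volume_mm3 / 1000.0

    if truth == "programmed":
        labels = prog_labels.copy()
        bwd_end = np.full_like(seeds, np.nan)
        fwd_end = np.full_like(seeds, np.nan)
    elif truth == "oracle":
        t_fwd_end = spec.t_ivr_ms
        t_bwd_end = spec.t_ivr_ms - spec.cycle_ms
        _, fwd = reference_trace_batch(field, seeds, spec.t_ivc_ms, t_fwd_end)
        _, bwd = reference_trace_batch(field, seeds, spec.t_ivc_ms, t_bwd_end)
        fwd_end = fwd[-1]
        bwd_end = bwd[-1]
        labels = _label_endpoints(spec, bwd_end, fwd_end)
    else:
        raise ValidationError(f"unknown truth mode {truth!r}")

    counts = np.bincount(labels, minlength=5)
    truth_obj = PhantomTruth(
        labels=labels,
        seed_positions_mm=seeds,
        backward_end_mm=bwd_end,
        forward_end_mm=fwd_end,
        edv_ml=edv_ml,
        inflow_ml=(counts[DIRECT] + counts[RETAINED]) * voxel_ml,
        outflow_ml=(counts[DIRECT] + counts[DELAYED]) * voxel_ml,
        source=truth,
    )
    return LVPhantom(
        spec=spec,
        field=field,
        magnitude=magnitude,
        mask_ivc=mask_ivc,
        mask_ivr=mask_ivr,
        truth=truth_obj,
        pool_mask=pool_mask,
        programmed_labels=prog_labels,
        column_component=column_component,
    )


def _label_endpoints(spec: PhantomSpec, bwd_end: np.ndarray, fwd_end: np.ndarray) -> np.ndarray:
    """Truth classification from oracle endpoints, by direct arithmetic on
    the phantom's analytic geometry (no shared code with the classifier)."""

    def basal(p):
        return p[:, 2] > spec.z_base

    def in_chamber(p):
        lo, hi = spec.chamber_lo, spec.chamber_hi
        return (
            (p[:, 0] >= lo) & (p[:, 0] < hi)
            & (p[:, 1] >= lo) & (p[:, 1] < hi)
            & (p[:, 2] >= spec.z_apex) & (p[:, 2] < spec.z_base)
        )

    left_b, left_f = basal(bwd_end), basal(fwd_end)
    stay_b = left_b | in_chamber(bwd_end)
    stay_f = left_f | in_chamber(fwd_end)
    labels = np.full(len(bwd_end), RESIDUAL, dtype=np.int64)
    labels[left_b & ~left_f] = RETAINED
    labels[~left_b & left_f] = DELAYED
    labels[left_b & left_f] = DIRECT
    labels[~(stay_b & stay_f)] = EXCLUDED
    return labels
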