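"""Pathline integration through the cyclic, time-resolved velocity field.

Velocity sampling is trilinear in space between voxel centers and linear in
periodic time (the last frame wraps to frame 0, matching a retrospectively
gated, closed cardiac cycle).  Integration is classic 4th-order Runge-Kutta
with step-doubling error control: a step of size h is accepted when the
two-half-steps solution and the full-step solution agree within
``rel_tol_mm``; otherwise h is halved.  After five consecutive accepted
steps h grows by 1.5x, capped at ``max_step_ms``.  The accepted position is
the (more accurate) two-half-steps solution.

Backward tracing integrates dx/dt = v(x, t) with decreasing t; the time
passed to the sampler is always wrapped into [0, cycle_ms), so no field
negation is involved.  Outside the grid's voxel-center bounding box the
field is zero and the trace is frozen and flagged as truncated.

Everything here is deterministic: identical inputs give bit-identical
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .geometry import FlowGridMask
from .io import CM_S_TO_MM_MS, Pathline, ValidationError, VelocityField4D

__all__ = [
    "TraceSettings",
    "SeedSet",
    "Branch",
    "sample_velocity",
    "seed_from_mask",
    "trace",
    "trace_batch",
    "trace_full_cycle",
]


@dataclass
class TraceSettings:
    """Integrator controls.

    rel_tol_mm:
        Per-step error bound (default 0.3 mm, one tenth of a 3 mm voxel).
    max_step_ms:
        Step-size cap; ``None`` means the field's frame spacing.
    min_step_ms:
        Step-size floor; when the error bound cannot be met at the floor the
        step is accepted anyway (the data are only C0, so shrinking further
        buys nothing).
    max_steps:
        Guard against runaway integration.
    fixed_step_ms:
        If set, disables adaptivity and runs plain RK4 at this step
        (used for convergence studies).
    interpolation:
        ``"trilinear"`` (default) or ``"cubic"`` (scipy spline interpolation
        of the space-time samples; off by default since RK4's benefit is
        limited by C0 data).
    """

    rel_tol_mm: float = 0.3
    max_step_ms: float | None = None
    min_step_ms: float = 0.1
    max_steps: int = 10**6
    fixed_step_ms: float | None = None
    interpolation: str = "trilinear"

    def resolved_max_step(self, field: VelocityField4D) -> float:
        h = self.max_step_ms if self.max_step_ms is not None else field.dt_ms
        if self.min_step_ms > h:
            raise ValidationError("min_step_ms must not exceed max_step_ms")
        return h


@dataclass
class SeedSet:
    """One seed per inside voxel of the IVC mask, at the voxel center."""

    positions_mm: np.ndarray  # (n, 3)
    seed_ids: np.ndarray  # (n,)
    source_mask: FlowGridMask

    def __len__(self) -> int:
        return len(self.seed_ids)

    @property
    def edv_ml(self) -> float:
        """Flow-derived end-diastolic volume: seed count x voxel volume."""
        return len(self) * self.source_mask.voxel_volume_mm3 / 1000.0


class Branch(NamedTuple):
    """One integration branch: recorded times, positions, truncation flag."""

    times_ms: np.ndarray
    positions_mm: np.ndarray
    truncated: bool


# ---------------------------------------------------------------------------
# Velocity sampling
# ---------------------------------------------------------------------------


def _make_sampler(
    field: VelocityField4D, interpolation: str = "trilinear"
) -> Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Build a batched sampler ``f(pos (N,3), t (N,)) -> (vel mm/ms, out-of-domain mask)``."""
    V = field.velocity  # (nt, nx, ny, nz, 3), cm/s
    nt = field.n_frames
    dims = np.asarray(field.dims)
    origin = np.asarray(field.origin_mm)
    spacing = np.asarray(field.spacing_mm)
    cycle = field.cycle_ms
    dt = field.dt_ms

    if interpolation == "cubic":
        from scipy.interpolate import RegularGridInterpolator

        # pad time axis with frame 0 at t = cycle for periodic continuity
        tgrid = np.arange(nt + 1) * dt
        Vp = np.concatenate([V, V[:1]], axis=0)
        axes = (tgrid,) + tuple(
            origin[a] + spacing[a] * np.arange(dims[a]) for a in range(3)
        )
        rgi = RegularGridInterpolator(
            axes, Vp, method="cubic", bounds_error=False, fill_value=0.0
        )

        def sample_cubic(pos: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            pos = np.atleast_2d(pos)
            t = np.broadcast_to(np.atleast_1d(t), (len(pos),))
            tw = np.mod(t, cycle)
            pts = np.c_[tw, pos]
            vel = rgi(pts) * CM_S_TO_MM_MS
            rel = (pos - origin) / spacing
            out = ((rel < 0) | (rel > dims - 1)).any(axis=1)
            vel[out] = 0.0
            return vel, out

        return sample_cubic

    if interpolation != "trilinear":
        raise ValidationError(f"unknown interpolation {interpolation!r}")

    def sample(pos: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        t = np.broadcast_to(np.atleast_1d(np.asarray(t, dtype=float)), (len(pos),))
        # periodic time interpolation
        f = np.mod(t, cycle) / dt
        k0 = np.floor(f).astype(np.int64)
        wt = f - k0
        k0 = np.mod(k0, nt)
        k1 = np.mod(k0 + 1, nt)
        # spatial trilinear
        rel = (pos - origin) / spacing
        out = ((rel < 0) | (rel > dims - 1)).any(axis=1)
        relc = np.clip(rel, 0.0, dims - 1.0)
        i0 = np.minimum(np.floor(relc).astype(np.int64), dims - 2)
        i0 = np.maximum(i0, 0)
        w = relc - i0  # in [0, 1]
        vel = np.zeros((len(pos), 3))
        wx, wy, wz = w[:, 0], w[:, 1], w[:, 2]
        for dx in (0, 1):
            fx = wx if dx else 1.0 - wx
            for dy in (0, 1):
                fy = wy if dy else 1.0 - wy
                for dz in (0, 1):
                    fz = wz if dz else 1.0 - wz
                    cw = (fx * fy * fz)[:, None]
                    ix, iy, iz = i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz
                    v0 = V[k0, ix, iy, iz]
                    v1 = V[k1, ix, iy, iz]
                    vel += cw * (v0 * (1.0 - wt)[:, None] + v1 * wt[:, None])
        vel *= CM_S_TO_MM_MS
        vel[out] = 0.0
        return vel, out

    return sample


def sample_velocity(
    field: VelocityField4D,
    p: np.ndarray,
    t_ms: float | np.ndarray,
    return_domain_flag: bool = False,
    interpolation: str = "trilinear",
):
    """Sample the velocity field at world position(s) ``p`` and time(s) ``t_ms``.

    Returns velocity in mm/ms.  Positions outside the voxel-center bounding
    box yield the zero vector; pass ``return_domain_flag=True`` to also get
    the out-of-domain mask.
    """
    single = np.ndim(p) == 1
    vel, out = _make_sampler(field, interpolation)(p, t_ms)
    if single:
        vel, out = vel[0], bool(out[0])
    if return_domain_flag:
        return vel, out
    return vel


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def seed_from_mask(fgm: FlowGridMask) -> SeedSet:
    """One seed per inside voxel at its center, ordered lexicographically."""
    idx = np.argwhere(fgm.inside)  # argwhere is lexicographic already
    if len(idx) == 0:
        raise ValidationError("cannot seed from an empty mask")
    positions = np.asarray(fgm.origin_mm) + idx * np.asarray(fgm.spacing_mm)
    return SeedSet(
        positions_mm=positions.astype(float),
        seed_ids=np.arange(len(idx), dtype=np.int64),
        source_mask=fgm,
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _rk4_step(sample, x, t, h, k1):
    """One classic RK4 step for all rows of x; k1 = v(x, t) precomputed."""
    h2 = (h / 2.0)[:, None]
    k2, _ = sample(x + h2 * k1, t + h / 2.0)
    k3, _ = sample(x + h2 * k2, t + h / 2.0)
    k4, _ = sample(x + h[:, None] * k3, t + h)
    return x + (h / 6.0)[:, None] * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def trace_batch(
    field: VelocityField4D,
    seeds: np.ndarray,
    t0: float,
    t1: float,
    settings: TraceSettings | None = None,
) -> list[Branch]:
    """Trace many seeds from t0 to t1 (t1 < t0 = backward tracing).

    All trajectories are advanced together with individually adaptive step
    sizes; results are identical to tracing each seed alone.
    """
    if settings is None:
        settings = TraceSettings()
    if t0 == t1:
        seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
        return [Branch(np.array([t0]), s.reshape(1, 3).copy(), False) for s in seeds]

    sample = _make_sampler(field, settings.interpolation)
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    n = len(seeds)
    direction = 1.0 if t1 > t0 else -1.0
    max_h = settings.resolved_max_step(field)
    min_h = settings.min_step_ms
    fixed = settings.fixed_step_ms
    tol = settings.rel_tol_mm

    bbox_lo = field.bbox_min_mm
    bbox_hi = field.bbox_max_mm

    pos = seeds.copy()
    t = np.full(n, float(t0))
    h_ctrl = np.full(n, (fixed if fixed is not None else max_h) * direction)
    accept_run = np.zeros(n, dtype=np.int64)
    attempts = np.zeros(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    truncated = np.zeros(n, dtype=bool)

    # initial out-of-domain seeds are frozen immediately
    rel0 = (pos - bbox_lo) >= 0
    rel1 = (pos - bbox_hi) <= 0
    out0 = ~(rel0.all(axis=1) & rel1.all(axis=1))
    truncated[out0] = True
    active[out0] = False

    rec_idx: list[np.ndarray] = []
    rec_t: list[np.ndarray] = []
    rec_pos: list[np.ndarray] = []

    while active.any():
        idx = np.nonzero(active)[0]
        x = pos[idx]
        tt = t[idx]
        rem = t1 - tt
        hh = h_ctrl[idx]
        clamped = np.abs(hh) >= np.abs(rem)
        hh = np.where(clamped, rem, hh)

        k1, _ = sample(x, tt)
        if fixed is not None:
            x_new = _rk4_step(sample, x, tt, hh, k1)
            accept = np.ones(len(idx), dtype=bool)
        else:
            x_full = _rk4_step(sample, x, tt, hh, k1)
            x_half = _rk4_step(sample, x, tt, hh / 2.0, k1)
            k1b, _ = sample(x_half, tt + hh / 2.0)
            x_new = _rk4_step(sample, x_half, tt + hh / 2.0, hh / 2.0, k1b)
            err = np.linalg.norm(x_new - x_full, axis=1)
            accept = (err <= tol) | (np.abs(hh) <= min_h * (1 + 1e-12))

        attempts[idx] += 1
        if (attempts > settings.max_steps).any():
            bad = int(np.argmax(attempts))
            raise RuntimeError(
                f"trace exceeded max_steps={settings.max_steps} for seed {bad} "
                f"at t={t[bad]:.3f} ms, |h|={abs(h_ctrl[bad]):.3g} ms"
            )

        acc_idx = idx[accept]
        if len(acc_idx):
            t_acc = np.where(clamped[accept], t1, tt[accept] + hh[accept])
            pos[acc_idx] = x_new[accept]
            t[acc_idx] = t_acc
            rec_idx.append(acc_idx.copy())
            rec_t.append(t_acc)
            rec_pos.append(x_new[accept])

            # domain exit: freeze and flag
            out = (
                (x_new[accept] < bbox_lo) | (x_new[accept] > bbox_hi)
            ).any(axis=1)
            truncated[acc_idx[out]] = True
            active[acc_idx[out]] = False
            # finished seeds
            done = clamped[accept] & ~out
            active[acc_idx[done]] = False

            if fixed is None:
                accept_run[acc_idx] += 1
                grow = accept_run >= 5
                h_ctrl[grow] = np.clip(h_ctrl[grow] * 1.5, -max_h, max_h)
                accept_run[grow] = 0

        rej_idx = idx[~accept]
        if len(rej_idx):
            h_new = h_ctrl[rej_idx] / 2.0
            h_new = np.sign(h_new) * np.maximum(np.abs(h_new), min_h)
            h_ctrl[rej_idx] = h_new
            accept_run[rej_idx] = 0

    # reassemble per-seed records
    if rec_idx:
        all_idx = np.concatenate(rec_idx)
        all_t = np.concatenate(rec_t)
        all_pos = np.concatenate(rec_pos)
        order = np.argsort(all_idx, kind="stable")
        all_idx, all_t, all_pos = all_idx[order], all_t[order], all_pos[order]
        counts = np.bincount(all_idx, minlength=n)
        splits = np.cumsum(counts)[:-1]
        t_per_seed = np.split(all_t, splits)
        pos_per_seed = np.split(all_pos, splits)
    else:
        t_per_seed = [np.empty(0)] * n
        pos_per_seed = [np.empty((0, 3))] * n

    branches = []
    for i in range(n):
        times = np.concatenate([[t0], t_per_seed[i]])
        positions = np.vstack([seeds[i : i + 1], pos_per_seed[i]])
        branches.append(Branch(times, positions, bool(truncated[i])))
    return branches


def trace(
    field: VelocityField4D,
    seed: np.ndarray,
    t0: float,
    t1: float,
    settings: TraceSettings | None = None,
) -> Branch:
    """Trace a single seed from t0 to t1; see :func:`trace_batch`."""
    if t0 == t1:
        raise ValidationError("trace requires t0 != t1 (use trace_batch for degenerate spans)")
    return trace_batch(field, np.asarray(seed, dtype=float).reshape(1, 3), t0, t1, settings)[0]


def full_cycle_span(t_ivc: float, t_ivr: float, cycle_ms: float) -> tuple[float, float]:
    """Endpoint times of the two branches.

    Returns ``(t_bwd_end, t_fwd_end)``: the forward end is the first time
    >= t_ivc congruent to t_ivr (mod cycle); the backward end is one cycle
    earlier, so the merged pathline spans exactly one cardiac cycle.
    """
    t_fwd_end = t_ivr if t_ivr >= t_ivc else t_ivr + cycle_ms
    return t_fwd_end - cycle_ms, t_fwd_end


def trace_full_cycle(
    field: VelocityField4D,
    seeds: SeedSet,
    t_ivc: float,
    t_ivr: float,
    settings: TraceSettings | None = None,
) -> list[Pathline]:
    """Trace every seed forward and backward in time to IVR, covering the
    complete cardiac cycle.  No mask constrains the tracing."""
    if not (0 <= t_ivc < field.cycle_ms and 0 <= t_ivr < field.cycle_ms):
        raise ValidationError("t_ivc and t_ivr must lie in [0, cycle_ms)")
    if t_ivc == t_ivr:
        raise ValidationError("t_ivc and t_ivr must differ")
    t_bwd_end, t_fwd_end = full_cycle_span(t_ivc, t_ivr, field.cycle_ms)

    fwd = trace_batch(field, seeds.positions_mm, t_ivc, t_fwd_end, settings)
    bwd = trace_batch(field, seeds.positions_mm, t_ivc, t_bwd_end, settings)

    pathlines = []
    for sid, p0, fb, bb in zip(seeds.seed_ids, seeds.positions_mm, fwd, bwd):
        # backward branch recorded with decreasing times; reverse and drop
        # the duplicated seed sample at t_ivc
        times = np.concatenate([bb.times_ms[::-1][:-1], fb.times_ms])
        positions = np.vstack([bb.positions_mm[::-1][:-1], fb.positions_mm])
        pathlines.append(
            Pathline(
                seed_id=int(sid),
                seed_position_mm=p0,
                times_ms=times,
                positions_mm=positions,
                truncated_backward=bb.truncated,
                truncated_forward=fb.truncated,
            )
        )
    return pathlines
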