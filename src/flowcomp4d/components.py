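"""Separation of pathlines into the four LV flow components, volume
quantification, the inflow/outflow accuracy check, kinetic-energy curves,
quality control, and an isovolumetric-timing helper.

Each pathline is emitted at IVC and spans one full cardiac cycle, from the
previous IVR (backward branch, diastole) to the analyzed IVR (forward
branch, systole).  The IVR LV geometry and the basal plane decide where it
went:

* **Direct Flow** — enters the LV during diastole and leaves during systole
  (both endpoints basal of the plane);
* **Retained Inflow** — enters during diastole but does not leave during
  systole;
* **Delayed Ejection Flow** — resides in the LV during diastole and leaves
  during systole;
* **Residual Volume** — resides within the LV for at least two cycles;
* **Excluded** — a non-basal endpoint falls outside the IVR LV volume: the
  pathline was emitted from the myocardium or left the LV through data
  imperfections, and it is reported but never redistributed.

Classification uses the endpoint state at IVR (where the pathline *is* at
IVR), not first crossing; the first basal-crossing time is recorded
separately per pathline to support future regurgitation detection.

Each pathline represents one voxel volume of blood: component volume =
pathline count x voxel volume.  The accuracy check compares
Inflow = Direct Flow + Retained Inflow against
Outflow = Direct Flow + Delayed Ejection Flow, which should agree in a
conservative dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

from .geometry import BasalPlane, FlowGridMask, is_basal_of, is_inside
from .io import Pathline, ValidationError, VelocityField4D
from .tracing import TraceSettings, _make_sampler, trace_batch

__all__ = [
    "ComponentLabel",
    "ComponentResult",
    "KineticEnergyCurves",
    "QCReport",
    "classify",
    "classify_all",
    "first_basal_crossing",
    "quantify",
    "flow_balance",
    "kinetic_energy",
    "qc_leak_fraction",
    "suggest_isovolumetric_times",
]


class ComponentLabel(IntEnum):
    DIRECT_FLOW = 0
    RETAINED_INFLOW = 1
    DELAYED_EJECTION = 2
    RESIDUAL_VOLUME = 3
    EXCLUDED = 4


#: Human-readable names used in reports.
LABEL_NAMES = {
    ComponentLabel.DIRECT_FLOW: "direct_flow",
    ComponentLabel.RETAINED_INFLOW: "retained_inflow",
    ComponentLabel.DELAYED_EJECTION: "delayed_ejection_flow",
    ComponentLabel.RESIDUAL_VOLUME: "residual_volume",
    ComponentLabel.EXCLUDED: "excluded",
}


def classify(
    pathline: Pathline,
    ivr_mask: FlowGridMask,
    plane: BasalPlane,
) -> ComponentLabel:
    """Label one pathline from its endpoint state at the two IVR times."""
    if pathline.truncated_backward or pathline.truncated_forward:
        return ComponentLabel.EXCLUDED
    B = pathline.start_position  # at previous IVR
    F = pathline.end_position  # at analyzed IVR
    left_bwd = is_basal_of(plane, B)
    left_fwd = is_basal_of(plane, F)
    stayed_bwd = left_bwd or is_inside(ivr_mask, B)
    stayed_fwd = left_fwd or is_inside(ivr_mask, F)
    if not (stayed_bwd and stayed_fwd):
        return ComponentLabel.EXCLUDED
    if left_bwd and left_fwd:
        return ComponentLabel.DIRECT_FLOW
    if left_bwd:
        return ComponentLabel.RETAINED_INFLOW
    if left_fwd:
        return ComponentLabel.DELAYED_EJECTION
    return ComponentLabel.RESIDUAL_VOLUME


def classify_all(
    pathlines: Sequence[Pathline],
    ivr_mask: FlowGridMask,
    plane: BasalPlane,
) -> np.ndarray:
    """Vectorized :func:`classify` over many pathlines."""
    n = len(pathlines)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    B = np.array([p.start_position for p in pathlines])
    F = np.array([p.end_position for p in pathlines])
    trunc = np.array(
        [p.truncated_backward or p.truncated_forward for p in pathlines], dtype=bool
    )
    left_bwd = is_basal_of(plane, B)
    left_fwd = is_basal_of(plane, F)
    stayed_bwd = left_bwd | is_inside(ivr_mask, B)
    stayed_fwd = left_fwd | is_inside(ivr_mask, F)
    labels = np.full(n, int(ComponentLabel.RESIDUAL_VOLUME), dtype=np.int64)
    labels[left_bwd & ~left_fwd] = int(ComponentLabel.RETAINED_INFLOW)
    labels[~left_bwd & left_fwd] = int(ComponentLabel.DELAYED_EJECTION)
    labels[left_bwd & left_fwd] = int(ComponentLabel.DIRECT_FLOW)
    labels[~(stayed_bwd & stayed_fwd) | trunc] = int(ComponentLabel.EXCLUDED)
    return labels


def first_basal_crossing(pathline: Pathline, plane: BasalPlane) -> float | None:
    """Time of the first apical-to-basal crossing of the basal plane, or None.

    Stored per pathline to make regurgitant traces identifiable by the
    timing and location where they leave the segmented volume.
    """
    d = plane.signed_distance(pathline.positions_mm)
    crossing = (d[:-1] <= 0) & (d[1:] > 0)
    idx = np.nonzero(crossing)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    # linear interpolation of the crossing time within the segment
    frac = -d[i] / (d[i + 1] - d[i])
    return float(pathline.times_ms[i] + frac * (pathline.times_ms[i + 1] - pathline.times_ms[i]))


@dataclass
class ComponentResult:
    """Per-component counts, volumes and percentages of flow-derived EDV.

    Percentages use the total EDV (all seeds) as denominator, with the
    excluded percentage reported alongside, so the four components need not
    sum to 100% when pathlines were excluded.
    """

    counts: dict[ComponentLabel, int]
    voxel_volume_mm3: float
    n_seeds: int

    def __post_init__(self) -> None:
        total = sum(self.counts.get(lab, 0) for lab in ComponentLabel)
        if total != self.n_seeds:
            raise ValidationError(
                f"label counts sum to {total}, expected n_seeds={self.n_seeds}"
            )

    @property
    def edv_ml(self) -> float:
        return self.n_seeds * self.voxel_volume_mm3 / 1000.0

    def volume_ml(self, label: ComponentLabel) -> float:
        return self.counts.get(label, 0) * self.voxel_volume_mm3 / 1000.0

    def percent_of_edv(self, label: ComponentLabel) -> float:
        if self.n_seeds == 0:
            return 0.0
        return 100.0 * self.counts.get(label, 0) / self.n_seeds

    @property
    def inflow_ml(self) -> float:
        """Inflow = Direct Flow + Retained Inflow."""
        return self.volume_ml(ComponentLabel.DIRECT_FLOW) + self.volume_ml(
            ComponentLabel.RETAINED_INFLOW
        )

    @property
    def outflow_ml(self) -> float:
        """Outflow = Direct Flow + Delayed Ejection Flow."""
        return self.volume_ml(ComponentLabel.DIRECT_FLOW) + self.volume_ml(
            ComponentLabel.DELAYED_EJECTION
        )

    def to_dict(self) -> dict:
        comps = {}
        for lab in ComponentLabel:
            comps[LABEL_NAMES[lab]] = {
                "count": int(self.counts.get(lab, 0)),
                "volume_ml": self.volume_ml(lab),
                "percent_of_edv": self.percent_of_edv(lab),
            }
        return {
            "components": comps,
            "edv_ml": self.edv_ml,
            "n_seeds": int(self.n_seeds),
            "voxel_volume_mm3": self.voxel_volume_mm3,
            "inflow_ml": self.inflow_ml,
            "outflow_ml": self.outflow_ml,
        }


def quantify(
    labels: np.ndarray | Sequence[int],
    voxel_volume_mm3: float,
    n_seeds: int,
) -> ComponentResult:
    """Component volumes: pathline count per label times the voxel volume."""
    labels = np.asarray(labels, dtype=np.int64)
    if len(labels) != n_seeds:
        raise ValidationError(f"got {len(labels)} labels for n_seeds={n_seeds}")
    counts = {lab: int((labels == int(lab)).sum()) for lab in ComponentLabel}
    return ComponentResult(counts=counts, voxel_volume_mm3=voxel_volume_mm3, n_seeds=n_seeds)


def flow_balance(result: ComponentResult, threshold: float = 0.10) -> dict:
    """The per-study accuracy check: compare LV inflow and outflow.

    ``rel_diff = |inflow - outflow| / mean(inflow, outflow)``; the report is
    flagged when the relative difference exceeds ``threshold``.
    """
    inflow = result.inflow_ml
    outflow = result.outflow_ml
    abs_diff = abs(inflow - outflow)
    mean = 0.5 * (inflow + outflow)
    if mean == 0:
        return {
            "inflow_ml": inflow,
            "outflow_ml": outflow,
            "abs_diff_ml": abs_diff,
            "rel_diff": None,
            "flagged": True,
            "note": "both inflow and outflow are zero; relative difference undefined",
        }
    rel = abs_diff / mean
    return {
        "inflow_ml": inflow,
        "outflow_ml": outflow,
        "abs_diff_ml": abs_diff,
        "rel_diff": rel,
        "flagged": bool(rel > threshold),
    }


@dataclass
class KineticEnergyCurves:
    """Kinetic energy per component over the cycle, in microjoules.

    ``KE_c(t) = sum over pathlines in c of 0.5 * rho * |v(x_p(t), t)|^2 * V_voxel``.
    """

    times_ms: np.ndarray
    ke_microjoule: np.ndarray  # (n_labels, n_times), ordered by ComponentLabel

    def for_label(self, label: ComponentLabel) -> np.ndarray:
        return self.ke_microjoule[int(label)]

    def to_dict(self) -> dict:
        return {
            "times_ms": self.times_ms.tolist(),
            "ke_microjoule": {
                LABEL_NAMES[lab]: self.ke_microjoule[int(lab)].tolist()
                for lab in ComponentLabel
            },
        }


def kinetic_energy(
    pathlines: Sequence[Pathline],
    labels: np.ndarray | Sequence[int],
    field: VelocityField4D,
    density_kg_m3: float = 1060.0,
) -> KineticEnergyCurves:
    """Component kinetic-energy curves over the cardiac cycle.

    Each pathline's position is interpolated at every frame time within its
    span, the field is sampled there, and KE contributions are summed per
    component.  With velocity in mm/ms (= m/s) and voxel volume in mm^3,
    ``0.5 * rho * v^2 * V`` is in nanojoules * 1e3, i.e. converted to
    microjoules via the 1e-9 m^3/mm^3 factor.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if len(labels) != len(pathlines):
        raise ValidationError("labels must align with pathlines")
    frame_times = field.frame_times_ms
    n_lab = len(ComponentLabel)
    ke = np.zeros((n_lab, field.n_frames))
    if len(pathlines) == 0:
        return KineticEnergyCurves(times_ms=frame_times, ke_microjoule=ke)
    voxel_volume_m3 = field.voxel_volume_mm3 * 1e-9
    sampler = _make_sampler(field)
    cycle = field.cycle_ms

    # map each frame time into each pathline's span by cycle congruence
    all_pos = []
    all_t = []
    all_lab = []
    all_frame = []
    for p, lab in zip(pathlines, labels):
        t_lo, t_hi = p.times_ms[0], p.times_ms[-1]
        shift = np.where(frame_times > t_hi + 1e-9, frame_times - cycle, frame_times)
        shift = np.where(shift < t_lo - 1e-9, shift + cycle, shift)
        inside = (shift >= t_lo - 1e-9) & (shift <= t_hi + 1e-9)
        if not inside.any():
            continue
        tq = np.clip(shift[inside], t_lo, t_hi)
        all_pos.append(p.position_at(tq))
        all_t.append(tq)
        all_lab.append(np.full(inside.sum(), lab))
        all_frame.append(np.nonzero(inside)[0])
    pos = np.vstack(all_pos)
    tq = np.concatenate(all_t)
    labv = np.concatenate(all_lab)
    framev = np.concatenate(all_frame)
    vel, _ = sampler(pos, tq)  # mm/ms = m/s
    contrib = 0.5 * density_kg_m3 * (vel**2).sum(axis=1) * voxel_volume_m3 * 1e6  # uJ
    np.add.at(ke, (labv, framev), contrib)
    return KineticEnergyCurves(times_ms=frame_times, ke_microjoule=ke)


@dataclass
class QCReport:
    leak_fraction: float
    n_seeds: int
    n_leaks: int
    cluster_warning: bool
    dominant_exit_direction: str | None
    dominant_exit_fraction: float | None
    median_exit_spread_mm: float | None
    exit_points_mm: np.ndarray = field(repr=False, default=None)


_AXIS_NAMES = ("x", "y", "z")


def qc_leak_fraction(
    field_: VelocityField4D,
    emission_plane: BasalPlane,
    pool_mask: FlowGridMask,
    t0: float,
    t1: float,
    settings: TraceSettings | None = None,
    cluster_fraction: float = 0.5,
    min_leaks_for_warning: int = 5,
) -> QCReport:
    """Data quality control: pathlines emitted from a plane at the mitral
    annulus should never leave the blood pool.

    Seeds are the centers of pool voxels whose half-open cell straddles the
    emission plane (a regular grid at voxel spacing on the plane).  Each is
    traced over [t0, t1]; the returned fraction counts pathlines whose
    position ever leaves ``pool_mask``.  A systematic-offset warning is
    raised when the leaks exit coherently through one side of the pool
    (>= ``cluster_fraction`` of exits share the same dominant outward axis
    direction), echoing aberrant pathlines leaving the blood pool at a
    specific site.  The spread of exit points around their medoid is also
    reported.
    """
    centers_idx = np.argwhere(pool_mask.inside)
    centers = np.asarray(pool_mask.origin_mm) + centers_idx * np.asarray(pool_mask.spacing_mm)
    half = 0.5 * min(pool_mask.spacing_mm)
    d = emission_plane.signed_distance(centers)
    on_plane = (d >= -half) & (d < half)
    seeds = centers[on_plane]
    if len(seeds) == 0:
        raise ValidationError("no pool voxels on the emission plane; empty seed grid")
    if t0 == t1:
        return QCReport(0.0, len(seeds), 0, False, None, None, None, np.empty((0, 3)))
    branches = trace_batch(field_, seeds, t0, t1, settings)
    leaks = []
    exit_dirs = []
    for seed, br in zip(seeds, branches):
        inside = is_inside(pool_mask, br.positions_mm)
        if inside.all():
            continue
        i = int(np.argmin(inside))  # first position outside the pool
        exit_point = br.positions_mm[i]
        leaks.append(exit_point)
        prev = br.positions_mm[max(i - 1, 0)]
        step = exit_point - prev
        if np.linalg.norm(step) == 0:
            step = exit_point - seed
        axis = int(np.argmax(np.abs(step)))
        exit_dirs.append((axis, int(np.sign(step[axis])) or 1))
    n_leaks = len(leaks)
    frac = n_leaks / len(seeds)
    warning = False
    dominant = None
    dom_frac = None
    spread = None
    if n_leaks:
        pts = np.array(leaks)
        medoid = np.median(pts, axis=0)
        spread = float(np.median(np.linalg.norm(pts - medoid, axis=1)))
        dirs, counts = np.unique(np.array(exit_dirs), axis=0, return_counts=True)
        top = int(np.argmax(counts))
        dom_frac = counts[top] / n_leaks
        axis, sign = dirs[top]
        dominant = f"{'+' if sign > 0 else '-'}{_AXIS_NAMES[axis]}"
        warning = n_leaks >= min_leaks_for_warning and dom_frac >= cluster_fraction
    return QCReport(
        leak_fraction=frac,
        n_seeds=len(seeds),
        n_leaks=n_leaks,
        cluster_warning=warning,
        dominant_exit_direction=dominant,
        dominant_exit_fraction=dom_frac,
        median_exit_spread_mm=spread,
        exit_points_mm=np.array(leaks) if leaks else np.empty((0, 3)),
    )


def suggest_isovolumetric_times(
    field_: VelocityField4D,
    plane: BasalPlane,
    lv_mask: FlowGridMask,
    zero_flux_fraction: float = 0.05,
) -> dict:
    """Suggest t_IVC and t_IVR from the basal-plane flux curve.

    Computes the volumetric flux Q(t) through the basal plane over the LV
    footprint for every frame, finds the (cyclic) runs of near-zero |Q|
    bracketing the systolic outflow peak, and returns their midpoints.  The
    isovolumetric phases are exactly the windows with no transvalvular flow,
    so these minima are the candidate emission/endpoint times.  This is a
    helper only: the suggestion must be confirmed by the user, mirroring the
    manual determination by inspecting streamlines across the valves.

    Raises when the flux curve has no two zero-flow windows (e.g. constant
    flux), advising manual entry.
    """
    centers_idx = np.argwhere(lv_mask.inside)
    centers = np.asarray(lv_mask.origin_mm) + centers_idx * np.asarray(lv_mask.spacing_mm)
    spacing = np.asarray(lv_mask.spacing_mm)
    # LV-side voxel layer adjacent to the plane
    step = float(np.abs(spacing @ np.abs(plane.normal_mm)))
    d = plane.signed_distance(centers)
    layer = (d < 0) & (d >= -step)
    if not layer.any():
        raise ValidationError("no LV voxels adjacent to the basal plane")
    pts = centers[layer]
    # cross-sectional area represented by one voxel column through the plane
    area = lv_mask.voxel_volume_mm3 / step
    sampler = _make_sampler(field_)
    n_frames = field_.n_frames
    Q = np.empty(n_frames)
    for k, tk in enumerate(field_.frame_times_ms):
        vel, _ = sampler(pts, np.full(len(pts), tk))
        Q[k] = (vel @ plane.normal_mm).sum() * area  # mm^3/ms
    absQ = np.abs(Q)
    peak = absQ.max()
    if peak == 0:
        raise ValidationError("flux through the basal plane is zero at all frames")
    quiet = absQ <= zero_flux_fraction * peak
    if quiet.all() or not quiet.any():
        raise ValidationError(
            "flux curve has no distinct zero-flow windows; enter t_IVC/t_IVR manually"
        )
    # cyclic runs of quiet frames
    runs = []
    visited = np.zeros(n_frames, dtype=bool)
    for start in range(n_frames):
        if quiet[start] and not visited[start] and not quiet[(start - 1) % n_frames]:
            frames = []
            k = start
            while quiet[k] and not visited[k]:
                visited[k] = True
                frames.append(k)
                k = (k + 1) % n_frames
            runs.append(frames)
    if len(runs) < 2:
        raise ValidationError(
            "flux curve has fewer than two zero-flow windows; enter t_IVC/t_IVR manually"
        )
    dt = field_.dt_ms
    cycle = field_.cycle_ms

    def run_midpoint_ms(frames: list[int]) -> float:
        # middle of the run's minimal-|Q| frames (cyclic order preserved):
        # the quiet run may include asymmetric pulse tails; the true
        # isovolumetric window is where the flux actually bottoms out
        q = absQ[frames]
        lo = q.min()
        best = [i for i, v in enumerate(q) if v <= lo + 1e-12 * max(peak, 1.0)]
        mid = frames[0] + best[len(best) // 2]
        return (mid % n_frames) * dt

    # the systolic outflow peak: maximal positive flux along the basal normal
    k_peak = int(np.argmax(Q))
    # pick the quiet runs immediately before and after the peak (cyclically)
    def cyclic_gap(a: float, b: float) -> float:
        return (b - a) % cycle

    mids = [run_midpoint_ms(r) for r in runs]
    t_peak = k_peak * dt
    t_ivc = min(mids, key=lambda m: cyclic_gap(m, t_peak))
    t_ivr = min(mids, key=lambda m: cyclic_gap(t_peak, m))
    return {
        "t_ivc_ms": float(t_ivc),
        "t_ivr_ms": float(t_ivr),
        "flux_mm3_per_ms": Q,
        "frame_times_ms": field_.frame_times_ms,
    }
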