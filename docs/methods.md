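# Methods

This note documents the models, numerical choices and validation design of
`flowcomp4d`, and states what the synthetic tests do and do not show about
real data.

## Data model and conventions

Velocity fields live on a regular grid; voxel index (i, j, k) maps to the
voxel **center**; world coordinates are in millimetres. Velocity is stored
in cm/s as acquired and converted to mm/ms (×0.01) inside the samplers, so
that with time in milliseconds all integrator arithmetic is unit-uniform
(1 mm/ms = 1 m/s). Time runs from cycle start with frame k sampled at
k·T/N (T the RR interval, N the frame count) and is periodic by contract:
retrospectively gated reconstruction closes the cycle, so frame N−1 wraps
to frame 0. Segmentation masks are short-axis slice stacks on their own
grid with a 4×4 affine; an explicit `slice_direction` flag declares whether
the slice index increases apex→base or base→apex, which fixes the meaning
of "basal of" unambiguously.

Two storage dialects are supported (per-frame NIfTI volumes + YAML sidecar,
or a single HDF5 file) so that round-trips are bit-exact and testable;
scanner exports are site-specific and out of scope, as is DICOM ingestion.

## Velocity post-processing

**Phase unwrap.** Phase-contrast velocities alias by multiples of 2·VENC.
The correction is temporal-only: sweeping frames forward from frame 0, each
sample is shifted by the integer multiple of 2·VENC that minimizes the jump
to its already-corrected temporal predecessor. This restores any aliased
sample whose true consecutive-frame change is below VENC, and is idempotent
on wrap-free data. A voxel aliased identically at every frame produces no
temporal jump and is undetectable by construction — a documented
limitation; spatial unwrapping is not attempted.

**Background offset.** Eddy currents leave a slowly varying spatial offset
in the measured velocities. Per time frame and per velocity component, a
trivariate polynomial of total degree ≤ 4 (35 terms) is fitted by weighted
least squares over the grid, with coordinates normalized to [−1, 1]³ for
conditioning (coefficients are reported in normalized space together with
the affine map). The static-tissue weight is

    w = m̄_norm · exp(−s² / (2 σ₀²)),

where m̄_norm is the time-averaged signal magnitude rescaled to [0, 1] by
its 95th percentile (clipped) and s is the temporal standard deviation of
speed. The multiplicative Gaussian form is this package's definition: it is
monotone in both ingredients, bounded and differentiable; σ₀ defaults to
2 cm/s and is configurable, as is the combination strategy in principle.
The fit is solved by `scipy.linalg.lstsq` on the √w-scaled design with an
explicit rank check (coplanar weighted voxels are rejected with a
diagnostic). Weighted least squares is exactly unbiased under zero-mean
noise; the test suite verifies noiseless recovery to 1e-8 relative error
and Monte-Carlo unbiasedness at the 3-sigma confidence level via a joint
chi-square over the standardized coefficient means.

A practical caveat the tests make visible: when blood moves barely faster
than σ₀, slow flow receives non-negligible static-tissue weight and the
polynomial partially absorbs it. The default analysis therefore leaves the
correction off unless magnitude data are provided and the user enables it.

## Geometry

Masks are resampled to the flow grid by voxel-center containment (nearest
neighbor in mask index space). Membership must be binary and exactly
consistent with seeding — pathlines are emitted from voxel centers — which
rules out fractional partial-volume schemes. Deterministic tie rules: a
point belongs to the half-open voxel cell [center − s/2, center + s/2)
(lower-inclusive); a point exactly on the basal plane is **not** basal
(ties break apically). The basal plane passes through the basal face of the
most basal slice (slice center shifted half a slice thickness toward the
base) with unit normal along the stack axis toward the base; it is a single
infinite plane — pathlines basal of it are "out of the LV" regardless of
lateral position. Both phases are resampled to the flow grid for symmetry.
Nearest-neighbor resampling converges to the mask's own discrete volume as
the flow grid is refined; the segmentation's slice discretization itself is
an input, not something resampling can undo.

## Pathline integration

Sampling is trilinear in space between voxel centers and linear in periodic
time; outside the voxel-center bounding box the field is zero and the trace
is frozen and flagged truncated (the classifier then excludes it). Cubic
space-time interpolation is available but off by default: the data are C⁰
and the integrator's benefit is limited accordingly.

Integration is classic RK4 with step-doubling error control: step h is
accepted when the two-half-steps and full-step solutions agree within
`rel_tol_mm` (default 0.3 mm, a tenth of a 3 mm voxel); otherwise h is
halved, with a floor (`min_step_ms`, default 0.1 ms) at which the step is
accepted regardless — shrinking further buys nothing against C⁰ data. After
five consecutive accepts h grows by 1.5×, capped at the frame spacing. The
accepted position is the more accurate two-half-steps composite; plain
Richardson extrapolation is deliberately not applied because its h⁴ error
model fails at the field's temporal kinks. A fixed-step mode
(`fixed_step_ms`) disables adaptivity for convergence studies; measured
convergence order on a solid-body rotation (linear in space, hence
represented exactly by trilinear interpolation) is 4.0.

Backward tracing integrates dx/dt = v(x, t) with decreasing t — no field
negation — and all sampler times are wrapped into [0, T). The full-cycle
trace runs forward from t_IVC to the first time ≥ t_IVC congruent to t_IVR
(mod T), and backward to the time one cycle earlier, so every pathline
spans exactly one cycle with t_IVC interior. Tracing is deterministic:
identical inputs give bit-identical trajectories, and the pathline count
always equals the seed count (truncation flags, never dropped records).

## Classification and quantification

Labels are decided by the **endpoint state at the two IVR times** (not
first crossing): basal-of-plane tests decide "left the LV", and for
non-basal endpoints an inside-IVR-volume test separates LV blood from
excluded traces. A first basal-crossing time is additionally recorded per
pathline to support future regurgitation detection. A pathline that exits
basally and re-enters before IVR is labeled by its final state — the
endpoint rule resolves this case deterministically.

Percentages use total flow-derived EDV (all seeds) as denominator, with the
excluded percentage reported alongside, so the four components need not sum
to 100% when traces were excluded; exclusion stays visible instead of being
silently redistributed. The inflow/outflow report computes
|in − out| / mean(in, out) and flags above a configurable threshold
(default 10%). Kinetic energy uses blood density 1060 kg/m³ (configurable);
with velocity in mm/ms (= m/s) and voxel volume in mm³ the per-pathline
term ½ρv²V converts to microjoules via the 10⁻⁹ m³/mm³ factor.

**QC.** Seeds on a plane at the mitral annulus (pool voxels whose cell
straddles the plane, i.e. a grid at voxel spacing) are traced over a
window; the leak fraction counts pathlines that ever leave the blood pool.
The systematic-offset warning fires when ≥ 50% of leaks exit through the
same dominant outward axis direction of the pool boundary: a uniform
velocity offset drives exits coherently through one wall, whereas
noise-driven leaks scatter isotropically. (A literal "within one
voxel-diameter blob" criterion cannot fire for a uniform offset, whose
exits spread along the whole wall; the directional rule detects exactly the
"specific exit site" pattern the check exists for.) The median exit spread
about the exit medoid is reported alongside.

**Timing helper.** The basal-plane volumetric flux Q(t) over the LV
footprint is computed per frame; the isovolumetric phases are the (cyclic)
near-zero-|Q| windows bracketing the systolic outflow peak, and the helper
returns the midpoints of their minimal-flux frames. It never feeds the
pipeline silently: the suggestion is written out and must be confirmed as
an explicit config value.

## The LV phantom

The phantom is kinematic — a prescribed velocity program, not CFD — because
ground truth must be exact by construction and the method consumes velocity
fields regardless of physical origin. A box chamber (48 mm square
footprint; depth snapped to whole mask slices so EDV ≈ 146 mL → 5376 seeds
at 3 mm) sits below a basal plane with its apertures on the basal face. The
cross-section is partitioned into z-columns ordered by distance from the
center — direct flow innermost like the transmitral jet core, residual
volume at the periphery — with counts matching the programmed fractions
(default 30/18/17/35 %) by largest remainder, so realized fractions deviate
by at most half a column. Flow is purely axial, v = (0, 0, v_z(x, y, t)):
exactly divergence-free, and particles launched at voxel centers never
leave their column, so trajectories are closed-form.

The cycle (1000 ms, 40 frames, t_IVC = 0, t_IVR = 350 ms) has sin²-shaped
ejection and inflow pulses inside frame-aligned windows ([25, 325] and
[375, 975] ms) with 25 ms quiet margins around both isovolumetric times.
Frame alignment matters: the discrete trapezoid integral of a sampled sin²
pulse over a whole window equals the analytic value exactly, and RK4 steps
that land on frame times integrate the piecewise-linear-in-time field with
machine-precision accuracy. Pulse amplitudes are set from the programmed
displacements (ejection stroke = chamber depth + one lattice unit,
66 mm → 44 cm/s peak; inflow stroke = chamber depth, 63 mm → 21 cm/s peak;
both safely below VENC 100 cm/s), so classification margins are exact
arithmetic (≥ half a voxel), not statistical accidents. The QC blood-pool
mask adds a one-voxel "sump" layer below the apex so basal-plane QC seeds
riding the full inflow stroke stay inside the pool. Magnitude frames are
bright over blood and the tissue slab below the base and dim in air, which
exercises the static-tissue weighting. Optional Gaussian velocity noise
(default 0) is driven by a single recorded integer seed.

Ground truth comes from an independent oracle: fixed-step classical RK4 at
step = frame spacing / 100, built on `scipy.interpolate.
RegularGridInterpolator` over the padded space-time grid — a fully separate
code path from the adaptive tracer — with endpoint classification done by
direct arithmetic on the phantom's analytic geometry. A `programmed` truth
mode returns the analytic column labels without tracing; on noiseless
phantoms the two agree exactly, and the cheap mode keeps the
high-resolution (1.5 mm / 80 frame, 43 008 seed) convergence run inside a
practical time budget.

**What the phantom does not emulate:** deforming walls and valve geometry,
realistic jet profiles and vortices, partial-volume and intravoxel
dephasing, misregistration between morphological and flow data, and
measurement noise correlated with anatomy. Passing these tests shows the
*analysis chain* is correct and self-consistent — integration, geometry,
bookkeeping, conservation — not that any in-vivo acquisition meets its
assumptions; the per-study inflow/outflow check exists precisely because
real data must earn that trust each time.

## Problem sizes and runtime

Default validation runs use the 3 mm / 40-frame phantom (5376 pathlines,
oracle at 0.25 ms steps) plus one 1.5 mm / 80-frame fraction-recovery run;
the full suite completes in a few minutes on one CPU. The Monte-Carlo
unbiasedness study uses 100 repetitions on a 10³ grid at noise σ = 5 cm/s.

## Known limitations

- Temporal-only unwrapping misses constant (all-frame) aliasing.
- Static-tissue weights discriminate poorly when blood speed is comparable
  to σ₀; background correction is therefore opt-in.
- The endpoint classification rule attributes basally-exited-and-returned
  blood by final position; with valve regurgitation the recorded
  first-crossing times would be the starting point for a correction, which
  is not implemented.
- Exclusion uses the IVR volume only; no deformable LV boundary between IVC
  and IVR is modeled.
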