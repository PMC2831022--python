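"""Velocity post-processing: temporal phase-wrap correction and weighted
4th-order polynomial background-offset correction fitted to static tissue.

Phase-contrast velocities alias by multiples of 2*VENC; cine data allow a
temporal unwrap because true blood velocity rarely jumps by more than VENC
between consecutive frames.  Eddy currents and other system imperfections
add a slowly varying spatial offset to the measured velocities; this offset
is estimated per time frame and per velocity component as a trivariate
polynomial of total degree <= 4, fitted by weighted least squares where the
weights favour static tissue.  The static-tissue weight combines the
time-averaged signal magnitude (high where there is tissue) with the
temporal standard deviation of speed (low where nothing moves):

    w = m_norm * exp(-s^2 / (2 * sigma0^2))

with m_norm the time-averaged magnitude rescaled to [0, 1] by its 95th
percentile (clipped) and sigma0 = 2 cm/s by default.  Coordinates are
normalized to [-1, 1]^3 for conditioning; coefficients are stored in the
normalized frame together with the affine normalization map.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import scipy.linalg

from .io import MagnitudeField4D, ValidationError, VelocityField4D

__all__ = [
    "StaticTissueWeights",
    "BackgroundModel",
    "unwrap_phase",
    "compute_static_weights",
    "polynomial_exponents",
    "fit_background",
    "apply_correction",
]


@dataclass
class StaticTissueWeights:
    """Per-voxel static-tissue confidence in [0, 1], time-independent."""

    weights: np.ndarray  # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise ValidationError("weights must be 3-D")
        if not np.isfinite(self.weights).all():
            raise ValidationError("weights must be finite")
        if (self.weights < 0).any() or (self.weights > 1).any():
            raise ValidationError("weights must lie in [0, 1]")
        if not (self.weights > 0).any():
            raise ValidationError("weights are all zero")


def polynomial_exponents(degree: int) -> np.ndarray:
    """All (px, py, pz) with px+py+pz <= degree, in a fixed deterministic order."""
    return np.array(
        [e for e in product(range(degree + 1), repeat=3) if sum(e) <= degree],
        dtype=np.int64,
    )


@dataclass
class BackgroundModel:
    """Per-frame, per-component polynomial background offset.

    ``coeffs`` has shape (n_frames, 3, n_terms) with terms ordered as
    :func:`polynomial_exponents`; coordinates are normalized by
    ``x_norm = (x - center) / halfwidth`` mapping the grid bounding box to
    [-1, 1]^3.  For degree 4 there are C(4+3, 3) = 35 terms per component
    per frame.
    """

    degree: int
    coeffs: np.ndarray
    center_mm: np.ndarray
    halfwidth_mm: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        n_terms = len(polynomial_exponents(self.degree))
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != 3 or self.coeffs.shape[2] != n_terms:
            raise ValidationError(
                f"coeffs must have shape (n_frames, 3, {n_terms}), got {self.coeffs.shape}"
            )
        if not np.isfinite(self.coeffs).all():
            raise ValidationError("non-finite model coefficients")
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        self.halfwidth_mm = np.asarray(self.halfwidth_mm, dtype=float).reshape(3)

    @property
    def exponents(self) -> np.ndarray:
        return polynomial_exponents(self.degree)

    def design_matrix(self, points_mm: np.ndarray) -> np.ndarray:
        """Vandermonde matrix of the normalized monomials at world points."""
        pts = (np.atleast_2d(points_mm) - self.center_mm) / self.halfwidth_mm
        exps = self.exponents
        # product over axes of coordinate^exponent
        return (
            pts[:, 0][:, None] ** exps[:, 0]
            * pts[:, 1][:, None] ** exps[:, 1]
            * pts[:, 2][:, None] ** exps[:, 2]
        )

    def evaluate(self, points_mm: np.ndarray, frame: int) -> np.ndarray:
        """Offset (cm/s, shape (N, 3)) at world points for one time frame."""
        X = self.design_matrix(points_mm)
        return X @ self.coeffs[frame].T


def unwrap_phase(field: VelocityField4D) -> VelocityField4D:
    """Temporal phase unwrap, sweeping frames forward from frame 0.

    For each voxel and component, each frame's value is shifted by the
    integer multiple of 2*VENC that minimizes the jump to its (already
    corrected) temporal predecessor.  Idempotent on wrap-free data.  A value
    wrapped identically at every frame produces no temporal jump and cannot
    be detected — a documented limitation of temporal-only unwrapping.
    """
    venc = field.venc_cm_s
    v = field.velocity.copy()
    for k in range(1, field.n_frames):
        delta = v[k - 1] - v[k]
        n_wraps = np.round(delta / (2.0 * venc))
        v[k] += 2.0 * venc * n_wraps
    return field.with_velocity(v)


def compute_static_weights(
    velocity: VelocityField4D,
    magnitude: MagnitudeField4D,
    sigma0_cm_s: float = 2.0,
    magnitude_percentile: float = 95.0,
) -> StaticTissueWeights:
    """Static-tissue weights from signal magnitude and temporal velocity spread."""
    magnitude.assert_paired(velocity)
    mbar = magnitude.magnitude.mean(axis=0)
    scale = np.percentile(mbar, magnitude_percentile)
    if scale <= 0:
        raise ValidationError("magnitude is zero everywhere")
    m_norm = np.clip(mbar / scale, 0.0, 1.0)
    speed = np.linalg.norm(velocity.velocity, axis=-1)  # (nt, nx, ny, nz), cm/s
    s = speed.std(axis=0)
    w = m_norm * np.exp(-(s**2) / (2.0 * sigma0_cm_s**2))
    return StaticTissueWeights(weights=w)


def _grid_points(field: VelocityField4D) -> np.ndarray:
    nx, ny, nz = field.dims
    ox, oy, oz = field.origin_mm
    sx, sy, sz = field.spacing_mm
    X, Y, Z = np.meshgrid(
        ox + sx * np.arange(nx),
        oy + sy * np.arange(ny),
        oz + sz * np.arange(nz),
        indexing="ij",
    )
    return np.c_[X.ravel(), Y.ravel(), Z.ravel()]


def fit_background(
    field: VelocityField4D,
    weights: StaticTissueWeights,
    degree: int = 4,
) -> BackgroundModel:
    """Weighted least-squares polynomial fit of the background offset,
    independently per time frame and per velocity component."""
    if not 0 <= degree <= 4:
        raise ValidationError("degree must be in {0..4}")
    if weights.weights.shape != field.dims:
        raise ValidationError("weights geometry does not match field")
    exps = polynomial_exponents(degree)
    n_terms = len(exps)
    w = weights.weights.ravel()
    sel = w > 0
    if sel.sum() < n_terms:
        raise ValidationError(
            f"only {int(sel.sum())} voxels with positive weight; need >= {n_terms}"
        )
    pts = _grid_points(field)
    center = 0.5 * (field.bbox_min_mm + field.bbox_max_mm)
    halfwidth = np.maximum(0.5 * (field.bbox_max_mm - field.bbox_min_mm), 1e-12)
    model = BackgroundModel(
        degree=degree,
        coeffs=np.zeros((field.n_frames, 3, n_terms)),
        center_mm=center,
        halfwidth_mm=halfwidth,
    )
    X = model.design_matrix(pts[sel])
    sw = np.sqrt(w[sel])[:, None]
    Xw = X * sw
    rank = np.linalg.matrix_rank(Xw)
    if rank < n_terms:
        raise ValidationError(
            f"rank-deficient background design: rank {rank} < {n_terms} terms "
            "(weighted voxels do not span the polynomial space; e.g. all coplanar)"
        )
    vel = field.velocity.reshape(field.n_frames, -1, 3)
    for k in range(field.n_frames):
        rhs = vel[k][sel] * sw  # (n_sel, 3)
        sol, *_ = scipy.linalg.lstsq(Xw, rhs, lapack_driver="gelsd")
        model.coeffs[k] = sol.T
    return model


def apply_correction(field: VelocityField4D, model: BackgroundModel) -> VelocityField4D:
    """Subtract the background model at every voxel center, every frame."""
    pts = _grid_points(field)
    X = model.design_matrix(pts)
    if model.coeffs.shape[0] != field.n_frames:
        raise ValidationError("model frame count does not match field")
    v = field.velocity.copy()
    nvox = X.shape[0]
    if v.reshape(field.n_frames, -1, 3).shape[1] != nvox:
        raise ValidationError("model geometry does not match field")
    for k in range(field.n_frames):
        offset = X @ model.coeffs[k].T  # (nvox, 3)
        v[k] -= offset.reshape(field.dims + (3,))
    return field.with_velocity(v)
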