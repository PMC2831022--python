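"""Geometric constraints: masks on the flow grid, the basal plane, and
inside/outside and basal/apical queries.

The segmentation masks (short-axis slice stacks) live on their own grid; the
analysis needs them on the velocity-field grid.  Rasterization is by voxel
*center* containment (nearest neighbor in mask index space): this keeps
membership binary and exactly consistent with seeding, which emits one
pathline from the center of each inside voxel.

Tie rules, stated once and used everywhere so classification is
deterministic:

* a world point belongs to the flow voxel whose half-open cell
  ``[center - s/2, center + s/2)`` contains it (lower-inclusive);
* a point exactly on the basal plane is *not* basal (ties break apically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SegmentationMask, ValidationError, VelocityField4D

__all__ = [
    "FlowGridMask",
    "BasalPlane",
    "rasterize_mask",
    "basal_plane_from_mask",
    "is_inside",
    "is_basal_of",
]


@dataclass
class FlowGridMask:
    """A binary mask resampled onto the flow grid."""

    inside: np.ndarray  # bool (nx, ny, nz)
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside).astype(bool)
        if self.inside.ndim != 3:
            raise ValidationError("FlowGridMask.inside must be 3-D")
        if not self.inside.any():
            raise ValidationError("FlowGridMask has no inside voxels")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)  # type: ignore[assignment]
        self.origin_mm = tuple(float(s) for s in self.origin_mm)  # type: ignore[assignment]

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.inside.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    @property
    def volume_ml(self) -> float:
        """Flow-derived volume of this phase in mL."""
        return self.n_inside * self.voxel_volume_mm3 / 1000.0

    def world_to_voxel_index(self, p: np.ndarray) -> np.ndarray:
        """Half-open (lower-inclusive) voxel ownership of world points."""
        p = np.atleast_2d(np.asarray(p, dtype=float))
        rel = (p - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)
        return np.floor(rel + 0.5).astype(np.int64)


@dataclass
class BasalPlane:
    """The plane of the most basal short-axis slice's basal face.

    ``normal_mm`` is a unit vector pointing from the LV toward the base
    (atrium/aorta side); crossing the plane along the normal means leaving
    the LV "the physiological way" through a valve.
    """

    point_mm: np.ndarray
    normal_mm: np.ndarray

    def __post_init__(self) -> None:
        self.point_mm = np.asarray(self.point_mm, dtype=float).reshape(3)
        self.normal_mm = np.asarray(self.normal_mm, dtype=float).reshape(3)
        n = np.linalg.norm(self.normal_mm)
        if not np.isfinite(n) or n == 0:
            raise ValidationError("basal plane normal must be nonzero")
        self.normal_mm = self.normal_mm / n

    def signed_distance(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return (p - self.point_mm) @ self.normal_mm


def rasterize_mask(mask: SegmentationMask, target: VelocityField4D) -> FlowGridMask:
    """Resample a segmentation mask onto the flow grid.

    A flow voxel is inside iff its center maps into a true mask voxel
    (nearest neighbor in mask index space).  Raises if the mask does not
    overlap the flow field of view.
    """
    nx, ny, nz = target.dims
    sx, sy, sz = target.spacing_mm
    ox, oy, oz = target.origin_mm
    xs = ox + sx * np.arange(nx)
    ys = oy + sy * np.arange(ny)
    zs = oz + sz * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    centers = np.c_[X.ravel(), Y.ravel(), Z.ravel()]
    idx = mask.world_to_index(centers)
    nn = np.floor(idx + 0.5).astype(np.int64)  # nearest mask voxel, lower-inclusive ties
    dims = np.asarray(mask.dims)
    in_bounds = ((nn >= 0) & (nn < dims)).all(axis=1)
    inside = np.zeros(len(centers), dtype=bool)
    valid = nn[in_bounds]
    inside[in_bounds] = mask.voxels[valid[:, 0], valid[:, 1], valid[:, 2]]
    if not inside.any():
        raise ValidationError("mask does not overlap the flow field of view")
    return FlowGridMask(
        inside=inside.reshape(nx, ny, nz),
        spacing_mm=target.spacing_mm,
        origin_mm=target.origin_mm,
    )


def basal_plane_from_mask(mask: SegmentationMask) -> BasalPlane:
    """Plane through the basal face of the basal slice.

    The plane point is the basal-slice stack-axis position shifted half a
    slice thickness toward the base; the normal is the slice-stack axis
    oriented toward the base.
    """
    # stack axis in world space: image of a unit step along the slice index
    axis = mask.affine[:3, 2].astype(float)
    axis_unit = axis / np.linalg.norm(axis)
    if mask.slice_direction == "base_to_apex":
        base_dir = -axis_unit  # index increases toward apex
    else:
        base_dir = axis_unit
    # center of the basal slice (any in-plane position works; use (0,0))
    center = mask.index_to_world([0.0, 0.0, float(mask.basal_slice_index)])[0]
    point = center + base_dir * (mask.slice_thickness_mm / 2.0)
    return BasalPlane(point_mm=point, normal_mm=base_dir)


def is_inside(fgm: FlowGridMask, p: np.ndarray) -> bool | np.ndarray:
    """True iff the flow voxel owning ``p`` exists and is inside.

    Points outside the grid are outside.  Accepts a single point or an
    (N, 3) array.
    """
    single = np.ndim(p) == 1
    nn = fgm.world_to_voxel_index(p)
    dims = np.asarray(fgm.dims)
    in_bounds = ((nn >= 0) & (nn < dims)).all(axis=1)
    out = np.zeros(len(nn), dtype=bool)
    valid = nn[in_bounds]
    out[in_bounds] = fgm.inside[valid[:, 0], valid[:, 1], valid[:, 2]]
    return bool(out[0]) if single else out


def is_basal_of(plane: BasalPlane, p: np.ndarray) -> bool | np.ndarray:
    """True iff ``p`` is strictly on the basal side of the plane.

    Points exactly on the plane are NOT basal.
    """
    single = np.ndim(p) == 1
    d = plane.signed_distance(np.atleast_2d(p))
    out = d > 0
    return bool(out[0]) if single else out
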