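"""Data model and file I/O for 4D flow velocity data, LV masks, pathlines and results.

The in-memory containers defined here are shared by every other module:

* :class:`VelocityField4D` — a three-directional velocity field sampled on a
  regular grid over one (cyclic) cardiac cycle, as reconstructed from 3D cine
  phase-contrast CMR.
* :class:`MagnitudeField4D` — the co-registered signal-magnitude frames.
* :class:`SegmentationMask` — a binary LV blood-pool segmentation given as a
  stack of short-axis slices with a designated basal slice.
* :class:`Pathline` — one seed's trajectory over a full cardiac cycle
  (backward branch through diastole + forward branch through systole).
* :class:`AnalysisConfig` — analysis timing and physical constants.

Two storage dialects are supported for velocity/magnitude data: a directory
of per-frame, per-component NIfTI volumes with a YAML sidecar ("dialect A"),
and a single HDF5 file ("dialect B").  Masks are NIfTI + YAML sidecar.
Pathlines are exported as VTK legacy ASCII polydata so that standard
visualization tools can load them.  Results go to JSON plus a CSV table.

Conventions: world coordinates in millimetres; voxel index (i, j, k) maps to
the voxel *center*; time in milliseconds from cycle start, with frame k
sampled at k * cycle_ms / n_frames and periodic wrap-around; velocity is
stored in cm/s as acquired (1 cm/s = 0.01 mm/ms).
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "CM_S_TO_MM_MS",
    "VelocityField4D",
    "MagnitudeField4D",
    "SegmentationMask",
    "Pathline",
    "AnalysisConfig",
    "ValidationError",
    "read_velocity_dataset",
    "write_velocity_dataset",
    "read_magnitude_dataset",
    "read_mask",
    "write_mask",
    "export_pathlines",
    "read_pathlines",
    "write_results",
    "read_results",
]

#: 1 cm/s expressed in mm/ms.
CM_S_TO_MM_MS = 0.01


class ValidationError(ValueError):
    """Raised when a file or container violates its declared contract."""


def _as_triple(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValidationError(f"{name} must have length 3, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class VelocityField4D:
    """Time-resolved three-directional velocity field on a regular grid.

    Parameters
    ----------
    velocity:
        Array of shape ``(n_frames, nx, ny, nz, 3)`` in cm/s, component
        order (x, y, z) in world axes.
    spacing_mm, origin_mm:
        Grid geometry; ``origin_mm`` is the world position of the center of
        voxel (0, 0, 0).
    cycle_ms:
        RR interval; frame k is sampled at ``k * cycle_ms / n_frames`` and
        time is periodic (sampling at t and t + cycle_ms is identical).
    venc_cm_s:
        Velocity-encoding range of the acquisition.
    """

    velocity: np.ndarray
    spacing_mm: tuple[float, float, float]
    cycle_ms: float
    venc_cm_s: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValidationError(
                f"velocity must have shape (n_frames, nx, ny, nz, 3), got {self.velocity.shape}"
            )
        if self.velocity.shape[0] < 2:
            raise ValidationError("n_frames must be >= 2")
        bad = ~np.isfinite(self.velocity)
        if bad.any():
            frame = int(np.argwhere(bad)[0, 0])
            raise ValidationError(f"non-finite velocity values in frame {frame}")
        self.spacing_mm = _as_triple(self.spacing_mm, "spacing_mm")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing_mm must be positive, got {self.spacing_mm}")
        self.origin_mm = _as_triple(self.origin_mm, "origin_mm")
        self.cycle_ms = float(self.cycle_ms)
        self.venc_cm_s = float(self.venc_cm_s)
        if self.cycle_ms <= 0:
            raise ValidationError("cycle_ms must be positive")
        if self.venc_cm_s <= 0:
            raise ValidationError("venc_cm_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.velocity.shape[1:4]

    @property
    def dt_ms(self) -> float:
        """Frame spacing in ms."""
        return self.cycle_ms / self.n_frames

    @property
    def frame_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ms

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def bbox_min_mm(self) -> np.ndarray:
        """Lower corner of the voxel-center bounding box."""
        return np.asarray(self.origin_mm, dtype=float)

    @property
    def bbox_max_mm(self) -> np.ndarray:
        """Upper corner of the voxel-center bounding box."""
        return self.bbox_min_mm + (np.asarray(self.dims) - 1) * np.asarray(self.spacing_mm)

    def same_geometry(self, other) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def with_velocity(self, velocity: np.ndarray) -> "VelocityField4D":
        return replace(self, velocity=velocity)


@dataclass
class MagnitudeField4D:
    """Signal-magnitude frames sharing the geometry of a velocity field."""

    magnitude: np.ndarray  # (n_frames, nx, ny, nz), arbitrary units, >= 0
    spacing_mm: tuple[float, float, float]
    cycle_ms: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        if self.magnitude.ndim != 4:
            raise ValidationError(
                f"magnitude must have shape (n_frames, nx, ny, nz), got {self.magnitude.shape}"
            )
        if not np.isfinite(self.magnitude).all():
            raise ValidationError("non-finite magnitude values")
        if (self.magnitude < 0).any():
            raise ValidationError("magnitude must be non-negative")
        self.spacing_mm = _as_triple(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_triple(self.origin_mm, "origin_mm")
        self.cycle_ms = float(self.cycle_ms)

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.magnitude.shape[1:4]

    def assert_paired(self, vel: VelocityField4D) -> None:
        """Check geometry identity with the paired velocity field."""
        if self.dims != vel.dims or self.n_frames != vel.n_frames:
            raise ValidationError(
                f"magnitude geometry {self.dims}x{self.n_frames} does not match "
                f"velocity {vel.dims}x{vel.n_frames}"
            )
        if not (
            np.allclose(self.spacing_mm, vel.spacing_mm)
            and np.allclose(self.origin_mm, vel.origin_mm)
        ):
            raise ValidationError("magnitude grid geometry does not match velocity field")


#: Allowed values of SegmentationMask.slice_direction: the anatomical
#: direction in which the slice index increases.
SLICE_DIRECTIONS = ("base_to_apex", "apex_to_base")


@dataclass
class SegmentationMask:
    """Binary LV blood-pool mask: a stack of short-axis slices.

    The third voxel index is the slice index.  ``slice_direction`` declares
    whether that index increases from base toward apex or the reverse, which
    fixes the meaning of "basal of".  ``affine`` maps voxel indices (at voxel
    centers) to world mm.
    """

    voxels: np.ndarray  # bool (ni, nj, n_slices)
    in_plane_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    affine: np.ndarray  # 4x4
    basal_slice_index: int
    slice_direction: str
    phase_label: str  # "IVC" | "IVR"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError("mask voxels must be 3-D")
        if not self.voxels.any():
            raise ValidationError("empty mask")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        self.in_plane_spacing_mm = tuple(float(s) for s in self.in_plane_spacing_mm)  # type: ignore[assignment]
        if len(self.in_plane_spacing_mm) != 2 or any(s <= 0 for s in self.in_plane_spacing_mm):
            raise ValidationError("in_plane_spacing_mm must be a positive pair")
        self.slice_thickness_mm = float(self.slice_thickness_mm)
        if self.slice_thickness_mm <= 0:
            raise ValidationError("slice_thickness_mm must be positive")
        self.basal_slice_index = int(self.basal_slice_index)
        n_slices = self.voxels.shape[2]
        if not 0 <= self.basal_slice_index < n_slices:
            raise ValidationError(
                f"basal_slice_index {self.basal_slice_index} outside slice range [0, {n_slices})"
            )
        if self.slice_direction not in SLICE_DIRECTIONS:
            raise ValidationError(
                f"slice_direction must be one of {SLICE_DIRECTIONS}, got {self.slice_direction!r}"
            )
        if self.phase_label not in ("IVC", "IVR"):
            raise ValidationError(f"phase_label must be 'IVC' or 'IVR', got {self.phase_label!r}")
        # every true voxel must lie at or apical of the basal slice
        ks = np.unique(np.argwhere(self.voxels)[:, 2])
        if self.slice_direction == "base_to_apex":
            basal_of = ks < self.basal_slice_index
        else:  # apex_to_base: higher index is more basal
            basal_of = ks > self.basal_slice_index
        if basal_of.any():
            raise ValidationError(
                "mask contains true voxels basal of basal_slice_index "
                f"(slices {ks[basal_of].tolist()})"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ homog.T).T[:, :3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        homog = np.c_[xyz, np.ones(len(xyz))]
        return (inv @ homog.T).T[:, :3]


@dataclass
class Pathline:
    """One seed's trajectory over a full cardiac cycle.

    Times cover ``[t_ivr_previous, t_ivr]`` with ``t_ivc`` interior (the
    backward branch is stored reversed so that times are strictly
    increasing).  Times on the backward branch may be negative — they are
    ordinary clock times of the previous cycle; the velocity field is
    periodic so only ``t mod cycle_ms`` matters for sampling.
    """

    seed_id: int
    seed_position_mm: np.ndarray
    times_ms: np.ndarray
    positions_mm: np.ndarray
    truncated_backward: bool = False
    truncated_forward: bool = False

    def __post_init__(self) -> None:
        self.seed_position_mm = np.asarray(self.seed_position_mm, dtype=float).reshape(3)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if self.positions_mm.shape != (len(self.times_ms), 3):
            raise ValidationError("positions_mm must align with times_ms")
        if len(self.times_ms) >= 2 and not (np.diff(self.times_ms) > 0).all():
            raise ValidationError("pathline times must be strictly increasing")

    @property
    def start_position(self) -> np.ndarray:
        """Position at the previous IVR (backward-branch endpoint)."""
        return self.positions_mm[0]

    @property
    def end_position(self) -> np.ndarray:
        """Position at IVR (forward-branch endpoint)."""
        return self.positions_mm[-1]

    def position_at(self, t_ms: float | np.ndarray) -> np.ndarray:
        """Linearly interpolated position(s) at time(s) within the span."""
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        out = np.empty((len(t), 3))
        for a in range(3):
            out[:, a] = np.interp(t, self.times_ms, self.positions_mm[:, a])
        return out if np.ndim(t_ms) else out[0]


@dataclass
class AnalysisConfig:
    """Timing and physical constants of one analysis."""

    t_ivc_ms: float
    t_ivr_ms: float
    blood_density_kg_m3: float = 1060.0
    flow_balance_threshold: float = 0.10

    def validate(self, cycle_ms: float) -> None:
        if not (0 <= self.t_ivc_ms < cycle_ms and 0 <= self.t_ivr_ms < cycle_ms):
            raise ValidationError(
                f"t_ivc/t_ivr must lie in [0, {cycle_ms}), got {self.t_ivc_ms}, {self.t_ivr_ms}"
            )
        if self.t_ivc_ms == self.t_ivr_ms:
            raise ValidationError("t_ivc_ms and t_ivr_ms must differ")
        if self.blood_density_kg_m3 <= 0:
            raise ValidationError("blood_density_kg_m3 must be positive")


# ---------------------------------------------------------------------------
# Velocity / magnitude datasets
# ---------------------------------------------------------------------------

_COMPONENT_NAMES = ("x", "y", "z")


def _nifti_affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing_mm)
    aff[:3, 3] = origin_mm
    return aff


def write_velocity_dataset(
    field: VelocityField4D,
    path: str | os.PathLike,
    format: str = "nifti",
    magnitude: MagnitudeField4D | None = None,
) -> Path:
    """Write a velocity (and optionally magnitude) dataset.

    ``format='nifti'`` (dialect A): one ``.nii.gz`` per (frame, component)
    named ``vel_t{k:03d}_{x|y|z}.nii.gz`` plus a ``dataset.yaml`` sidecar.
    ``format='hdf5'`` (dialect B): a single HDF5 file with datasets
    ``/velocity`` and optionally ``/magnitude`` and geometry attributes.
    """
    path = Path(path)
    if format == "nifti":
        import nibabel as nib

        path.mkdir(parents=True, exist_ok=True)
        aff = _nifti_affine(field.spacing_mm, field.origin_mm)
        for k in range(field.n_frames):
            for c, cname in enumerate(_COMPONENT_NAMES):
                img = nib.Nifti1Image(
                    np.ascontiguousarray(field.velocity[k, :, :, :, c]), aff
                )
                nib.save(img, path / f"vel_t{k:03d}_{cname}.nii.gz")
            if magnitude is not None:
                img = nib.Nifti1Image(np.ascontiguousarray(magnitude.magnitude[k]), aff)
                nib.save(img, path / f"mag_t{k:03d}.nii.gz")
        sidecar = {
            "n_frames": field.n_frames,
            "cycle_ms": field.cycle_ms,
            "venc_cm_s": field.venc_cm_s,
            "spacing_mm": list(field.spacing_mm),
            "origin_mm": list(field.origin_mm),
            "has_magnitude": magnitude is not None,
        }
        with open(path / "dataset.yaml", "w") as fh:
            yaml.safe_dump(sidecar, fh)
        return path
    if format == "hdf5":
        import h5py

        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as h5:
            h5.create_dataset("velocity", data=field.velocity)
            if magnitude is not None:
                h5.create_dataset("magnitude", data=magnitude.magnitude)
            h5.attrs["cycle_ms"] = field.cycle_ms
            h5.attrs["venc_cm_s"] = field.venc_cm_s
            h5.attrs["spacing_mm"] = list(field.spacing_mm)
            h5.attrs["origin_mm"] = list(field.origin_mm)
        return path
    raise ValidationError(f"unsupported format {format!r}; use 'nifti' or 'hdf5'")


def read_velocity_dataset(path: str | os.PathLike, format: str = "auto") -> VelocityField4D:
    """Read a velocity dataset in either supported dialect.

    Metadata (spacing, cycle length, VENC) comes from the sidecar or HDF5
    attributes; missing metadata is an error, never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"dataset path does not exist: {path}")
    if format == "auto":
        format = "nifti" if path.is_dir() else "hdf5"
    if format == "nifti":
        import nibabel as nib

        sidecar_path = path / "dataset.yaml"
        if not sidecar_path.exists():
            raise ValidationError(f"missing sidecar {sidecar_path}")
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh)
        for key in ("n_frames", "cycle_ms", "venc_cm_s", "spacing_mm", "origin_mm"):
            if key not in meta:
                raise ValidationError(f"sidecar missing required key {key!r}")
        n_frames = int(meta["n_frames"])
        frames = []
        for k in range(n_frames):
            comps = []
            for cname in _COMPONENT_NAMES:
                f = path / f"vel_t{k:03d}_{cname}.nii.gz"
                if not f.exists():
                    raise ValidationError(
                        f"sidecar declares n_frames={n_frames} but volume for frame {k} "
                        f"component {cname} is missing"
                    )
                comps.append(np.asanyarray(nib.load(f).dataobj, dtype=np.float64))
            frames.append(np.stack(comps, axis=-1))
        velocity = np.stack(frames, axis=0)
        return VelocityField4D(
            velocity=velocity,
            spacing_mm=tuple(meta["spacing_mm"]),
            origin_mm=tuple(meta["origin_mm"]),
            cycle_ms=float(meta["cycle_ms"]),
            venc_cm_s=float(meta["venc_cm_s"]),
        )
    if format == "hdf5":
        import h5py

        with h5py.File(path, "r") as h5:
            if "velocity" not in h5:
                raise ValidationError("HDF5 file has no /velocity dataset")
            for key in ("cycle_ms", "venc_cm_s", "spacing_mm", "origin_mm"):
                if key not in h5.attrs:
                    raise ValidationError(f"HDF5 file missing attribute {key!r}")
            return VelocityField4D(
                velocity=h5["velocity"][()],
                spacing_mm=tuple(h5.attrs["spacing_mm"]),
                origin_mm=tuple(h5.attrs["origin_mm"]),
                cycle_ms=float(h5.attrs["cycle_ms"]),
                venc_cm_s=float(h5.attrs["venc_cm_s"]),
            )
    raise ValidationError(f"unsupported format {format!r}")


def read_magnitude_dataset(path: str | os.PathLike, format: str = "auto") -> MagnitudeField4D:
    """Read magnitude frames from a dataset written with ``magnitude=``."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"dataset path does not exist: {path}")
    if format == "auto":
        format = "nifti" if path.is_dir() else "hdf5"
    if format == "nifti":
        import nibabel as nib

        with open(path / "dataset.yaml") as fh:
            meta = yaml.safe_load(fh)
        if not meta.get("has_magnitude", False):
            raise ValidationError("dataset has no magnitude volumes")
        mags = []
        for k in range(int(meta["n_frames"])):
            mags.append(np.asanyarray(nib.load(path / f"mag_t{k:03d}.nii.gz").dataobj, dtype=np.float64))
        return MagnitudeField4D(
            magnitude=np.stack(mags, axis=0),
            spacing_mm=tuple(meta["spacing_mm"]),
            origin_mm=tuple(meta["origin_mm"]),
            cycle_ms=float(meta["cycle_ms"]),
        )
    import h5py

    with h5py.File(path, "r") as h5:
        if "magnitude" not in h5:
            raise ValidationError("HDF5 file has no /magnitude dataset")
        return MagnitudeField4D(
            magnitude=h5["magnitude"][()],
            spacing_mm=tuple(h5.attrs["spacing_mm"]),
            origin_mm=tuple(h5.attrs["origin_mm"]),
            cycle_ms=float(h5.attrs["cycle_ms"]),
        )


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------


def write_mask(mask: SegmentationMask, path: str | os.PathLike) -> Path:
    """Write a mask as NIfTI (``<path>.nii.gz``) + YAML sidecar (``<path>.yaml``)."""
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nii = path.with_suffix(".nii.gz")
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    nib.save(img, nii)
    sidecar = {
        "phase": mask.phase_label,
        "basal_slice_index": mask.basal_slice_index,
        "slice_direction": mask.slice_direction,
        "in_plane_spacing_mm": list(mask.in_plane_spacing_mm),
        "slice_thickness_mm": mask.slice_thickness_mm,
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return nii


def read_mask(path: str | os.PathLike, phase_label: str | None = None) -> SegmentationMask:
    """Read a mask written by :func:`write_mask`.

    The volume is binarized by thresholding at 0.5; the basal-slice
    designation must be present in the sidecar.
    """
    import nibabel as nib

    path = Path(path)
    nii = path if path.suffixes else path.with_suffix(".nii.gz")
    if not nii.exists():
        raise ValidationError(f"mask volume not found: {nii}")
    base = str(nii)
    for suf in (".nii.gz", ".nii"):
        if base.endswith(suf):
            base = base[: -len(suf)]
            break
    sidecar_path = Path(base + ".yaml")
    if not sidecar_path.exists():
        raise ValidationError(f"mask sidecar not found: {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    if "basal_slice_index" not in meta:
        raise ValidationError("mask sidecar missing basal_slice_index")
    img = nib.load(nii)
    voxels = np.asanyarray(img.dataobj, dtype=np.float64) > 0.5
    return SegmentationMask(
        voxels=voxels,
        in_plane_spacing_mm=tuple(meta["in_plane_spacing_mm"]),
        slice_thickness_mm=float(meta["slice_thickness_mm"]),
        affine=np.asarray(img.affine),
        basal_slice_index=int(meta["basal_slice_index"]),
        slice_direction=meta["slice_direction"],
        phase_label=phase_label if phase_label is not None else meta["phase"],
    )


# ---------------------------------------------------------------------------
# Pathline export (VTK legacy ASCII polydata)
# ---------------------------------------------------------------------------


def export_pathlines(
    pathlines: Sequence[Pathline],
    labels: Sequence[int],
    path: str | os.PathLike,
) -> Path:
    """Write pathlines as VTK legacy ASCII polydata with an integer cell
    attribute ``component`` (one polyline per pathline)."""
    if len(pathlines) != len(labels):
        raise ValidationError(
            f"got {len(pathlines)} pathlines but {len(labels)} labels"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_points = sum(len(p.times_ms) for p in pathlines)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("flowcomp4d pathlines\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n_points} float\n")
        for p in pathlines:
            for xyz in p.positions_mm:
                fh.write(f"{xyz[0]:.6g} {xyz[1]:.6g} {xyz[2]:.6g}\n")
        n_lines = len(pathlines)
        size = sum(len(p.times_ms) + 1 for p in pathlines)
        fh.write(f"LINES {n_lines} {size}\n")
        offset = 0
        for p in pathlines:
            n = len(p.times_ms)
            fh.write(" ".join([str(n)] + [str(offset + i) for i in range(n)]) + "\n")
            offset += n
        fh.write(f"CELL_DATA {n_lines}\n")
        fh.write("SCALARS component int 1\nLOOKUP_TABLE default\n")
        for lab in labels:
            fh.write(f"{int(lab)}\n")
    return path


def read_pathlines(path: str | os.PathLike) -> tuple[list[np.ndarray], list[int]]:
    """Read back a polydata file written by :func:`export_pathlines`.

    Returns per-line vertex arrays and the ``component`` labels.  Intended
    for round-trip verification; timing information is not stored in the
    geometry file.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(range(len(tokens)))

    def find(keyword: str, start: int = 0) -> int:
        for i in range(start, len(tokens)):
            if tokens[i] == keyword:
                return i
        raise ValidationError(f"keyword {keyword} not found in {path}")

    ip = find("POINTS")
    n_points = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3 : ip + 3 + 3 * n_points], dtype=float).reshape(n_points, 3)
    il = find("LINES", ip)
    n_lines = int(tokens[il + 1])
    pos = il + 3
    lines = []
    for _ in range(n_lines):
        n = int(tokens[pos])
        idx = np.array(tokens[pos + 1 : pos + 1 + n], dtype=int)
        lines.append(coords[idx])
        pos += n + 1
    ic = find("SCALARS", il)
    # skip "SCALARS component int 1" + "LOOKUP_TABLE default"
    pos = ic + 6
    labels = [int(t) for t in tokens[pos : pos + n_lines]]
    return lines, labels


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


def write_results(result_dict: dict, path: str | os.PathLike) -> Path:
    """Write a machine-readable results report: JSON plus a CSV table.

    ``path`` is the JSON file; a sibling ``.csv`` holds the per-component
    table.  Numbers round-trip losslessly through the JSON file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(result_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    comps = result_dict.get("components", {})
    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["component", "count", "volume_ml", "percent_of_edv"])
        for name, row in comps.items():
            writer.writerow(
                [name, row.get("count"), row.get("volume_ml"), row.get("percent_of_edv")]
            )
    return path


def read_results(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)
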