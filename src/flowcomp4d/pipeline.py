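"""Orchestration: the end-to-end analysis mirroring the three manual steps
of the method — geometric constraints, pathline computation, component
separation — plus configuration handling and reproducible run manifests.

The two required user inputs are exactly the two manual inputs of the
underlying protocol: the LV segmentations (IVC and IVR) and the
isovolumetric times.  Everything else has defaults.  A run manifest records
all parameters, the software version and input checksums, so identical
manifests yield bit-identical results files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .components import (
    ComponentLabel,
    ComponentResult,
    KineticEnergyCurves,
    classify_all,
    flow_balance,
    kinetic_energy,
    quantify,
    suggest_isovolumetric_times,
)
from .correction import apply_correction, compute_static_weights, fit_background, unwrap_phase
from .geometry import basal_plane_from_mask, rasterize_mask
from .io import (
    AnalysisConfig,
    MagnitudeField4D,
    SegmentationMask,
    ValidationError,
    VelocityField4D,
    export_pathlines,
    read_magnitude_dataset,
    read_mask,
    read_velocity_dataset,
    write_results,
)
from .tracing import TraceSettings, seed_from_mask, trace_full_cycle

__all__ = ["PipelineConfig", "AnalysisBundle", "analyze_flow", "run"]


@dataclass
class PipelineConfig:
    """Schema-validated run configuration; unknown keys are rejected."""

    velocity_path: str
    ivc_mask_path: str
    ivr_mask_path: str
    t_ivc_ms: float | str
    t_ivr_ms: float | str
    output_dir: str
    magnitude_path: str | None = None
    correction_enabled: bool = False
    correction_degree: int = 4
    correction_sigma0_cm_s: float = 2.0
    unwrap_enabled: bool = True
    tracing: dict = field(default_factory=dict)
    blood_density_kg_m3: float = 1060.0
    flow_balance_threshold: float = 0.10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        import dataclasses

        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        missing = {
            k
            for k, f in cls.__dataclass_fields__.items()
            if f.default is dataclasses.MISSING
            and f.default_factory is dataclasses.MISSING
            and k not in data
        }
        if missing:
            raise ValidationError(f"missing required config keys: {sorted(missing)}")
        cfg = cls(**data)
        known_trace = set(TraceSettings.__dataclass_fields__)
        unknown_trace = set(cfg.tracing) - known_trace
        if unknown_trace:
            raise ValidationError(f"unknown tracing keys: {sorted(unknown_trace)}")
        return cfg

    def trace_settings(self) -> TraceSettings:
        return TraceSettings(**self.tracing)


@dataclass
class AnalysisBundle:
    """Everything one analysis produced."""

    result: ComponentResult
    balance: dict
    ke: KineticEnergyCurves
    labels: np.ndarray
    pathlines: list
    seeds: object
    edv_ml: float

    def results_dict(self) -> dict:
        d = self.result.to_dict()
        d["flow_balance"] = self.balance
        d["kinetic_energy"] = self.ke.to_dict()
        return d


def analyze_flow(
    field: VelocityField4D,
    mask_ivc: SegmentationMask,
    mask_ivr: SegmentationMask,
    config: AnalysisConfig,
    settings: TraceSettings | None = None,
    magnitude: MagnitudeField4D | None = None,
    correct: bool = False,
    unwrap: bool = True,
    correction_degree: int = 4,
    correction_sigma0_cm_s: float = 2.0,
) -> AnalysisBundle:
    """The full automatic analysis on in-memory inputs.

    correct -> rasterize masks -> basal plane -> seed -> trace full cycle ->
    classify -> quantify -> flow balance -> kinetic energy.
    """
    config.validate(field.cycle_ms)
    if unwrap:
        field = unwrap_phase(field)
    if correct:
        if magnitude is None:
            raise ValidationError("background correction requires magnitude data")
        weights = compute_static_weights(field, magnitude, sigma0_cm_s=correction_sigma0_cm_s)
        model = fit_background(field, weights, degree=correction_degree)
        field = apply_correction(field, model)

    ivc_fgm = rasterize_mask(mask_ivc, field)
    ivr_fgm = rasterize_mask(mask_ivr, field)
    plane = basal_plane_from_mask(mask_ivr)

    seeds = seed_from_mask(ivc_fgm)
    pathlines = trace_full_cycle(field, seeds, config.t_ivc_ms, config.t_ivr_ms, settings)
    labels = classify_all(pathlines, ivr_fgm, plane)
    result = quantify(labels, field.voxel_volume_mm3, len(seeds))
    balance = flow_balance(result, threshold=config.flow_balance_threshold)
    ke = kinetic_energy(pathlines, labels, field, density_kg_m3=config.blood_density_kg_m3)
    return AnalysisBundle(
        result=result,
        balance=balance,
        ke=ke,
        labels=labels,
        pathlines=pathlines,
        seeds=seeds,
        edv_ml=seeds.edv_ml,
    )


def _resolve_input(path: str) -> Path:
    p = Path(path)
    if p.exists():
        return p
    alt = Path(str(p) + ".nii.gz")
    if alt.exists():
        return alt
    return p


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for p in sorted(path.rglob("*")):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> AnalysisBundle:
    """File-based end-to-end run; writes results, pathlines and a manifest.

    When ``t_ivc_ms``/``t_ivr_ms`` is the string ``"suggest"``, the
    basal-plane flux helper computes candidate times, writes them to
    ``suggested_times.json`` and raises: the suggestion must be confirmed by
    entering the values explicitly — timing is one of the two deliberate
    user inputs and is never silently applied.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    field = read_velocity_dataset(config.velocity_path)
    magnitude = (
        read_magnitude_dataset(config.magnitude_path)
        if config.magnitude_path is not None
        else None
    )
    mask_ivc = read_mask(config.ivc_mask_path, phase_label="IVC")
    mask_ivr = read_mask(config.ivr_mask_path, phase_label="IVR")

    if config.t_ivc_ms == "suggest" or config.t_ivr_ms == "suggest":
        ivc_fgm = rasterize_mask(mask_ivc, field)
        plane = basal_plane_from_mask(mask_ivc)
        suggestion = suggest_isovolumetric_times(field, plane, ivc_fgm)
        with open(out / "suggested_times.json", "w") as fh:
            json.dump(
                {
                    "t_ivc_ms": suggestion["t_ivc_ms"],
                    "t_ivr_ms": suggestion["t_ivr_ms"],
                },
                fh,
                indent=2,
            )
        raise ValidationError(
            f"suggested t_ivc={suggestion['t_ivc_ms']} ms, "
            f"t_ivr={suggestion['t_ivr_ms']} ms written to suggested_times.json; "
            "confirm by setting t_ivc_ms/t_ivr_ms explicitly"
        )

    analysis_config = AnalysisConfig(
        t_ivc_ms=float(config.t_ivc_ms),
        t_ivr_ms=float(config.t_ivr_ms),
        blood_density_kg_m3=config.blood_density_kg_m3,
        flow_balance_threshold=config.flow_balance_threshold,
    )
    bundle = analyze_flow(
        field,
        mask_ivc,
        mask_ivr,
        analysis_config,
        settings=config.trace_settings(),
        magnitude=magnitude,
        correct=config.correction_enabled,
        unwrap=config.unwrap_enabled,
        correction_degree=config.correction_degree,
        correction_sigma0_cm_s=config.correction_sigma0_cm_s,
    )

    write_results(bundle.results_dict(), out / "results.json")
    export_pathlines(bundle.pathlines, bundle.labels, out / "pathlines.vtk")
    with open(out / "ke_curves.csv", "w") as fh:
        names = [name for name in bundle.ke.to_dict()["ke_microjoule"]]
        fh.write("time_ms," + ",".join(names) + "\n")
        for i, t in enumerate(bundle.ke.times_ms):
            row = ",".join(f"{bundle.ke.ke_microjoule[j, i]!r}" for j in range(len(names)))
            fh.write(f"{t!r},{row}\n")

    manifest = {
        "software": "flowcomp4d",
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "inputs": {
            "velocity": _sha256(_resolve_input(config.velocity_path)),
            "ivc_mask": _sha256(_resolve_input(config.ivc_mask_path)),
            "ivr_mask": _sha256(_resolve_input(config.ivr_mask_path)),
        },
    }
    if config.magnitude_path is not None:
        manifest["inputs"]["magnitude"] = _sha256(Path(config.magnitude_path))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle
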