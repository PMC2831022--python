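# flowcomp4d

Semi-automatic quantification of 4D (3D + time) left-ventricular blood flow
from three-directional, three-dimensional cine phase-contrast CMR velocity
data.

## The problem

Within the beating left ventricle (LV), blood follows complex time-varying
3D paths that are disturbed in disease. 4D flow CMR measures the full
velocity field **v**(x, t) over the cardiac cycle, but turning it into
quantitative, reproducible numbers requires integrating that field into
trajectories and relating them to the LV anatomy. `flowcomp4d` implements
an analysis with exactly two manual inputs — the LV endocardial
segmentation (at isovolumetric contraction, IVC, and isovolumetric
relaxation, IVR) and the two isovolumetric times — and automates the rest:

1. **Geometric constraints.** The binary IVC and IVR LV masks (short-axis
   slice stacks) are resampled onto the flow grid; the most basal slice
   defines the *basal plane*, crossing which means leaving the LV through a
   valve.
2. **Pathlines.** From the center of every voxel of the IVC LV blood pool,
   a pathline dx/dt = **v**(x, t) is integrated with adaptive 4th-order
   Runge–Kutta, forward and backward in time until IVR, covering the
   complete cardiac cycle. No mask constrains the tracing.
3. **Component separation.** Using where each pathline *is* at the two IVR
   times relative to the IVR LV volume and the basal plane, every pathline
   is assigned to one of four flow components:

   | component | diastole (backward) | systole (forward) |
   |---|---|---|
   | Direct Flow | enters the LV | leaves the LV |
   | Retained Inflow | enters the LV | stays |
   | Delayed Ejection Flow | already inside | leaves the LV |
   | Residual Volume | already inside | stays |

   Pathlines whose non-basal endpoint falls outside the IVR LV volume were
   emitted from myocardium or corrupted by data imperfections and are
   *excluded* (reported, never redistributed).

Each pathline represents one voxel volume of blood, so component volume =
count × voxel volume, and the flow-derived end-diastolic volume (EDV) is
seed count × voxel volume. The built-in accuracy check exploits
conservation: *Inflow* = Direct Flow + Retained Inflow must match
*Outflow* = Direct Flow + Delayed Ejection Flow. Component kinetic-energy
curves KE_c(t) = Σ ½ ρ ‖**v**(x_p(t), t)‖² V_voxel are computed along the
labeled pathlines.

Supporting stages: temporal phase-wrap correction (velocities alias by
multiples of 2·VENC), a per-frame weighted 4th-order polynomial
background-offset fit to static tissue, and a blood-pool leak QC (pathlines
emitted at the mitral annulus must never leave the blood pool; coherent
leaks through one site indicate a systematic velocity offset).

Because no public in-vivo 4D flow dataset accompanies this method, the
package ships a kinematic LV phantom: an exactly divergence-free,
frame-aligned flow program with programmable component fractions whose
ground-truth labels come from an independent fixed-step integrator.

## Worked example

```python
import numpy as np
from flowcomp4d.io import AnalysisConfig
from flowcomp4d.phantom import PhantomSpec, make_lv_phantom
from flowcomp4d.pipeline import analyze_flow
from flowcomp4d.components import ComponentLabel

spec = PhantomSpec()            # 3 mm voxels, 40 frames, VENC 100 cm/s,
                                # fractions (30, 18, 17, 35)%
ph = make_lv_phantom(spec, truth="oracle")
cfg = AnalysisConfig(t_ivc_ms=0.0, t_ivr_ms=350.0)
b = analyze_flow(ph.field, ph.mask_ivc, ph.mask_ivr, cfg)

print(f"EDV {b.result.edv_ml:.1f} mL from {b.result.n_seeds} pathlines")
for c in ComponentLabel:
    print(f"{c.name:17s} {b.result.counts[c]:5d}  "
          f"{b.result.volume_ml(c):6.2f} mL  {b.result.percent_of_edv(c):5.2f} %")
print(f"inflow {b.balance['inflow_ml']:.2f} mL vs outflow "
      f"{b.balance['outflow_ml']:.2f} mL "
      f"({100 * b.balance['rel_diff']:.2f} % difference)")
print(f"labels match ground truth: {(b.labels == ph.truth.labels).mean():.1%}")
```

prints

```
EDV 145.2 mL from 5376 pathlines
DIRECT_FLOW        1617   43.66 mL  30.08 %
RETAINED_INFLOW     966   26.08 mL  17.97 %
DELAYED_EJECTION    903   24.38 mL  16.80 %
RESIDUAL_VOLUME    1890   51.03 mL  35.16 %
EXCLUDED              0    0.00 mL   0.00 %
inflow 69.74 mL vs outflow 68.04 mL (2.47 % difference)
labels match ground truth: 100.0%
```

The 5376 pathlines partition the 145 mL flow-derived EDV into the four
components within half a voxel column of the programmed fractions; inflow
and outflow agree within a few percent, as they must for a
divergence-free field with no excluded traces.

The same analysis is available from the shell: `flowcomp4d phantom` writes
a synthetic dataset (NIfTI + YAML or HDF5), `flowcomp4d run --config
analysis.yaml` executes the pipeline and writes `results.json`/`.csv`,
labeled pathlines as VTK polydata, kinetic-energy curves, and a manifest
with input checksums; `flowcomp4d correct`, `trace` and `qc` expose the
individual stages.

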