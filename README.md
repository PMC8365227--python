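# aneuflow

Desk-scale computational study of how stent metal coverage changes the
hemodynamics of an idealized sidewall aneurysm.

The package builds a 2D planar reduction of a sidewall-aneurysm /
parent-artery domain (4 mm lumen, 5 mm sac radius, 5.27 mm neck),
deploys parametric virtual stents across the neck — a laser-cut
closed-cell device, braided devices, with overlapping and push-pull
compaction — measures their metal coverage rate (MCR) by rasterizing the
metal lattice, and simulates pulsatile incompressible flow with a
Womersley-profile inlet, zero-pressure outlet, rigid no-slip walls and a
homogenized porous-screen model of the device at the neck.  From the
systolic field of the third cardiac cycle it reports energy loss between
two parent-artery planes, average neck velocity and sac inflow rate,
their reduction rates versus the unstented control, and the Pearson
correlation of MCR with each parameter.

## Layout

| module | role |
| --- | --- |
| `aneuflow.geometry` | sidewall sac + parent channel, raster grid, measurement planes A/B/C |
| `aneuflow.stent_model` | stent lattices, overlap/compaction transforms, MCR rasters, device presets |
| `aneuflow.flow_solver` | staggered-grid projection solver, Womersley inlet, neck screen momentum sink |
| `aneuflow.hemodynamic_metrics` | energy loss, neck velocity/inflow, reduction rates |
| `aneuflow.study_pipeline` | device-matrix sweeps, Pearson analysis, fixture diff report |
| `aneuflow.validation_fixtures` | analytic channel flows, packaged study-table fixture, reduced matrices |

Device presets (`enterprise`, `lvis`, `pipeline`) live in
`src/aneuflow/data/device_presets.yaml`; their metal widths and maximum
compaction factors were calibrated once against published single-device
coverage values with `scripts/calibrate_presets.py`.  Composite
configurations (overlap, compaction stacks) are emergent, not
calibrated.

## CLI

```sh
aneuflow stent mcr --device lvis --layers 2 --compaction max
aneuflow run --out outdir/ --device pipeline            # systolic VTK export
aneuflow study --out results/                           # full device matrix
aneuflow report --against-paper                         # fixture diff report
aneuflow validate --case poiseuille
```

`aneuflow study` with no config runs the 10-row device matrix (control;
Enterprise x1/x2/x3; LVIS x1/x2 plain and compacted; Pipeline plain and
compacted) and writes `table1_analogue.csv`, `correlations.json` and a
complete run manifest.

## Scope notes

* The study is a 2D planar reduction; all "volumes" and flow rates are
  per-unit-depth quantities scaled by a depth equal to the parent
  diameter (recorded in every output manifest).  Absolute hemodynamic
  magnitudes of the original 3D resolved-strut simulations are not
  reproducible at this scale; orderings, monotone trends and correlation
  signs are the reproduction targets.
* The device is homogenized into a screen with a solidity-dependent
  pressure-jump law (screen-drag inertial term, Kozeny-type viscous
  term); struts are never resolved.
* The inlet waveform shape (period, mean, two harmonics) is a documented
  modeling choice, configurable per run.
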