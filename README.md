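# nemashell

Active-nematic vertex-model simulation of closed cellular shells with
mechanochemical feedback, plus the accompanying quantitative analysis
tools.

The model is a vertex model on a closed polygonal surface (a spheroid of
~100–1000 cells) enclosing an incompressible lumen. Each cell carries a
unit nematic (fiber) orientation in its tangent plane and a morphogen
molecule count. Global contraction pulses generate traceless active
stresses along the fiber axes; mechanical strain gates morphogen
production through a sharp sigmoid; fibers align to morphogen gradients.
The package reproduces mechanical strain focusing at nematic topological
defects during single contraction events, and the self-organization of a
"+1 defect + morphogen peak" organizer (or its four-+1/2-defect failure
mode when production is off) over trains of pulses.

Also included: the 2D fiber-orientation image analysis pipeline
(structure tensor, doubled-angle smoothing, coherence, nematic order
parameter, winding-number defect detection) and the strain
quantifications (per-graph-distance logarithmic area strain, peak-frame
selection, large/small event classes, triangle-method cell-shape
anisotropy).

## Layout

| module                | contents |
|-----------------------|----------|
| `nemashell.shell`     | closed polygonal shells: connectivity, per-cell geometry, enclosed volume, graph distances, validation |
| `nemashell.synthetic` | generators: spherical Voronoi shells, initial nematic patterns (`fragment`, `late_defects`, `four_half`, `uniform`, `random`), fiber-texture rasters, synthetic area series |
| `nemashell.mechanics` | vertex-model energy and analytic forces, volume-constrained overdamped stepping, bond collapse + T1 resolution, 2D Poisson ratio |
| `nemashell.nematic`   | tangent-plane nematic transport, neighbor alignment, gradient alignment, unit-norm dynamics, defect detection with charge accounting |
| `nemashell.morphogen` | inter-cell diffusion, degradation, strain-gated sigmoid production, tangent-plane least-squares gradients |
| `nemashell.driver`    | contraction protocols, single-event runs, amplitude calibration, full regeneration runs, outcome classification, (eps_th, alpha) phase scans |
| `nemashell.strain`    | log area strain profiles, event classification, cell-shape tensors |
| `nemashell.imaging`   | raster orientation analysis and 2D defect detection |
| `nemashell.io`        | ASCII PLY / legacy VTK meshes, JSON snapshot container |

## CLI

One entry point with subcommands:

```sh
nemashell make-synthetic mesh --n-cells 200 --seed 1 --out shell.ply
nemashell make-synthetic nematic --mesh shell.ply --pattern late_defects --out nem.json
nemashell make-synthetic image --kind aster --out aster.tif
nemashell simulate-event --config scenario.yaml --seed 1 --out event.json
nemashell calibrate --config scenario.yaml --target 0.6931
nemashell simulate-regeneration --config scenario.yaml --n-pulses 20 --out outcome.json
nemashell phase-scan --eps-th 0.4 --eps-th 0.8 --alpha 0 --alpha 10 --out scan.csv
nemashell analyze-strain --areas areas.csv --distances dist.csv --out strain.json
nemashell analyze-orientation --image fibers.tif --pixel-size 1.0 --out-prefix out
```

The YAML config accepts any `ScenarioConfig` / `MechanicsParams` /
`MorphogenParams` / `ContractionProtocol` field; see `nemashell/cli.py`
for an example.

## Units

Dimensionless model units: lengths in units of sqrt(A0) (A0 the preferred
cell area), energies in units of K·A0², time in units of gamma/(K·A0).
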