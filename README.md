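# reciprotes

Reciprocity-based targeting for transcranial electrical stimulation (TES)
on synthetic layered-sphere head models.

Weak scalp currents (tDCS/tACS) modulate cortical excitability, but choosing
*which* electrodes to drive — the montage — so that the current density at a
cortical target is strong, correctly oriented and focal is a nontrivial
optimization problem. `reciprotes` is a self-contained toolkit for studying
this problem without any imaging data: it bundles

* a **complete-electrode-model (CEM) finite-element forward solver** for the
  quasi-static volume conduction problem ∇·(σ∇ψ) = 0, shared by TES
  (scalp injection) and EEG (cortical dipole sources);
* the **EEG–TES reciprocity principle**,
  Φ(a) − Φ(b) = d·∇ψ_ab(r) / I_ab,
  linking the scalp topography Φ of a dipole **d** at **r** to the potential
  ψ_ab produced by injecting I_ab through electrodes a, b — and four
  electrode-selection methods built on it (*one-source*, *opposite*, *ring*,
  *ROADSS*);
* **least-squares** (c = (TᵀT)⁻¹Tᵀe with e = b⊗d) and **LCMV**
  (min ‖Tc‖² s.t. T̃c = d) reference optimizers on the 3T×(L−1) transfer
  matrix **T** of element field responses to elementary injection patterns;
* a **performance-metric suite**: target intensity |J| and directional
  intensity J·d, directionality, global and 3 cm-local center-of-gravity
  targeting error (75% threshold), global half-density focality radius, and
  the local focality ratio F_LOC;
* **closed-form concentric-sphere oracles** (multilayer dipole Legendre
  series, point-electrode pair potentials) used to validate the FEM solver.

Head models are deterministic concentric-shell tetrahedral meshes
(brain/CSF/skull/scalp, conductivities 0.33/1.79/0.008/0.35 S/m) with
quasi-uniform Fibonacci-lattice scalp montages of any size (64/128/256…)
and CEM contact impedances (default 2.01 Ω·m², the value implied by a
40 kΩ lumped contact resistance on an 8 mm electrode).

## Worked example

```python
from reciprotes import RunConfig, run_pipeline
run_pipeline(RunConfig(), "example_run")   # 4-layer sphere, 64 electrodes
```

builds an 83 101-element head (14 877 nodes), solves the 63 elementary
patterns for the transfer matrix, places a cortical target at the apex, and
evaluates all six methods (`example_run/metrics.csv`):

```
method      intensity  J·d      direc.  TE_glob  TE_loc  focal.  F_loc
one_source  0.0797    -0.0709   -0.890  0.0119   0.0119  0.0788  0.088
opposite    0.0351    -0.0350   -0.999  0.0223   0.0115  0.0896  0.075
ring        0.0251    -0.0251   -0.997  0.0710   0.0091  0.0680  0.076
roadss      0.0251    -0.0251   -0.997  0.0710   0.0091  0.0680  0.076
ls          0.0564     0.0546    0.969  0.0111   0.0111  0.0747  0.091
lcmv        0.0440     0.0438    0.996  0.0063   0.0061  0.0760  0.080
```

Intensities are in A/m² for a 1 mA budget, distances in meters. Reading the
table: the uncapped *one-source* montage delivers the largest current
density at the target; *opposite* trades intensity for near-perfect
directionality; *ring* concentrates current (smallest global focality
radius, 6.8 cm vs 9.0 cm) at the price of intensity; and *ROADSS*
reproduces the ring layout here because the apex target is purely radial —
for tangential targets it migrates toward the *opposite* layout. The
negative J·d of the reciprocity methods reflects polarity: sources sit on
the topography maximum (anodal), which drives current *into* the cortex,
antiparallel to the outward normal; swapping sources and sinks reverses
the sign. LS/LCMV impose the field along +d directly.

The same run is available from the shell:

```sh
reciprotes run --out example_run --electrodes 64 --seed-point 0,0,0.077
```

## Layout

| module | contents |
| --- | --- |
| `reciprotes.mesh` | layered-sphere meshing, electrode placement, stretch-factor quality |
| `reciprotes.io` | TetGen `.node`/`.ele`, VTK legacy, montage TSV, pattern CSV |
| `reciprotes.fem` | CEM assembly, direct/PCG solvers, per-element E and J |
| `reciprotes.sources` | elementary patterns, transfer matrix, dipole loads, topographies, reciprocity check |
| `reciprotes.targeting` | LS, LCMV, one-source/opposite/ring/ROADSS, brute-force pole pairs |
| `reciprotes.metrics` | intensity, directionality, targeting errors, focality |
| `reciprotes.analytic` | multilayer-sphere dipole series, point-electrode closed forms |
| `reciprotes.pipeline` / `reciprotes.cli` | end-to-end runs, `reciprotes` command |

See `docs/methods.md` for the model details, conventions and limitations.
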