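# lumenflow

Simulation of small-intestinal motility and the luminal transport it
imposes on orally delivered therapeutics.

Oral biologics typically pair a macromolecule (here insulin) with a
permeation enhancer (here sodium caprate, C10): the enhancer only helps if
both molecules arrive at the epithelium together.  Whether they do is
largely a question of intestinal hydrodynamics.  `lumenflow` models a
segment of small intestine as an axisymmetric tube whose wall moves with
one of the two physiological motility programmes —

* **segmentation** (fed state): standing rhythmic contractions,
  wall radius `h(z,t) = r0 + delta*sin(2*pi*t/tp)*cos(2*pi*z/lambda) + B(t)`,
  where the offset `B(t)` enforces exact volume conservation per
  wavelength;
* **peristalsis** (fasted state): a travelling wave
  `h = r0 + delta*sin(2*pi*(z - c*t)/lambda)`, solved in the wave frame —

solves the incompressible Navier–Stokes equations (Newtonian water or a
power-law nutritional drink) on the deforming lumen, advects the two
dissolved species through the resulting flow for thirty contraction
cycles, and quantifies epithelial delivery: mole fractions within
villus-scale wall layers (thickness D/15 and D/30 of the rest diameter),
escape from the release pocket, wall-surface concentrations `c/ci`, wall
shear stress, and a **colocalisation score**

    CS = Cbar_MM * Cbar_PE / (1 + dt^2 + dz^2 + dr^2)   in [0, 1],

which rewards cases where both species reach high wall concentrations at
the same place and time.  A factorial sweep over the six variability
factors (motility type, intensity, fluid, pocket volume, occlusion ratio,
release position) feeds K-means clustering of CS and an XGBoost regression
with exact TreeSHAP attribution of which factors matter.

The physics and the numerics are documented in `docs/methods.md`.

## Worked example

```sh
python examples/01_wall_kinematics.py
```

prints (abridged):

```
2 mL pocket : rest radius r0 = 0.5150 cm, amplitude delta = 0.3112 cm
10 mL pocket: rest radius r0 = 0.8811 cm, amplitude delta = 0.5323 cm
radial excursion ratio (10 mL / 2 mL): 1.711
max relative volume error over one cycle: 3.49e-16
min wall radius / rest radius: 0.3000 (occlusion ratio 0.3)
```

— the large pocket's epithelium travels 1.7× farther per cycle (that ratio
drives its higher luminal velocities), the conservation offset keeps the
luminal volume constant to machine precision, and the realised minimum
radius reproduces the requested occlusion ratio.  The other examples run a
segmentation flow and print settled-cycle velocity and wall-shear
summaries (`02`), track insulin/C10 delivery metrics for a short baseline
case (`03`), and demonstrate the clustering + SHAP attribution pipeline on
a sweep table with a planted dominant factor (`04`).

A thin CLI covers shell use:

```sh
lumenflow run-case  run.yaml     # one case -> metrics.csv + VTK snapshot
lumenflow run-sweep sweep.yaml   # factor grid -> sweep_table.csv
lumenflow analyze   sweep_table.csv   # clustering + SHAP ranking
lumenflow verify                 # built-in verification fixtures
```

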