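# Methods

`lumenflow` simulates how the two motility programmes of the human small
intestine — fed-state **segmentation** (standing, rhythmic circumferential
contractions) and fasted-state **peristalsis** (a travelling contraction
wave) — move dissolved therapeutics from a released bolus to the epithelial
surface.  The model system follows the oral-biologics co-administration
problem: a macromolecule (insulin, 2 mM) and a permeation enhancer (sodium
caprate "C10", 100 mM) are released together on the lumen centreline and
tracked for thirty contraction cycles under zero epithelial absorption, so
that everything measured is hydrodynamic transport.

## Wall kinematics

The lumen is an axisymmetric tube of rest radius `r0` whose wall position
`h(z,t)` is prescribed (no fluid-structure coupling):

* segmentation: `h = r0 + delta*sin(2*pi*t/tp)*cos(2*pi*z/lambda) + B(t)`
  with the offset `B(t) = sqrt(r0^2 - (delta^2/2) sin^2(2*pi*t/tp)) - r0`.
  `B` makes the luminal volume per wavelength *exactly* constant at every
  instant (the sinusoidal standing wave alone would pump fluid through the
  periodic ends because the cross-section involves `h^2`); its time
  derivative is the closed-form correction velocity used by the wall-motion
  boundary condition.
* peristalsis: `h = r0 + delta*sin(2*pi*(z - c*t)/lambda)`, a pure
  travelling wave, solved in the frame moving at the wave speed `c` where
  the geometry (and, at steady state, the flow) is stationary.

Geometry is derived from physiological descriptors: pocket volume `V`
(rest cylinder of one wavelength, `r0 = sqrt(V/(pi*lambda))`; bundled
pairings 2 mL ↔ 2.4 cm and 10 mL ↔ 4.1 cm), and occlusion ratio
`OR = min-cycle radius / r0` (0.3/0.5/0.7 bundled).  For segmentation the
minimum realised radius includes the offset `B`, giving
`delta = r0*(-2*OR + sqrt(6 - 2*OR^2))/3`; a switch (`volume_offset=False`)
provides the plain `delta = (1-OR)*r0` inversion instead, because the
literature definition does not pin this down.  Motility intensity maps to
(period, wave speed) = light (7 s, 0.5 cm/s), moderate (5 s, 1 cm/s),
vigorous (3 s, 1.5 cm/s); segmentation is governed by the period and
peristalsis by the wave speed (its period at a fixed station is
`lambda/c` — using both simultaneously with the bundled wavelengths would
be kinematically inconsistent).

Domains: 3 pockets (wavelengths) for segmentation with axially periodic
flow; 30 pockets for peristalsis so the drug stays inside the domain for
the full 30 periods.

## Fluids and species

Water at 37 °C (Newtonian, 0.6913 mPa·s, 0.9934 g/cm³) represents the
fasted lumen.  The fed lumen is a shear-thinning nutritional drink modelled
as a power-law fluid `mu = K*gamma_dot^(n-1)` with the shear rate clamped
to [1e-3, 1e3] 1/s.  **The bundled drink parameters are a documented
stand-in** (`K = 4 mPa·s^n`, `n = 0.70`, `rho = 1.05 g/cm³`): no tabulated
rheometry ships with the package, so the parameters were calibrated once so
that the simulated drink reproduces the relative observables reported for
such drinks against water in this motility regime — peak luminal velocity
about +19%, surface-averaged wall shear ≈ 2.4×, maximum shear ≈ 2.8× — and
sits in the moderate-Reynolds regime those observables imply (Re ≈ 10–20 at
the baseline case).  A much more viscous stand-in cannot be reconciled with
those observables: beyond ~10× water the flow becomes quasi-static, and a
quasi-static generalised-Newtonian flow under a cyclic prescribed wall is
kinematically reversible, eliminating the convective near-wall migration
that is the central observable here.  Users with fitted rheometry should
register their own `FluidModel`.

Species diffusivities are referenced to water at 37 °C — insulin
1.11e-6 cm²/s; C10 concentration-dependent, interpolated linearly in
log10(c) between 5.50× insulin at 1 mM and 3.15× at 100 mM and clamped
outside [1, 100] mM — and rescaled to other fluids by the Stokes–Einstein
relation using one scalar reference viscosity per fluid, evaluated at the
characteristic wall shear rate `(2*pi*delta/tp)/r0` (a field-coupled
rescaling would be inconsistent with treating D as a species property).

## Flow solver

Incompressible axisymmetric Navier–Stokes on the boundary-fitted map
`eta = r/h(z,t)` (an ALE formulation in mapped coordinates; the mesh
follows the wall exactly, so no remeshing and no interpolation error at the
moving boundary).  Finite volumes with exact metric face fluxes; velocities
and pressure collocated at cell centres, volume fluxes at faces.

* **Advection**: two-stage Runge–Kutta with second-order linear-upwind face
  reconstruction, using the divergence-free face fluxes relative to the
  mesh motion.
* **Viscosity**: the stress divergence is split exactly into direction-wise
  diffusion (implicit; axial/radial coefficients (2mu, mu) for the axial
  momentum and (mu, 2mu) plus the `-2 mu v/r^2` geometric term for the
  radial momentum) and one explicit mixed-derivative remainder per
  component.  Power-law viscosity enters through a lagged shear-rate field.
* **Projection**: incremental pressure projection on face fluxes — the
  previous pressure gradient rides in the predictor and only the increment
  is solved each step, so the discrete steady state satisfies the unsplit
  momentum balance (without this the steady wave-frame flow carries an
  O(dt) bias that reached tens of per cent of the peristaltic mean flow).
  Metric cross terms of the pressure operator converge in a
  deferred-correction iteration (tolerance 1e-10 relative), making the face
  fluxes divergence-free to solver precision; the moving-wall flux is the
  exact discrete volume change per step, so total volume and a uniform
  passive scalar are preserved to the same precision.
* **Stabilisation**: cell velocities are corrected with the face-averaged
  projection corrections (a cell-gradient correction is inconsistent with
  the face operator and lets divergence modes grow at boundaries), plus a
  weak fourth-difference axial filter (`alpha = 0.2`, an O(dz^3) term) that
  removes odd–even cell-velocity modes invisible to face-averaged fluxes.
* **Boundaries**: no-slip/no-penetration at the wall via a one-sided
  quadratic (second-order) Dirichlet flux; symmetry at the axis (zero-area
  mapped face plus the geometric damping term); axially periodic.  In the
  peristaltic wave frame the wall condition is `u = -c`, `v = -c dh/dz`
  (the lab-frame wall moves purely radially).
* **Time step**: advective CFL 0.3 with a cap of tp/160, adaptive.

## Scalar transport

Conservative finite-volume advection–diffusion per species on the same
grid: van Leer slope-limited upwind faces, compact two-point diffusion with
the wall-metric factor (metric cross-diffusion is neglected — immaterial at
Péclet numbers of 1e5–1e7), explicit in time with diffusion sub-cycling if
ever needed.  The unsplit multidimensional update can undershoot zero
slightly at reconstruction corners, so each step ends with a conservative
positivity fixup: negative cells are zeroed and their mass deficit
(~1e-8 of the total) is absorbed proportionally by the remaining field,
keeping the concentrations non-negative and the totals exactly conserved.  The discrete mesh flux equals the
exact per-step cell-volume change, so with closed boundaries total moles
are conserved to projection precision and a uniform field stays uniform.
Open axial ends use first-order advective outflow with zero inflow
concentration and zero diffusive flux; mass "escapes" as it would into the
continuing gut.

The bolus is an isotropic Gaussian about the centreline (peak = each
species' initial concentration, default width `sigma = r0/10`, released
instantaneously at t = 0 when the segmentation wall is undeformed), at the
most-occluded pocket centre or `lambda/4` off-centre.  Both species share
the release (the co-administration premise).  For peristalsis, the bolus is
placed in a pocket chosen from the computed wave-frame drift so it stays
within the 30-pocket domain, and is shrunk to fit the locally occluded
lumen when the release station is the wave trough; the run aborts with an
instruction to enlarge the domain if the bolus nears the upstream end.

## Delivery metrics and colocalisation

Per time step: mole percentages in wall shells of thickness D/15 and D/30
(D = 2*r0, the rest diameter — villus-length scale; shells measured from
the instantaneous wall with exact annulus-overlap weights), escape
percentage from the fixed axial extent of the release pocket, the wall
concentration profile `c/ci` (wall-adjacent cell; the no-flux condition
makes this second-order), its running maximum and location, detection onset
(`c/ci > 0.001`), and wall shear (one-sided quadratic tangential gradient,
effective viscosity at the wall shear rate, area-weighted average and max).

The colocalisation score of a case is

    CS = Cbar_MM * Cbar_PE / (1 + dt^2 + dz^2 + dr^2),

with `Cbar` the per-case time-maximum wall concentrations normalised by the
ensemble maximum per species (so at least one case reaches 1), and the
separation terms the absolute (t, z, r) distances between the two species'
peaks normalised by the simulated duration (n_periods*tp), the wavelength,
and the rest radius respectively.  These normalisers are package choices
(configurable); the score is bounded in [0, 1] and monotone in each term.

## Sweep, clustering, attribution

`run_sweep` executes a factor grid (the full study grid is 3 intensities ×
2 fluids × 2 volumes × 3 ORs × 2 release positions per motility type = 72 +
72 cases), logs and excludes failed cases, and scores CS across the
ensemble.  Analysis follows the study workflow: non-parametric group tests
(exact Mann–Whitney for two groups; Kruskal–Wallis plus pairwise Dunn tests
with Holm adjustment otherwise), 1-D K-means on CS (default k = 4, clusters
reported by ascending mean; an exact dynamic-programming clustering serves
as the optimality oracle in tests), and XGBoost regression of CS on the six
factors (Min–Max-scaled numerics, one-hot categoricals, 80/20 split,
optional 3-fold grid search over n_estimators 50–700, learning rate
0.005–0.2, depth 3–9, subsample 0.6–1.0) with exact TreeSHAP attributions;
factors are ranked by mean |SHAP| summed over their encoded columns.  By
default attribution trains on the largest CS cluster, with a switch for the
full table.  All stages are seeded and deterministic.

## Verification

Independent oracles, none sharing discretisation code with the solvers:

* rigid-tube pressure-driven flow vs the parabolic profile and
  `tau_w = 4 mu U / R` (≤ 1% at the scaled-down resolution);
* free peristaltic pumping vs classical axisymmetric lubrication theory by
  quadrature in the long-wavelength, low-Reynolds limit (λ/r0 ≈ 157,
  Re ≈ 0.03; the mean flow is a ~9% cancellation residual of two large
  terms, making this a stringent test — agreement is ~0.02%);
* method of manufactured solutions (solenoidal Stokes-streamfunction field,
  sympy-derived sources) with dt refined quadratically alongside the mesh;
  the Richardson-triplet observed order is ≈ 2.1 (pairwise orders 2.05 and
  1.90 — a subdominant wall-boundary component converges slightly below 2);
* free Gaussian spreading vs `sigma^2 = sigma_0^2 + 2 D t` (≤ 1%);
* synthetic sweep tables with planted factor effects for end-to-end
  attribution recovery.

## Scaled-down study conditions

The bundled resolution presets are `coarse` (32 axial cells per wavelength
× 16 radial, tanh-stretched to the wall), `medium` (64 × 32), and
`production` (128 × 64, first cell ≤ r0/200).  The package's own
grid-sensitivity study (near-wall mole percentage of the baseline case
under axial/radial refinement) shows the near-wall migration is controlled
by axial resolution: the D/15 peak of the baseline case rises
monotonically — 31% (32/wave), 42.7% (64/wave), 53.3% (96/wave) — toward
the values a converged solution reaches, while its timing sharpens toward
period 6–8.  The reproduction runs use 72 × 36 cells/wavelength truncated
to twelve periods (which contain the peak; the peristaltic wall-surface
maximum saturates within the first two periods, so its run is truncated to
fifteen) for near-wall concentration metrics, and the `coarse` preset for
thirty-period bulk metrics (escape fractions) and velocity scans.  These
are the package's scaled-down conditions; quantitative agreement with
finite-element reference solutions at production resolution is
tolerance-based, not exact, and the near-wall percentages remain
under-predicted at these resolutions.

## Known limitations

* The epithelium is a rigid-in-structure, impermeable, no-slip boundary:
  no absorption, mucus, or villi microstructure; surface concentrations are
  upper bounds on what an absorbing wall would see.
* Waveforms are perfectly periodic; cycle-to-cycle irregularity of real
  motility is not modelled.
* The near-wall concentration boundary layer (tens of micrometres at these
  Péclet numbers) is thinner than the wall cell even at production
  resolution; species contrasts that live inside it (e.g. the few-percent
  difference between insulin and C10 surface peaks) are systematically
  muted relative to boundary-layer-resolving solvers.
* The drink rheology is a calibrated stand-in (above); drink-specific
  quantitative claims require fitted parameters.
* At the scaled-down resolutions the absolute near-wall percentages are
  under-predicted (the metric still rises under refinement at `medium`);
  orderings between conditions are robust in the cases examined.
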