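# Methods

## The model

`furrowsim` simulates ventral furrow (VF) formation in the early
*Drosophila* embryo as a fluid–structure interaction problem.  Cell
membranes (together with their load-bearing cortical cytoskeleton) are
elastic spring networks; the cytoplasm, yolk and perivitelline fluid are
Newtonian and inertialess; the rigid vitelline shell is a no-slip boundary.
Because the Reynolds number of gastrulation flows is of order 10⁻⁸
(`reynolds_number(1e3 kg/m³, 1 µm/s, 100 µm, 10 Pa·s)`), the velocity field
is determined instantaneously by the force distribution: the system is a
Stokes problem re-solved at every time step.

The solid and fluid are coupled by the immersed boundary method.  Each step:

1. **Forces** at every solid node: Hookean spring forces `k(ℓ − ℓ0)` plus
   active contractile tension.  Every membrane carries a small constitutive
   tension σ0; the apical and lateral membranes of the 16 mesodermal cells
   additionally carry a tension ramped linearly from 0 to σmax over the ramp
   duration T (or applied instantaneously).
2. **Spreading** of node forces to the staggered fluid grid with the 4-point
   Peskin kernel (exact partition of unity and vanishing first moment, so
   total force is conserved to round-off and linear velocity fields
   interpolate exactly).
3. **Stokes solve** of −∇·(η(∇u+∇uᵀ)) + ∇p = f, ∇·u = 0 with spatially
   varying viscosity on a MAC grid; the vitelline circle/spheroid is imposed
   by masking (pressure cells active when their centre is inside; faces
   active when both flanking cells are; everything else pinned to zero).
   The saddle system is factorized once per domain (SuperLU) and reused for
   every step, so a time step costs one pair of triangular solves.
4. **Interpolation** of grid velocities back to the nodes with the same
   kernel weights (the adjoint of spreading).
5. **Forward-Euler advection** of the nodes, `x ← x + dt·v`.

Incompressibility of the fluid makes compartment volumes (cells, yolk,
perivitelline space) conserved quantities; the suite verifies the drift
rather than enforcing it by correction.

### Active-tension details

Two refinements of the plain "constant contractile tension" are part of the
model:

* **Class weights.**  The ramped tension is weighted per membrane class
  (`apical_fraction`, default 1.0; `lateral_fraction`, default 0.15).  The
  relative magnitudes of apical and lateral contractility are free
  parameters of the model; with *equal* weights, tension minimizes total
  membrane length and the energetically preferred response is isotropic
  cell rounding (cells square up, the tissue never folds).  Apical-dominant
  weighting selects the constriction mode that drives invagination.
* **Saturation.**  A constant tension on a shrinking segment is singular —
  the segment collapses to zero length with diverging effective stiffness.
  Below `tension_cutoff_frac` (default 0.5) of the rest length, active
  tension decreases proportionally to the current length, mimicking
  motor-density saturation and keeping the explicit integrator stable.

Two optional constraint forces are available but disabled in the default
study (see *Known limitations*): a global perivitelline volume-conservation
penalty (`peri_stiffness`) and a one-sided vitelline contact force
(`wall_stiffness`, `wall_slack`).

## Geometry

**2D** (`build_cross_section_2d`): a transverse cross-section — a ring of
`n_cells` = 80 quadrilateral cells between the circular vitelline boundary
(R = 90 µm) and the yolk, with cell height 35 µm and a perivitelline layer
of width `gap` between the apical surfaces and the shell.  The 16 cells
centred on the ventral midline are mesodermal.  Membranes are subdivided
into springs either a fixed number per membrane (`nodes_per_membrane`) or
at a target segment length (`spacing`); simulations use `spacing` so the
stiffest spring (and with it the stable dt) is uniform.  Spring stiffness
is `K_m/ℓ0` where `K_m` is the membrane stretch modulus (E·h per unit
depth).  Lateral membranes carry signed positions −n/2…n/2−1 with position
0 exactly on the midline.

**3D** (`build_embryo_3d`): a prolate spheroid (default semi-axes
230 × 90 × 90 µm) whose epithelium band is tessellated into prism-like
cells (bands along the long axis × azimuthal sectors), every cell bounded
by watertight triangulated apical/lateral/basal plates; a `resolution`
parameter subdivides the patches.  The equal-spring correspondence for a
uniform triangular lattice (`k = √3·E·h/2`, lattice-fixed ν = 1/3) maps
plate material to spring stiffness.

`remove_basal_membranes` deletes every basal-class spring/face (the anillin
knockdown, in which cells stay open to the yolk); nodes shared with lateral
membranes survive, and volume bookkeeping switches to the merged yolk∪cells
compartment plus per-cell *retained* areas (the open polygon closed by its
basal chord).

## The frozen 2D study

The 2D model runs in arbitrary units, as is appropriate for a
cross-section toy model: η = 1, K_m = 1.  Geometry is metric (µm).  The
published cross-section model fixes only the mesodermal cell count (16);
all remaining values are this package's choices, set once:

| parameter | value | note |
|---|---|---|
| n_cells / R / height | 80 / 90 µm / 35 µm | typical transverse section |
| perivitelline gap | 8 µm | numerical: ≥3 grid cells so the kernel does not glue the tissue to the wall (a real embryo's film is ~1 µm; see limitations) |
| marker spacing | 1.3 µm | ≈ h/2 at the 80² grid; membrane leak < 1% |
| grid | 80² over the disk | h ≈ 2.3 µm |
| η_pv/η | 10⁻³ | low-viscosity perivitelline layer |
| σ0, σmax | 0.01, 4.0 K_m | constitutive vs ramped mesodermal tension |
| apical/lateral weight | 1.0 / 0.15 | apical-dominant constriction |
| ramp T | 20 s | model time units |
| dt | 0.06 (× η-factor) | explicit stability bound ≈ c·η·ℓ0/K_m |
| t_max / stop | 500 s, plateau rule | stop when the running max depth grows < 0.1 % R over the trailing 5 % of elapsed time |

Low-viscosity variants step at dt/100 (stability scales with η) and run
1.05 ramp durations — their dynamics are 100× faster, so this horizon is
the equivalent of 105 ramp durations of full-viscosity relaxation.

Furrow depth is the inward radial displacement of the ventral-midline
apical vertex relative to its initial radius.  The lateral membrane-length
profile is the arc length of each lateral chain indexed by signed position.
Flow recirculation integrates the vorticity over the left and right
half-domains.

Exact property of the scheme: scaling (η, ramp T, duration, dt) →
(η/c, T/c, duration/c, dt/c) reproduces the identical node trajectory on a
rescaled clock (Stokes linearity; verified to 10⁻⁶ relative in the suite).
Changing viscosity and changing ramp time are mathematically the same
experiment.

## Synthetic data generators

* **Tracks** emulate 0.5 µm beads imaged for 10 min.  `viscous`: planar
  Brownian motion, default D = 0.0075 µm²/s so that MSD(10 min) = 4Dτ =
  18 µm² — the regime in which beads wander ~4 µm, a fifth of a cell
  height, while the MSD stays linear.  `kelvin_voigt`: an exact
  Ornstein–Uhlenbeck process started from its stationary trap distribution
  (plateau 4·D·τ_r), the negative control an elastic cytoplasm would
  produce.  What these do **not** emulate: localization noise, frame
  dropouts, tracking errors, spatial heterogeneity — passing tests show
  estimator correctness, not robustness to imaging artefacts.
* **Profiles** emulate per-embryo lateral membrane lengths over positions
  −10…9: `double_peak` (late wild type: longest membranes peripheral in the
  furrow), `single_peak` (knockdown: longest central), `flat` (null).
  Gaussian per-position noise (2 µm) plus a half-sized embryo-level offset;
  amplitude 8 µm over a 25 µm baseline was chosen once so that the two
  patterns separate at p < 0.001 with realistic group sizes (10 vs 6
  embryos), matching the significance regime reported for real genotype
  comparisons.  Real profiles have correlated, asymmetric, heteroscedastic
  errors; the generator has none of these.

## Analysis pipelines

* **MSD**: time-and-ensemble averaged with overlapping windows, pair counts
  reported per lag.  Linearity: least-squares slope α of log MSD vs log τ;
  α ≥ 0.9 classifies as viscous (the threshold operationalizes
  "approximately linear" and is exposed).  Recoil: displacement projected
  on the pull axis; fraction < 0.05 counts as "no detectable recoil".
* **Profile statistics**: 20-position rows are trimmed symmetrically to 18
  (the reconciliation of 20 positions with six triples is unstated in the
  source protocol; one position is dropped from each flank), binned in
  sequential triples to six means, projected on the Fisher discriminant
  w ∝ S_w⁻¹(μ_A−μ_B) (ridge-regularized λ = 10⁻⁶·tr(S_w)/p when scatter is
  singular, which is routine at 6 bins and few embryos), and compared by
  the two-sample KS test (exact enumeration for |x|·|y| ≤ 400, asymptotic
  beyond).  Fitting the discriminant on the same data that is then tested
  inflates the type-I error; `compare_groups(split_fit=True)` fits on a
  held-out half and tests the rest, and the suite measures both rates.

## Numerical choices

* MAC discretization with the full symmetric stress form (variable
  viscosity); mirrored tangential ghosts at no-slip edges (second order at
  grid-aligned walls, first order on the staircase circle).  Pressure gauge
  fixed by pinning one interior cell, which is mass-exact because the
  masked divergence telescopes.
* Direct factorization is reused across steps; the residual is checked per
  solve.  In 3D, SuperLU fill-in limits practical grids to ~16³; meaningful
  3D production runs would need a multigrid or preconditioned iterative
  solver (not included).
* Explicit Euler advection with dt ≈ 0.2–0.25 of the spring stability
  limit; degenerate inputs (zero-length springs, NaN positions, escaping
  nodes) raise immediately rather than propagate.
* Tie-breaks: `time_to_max_depth` returns the earliest maximising sample; a
  trajectory whose depth is still rising at t_max is flagged rather than
  silently truncated.

## Known limitations

* **Desk-resolution perivitelline layer.**  The real perivitelline film is
  ~1 µm; at h ≈ 2.3 µm it must be widened to ~8 µm to keep the immersed
  boundary off the no-slip wall.  The widened layer is a fluid reservoir
  that admits a slow, volume-*independent* deformation mode in basally-open
  embryos: the mesodermal apical band digs inward while the ectoderm bulges
  outward into the gap.  Variants with more effective time (lower η ≡
  longer time; slower ramps) progress *further* along this mode.  In this
  regime the open-cell depth does not decrease under 100-fold viscosity
  reduction or 33-fold ramp slowing — the opposite of the behaviour the
  model family shows when the thin film is resolved, where wide craters are
  volume-starved and only volume-conserving folds can deepen.  Resolving
  the film (h ≲ 0.3 µm) is ~100× the desk-scale cost.  The constraint
  forces in `mechanics` (perivitelline-area penalty, vitelline contact)
  were built to restore the thin-film budget at coarse resolution; at this
  grid they also freeze the closed-cell furrow (every 2D invagination needs
  some film slack) and are therefore disabled in the frozen study.  The
  corresponding acceptance checks are left failing deliberately; the
  numbers the suite reports are the honestly simulated ones.
* Closed-cell volume drift is < 1 % over a full baseline run at the frozen
  resolution but grows at coarser grids or sparser markers.
* No membrane bending stiffness (stretch-dominated plates), no cell
  rearrangements (connectivity is fixed for a whole run), no viscoelastic
  membrane laws.
* The 3D path ships validated geometry, mechanics and solver components
  and a coupled smoke run; quantitative 3D furrow depths additionally
  require the measured material-parameter set, which is not part of this
  package's inputs — the defaults are documented placeholders.
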