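# Methods

`thrombotaxis` models how neutrophils crawl among platelet thrombi in a
parallel-plate flow chamber. Thrombi growing on a collagen-coated coverslip
release soluble chemoattractant (CA) into the perfusing blood; the flow
stretches the CA into a downstream tail; crawling neutrophils read the local
CA gradient through surface receptors and bias their motion accordingly —
which, in the tail of a thrombus, means moving against the flow. The package
computes the CA field, simulates receptor-driven walkers in it, and provides
the trajectory statistics used to compare model and experiment.

## Geometry and units

The chamber plane is a regular 2D grid with isotropic spacing `dx` (um).
The flow axis is +x; x grows with column index, y with row index; physical
coordinates sit at pixel centres. Units are um, seconds and nM throughout;
number density converts to concentration as 1 molecule/um^3 = 1.6606 nM.
Thrombi enter as binary masks (any positive pixel is thrombus), the ingested
output of an upstream pixel classifier; cell tracks enter as delimited
tables in either a canonical seconds-stamped dialect or the frame-indexed
dialect of particle-tracking software. The acquisition frame interval is
instrument-specific and is a required argument for the frame dialect, never
defaulted.

## Flow field

The full chamber (0.1 x 18 x 2 mm) carries laminar flow with wall shear
rates mu = 0-500 1/s. Neutrophils crawl on the coverslip, so the model
reduces the 3D chamber to the near-wall layer they inhabit: advection acts
at the crawling-plane speed `u = mu * h_ref`, with `h_ref = 5 um` (about
half a neutrophil height) as the default reference height. Two modes:

* **uniform** (default): plug flow `(u, 0)` ignoring obstacles — adequate
  because the CA source sits on the obstacles themselves and the tail forms
  downstream regardless of the local flow perturbation;
* **stokes**: steady incompressible creeping flow around the thrombi, in a
  streamfunction-vorticity formulation with Brinkman volume penalization
  (dimensionless strength 1e4, i.e. friction 1e4/dx^2) enforcing no-slip on
  thrombus pixels. The plug inlet and fixed side-wall streamfunction values
  make the inlet-to-outlet flux exactly conserved, and the discrete velocity
  field is divergence-free by construction. The linear system (two coupled
  Poisson blocks) is solved directly; residual above 1e-6 raises an error.

## Chemoattractant field

The CA is a single effective interleukin-like species: 8 kDa, D = 130
um^2/s, released at 2900 molecules per platelet per 30-minute perfusion.
The PF4 variant is the same model with a lower D. The platelet count of a
thrombus is its projected area divided by a 5 um^2 per-platelet footprint,
giving a uniform volumetric source on thrombus pixels of

    S = (2900/1800 s) / (5 um^2) / h_layer  molecules um^-3 s^-1,

depth-averaged over an effective near-wall layer `h_layer = 10 um`.
Release is continuous and transport across a 250 um field at these speeds
takes seconds, so the quasi-steady solution of

    D lap(c) - u . grad(c) + S = 0

is used; no transient mode is provided. Boundary conditions: absorbing
inlet (c = 0), advective outflow at the outlet, no-flux side walls.
Concentration is solved inside thrombi too — platelet aggregates are
permeable to diffusion at this scale; obstacles exclude flow and walker
motion only.

**Discretization.** Finite volumes with exponentially fitted
(Scharfetter-Gummel) face fluxes, `F = (D/dx)[B(-Pe) c_up - B(Pe) c_down]`
with `B(x) = x/(e^x - 1)` and the face Peclet number `Pe = u dx / D`.
This scheme is positivity-preserving and uniformly accurate from the
diffusive to the strongly advective regime, where plain upwinding would add
numerical diffusion of order `u dx / 2` — comparable to D itself at the
study's shear rates — and central differencing would oscillate. The sparse
linear system is solved directly; a solution with negative concentration
beyond round-off raises a numerical error advising grid refinement.

Against the free-space point-source kernel `c = (Q/2piD) e^{Ux/2D}
K0(Ur/2D)` the solver agrees to better than 2% (max, relative) over the
annulus 5dx <= r <= side/4 on a 512^2 grid at u = 500 um/s, with dx =
0.0625 um so that the lateral wake layer (2D/u ~ 0.5 um) is resolved.
The comparison excludes points where the analytic kernel falls below 1e-6
of its annulus maximum: upstream of a source at these Peclet numbers the
kernel decays like e^{-ur/D} (an e-folding every 0.26 um), reaching values
below the relative dynamic range any double-precision field solve can
represent pointwise; a relative error there is numerically meaningless.

## The walker

Each model neutrophil is a point walker with cell length `ell_c`
(10-20 um, default 15), persistence time `L = 22 s`, time step `dt = 1 s`,
mean speed `v_avg` (set per cell from its reference track in ensemble
runs), receptor dissociation constant `K_d` (default 1 nM) and sensitivity
`k`. Per step:

1. **Gradient sampling.** Sobel-type kernels with an ellipsoidal footprint
   — extent `ell_c` along the previous heading, `ell_c/2` across it —
   are rotated into the cell frame and applied by bilinear sampling of the
   concentration. Derivative rows are coordinate-weighted with binomial
   smoothing and normalized so a linear ramp `c = a x` returns exactly
   `a` nM/um at any rotation. Both gradient components are measured in the
   cell frame and rotated back, giving magnitude `|grad c|` and lab-frame
   direction `theta_grad`.
2. **Receptor occupancy.** The differential fractional receptor occupancy
   across the cell is `DFRO = (ell_c/K_d) |grad c| / (1 + c/K_d)^2`. It is
   clamped at 1 (a fractional occupancy difference cannot exceed one)
   before forming the von Mises concentration `kappa = k * min(DFRO, 1)`.
3. **Heading.** `theta_sum = theta_grad + theta_random`, with
   `theta_random ~ vonMises(0, kappa)`; `kappa = 0` is the uniform circle.
   When `|grad c| < 1e-12` nM/um the convention `theta_grad := theta_prev`
   applies, so an insensitive walker reduces to an unbiased persistent walk.
4. **Velocity recurrence.** With memory coefficient `B_mem = L/dt`,

       v^N = v_avg [ e(theta_sum^N) + B_mem e(theta_sum^{N-1}) ] / (1 + B_mem),

   a convex blend of unit-speed headings, so the per-step displacement
   never exceeds `v_avg dt` (equality only when the heading repeats).
5. **Obstacles and edges.** A step that would land on a thrombus pixel or
   leave the walkable margin is truncated to the last admissible point
   along the segment (scanned at half-pixel resolution); the heading is
   kept. The margin is the larger of 10 um (unseen thrombi may lie beyond
   the field edge) and the rotated kernel footprint radius, so gradient
   sampling never clips. A walker whose window is clipped at its very
   start terminates with reason "edge".

The initial heading is drawn uniformly unless a reference track supplies
its first-step direction, in which case ensemble runs share the reference's
start, heading and mean speed and differ only in their noise streams (seed
= base seed + run index, recorded per run).

`dt = 1 s` resolves crawling speeds (~0.1 um/s) at sub-pixel steps and
makes `B_mem = 22` with the cited persistence time. The sensitivity `k` is
not experimentally constrained anywhere; the default `k = 5000` was fixed
once from the model's own scales: with the CA parameters above, wake DFRO
values are ~1e-4 on the tail axis and ~2e-3 at its flanks, so k = 5000
yields kappa ~ 0.5-10 there — strong but stochastic gradient following.
Counter-flow emergence is robust from k ~ 1000 upward.

## Trajectory statistics

* **Angles.** Step angles are measured against the flow axis, wrapped to
  (-pi, pi]; histograms carry the mean resultant vector. Tracks shorter
  than 250 s are dropped and survivors resampled to a uniform grid
  (default 5 s) before angle analysis, matching the acquisition analysis.
* **Proximity.** Distance from each track point to the nearest thrombus
  edge via the Euclidean distance transform (0 inside a thrombus). The
  null is a random trajectory with the same step lengths (hence the same
  speed profile) and independent uniform directions from a uniform start;
  out-of-bounds steps re-draw the direction only, so lengths are conserved
  exactly. Significance: two-sided Mann-Whitney U, exact for small
  samples. The test compares per-cell mean distances by default: points
  within one track are strongly autocorrelated, and pooling them would
  overstate the sample size and miscalibrate the null; pooled per-point
  distances are returned alongside and can be tested with
  `reduction="points"`.
* **Selection.** Cells eligible for model comparison have (a) under 10%
  of steps classified as rolling — faster than 1 um/s (about 5x a typical
  crawl; the threshold is configurable, as "rolling" is not quantified
  experimentally) within 30 degrees of the flow axis; (b) no neighbour in
  the upstream half-disc of radius 10 um at any co-observed time (active
  neutrophils secrete their own attractant); (c) all points more than
  10 um from the field edge.
* **Scoring.** Model and reference are resampled onto a shared uniform
  grid over their temporal overlap; the score is the mean point-wise
  Euclidean distance (a pseudometric). A run "resembles" its reference
  when the score is within one cell length `ell_c` — a declared
  reconstruction: no operational criterion is stated for the original
  success counts, and one cell length brackets the reported mean
  successful distance.

## Synthetic scenarios

`synthio` generates the study conditions: a square field of 100-250 um
side (default 200 um at 1 um/px), a few non-overlapping disc thrombi
(default 4, radius 8 +/- 2 um, ~2% area coverage; ellipse-shaped blobs as
a fuzz option), shear 100 1/s, and reference tracks produced by the walker
itself with known parameters (default 18 cells, 250 s, 0.15 um/s).
Starts are uniform over the margin-inset field, keep half a cell length
clear of thrombi, and default to 25 um mutual separation so generated
cells pass the selection criteria by construction; draws that pin against
an obstacle (zero path length) are rejected and resampled. What the
generator does **not** emulate: rolling and detachment, cell-cell
attraction, irregular classifier-shaped thrombus boundaries (beyond the
ellipse option), localization noise, and frame-rate jitter — so passing
tests demonstrate the mechanisms, not performance on raw microscopy.

## Statistical design of the acceptance checks

* The 18-cell x 36-run layout is reproduced exactly (648 runs) and the
  full-model ensembles are compared with chemoattractant-insensitive
  (k = 0) ensembles by Mann-Whitney on the pooled per-run scores.
* Sensitivity recovery scores candidates {k*/4, k*/2, k*, 2k*, 4k*}
  against tracks generated at k*; each of 50 replicates averages the mean
  score over 3 reference cells and 12 runs per candidate. A single
  reference leaves the replicate dominated by that trajectory's
  idiosyncrasy; averaging over three isolates the sensitivity signal.
* Null calibration generates insensitive walkers with iid uniform starts
  (the exact Mann-Whitney null assumes independent sampling units, which
  the 25 um separation constraint would violate) and checks the p-value
  distribution against U(0,1) by Kolmogorov-Smirnov over 200 replicates.

## Numerical choices and limitations

* Direct sparse solves throughout (no iteration tolerance to tune); the
  advection scheme's positivity means Peclet instability surfaces as an
  explicit error rather than silent oscillation.
* Bilinear interpolation everywhere a field is sampled off-grid; distances
  inherit +/- dx accuracy from the mask raster.
* Zero-length steps carry no direction and are skipped in angle analysis;
  an all-static track yields an empty angle set with a warning.
* The model omits rolling, attachment/detachment, 3D motion, turbulence,
  thrombin chemistry and multi-species chemokine mixtures; a single
  effective CA is simulated per run. Absolute CA calibration is absorbed
  by the configurable pair (k, K_d) — only their combination with the
  source rate is identifiable from trajectories.
* Walkers can legitimately pin against a thrombus edge under strong
  gradients (step truncation with heading retained); ensemble references
  are screened for this degeneracy, simulation output is not.
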