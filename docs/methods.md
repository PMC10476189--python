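# Methods

## The model

IgG is represented by six spherical beads: a stem `S` (a_H = 4.50 nm), a
small hinge `H` (1.00 nm), and two arms of two beads each
(`A1`-`A2`, `A1p`-`A2p`, 2.42 nm), connected by stiff harmonic bonds
(S-H 6.0 nm; H-A1 3.9 nm; A1-A2 3.0 nm; kappa = 1909.9 kcal mol^-1 nm^-2)
so that the two beads of an arm overlap and form an elongated lobe.
Harmonic angle terms control the shape: three soft terms at the hinge
(S-H-A1, S-H-A1p, A1-H-A1p) act as a ball-and-socket joint, and one stiff
180-degree term per arm (H-A1-A2, H-A1p-A2p) keeps each arm straight.
Both bonded forms use the 1/2-prefactor convention,
U = 1/2 k (x - x_eq)^2; the prefactor is a configuration switch
(`bond_prefactor`) because either convention appears in the literature and
the bonds are stiff enough that observables are insensitive to it.

Beads are uncharged and attraction-free: sterics only, and only *between*
molecules — beads of one IgG may overlap freely, which is what lets two
2.42 nm beads at 3.0 nm spacing mimic a Fab arm.  Hard cores are realised
as a finite harmonic overlap repulsion U = 1/2 k_ov (sigma - r)^2 with
k_ov = 4000 kcal mol^-1 nm^-2, steep enough that thermal overlaps stay
below ~0.05 nm at k_B T = 0.58 kcal/mol; a true hard-sphere rejection
scheme would not have a continuous force for the overdamped propagator.
Ficoll 70 crowders are single inert spheres of radius 5.1 nm (hard-core =
hydrodynamic radius).  Walls (used in binding experiments) apply the same
quadratic penalty below bead-surface contact; antigen sites are geometric
hemispheres of radius 1.0 nm on the wall and exert no force.

### Angle parameters

The hinge equilibrium angles and force constants are the model's only
free parameters here.  Defaults: theta_eq = 90 degrees with
xi = 1.0 kcal mol^-1 rad^-2 for the three hinge terms — this puts the
maxima of the arm-arm (psi) and arm-stem (phi) angle densities at
90 degrees with the broad, slightly skewed shape characteristic of IgG
flexibility measurements — and theta_eq = 180 degrees with
xi = 500 kcal mol^-1 rad^-2 for the arm-straightening terms, which leaves
about 2 degrees of rms axis wobble, negligible against the ~25-degree
width of the hinge distributions while adding no timestep constraint
beyond the bonds'.  `analysis.calibrate_angles` can refit
(theta_eq, xi) to an externally supplied angle CDF by minimising the
sup-distance between the single-angle Boltzmann prediction and the
target.

## Dynamics

The overdamped Ermak-McCammon scheme advances positions by
`(D F) dt / k_B T + sqrt(2 dt) L z` with `L L^T = D`, where D is the
Rotne-Prager-Yamakawa diffusion matrix generalised to unequal radii,
including the overlap-regularised branch (continuous at contact, positive
definite for any configuration).  RPY is divergence-free, so no
mobility-divergence drift term is needed, and none exists in the code.

Hydrodynamic coupling scope is a mode switch:

* `rpy_intra` (default): coupling within each molecule, molecules
  mutually free-draining.  This is sufficient for the dilute-limit
  transport coefficients and keeps crowded systems affordable.
* `free_draining`: plain Stokes drag, used for equilibrium sampling where
  mobilities cannot affect the stationary distribution.
* `rpy_all`: all-pairs minimum-image coupling (no Ewald summation; a
  far-field approximation for crowded boxes).

Units are nm, us, kcal/mol throughout; temperature 293.15 K and viscosity
1.002 mPa s by default, the unique pair consistent with the model's target
dilute diffusion coefficient and hydrodynamic radius under the
Stokes-Einstein-Sutherland relation.

### Timestep and stability

The stiffest relaxation is a bond on the smallest bead:
tau = k_B T / (D_bead k_eff) ~ 1.4 ps for the hinge.  `run` refuses
dt > tau/5; the default dt = 0.2 ps.  Long equilibrium-sampling runs in the
tests use the same tau/5 rule applied to deliberately softened bonds
(kappa does not enter any angular equilibrium distribution — the
configurational measure factorises over bond vectors — so softening bonds
is a pure efficiency device for sampling angle statistics).  A runtime
guard aborts if any bead moves more than half the smallest hard-core
radius in one step.

The mobility matrix can be refreshed every `mobility_stride` steps
(default 1).  Conformations move ~0.01 nm per step, so a stride of 10
(used for the long production runs) changes the mobility by a relative
~1e-3 between refreshes; the noise Cholesky factor is refreshed on the
same stride.

## Observables

* Molecule position = unweighted geometric centre of bead centres;
  R_g likewise unweighted.  Both are rotation-invariant and avoid an
  arbitrary mass assignment for beads that represent volume, not mass.
* D from the time-origin-averaged MSD (FFT-based) of molecule centres:
  least-squares slope over a lag window divided by 6.  The default
  single-IgG window starts at 0.5 us, past the conformational/rotational
  transient (the stem-axis relaxation time is 1/(2 D_r) ~ 0.45 us); the
  window top is kept at a small multiple of the start because the variance
  of a time-averaged MSD grows quadratically with lag.  Windows are logged
  run configuration items.  Uncertainties come from block averaging
  (trajectory thirds, pooled across seeds).
* D_r from the first-rank stem-axis (S->H) ACF fitted log-linearly to
  exp(-2 D_r t).  The early ACF contains a fast hinge-wobble transient, so
  the default fit window starts after ~0.1 us and stops before the ACF
  decays into noise; like the MSD window this is a logged choice, and the
  fitted value is known to be window-sensitive at the +-10% level.
* psi = angle between arm axes (H->A2, H->A2p); phi = angle between the
  stem axis (H->S) and each arm axis.  Empirical PDFs are obtained by
  Gaussian-smoothing the empirical CDF (5-degree bandwidth) before
  central differencing; raw differentiation of an empirical CDF is
  noise-dominated.
* Crowding sensitivities: least-squares slopes with the intercept pinned
  at the dilute reference, D/D0 = 1 - alpha*phi_occ and
  Rg/Rg0 = 1 - alpha_g*phi_occ; alpha_nonflex = alpha + alpha_g by
  definition.
* phi_occ = union volume of hard-core spheres over box volume, counting
  IgG and Ficoll alike; intra-IgG sphere overlaps are subtracted
  (pairwise lens volumes, with a Monte-Carlo fallback if triple overlaps
  ever appear) so overlapping arm beads do not inflate the fraction.

### Equilibrium references

Two independent Boltzmann references validate the sampler: 1-D quadrature
of r^2 exp(-U/kT) and sin(theta) exp(-U/kT) for isolated bonds/angles, and
a three-dimensional quadrature over the coupled hinge (stem direction and
two straight arm directions, polar angles + relative azimuth) for the
psi/phi distributions of the full IgG.  The coupled quadrature treats arms
as rigid axes; the neglected arm wobble (~2 degrees rms) is far below the
resolution of the KS comparisons it serves.

## Association kinetics (NAM)

Trajectories start with the IgG centre at l0 = 30 nm from the antigen,
count as reactive when an arm-tip bead comes within 0.1 nm
surface-to-surface of the antigen, and as escaped beyond l_esc = 35 nm;
Omega = l0/l_esc.  The rate is k = 4 pi D R_eff with
R_eff = beta l0 / (1 - (1-beta) Omega); beta carries a Wilson 95% interval.
The whole pipeline is validated against the Smoluchowski rate of a
perfectly absorbing sphere (adaptive-timestep free tracer; the per-axis
rms step is 3% of the gap to the nearest boundary, at which point the
first-passage discretisation bias is below the oracle's 5% tolerance).
The mutual D entering k is the IgG translational D at the corresponding
phi_occ (the antigen is immobile).  Budget-exhausted runs count as
non-reactive (first step) or right-censored (second step) and are
reported.  For the second step one arm tip is tethered to antigen 1 by a
stiff harmonic bond at the contact distance — preserving ball-and-socket
flexibility — and the first-passage time of the free tip to antigen 2 at
in-plane distance d is recorded, along with the (z, rho) occupancy of the
free tip.

## Synthetic-data scope

All test inputs are generated by the package itself (packed systems,
seeded BD runs, quadrature references, binomial draws); no experimental
data ships with it.  What passing tests show is therefore internal
consistency with the stated model — harmonic + hard-core + far-field RPY —
not agreement with laboratory measurements of IgG; in particular real
antibodies have charge, dispersion and solvent-structure effects that the
model excludes by construction.

## Packaged experiment sizes

Single-CPU reproducibility drives the default problem sizes, all of them
ordinary package choices exposed as parameters:

* dilute transport: 2 seeded boxes of 8 hydrodynamically independent IgG
  copies, 6 us production each (96 us of effective sampling), dt = 0.25 ps
  (inside the tau/5 stability rule), mobility refresh every 10 steps;
* angle equilibrium: one 280 us free-draining run with softened bonds,
  ~1e5 psi samples;
* crowding sweep (test fixture): free-draining mode, 4 IgG in a 50 nm
  box, 0.8 us per phi point -- enough to exercise the full pipeline but
  far below what the alpha sensitivities need, so those comparisons are
  reported with their (large) statistical uncertainty;
* binding steps (test fixtures): tens of NAM trajectories per condition
  rather than the >=1000 of a production study; beta intervals are
  correspondingly wide.  Production-scale runs use the same code paths
  through the CLI.

## Known limitations

* Far-field (RPY) hydrodynamics only, with no inter-molecular coupling in
  the default mode and no Ewald summation in `rpy_all`: absolute crowded
  slowdowns are systematically steeper than experiment-calibrated
  reference values, because steric obstruction is not softened by
  solvent-mediated collective motion.  The crowding-sensitivity fits are
  therefore mode-dependent; directional statements (slowdown, compaction)
  are robust, the alpha magnitudes are not.
* The dilute transport coefficients of this parameterisation agree with
  the nominal targets only to within a few percent (see the acceptance
  outputs); the hinge force constants and the treatment of periodic
  hydrodynamic images in the original parameterisation are not
  recoverable from the available description, and no parameter here was
  adjusted to chase the printed values.
* Desk-scale statistics: the packaged experiment sizes (tens of us of
  sampling, hundreds of NAM trajectories) are chosen to run on a single
  CPU; quantities quoted with block-averaged errors make the statistical
  limits explicit.
* Rotational diffusion under crowding is deliberately out of scope: the
  window sensitivity of the ACF fit makes phi_occ trends in D_r
  unresolvable at these run lengths.
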