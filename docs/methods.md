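# Methods

This note documents the models implemented in `sasbead`, the numerical
choices behind them, and what the package's validation does and does not
demonstrate.

## Bead-model construction

A particle is specified as an ordered list of geometric subunits drawn
from a fixed catalogue (sphere, tri-axial ellipsoid, cylinder, disc, cube,
cuboid, hollow sphere, hollow cube, cylindrical ring, discoidal ring).
Each subunit carries dimensions in Å, an excess scattering length density
Δρ in arbitrary relative units (negative values are physical — e.g. a
hydrocarbon core in water seen by X-rays), and a center-of-mass shift.
Subunits are axis-aligned (cylinder/disc/ring axis along z); orientation
is deliberately not a parameter, placement freedom being the
center-of-mass shift only.

The model is discretised into `n_points_total` beads (default **N =
5000**, balancing precision against the O(N²) pair cost) at constant
point density: points are allocated to subunits proportional to their
analytic volumes by the largest-remainder rule (remainder ties broken by
subunit order), then sampled uniformly by rejection from each subunit's
bounding cuboid — uniform by construction and a single code path for every
kind.  Each bead receives the weight Δb = Δρ·V_point with V_point = ΣV/N
constant across the model.

Overlap between subunits is handled in one of two ways:

* **exclusion (default)** — beads of an earlier-listed subunit that fall
  inside any later-listed subunit are deleted.  Later subunits therefore
  "carve" earlier ones, which lets a small core cylinder listed last cut
  its volume out of a larger shell cylinder.  Deleted beads are *not*
  replaced: re-sampling would break the constant density, so the total
  may drop below N.
* **keep** — all beads are kept, and the effective contrast of an overlap
  region is the sum of the overlapping subunits' contrasts.

Which subunit "wins" a contested region is a convention, not physics; the
later-wins rule was chosen because it supports the carving idiom above.
Degenerate subunits (volume < 10⁻⁶ Å³, hollow bodies with inner ≥ outer)
are rejected at construction.

## Pair histogram and the Debye transform

All N(N−1)/2 pair distances are processed in streamed chunks (peak memory
O(chunk·N), so clouds far larger than the default N fit in ordinary RAM).
The weighted histogram uses bin width dr = D_max·(1+ε)/n_bins with
ε = 10⁻⁹ so the largest observed distance falls inside the last bin;
self-pairs are excluded, and the exported p(r) gains a leading (0, 0) row
and is normalized to max |p| = 1.  D_max is the exact largest pair
distance, not a bin edge; R_g comes from the discrete second moment of the
histogram, which for tiny clouds carries an O(dr) bias relative to the
exact pair distances (≈0.5% for a 2-point cloud at 100 bins) that vanishes
in the continuum limit the formula assumes.

The default bin count is n_bins = min(⌈√N_pairs⌉, 1000) with floor 50:
the square-root rule balances bin-count noise against resolution, and the
cap keeps the q-transform cheap (at the cap the residual smearing of
sin(x)/x over a bin is (q·dr)²/24 ≲ 2·10⁻³ relative at q = 0.5 Å⁻¹ for a
400 Å particle — below the bead-sampling noise).  P(q) is evaluated once
per (q, bin), never per pair, with sinc(0) ≡ 1 at the removable
singularity; q grids must be non-negative.

A direct Debye double sum (`debye_intensity`) is kept alongside as the
exact O(N²·n_q) reference; the test suite holds the two routes to 10⁻³
relative agreement on random clouds.

Contrast-matched models (ΣΔb = 0) have I(0) = 0, so the normalized P(q)
is undefined; the package raises a dedicated error rather than dividing
by a near-zero forward scattering.

## Polydispersity

Sample heterogeneity is modelled as a Gaussian distribution of a single
global size-scale factor s applied to all pair distances:

    p_poly(r) ∝ Σ_m  exp(−½((s_m−1)/σ_poly)²) · s_m⁶ · p_{s_m}(r)

with s_m a 15-node midpoint grid on [1−3σ_poly, 1+3σ_poly] and the s⁶
factor the squared relative volume v = s³ (intensity ∝ volume²; exact for
spheres, an approximation otherwise).  The integrand is smooth, and 15
nodes reproduce a 201-node reference to better than 0.1% on test shapes
(asserted in the suite).  σ_poly is restricted to (0, 0.33) so the
smallest scale 1−3σ_poly stays positive.  R_g and D_max are recomputed
from the polydisperse histogram; the s⁶ weighting favors enlarged copies,
so both grow with σ_poly.

## Structure factors, decoupling, roughness

Interparticle interference multiplies the intensity, I(q) ∝ P(q)·S(q),
and by contract touches **only** I(q): the reported p(r) is always that of
a single, non-interacting particle.

* **Percus–Yevick hard spheres** (radius R_hs, volume fraction
  η ∈ (0, 0.5]): the classic closed form S(q) = 1/(1 + 24η·G(A)/A) with
  A = 2qR_hs.  The three terms of G cancel catastrophically at small A, so
  for A < 0.1 each is replaced by its Taylor series through A⁴ (matched to
  an arbitrary-precision reference to ~10⁻⁹ in the tests); the A → 0 limit
  reproduces the compressibility value S(0) = (1−η)⁴/(1+2η)² exactly.
* **Fractal aggregates**: a fraction of the particles sit in mass-fractal
  aggregates of dimension D = 2 built of N_agg blocks of radius r0.  With
  D fixed at 2 the Teixeira form collapses to
  S_agg(q) = 1 + (N_agg−1)/(1+q²ξ²), and the cutoff length is set by
  requiring the forward limit of an N-mer, S_agg(0) = N_agg, giving
  ξ = r0·√(N_agg−1).  This minimal reconstruction (sharp forward
  normalization, no additional cutoff shape parameter) was chosen because
  it has the fewest free parameters consistent with a D = 2 aggregate.
  The blended curve is 1 + f·(S_agg−1) for aggregate fraction f.
* **Decoupling approximation** for nonspherical or multi-contrast
  particles: S_eff(q) = 1 + β(q)(S(q)−1) with β = ⟨A(q)⟩²/P(q).  For an
  arbitrary bead cloud the orientation-averaged amplitude is defined about
  the contrast-weighted center of mass,
  ⟨A(q)⟩ = Σ Δb_j sinc(q·|r_j − r_com|)/ΣΔb — exact for centrosymmetric
  bodies and reducing to the textbook sphere/ellipsoid expressions.
  β(0) = 1; the ratio is clipped to [0, 1] because bead noise near
  form-factor zeros would otherwise push it outside the physical range.
  β is computed from the monodisperse cloud even when polydispersity is
  on — a documented simplification consistent with applying S(q) after
  P(q) assembly.
* **Interface roughness** smears sharp inter-subunit boundaries by
  I(q)·exp(−½(qσ_R)²), applied after the structure factor; σ_R = 0 is an
  exact identity.

## Simulated noise

σ(q) = s·√((I(q)+c)/(k·q)) with k = 5·10⁶ and c = 0.05 Å, constants chosen
to imitate typical synchrotron SAXS uncertainties; the user scale s
(default 1) multiplies σ linearly.  I_sim is drawn independently per grid
point from Normal(I, σ), reproducibly under a seed.  Negative draws are
kept — buffer-subtracted SAXS data legitimately go negative — and q = 0 is
dropped from the noise grid (σ diverges there).  The default q grid is
linear, 0.001–0.5 Å⁻¹ with 400 points: a typical synchrotron range,
consistent with the error model's divergence at q = 0.

## Analytic oracles and fitting

Closed-form, orientationally averaged form factors (sphere, cylinder,
ellipsoid of revolution, core–shell cylinder) are normalized to P(0) = 1.
Orientational averages use 128-point Gauss–Legendre quadrature on
cos α ∈ [0, 1], which matches a 1024-point reference to 10⁻⁸ on the
core-shell reference geometry.  The core–shell cylinder superposes the
core at contrast (ρ_core − ρ_shell) and the outer envelope
(r_core + t, l_core + 2t) at ρ_shell, each weighted by its volume.

The fit minimizes χ² = Σ((I_sim − scale·P_model)/σ)² by bounded
trust-region least squares with a numerical Jacobian.  Because scale and
contrast parameters can correlate strongly, the optimizer is multi-started
from three relatively jittered initial guesses (deterministic jitter) and
keeps the lowest χ²; parameter standard deviations come from the
covariance (JᵀJ)⁻¹·χ²_red at the optimum.  In the packaged validation
loop the core contrast is held fixed at −1 — freeing both contrasts and
the scale leaves them degenerate — and the initial guess is the geometry
the data were built from, the natural starting point when validating a
form-factor implementation against its own construction.

## What the validation shows — and what it does not

The synthetic-data generator emulates a 1-D, buffer-subtracted,
azimuthally averaged solution-scattering experiment with uncorrelated
Gaussian noise.  It does not emulate instrument resolution smearing, 2-D
detector effects, correlated systematics of real buffer subtraction, or
atomic form factors (beads are point scatterers).  Passing tests
therefore demonstrate internal consistency of the simulation chain and
correctness against closed forms, not agreement with any real instrument.

Precision of the bead discretisation is q-limited.  A 5000-bead model
reproduces closed-form intensities to well under 0.5% (median over
realizations) in the Guinier region, and on a log-intensity scale the
curves remain visually indistinguishable far beyond q = 0.2 Å⁻¹.
Pointwise *relative* accuracy, however, is bounded by the sampling noise
floor of order 10⁻⁴ (relative to forward scattering): wherever the true
form factor dips below ~10⁻³ — e.g. the first orientationally averaged
cylinder minimum, P ≈ 4·10⁻⁴ at q ≈ 0.077 Å⁻¹ for R = 50 Å, L = 400 Å — a
5% pointwise band cannot be held at N = 5000 (nor, at exact form-factor
zeros, at any N).  `form_factor_tracking_q` measures this honestly: the
tracking q reported by `sasbead validate` and `scripts/acceptance.py` is
the last grid point before the first 5% violation, and for the reference
cylinder it lands near the first deep minimum (~0.07 Å⁻¹), while the
deviation *between* minima stays small to ~0.2 Å⁻¹ and shrinks with N
(max deviation below 0.2 Å⁻¹ falls ≈0.65 → 0.23 → 0.10 for N = 5k → 20k →
80k).

Stochastic conventions throughout: every random stage (sampling, noise)
takes an explicit seed; identical spec + seed gives bit-identical outputs,
including written files.  Validation quantities that depend on the
realization are reported as medians over five seeds.

## Known limitations

* Subunits cannot be rotated; no triangle-mesh or voxel bodies.
* Polydispersity is a single global size scale — no per-axis or
  aggregation-number polydispersity.
* Structure factors are PY hard-sphere and the D = 2 fractal only; no
  sticky-hard-sphere or screened-Coulomb models, and interactions are
  never propagated into p(r).
* Analytic fit models cover the four shapes above; no resolution
  smearing or polydisperse analytic models in the fit harness.
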