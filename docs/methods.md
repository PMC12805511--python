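# Methods

## Model and assumptions

The molecule is described by its orientation **Ω** (a molecule-fixed frame
relative to the laboratory) and the natural internal coordinates **q** of a
Z-matrix (bond lengths, bond angles, dihedrals; Nₛ = 3N−6).  The solvent is
implicit: it enters only through fluctuation–dissipation (the hydrodynamic
diffusion tensor) and through the assumption that the equilibrium density is
Boltzmann.  The dynamics is purely diffusive (overdamped); momenta are
projected out.  The conformational potential is harmonic about a single
minimum-energy structure q₀ with curvature **K**.  Consequences worth
spelling out:

* Only fluctuations within one conformational basin are described.  Molecules
  hopping between minima of similar energy need one run per minimum and a
  Boltzmann-weighted combination of the relaxation rates, and that is only
  defensible for high barriers; activated torsional jumps are outside this
  package's scope.
* The diffusion tensor is evaluated once, at q₀, and held fixed along the
  trajectory ("configuration-independent diffusion").  This is what makes the
  Cholesky factor of D reusable and the integrator cheap; it is an
  approximation for large-amplitude motions.
* Rotation is free (no orienting medium), so the stationary orientation
  distribution is uniform on SO(3) — the property the convergence
  diagnostics test.

## Parametrization

**Hydrodynamics.**  Every atom is a bead of the same effective radius
R_eff (default 2 Å; 1.4 Å fits small saccharide relaxation better) with
Stokes–Einstein friction ξ = CπR_effη (C = 6 stick by default, 4 slip; any
positive value is accepted since only the product CR_effη matters).
Hydrodynamic interaction between beads uses the Rotne–Prager–Yamakawa tensor
for equal stick spheres, with the standard overlapping-sphere branch below
2R_eff — overlap is the normal situation at atomic radii, not an edge case.
The generalized friction is Ξ = Aᵀ M⁻¹ A, where A stacks the translation
identity, the rotation cross-product operators about the (uniform-weight)
bead centre, and the internal Jacobian in the input frame; the Z-matrix
parametrization is taken as the complete constraint set.  Translation is
removed by Schur complement, implemented as the rotational+internal sub-block
of k_BT Ξ⁻¹ (mathematically identical, numerically simpler); the 3×3
translational diffusion block is reported alongside.  All friction algebra is
SI internally; the returned tensor carries internal rows in (Å, rad) units so
it combines directly with curvatures in J/(Å, rad)².

**Curvature.**  The Cartesian Hessian (external input; plain text or HDF5,
Tinker's kcal·mol⁻¹·Å⁻² by default, converted to J/Å² per molecule) is
transformed with the placement-map Jacobian, K = BᵀHB.  At a stationary
point the gradient term of the exact chain rule vanishes, which is the
regime the model assumes anyway; the synthetic-fixture tests verify the
transformation recovers known constants to 1e−10 and is invariant under
rigid motion of the inputs.  Eigenvalues of K below 1e−8 of the largest are
floored to that threshold (with a warning) so K^{1/2} exists; genuinely
negative curvature raises.

**Assembly.**  D = blockdiag(E,T)ᵀ S Dʰʸᵈʳᵒ S blockdiag(E,T) with
S = blockdiag(I₃, K^{1/2}/√k_BT).  The thermal scaling touches only the
internal rows and columns: the rotational block already has units of 1/s, and
this placement is the one that reproduces the analytic sandbox tensor
(internal entry 10k, coupling c√k, rotation unscaled) exactly, which the
tests enforce.  E and T are eigh eigenvector matrices with the sign
convention "largest-magnitude component positive" (E additionally forced to
det +1) for reproducibility.

## Coordinates and conventions

* Placement frame: atom 1 at the origin, atom 2 on +z, atom 3 in the xz
  plane with positive x.  Any fixed convention is equivalent because only
  internal motion and the separately tracked rotation are physical.
* Dihedral sign: right-handed looking along the second→third atom of the
  chain (the field-standard convention; cross-checked against an independent
  structural-biology library in the tests).  Dihedrals live in (−π, π]; the
  ±π branch cut is handled by wrapping in differences.
* The Jacobian B = ∂x/∂q is computed by complex-step differentiation of the
  placement map (step 1e−200), exact to machine precision; the test oracle
  uses real central differences at step 1e−6, an independent route.
* Angles are radians internally; distances angstrom.
* ZYZ Euler angles throughout (via scipy's rotation machinery); quaternions
  scalar-first, with q̇ = ½ q ⊗ (0, ω_body) kinematics.

## Brownian-dynamics integration

The Euler step forms the increment −Δt W(Q) D [0₃; z] + √(2Δt) W(Q) D^{1/2} n
with standard-Gaussian noise n and W block-diagonal (quaternion kinematics
matrix b(Q) on rotational rows, identity on internal rows).  The internal
update adds the increment to the previous z — the discretized
Ornstein–Uhlenbeck recursion whose stationary density is the standard
Gaussian; omitting the previous state would not sample equilibrium at all.
The quaternion update Q ← Q̃ + λQ solves λ² + 2λ(Q·Q̃) + |Q̃|² = 1 taking
the root nearer +1 (continuity), so |Q| = 1 holds exactly after every step;
a negative discriminant is diagnosed as "step too large".  The Runge–Kutta
variant takes a virtual Euler step with the *same* noise vector (the virtual
quaternion is renormalized before re-evaluating W — a choice, made so that
b(Q) is always evaluated on the unit sphere), then averages the drift and the
noise-projection matrices between the start and virtual points.  It is
stable to Δt = 1/(2 ω_max) against 1/(10 ω_max) for Euler, and both are
verified to sample the same stationary density.

D^{1/2} is the Cholesky factor, computed once (D is configuration
independent).  Randomness comes from numpy's PCG64; trajectory i of an
ensemble is seeded with master_seed + i, so runs are bit-reproducible.
Initial conditions sample equilibrium directly: z ~ N(0, I) and orientation
uniform (normalized 4-D Gaussian quaternion).  A |z| excursion beyond 10
standard deviations aborts with a step-size diagnosis.

**Scheduling.**  Δt = 1/(2 ω_max) (RK) or 1/(10 ω_max) (Euler); 20
trajectories, each 1000 × τ with τ = 1/(6 ω_min) — the rank-2 slow time, the
quantity NMR observables actually relax with (the bare 1/ω_min is exposed as
`tau_bare`); dump stride targeting 10⁴ snapshots per trajectory.  Everything
is overridable, and an override of Δt above the stability bound warns rather
than errors.

## Observables

C(t) = 5⟨D²₀₀(Ω_dip(t+s)) D²₀₀(Ω_dip(s))⟩, averaged over all time origins
(FFT estimator) with lags capped at half the trajectory, then over
trajectories; the factor 5 makes C(0) = 1 at equilibrium.  The dipolar frame
has Z along the X–H bond and Y normal to the H–X–substituent plane; only the
bond direction enters D²₀₀ (cylindrical symmetry).

The multiexponential fit (default 4 terms, max 5) uses variable projection:
nonnegative weights by NNLS inside a trust-region optimization of log τₖ,
initialized log-spaced between the dump resolution and the trajectory
length.  This conditioning makes the single-exponential case exact to 1e−6
and keeps the fit deterministic; non-convergence raises carrying the best
iterate and asks for a user initial guess.  Coincident time constants are
merged.  No constant offset is fitted: free tumbling forces C(∞) = 0.

Spectral densities use J(ω) = 2∫₀^∞ C(t) cos ωt dt = Σ aₖ 2τₖ/(1+ω²τₖ²)
with C(0) = 1.  This J is five times the (2/5)τ Lorentzian of the standard
relaxation literature, so the dipolar prefactor is d²/20 (not the d²/4 that
accompanies the (2/5) convention), with d = (μ₀/4π) γ_H γ_X ħ/r³, effective
r = 1.13 Å by default (librational correction), and the axially symmetric CSA
strength is c² = (ω_X δ)²/15 (inactive at the default δ_CSA = 0).  The set is
self-consistent: it reproduces the extreme-narrowing NOE plateau
1 + γ_H/(2γ_X) ≈ 2.988 for ¹³C–¹H and the absolute T1/T2 scale of the
standard treatments.  Gyromagnetic ratios, ħ and μ₀ are CODATA values; ω_X
follows from the ¹H spectrometer frequency by the γ ratio.

## Convergence diagnostics

At equilibrium α and γ are uniform on [−π, π], cos β uniform on [−1, 1], and
each zᵢ standard normal.  The report computes a Kolmogorov–Smirnov statistic
for each coordinate but evaluates its significance at the number of
*effective* samples the run affords, n_eff = min(n, T_total·ω/2), with ω the
model's own relaxation rate for that coordinate (ω_min of D for orientation,
the diagonal D entry for each z) — KS p-values at the raw correlated sample
count would be meaningless.  A coordinate is declared converged only if
n_eff ≥ 25 and the test does not reject at 1%.  The 25-sample floor encodes
that a short run cannot demonstrate convergence however well its histogram
happens to look; it is what makes a τ-length run fail the orientational
check while a 1000τ run passes, the behaviour a practitioner should demand
before trusting J(0).

## Synthetic data

The fixture generator builds H–(C)ₙ–H chains from chosen internal force
constants (defaults 300 kcal mol⁻¹ Å⁻² bonds, 80 kcal mol⁻¹ rad⁻² angles,
10 kcal mol⁻¹ rad⁻² dihedrals — ordinary force-field magnitudes; a jitter
option scatters them by seed) and assembles the Cartesian Hessian as
H = Cᵀ diag(k_q) C with C the finite-difference Wilson matrix, so the true
internal curvature is known exactly and H is rigid-motion invariant by
construction.  What these fixtures emulate: a stiff covalent skeleton with
realistic frequency separation between bond stretches (~10¹³ s⁻¹ after
thermal scaling) and overall tumbling (~10¹⁰ s⁻¹ for a 4-atom molecule in
water).  What they do not emulate: anharmonicity, coupled off-diagonal force
constants, solvent-damped soft torsions of real oligosaccharides, or a
realistic molecular surface for the hydrodynamics — so passing tests
demonstrate the machinery (transformations, sampling, estimators,
relaxation algebra), not force-field accuracy for any real molecule.  The
analytic sandbox (c, k) plays the complementary role of an exactly solvable
reference: eigenvalues in closed form, equilibrium densities known, so the
integrator's sampling and the scheduling heuristics are tested against exact
statements.

## Problem sizes used in the shipped tests

The statistical suites run at deliberately modest scale, chosen so that each
check still has decisive power: the free-rotor law uses 20 trajectories of
1000 rank-2 times at Δt = 0.01/D_R (the schedule bound would allow 0.5/D_R,
but resolving a rate of 6D_R to 5% needs lags well inside 1/(6D_R));
Ornstein–Uhlenbeck checks use 8 trajectories of 100 relaxation times; the
end-to-end demo runs 4 trajectories of 50τ with 2000 dumps.  The relaxation
and scheduling arithmetic is exact and runs at full precision regardless of
these sizes.

## Known limitations

* Single-minimum harmonic energetics; no activated coordinates or
  multi-minimum Boltzmann weighting.
* Geometry-independent diffusion tensor.
* Equal bead radii; no volume correction or anisotropic slip.
* Dipolar + axially symmetric CSA relaxation only (¹³C–¹H and ¹⁵N–¹H); no
  cross-correlated relaxation, quadrupolar nuclei or chemical exchange.
* The CSA–dipolar frame tilt is carried as metadata but not used while
  δ_CSA = 0.
* Dense CPU linear algebra; the Cholesky factorization of D is the
  bottleneck for very large Nₛ.
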