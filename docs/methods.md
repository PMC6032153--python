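# Methods

This note documents the models behind each estimator, the synthetic
data they are validated against, and the numerical choices that are not
forced by the estimators themselves.

## Conventions and units

Coordinates are stored in nm, times in ps, temperatures in K. Angles
are radians internally and degrees at user-facing interfaces. The
bilayer normal is the box z-axis (the semi-isotropic NPT convention);
upper-leaflet tilts are measured against −z and lower-leaflet tilts
against +z, so an inward-pointing chain has a small positive tilt and
tilt angles live in [0°, 90°] for ordinary bilayers. Boxes are
orthorhombic only; minimum-image displacements use the half-open
convention [−L/2, L/2). Free energies from Boltzmann inversion are kept
in k<sub>B</sub>T throughout and converted (K<sub>A</sub> to mN/m) only at the reporting
layer. Leaflet assignment compares each molecule's head-center z with
the amphiphile center of mass; an exact tie labels upper, for
determinism.

## Estimators

**Molecular area.** A<sub>mol</sub> = L<sub>x</sub>L<sub>y</sub>/N<sub>mol</sub> per frame, no smoothing; the
reported spread is the plain standard deviation over frames.

**Thickness.** The head-group density of each leaflet is binned at
0.1 nm (a resolution that a few hundred frames populate smoothly) and
the peak refined by a quadratic through the maximum bin and its two
neighbors. If a second bin comes within 1% of the maximum more than 3
bins away the profile is declared ambiguous and the caller is asked for
narrower bins — smoothing before peak extraction is deliberately not
applied, so the refinement is the only interpolation step.

**Order parameters.** S<sub>CD</sub> is averaged over all hydrogens attached to
each chain carbon, including terminal-methyl hydrogens (the definition
makes no exclusion); carbons without hydrogens (ester carbonyls) are
skipped with a warning and reported as NaN. For united-atom or
synthetic chains the hydrogens are ideal-geometry reconstructions and
the output metadata says so. Gauche uses the open interval (−120°,
120°); a dihedral exactly at ±120° counts trans, so the boundary rule
is deterministic.

**K<sub>A</sub>.** Linear response with the plain sample variance over frames;
invariant to frame reordering by construction. The standard error is a
block bootstrap (20 contiguous blocks, 200 resamples) — the
original-study practice of averaging three independent MD runs is not
reproducible at desk scale, and the block bootstrap is the standard
single-trajectory substitute.

**Tilt modulus.** The tilt histogram (1° bins) is Jacobian-corrected
and inverted; empty bins are excluded; F is shifted so min F = 0. The
quadratic is fitted by least squares weighted by bin counts over
θ₀ ± 15°. Because a shallow PMF (χ ≲ 9 k<sub>B</sub>T/rad²) rises less than
1 k<sub>B</sub>T inside that window and the fit would be noise-dominated, the
window is widened once to √(2/χ̂) (capped at 45°) when a probe fit
detects this; the widening is recorded in the fit window of the result.
A PMF minimum at the edge of its support is an error, not a fit.

**Splay modulus.** Pairs are same-leaflet chains whose start atoms lie
within 1.0 nm laterally, with at least one member's tilt inside Θ ± σ
(Θ = histogram mode of the tilt distribution, ties to the lower angle;
σ = 5° for gel-phase and 10° for fluid-phase systems, auto-selected
from the phase label). Both inter- and intra-molecular chain pairs are
counted (configurable). The PMF fit is constrained to F₀ + (χ<sub>ij</sub>/2)θ²
— the form without a linear term — over (0°, 40°]; an unconstrained
variant exists for sensitivity checks. K<sub>C</sub><sup>eff</sup> is the pair-count-weighted
harmonic mean, which is bounded by the smallest and largest χ<sub>ij</sub>.

**Electrostatic potential.** The charge density (e/nm³, binned about
the bilayer center of mass) is integrated twice by cumulative
trapezoids outward from z = 0 in both directions, with φ(0) = 0 and the
implied boundary condition E(0) = 0. This is exact for membranes whose
two halves are each net-neutral; a net box charge above 10⁻³ e is
rejected as ill-posed.

**Hydrogen bonds.** The geometric criterion (donor–acceptor ≤ 0.35 nm
and H–donor–acceptor ≤ 30°) is the field's standard; both cutoffs are
config keys since the defining study does not state its own values.

**Residence and rotational times.** R(t) uses the intermittent
definition — a water counts if it is in the 0.45 nm shell of the
anion-center atoms (P for PC, S for IPA) at both the origin and
origin + t, absences between allowed — averaged per origin with 1/N₀
weighting, empty-shell origins skipped; R(0) = 1 by definition. C(t) is
⟨P₂(u(t₀)·u(t₀+t))⟩ over origins and molecules, evaluated through the
tensor-product expansion with FFTs. Both are fitted with
A₀e^(−t/τ₀) + A₁e^(−t/τ₁) under A₀, A₁ ≥ 0, τ₀ ≤ τ₁ and A₀+A₁ = C(0),
initialized from a two-segment log-linear fit, unweighted. Two
numerical guards keep the analytic integral τ = A₀τ₀ + A₁τ₁
well-posed: the fit uses only lags where the signal exceeds 2% of C(0)
(beyond that the curve is sampling noise), and time constants are
capped at five times the fitted span, since slower components are not
resolvable from the data and would otherwise inflate τ without bound.
If the fit fails to converge the trapezoidal integral of the data is
reported with a warning.

**Heat capacity.** C<sub>p</sub>(T<sub>i</sub>) = Var(H<sub>i</sub>)/(k<sub>B</sub>T<sub>i</sub>²) per replica in molar
units (k<sub>B</sub> in kJ/mol/K), shift-invariant in H by construction. The
module consumes enthalpy series labeled by temperature and is agnostic
to whether they come from raw replica-exchange replicas or demultiplexed
continuous trajectories; the sampling engine itself is out of scope.
T<sub>m</sub> is the quadratic-refined C<sub>p</sub> peak; a peak at the ladder edge is an
error (the ladder does not bracket the transition), and the uncertainty
is half the local ladder spacing.

**Phase label.** Advisory only: mean |S<sub>CD</sub>| over the middle third of
chain carbons below 0.2 labels liquid-disordered (Ld), at or above 0.2
gel (S); ripple phases have no quantitative detector here and must be
set manually.

## The synthetic bilayer generator

The generator emulates the features the estimators consume, each with a
recorded ground truth, while making no claim to physical packing
energetics:

- **Geometry.** Two leaflets of single-chain zwitterionic amphiphiles
  (a +1 cation center "N", a −1 anion center "S" 0.2 nm below it, and a
  methylene chain with two ideal-tetrahedral hydrogens per carbon, so
  an all-trans chain has |S<sub>CD</sub>| = 0.5 exactly at every position) on a
  jittered grid, 64 per leaflet by default, head sheets 3.8 nm apart.
- **Area fluctuations.** i.i.d. Gaussian A<sub>mol</sub> with variance
  k<sub>B</sub>T·A₀/(N·K<sub>A</sub>), the exact inverse of the linear-response estimator.
- **Tilt field.** Per-molecule per-frame tilts drawn by rejection
  sampling from P(θ) ∝ sin θ·exp(−χ/2(θ−θ₀)²) (exactness over speed;
  the envelope is the grid maximum of the bounded density). Azimuths
  uniform, frames independent.
- **Chains.** Internal-coordinate (NeRF) builds with dihedrals 180° or
  ±60° from per-dihedral Bernoulli masks.
- **Waters.** A TIP3-geometry 3-site model. Shell waters sit within
  0.45 nm of anion centers and escape with rate 1/τ<sub>res</sub> (Markov);
  the shell population is held stationary by re-admitting waters only
  after ≥ 6τ<sub>res</sub> out of the shell, so the survival correlation is
  exactly exponential over the usable lag range while origins never
  run empty. All dipoles undergo isotropic rotational diffusion D<sub>r</sub>
  (small random rotation vectors per step), giving C(t) = e^(−6D<sub>r</sub>t).
  Shell exchange and dipole rotation are independent processes, so
  τ and τ<sub>relax</sub> are tunable separately. An optional oriented-surface
  mode draws shell-water dipoles at a fixed angle from the outward
  normal for orientation-map recovery; that mode is documented as
  decoupled from the D<sub>r</sub> truth and is off by default so the rotational
  recovery stays clean.
- **Charges.** The ±1 head charges form two opposite sheets per
  leaflet at recorded surface density and separation; the plateau
  potential drop σ·d/ε₀ is stored as the analytic truth.

Default parameters describe a gel-like state: A₀ = 0.45 nm²,
K<sub>A</sub> = 1200 mN/m, T = 288 K, χ = 30 k<sub>B</sub>T/rad², θ₀ = 20°, all-trans
chains, τ<sub>res</sub> = 50 ps, D<sub>r</sub> = 0.002 rad²/ps, dt = 10 ps, 512 waters
(64 in-shell). The gel-like default is deliberate: with all-trans
chains every recorded truth has a closed form. The tilt-field moments
(mean tilt, ⟨P₂⟩ and hence S<sub>CD</sub> = −⟨P₂(cos θ)⟩/2) come from quadrature
of the sampling density, and the splay truth comes from a Legendre
expansion of the pair-angle density of two independent tilted
directors, conditioned on the same Θ ± σ gate the collector applies —
numeric integrals sharing no code with the estimators. With gauche
defects enabled the S<sub>CD</sub> truth has no closed form and is left unset.
The Legendre expansion (l ≤ 200) resolves tilt densities wider than
about 0.05 rad; stiffer fields get no analytic splay value.

**What the generator does not emulate** — and hence what passing
recovery tests do not show about real membranes: excluded-volume
packing, ripple-phase staggering, correlated tilt dynamics between
frames (tilts are redrawn each frame, so chain-directive C(t) is not
meaningful on synthetic data; rotational recovery uses water dipoles),
realistic partial-charge distributions, and undulation modes. The
estimators are validated as estimators; their behavior on real
trajectories inherits only their mathematical correctness.

## Problem sizes

The shipped verification uses the sizes at which the stochastic
tolerances hold comfortably: 2×10⁵ frames of area series (K<sub>A</sub> within
3%), 10⁶ angle samples (χ and χ<sub>ij</sub> within 5%), 4×10⁴ molecule-frames of
Bernoulli chains (gauche within ±0.01), 600 frames × 2048 waters for
residence (±10%), 1200 steps × 400 vectors for rotation (±10%), 18
replicas × 2×10⁴ enthalpy samples (T<sub>m</sub> within half the 5 K ladder
spacing), and a 64-per-leaflet, 500-frame bilayer for the end-to-end
pipeline, which completes in well under a minute on one CPU.

## Known limitations

- Orthorhombic boxes only; no triclinic support, no bond/topology
  inference, no force-field handling.
- The thickness is peak-to-peak of head-group densities, not the
  electron-density conventions (D<sub>B</sub>, 2D<sub>C</sub>).
- No spectral (undulation) bending-rigidity estimator and no
  dielectric/polarization correction to φ(z).
- Leaflet assignment assumes an intact bilayer not split across the
  periodic z-boundary.
- Uncertainties are single-trajectory (block bootstrap / fit
  covariance), not independent-replica spreads.
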