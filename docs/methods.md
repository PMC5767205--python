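# Methods

This note records the statistical models, conventions and numerical choices
behind `fepnet`, in the spirit of the methods documentation of estimator
libraries: what is computed, under which assumptions, and where the edges
are.

## Units and constants

Energies are kJ/mol on disk and at the API boundary; all estimators operate
on reduced potentials u = U/(k_B T) with k_B = 0.008314462618 kJ/mol/K and a
default temperature of 300 K. Lengths are nm, charges elementary charges.
The single electrostatic constant is 1/(4πε₀) = 138.935458 kJ·mol⁻¹·nm·e⁻²;
ε₀ never appears independently. The cubic lattice-sum (Wigner) constant is
ξ_LS = −2.837. TIP3P water enters through its bulk dielectric ε_s = 97 and
its quadrupole-moment trace γ_s = 0.00764 e·nm² (the corrected literature
value; an early source lists a tenfold larger number).

## Free-energy estimators

**EXP.** ΔF = −ln⟨e^(−Δu)⟩ over the sampling state, evaluated with a
max-shift (log-sum-exp); the backward direction flips the sign convention so
both directions estimate the same forward ΔF. The standard error is the
delta-method propagation of the weight variance. One-sided EXP is biased at
finite n (forward high, backward low), which is exactly why the
forward/backward gap serves as a convergence diagnostic.

**BAR.** The Bennett self-consistent equation is written in logistic form,
which is monotone in ΔF, and solved by bracketed Brent root finding between
the two EXP estimates widened by ±50 k_BT (tolerance 10⁻¹⁰, with automatic
bracket expansion for pathological inputs). The standard error is Bennett's
asymptotic variance from the Fermi-weight sums.

**MBAR.** The self-consistent equations are iterated (first five sweeps
damped by ½) and polished with Newton steps on the convex MBAR objective;
convergence requires max|Δf| < 10⁻¹⁰, with f₀ pinned to zero. Everything is
deterministic given the input order. The asymptotic covariance is the
standard sandwich estimator Θ = Wᵀ(I − W N Wᵀ)⁺W computed through the thin
SVD of the weight matrix. The inverse Hessian of the objective is *not*
used: the objective is a pseudo-likelihood under mixture sampling and its
observed information overstates the variance (on the harmonic-chain
calibration below it yields ~100% coverage at nominal 95%, whereas the
sandwich estimator gives 96.5% over 200 seeded runs). Bootstrap standard
errors (default 200 resamples, resampling whole decorrelated samples within
each sampling state, seedable) can be attached and are exposed alongside
the asymptotic ones, since published workflows differ in which they report.

**Decorrelation.** The statistical inefficiency g = 1 + 2Σ C(t) is summed
over positive autocorrelations and truncated at the first non-positive
C(t); an exactly constant series has g = 1 by convention. Samples are
thinned with stride ⌈g⌉. The decorrelation observable is the reduced-energy
difference to the adjacent λ state (the last state uses its left
neighbour) — a pragmatic, configurable choice; any scalar time series can
be passed to `statistical_inefficiency` directly. Note that ⌈g⌉ halves an
i.i.d. series whenever chance autocorrelation is marginally positive; this
is accepted as conservative.

**Leg combination.** ΔΔG_bind = ΔΔG_bound − ΔΔG_free with the total
variance as the sum of the per-interval leg variances. Per-interval
estimates are summed over whatever λ ladder the input provides — the
schedule is data, not code.

## Overlap diagnostics

All distribution measures are computed on a shared 50-bin histogram
spanning the pooled range of the forward samples and the negated backward
samples (bin count configurable). Ω is the Bhattacharyya coefficient
Σ√(p·q); K_AB is the harmonic-mean overlap integral Σ 2pq/(p+q); both lie
in [0, 1], are symmetric, and are invariant under a common shift. The bias
metrics are implemented as Π = √(2 ln N) − √(2s), with s the
Kullback–Leibler divergence of the sampled distribution from its partner
(Laplace pseudo-counts keep s finite on empty bins); sampling is adequate
when ln N exceeds the relative entropy, i.e. Π > 0, with 0.5 as the
rule-of-thumb warning threshold. The K_AB/Π family has several published
variants; the forms above are the ones implemented and tested here. w_max
is the largest normalised weight in the forward exponential average
(defined for a single sample, where it is 1). Warning thresholds
(Ω < 0.7, w_max > 0.5, EXP gap > 1 k_BT, MBAR–BAR gap > 0.5 k_BT, …) are
config-exposed defaults chosen so that converged Gaussian fixtures pass and
disjoint fixtures fail.

## Finite-size charge corrections

For a transformation that changes the ligand's net charge (0 ↔ −1 in the
shipped tables) under PBC/Ewald, five correction terms are evaluated per
snapshot from the residual integrated potentials I_P, I_L, I_L,hom, the
charges Q_P, Q_L, the cubic box edge L and the solvent count N_s:

- ΔG_NET + ΔG_USV = −ξ_LS/(8πε₀) · ((Q_P+Q_L)² − Q_P²)/(ε_s L)
- ΔG_RIP = ((I_P+I_L)(Q_P+Q_L) − I_P Q_P)/L³
- ΔG_EMP = −1/(8πε₀) · (16π²/45)(1 − 1/ε_s)((Q_P+Q_L)² − Q_P²) R_L⁵/L⁶
- ΔG_DSC = −γ_s Q_L N_s/(6ε₀L³)
- R_L = √[(I_L − I_L,hom) / ((1/(8πε₀))(4π/3)(1 − 1/ε_s)|Q_L|)]

The internal dielectric is fixed at unity. Terms are evaluated generically
at both end-state ligand charges; a neutral end state contributes exactly
zero (the I_L of a neutral ligand is not meaningful in this scheme and is
never consulted). The per-transformation correction is the
complex-minus-free difference of end-state differences, averaged over
snapshots; the uncertainty is the per-environment standard error of the
mean (n−1 denominator) combined in quadrature, since pairing complex and
free snapshots of independent simulations would be artificial. Mismatched
snapshot counts warn and average independently. The correction is exactly
antisymmetric under swapping the end states, scales as 1/L, 1/L³, 1/L⁶ and
N_s/L³ term by term, and on the shipped tables amounts to 6.8–8.4 kJ/mol
with a positive sign when the starting ligand is the charged one.

## Toy Poisson solver and the RIP definition

`pb_toy` solves ∇·(ε∇φ) = −4π·(138.935458)·ρ on a cubic grid (node spacing
h = L/(n−1)) with a 7-point stencil, harmonic-mean face permittivities,
trilinear charge assignment (the dominant discretisation error) and
Dirichlet boundary values from the analytic bulk-screened Coulomb
potential. Red-black SOR with ω = 1.9 is the primary solver (residual
< 10⁻⁸ relative to the source norm); a Jacobi-preconditioned conjugate
gradient on the same stencil is the fallback. Zero ionic strength
throughout: the correction theory is salt-free.

The RIP of a system is defined as the box integral of the *residual*
potential — numeric solution minus the analytic Coulomb potential of the
same charges screened by the system's own bulk dielectric (the singular
voxel of the reference integral uses the analytic cube average of 1/r,
2.3800774·h²). This reference choice matters: with it, the
heterogeneous-minus-homogeneous RIP difference of a centred Born ion equals
(2π/3)·k_e·q·(1 − 1/ε_s)R² in closed form, which is precisely what the R_L
formula inverts, and the homogeneous run doubles as a cancellation of the
grid self-energy error. A plain ∫φ dV definition would leave a
box-size-dependent tail and an undefined R_L. At 65³ the Born cavity radius
of 0.5 nm is recovered to ~1.5%; production solvers with molecular surfaces
remain out of scope, and RIPs for real systems are external inputs.

## Networks, cycles, absolute affinities

Edges are stored once with their direction; reverse traversal negates the
value and keeps the standard error. Cycle hysteresis is the signed edge sum
along the traversal (2-cycles are legal and close exactly at 0 ± √2·se);
its uncertainty is the quadrature sum. Simple cycles are enumerated up to a
length bound and canonicalised (rotated to the smallest ligand id, oriented
lexicographically, deduplicated). Absolute affinities anchor one reference
ligand and sum edges along minimum-edge-count paths, breaking ties by the
lexicographically smallest ligand sequence — a documented choice, since
multi-path resolution is under-determined; a weighted least-squares
alternative is deliberately not the default, to keep the published
path-summation semantics. Disconnected ligands are reported as missing
rather than raising.

## Benchmark statistics

MAD is the mean |calc − exp|. Because the direction of a relative
transformation is arbitrary, R² is computed direction-agnostically: every
pair enters as (c, e) and (−c, −e), whose doubled-set Pearson r² equals the
uncentered (Σce)²/(Σc²Σe²) — both forms are implemented and cross-asserted.
Kendall's τ uses the τ-b tie correction (the experimental column contains
tied zeros); τ_r,95 keeps only pairs whose calculated *and* experimental
values exceed 1.96 standard errors in magnitude, with 2.4 kJ/mol (1.7·√2)
as the default experimental uncertainty. Uncertainties of all measures come
from 1000 Gaussian resamples of both the calculated and experimental
values; the procedure is seeded and reproducible. The τ variants are the
least portable of these measures: different tie/filter conventions move
τ_r,95 substantially on a 39-pair table, and the values this package
reports are its own conventions applied consistently.

## Consensus docking

CS is the per-ligand mean score over available methods (missing entries are
excluded with a warning; score sentinels such as −16.7 for failed dockings
are data, not missing values). CR averages within-method ranks (ascending,
most negative first, average ranks on ties). Final orderings break ties by
ligand id. When recomputing CS from a published table whose per-method
scores are themselves rounded to 0.1 kJ/mol, the reconstruction can differ
from a CS computed from unrounded scores by up to 0.1 (0.05 from the mean
of rounded scores + 0.05 from printing the CS); the shipped table exhibits
exactly this, with 94/102 ligands within 0.05 and the rest at 0.06.

## Synthetic data

`gen_gaussian_work` draws forward work from N(ΔF + σ²/2, σ²) and backward
work from N(−ΔF + σ²/2, σ²), satisfying the Crooks fluctuation relation by
construction, so every estimator converges to ΔF. `gen_harmonic_chain`
samples each state u_i(x) = k_i x²/2 exactly from its Boltzmann
distribution with analytic f_i = ½ln(k_i/k₀). `gen_noisy_network` adds
i.i.d. Gaussian noise to exact edge differences. All generators are pure
functions of (parameters, seed), with per-state/per-edge SeedSequence
spawning so that enlarging a system leaves existing streams untouched.

What the synthetic data does *not* emulate: correlated time series (samples
are i.i.d., so decorrelation is exercised on separately constructed
series), fat-tailed or multimodal work distributions, conformational
trapping, and any force-field or sampling error of real simulations.
Passing estimator tests therefore demonstrate statistical correctness of
the analysis layer, not simulation accuracy.

## Problem sizes in the shipped checks

The test suite and the reproduction script use harmonic chains of 2–3
states with 500–1000 samples per state (100–200 seeded repetitions for
coverage checks), 10⁵ Gaussian work samples, and Poisson grids of 33³ in
unit tests and 65³ for the Born end-to-end check — sizes chosen so the full
suite runs in well under a minute per heavy check while keeping Monte-Carlo
error far below the asserted tolerances.

## Known limitations

- No trajectory parsing: energies arrive via the u_kn CSV dialect.
- The K_AB/Π overlap family follows one documented literature variant.
- Path-sum absolute conversion ignores cycle information (no least-squares
  reconciliation by default).
- The toy Poisson solver has no molecular surfaces, ionic strength or
  focusing; it exists to generate RIP fixtures and validate the Born limit.
- τ_r,95 depends strongly on filter conventions on small tables (see
  above).
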