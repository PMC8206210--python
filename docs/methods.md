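# Methods

## Models

**Random Lotka–Volterra community.** N species with densities x_i in a system
of size V. Each unordered pair interacts with probability c/N; interaction
rates R_ij are half-normal |Normal(0, σ²)|, so E[R] = μ = σ√(2/π) and
E[R²] = σ². A pair is predatory with probability p = (1 − γ)/2 (the predator
chosen by a fair coin), otherwise mutualistic or competitive with equal
probability; the signed coefficients α_ij then satisfy
E[α_ij α_ji] = γσ² over connected pairs. Every species has birth rate b and
self-regulation α_ii = −b, giving carrying capacity 1, and the community
matrix at the reference equilibrium x* = 1 coincides with the interaction
matrix (A_ij = α_ij, A_ii = −b). The demographic-noise correlator at x* has
per-species diagonal B_ii = 2b + Σ_{j~i} R_ij — whose ensemble mean is the
textbook value 2b + cμ — and off-diagonal −R_ij on predation pairs only
(only predation changes two species in one event), zero otherwise. We keep
the per-species diagonal rather than its mean: it is what the underlying
reaction scheme gives, it is what per-species (single-defect) spectra need,
and its ensemble mean is then a testable statement rather than an identity.

Stability: the elliptic law puts the rightmost edge of A's spectrum at
√(cσ²)(1 + γ) − b (`stability_edge`). Two caveats established numerically:
at fixed sparse degree (c ≈ 50) the sampled rightmost eigenvalue sits
O(1/c) — about 0.2–0.5 in the demonstration units — to the right of the
infinite-size edge regardless of N, while in the dense regime (c = N) it
concentrates on the edge to ~3/√N; and single instances at small N fluctuate
further still. `tune_to_marginal_stability` shifts the diagonal so the
sampled rightmost eigenvalue is exactly 0 (the noise diagonal's 2b term
follows the shift).

**Bipartite trophic community.** Nx predators (death rate d) and Ny prey
(birth rate b), wired as a random biregular bipartite graph: every predator
eats exactly cx prey, every prey is eaten by exactly cy predators
(Nx·cx = Ny·cy), all with the same rate α. Because degrees are exactly
regular, the group-averaged fixed point
x* = (cx·α·b − d)/(cx·cy·α² + 1), y* = (cy·α·d + b)/(cx·cy·α² + 1)
is an exact equilibrium of every sampled instance. A and B take their block
forms evaluated at (x*, y*). Wiring is sampled by stub matching followed by
degree-preserving double-edge swaps until no multi-edges remain; plain
rejection of non-simple matchings is hopeless at realistic degrees (the
acceptance probability is ~e^(−cx·cy/2)), while swap repair is approximately
uniform and more than adequate for spectral statistics.

## Spectra

All spectra use one convention: two-sided densities in angular frequency ω,
normalised so a component's stationary variance is (1/2π)∫Φ_ii dω over the
real line; only ω ≥ 0 is stored (real processes are even in ω).

**Exact oracle.** Φ(ω) = (A − iωI)⁻¹B(Aᵀ + iωI)⁻¹ = M⁻¹BM⁻ᴴ with
M = A − iωI, manifestly Hermitian PSD (`psd_direct`). For grids of
frequencies an eigendecomposition A = UΛU⁻¹ is done once; the mean spectrum
then costs O(N²) per frequency via
tr Φ = Σ_ab (UᴴU)_ab (DCDᴴ)_ba, C = U⁻¹BU⁻ᴴ, D = (Λ − iω)⁻¹, which is what
makes exact N = 1000 comparisons on 512-point grids routine
(`mean_psd_exact`, `psd_diag_exact`; both validated against the dense
formula). The stationary covariance solves the Lyapunov equation
AΣ + ΣAᵀ + B = 0 (scipy); the autocovariance is the cosine transform
(1/π)∫₀^∞ φ cos(ωτ) dω by the trapezoid rule, with an explicit error when
the grid undersamples the requested lags (Δω·τ > π/2).

**Cavity mean field.** The resolvent quadratic g r² − w r + 1 = 0
(w = b + iω, g = cγσ²) is solved in closed form; of its two roots the
physical one has Re r > 0 (the resolvent of a stable matrix is a mixture of
1/(iω − λ) with Re λ < 0), with the smaller-magnitude root on ties and the
explicit limit r = 1/w when |g| < 10⁻¹². The mean PSD follows from the
moments (E[A_ii], E[B_ii], E[A_ij²], E[A_ij A_ji], E[A_ij B_ij], c);
frequencies where the denominator 1 − c|r|²σ² is nonpositive are flagged and
set to +inf, never silently returned. Closed-form variants (weak-interaction
Lorentzian; γ = −1 quarter circle; γ = 0 exact form; γ = +1 marginal form)
are evaluated exactly as printed and tested against the full solution,
including the O(b) convergence of the quarter circle and the −2 and −1/2
low-frequency log-log slopes at the respective margins.

**Single-defect approximation.** One focal species keeps its actual sums
Σ A_ij², Σ A_ij B_ij, Σ A_ij A_ji and B_ii inside the mean-field background:
φ_i = (φ^MF ΣA_ij² + 2Re(r^MF)ΣA_ij B_ij + B_ii)/|A_ii + iω + r̄^MF ΣA_ij A_ji|².
Mean degree stands in for the excess degree (they agree to O(1/c) for
binomial degrees). At the demonstration setting (N = 500, c = 20, γ = −1) the
cross-species correlation with the exact oracle at low frequency is ≈ 0.92.

**Bipartite solver.** The two-group cavity equations reduce to a resolvent
pair 1/r_x = x* + iω + α²cx·x*y*·r_y (and x↔y with cy), iterated with
damping 0.5 from the non-interacting values with warm starts along the grid
and a spectral shift ω → ω − iε (ε = 10⁻⁶, halved until the set of excited
frequencies stabilises) to select the physical in-band solution; (φ_x, φ_y)
then solve a linear 2×2 system. Caps: 10⁴ iterations, tolerance 10⁻¹⁰,
per-frequency convergence flags surfaced. The excited band is bounded by
ω± = √(bd(1/cx + 1/cy ± 2/√(cx·cy))). Two facts the exact oracle confirms
and a reader should not over-read from the band picture: the suppression
below ω₋ is real but modest (the predator spectrum's ω → 0 floor sits ~14×
below the in-band peak at the demonstration parameters, not orders of
magnitude — the ≥100× suppression lives on the high-frequency side), and a
small order-1/N resonance appears at the frequency of the representative
two-species pair (imaginary part ≈ 1.00 at the demonstration parameters),
outside the band.

## Simulation

Euler–Maruyama with Gaussian increments of one-step covariance h·B/V, B
factorised by Cholesky (eigenvalue clipping with a warning if a small-N
sample is not numerically PSD). Strict stability of A is required; marginal
communities are rejected. Defaults: t_max = 2¹⁰, h = 2⁻⁷, noise evaluated at
the fixed point (the linear-noise regime the theory describes), with a
state-dependent mode that re-factorises B(x_t) on a configurable cache
interval for probing nonlinear noise effects. The default drift is the
linearisation A(x − x*): for a sampled finite mixed community the reference
point x* = 1 is an equilibrium only in expectation (the per-species residual
drift is O(√(cσ²))), so the literal nonlinear drift relaxes away from x* and
cannot reproduce the linear-noise theory; it remains available as
`drift_mode="full"` for feasibility studies. Densities are clipped at zero
(clip fraction recorded; >0.1% flags a run outside the linear regime) and
runs abort on blow-up. The transient t < 10/b is discarded before spectral
estimation. Empirical spectra are plain unwindowed periodograms
(h²/T)|DFT|² at ω_k = 2πk/T, averaged over species — asymptotically unbiased
for the package convention, with variance controlled by species/seed
averaging and frequency binning rather than windowing.

## The survey fixture and what it does (not) emulate

`generate_abundance_fixture` writes a wide abundance table shaped like a
daily coastal plankton survey: 88 days × 3 samples/day × ~100 species of
nonnegative densities, recorded at the survey cadence from a simulated
community. The default generator community uses the parameters inferred for
such a survey — b = 0.6643/day, cσ² = 0.1316, γ = 0.8078, N = 100, c = 10 —
which place the spectral edge at −0.0085. At N = 100 the sampled rightmost
eigenvalue usually overshoots that margin, so the generator raises b per
instance to a fixed −0.02 margin and records the instance's actual b as
ground truth. What the fixture does *not* emulate: measurement error,
zero-inflation/detection limits, seasonal forcing, and log-normal abundance
heterogeneity (all species share x* = 1). Passing recovery tests on it
therefore demonstrate the estimation pipeline, not robustness to those
real-data features.

## Fitting

Pipeline, mirroring the field analysis: average samples to daily values,
drop any species with a zero daily value, subtract species means, estimate
each species' spectrum by the AR covariance method (order 8; unwindowed
conditional least squares via statsmodels, trend-free), convert to the
two-sided angular-frequency convention with Δ = 1 day, average over species,
and fit scale·|r|²/(1 − |r|²·cσ²) by nonlinear least squares on 200 points
in (0, π/Δ]. Identifiability dictates the parameterisation: a mean spectrum
determines only b, the composite cσ², γ, and an overall scale (the noise
numerator 2b + cμ is absorbed into scale, and the fitter is exactly
invariant to rescaling the data). Optimisation: the scale is profiled in
closed form, 20 Latin-hypercube starts over b ∈ (0.01, 5), cσ² ∈ (10⁻⁴, 4),
γ ∈ (−1, 1) (optionally γ < 0), trust-region least squares with a penalty
ramp outside the stable region, ties broken toward smaller b. On noiseless
model curves all three parameters come back to 10⁻⁴.

Two quantified limitations of the fit applied to daily survey data. First,
fitting the continuous-time spectrum to a daily-sampled, daily-averaged
series carries an intrinsic aliasing bias: in the infinite-data limit at the
default generator parameters the fitted b is low by ~13% and cσ² by ~32%,
independent of AR order. Second, for γ > 0 the model family has a shallow
valley — γ ≈ 0 with larger cσ² produces a nearly identical curve — so short
(88-point) records scatter fits along it; γ < 0 communities are much better
identified (fine-sampled recovery of b is then <1%). The sign of γ survives
these effects in most but not all 88-day realisations (8/10 at the
defaults). Consequences for interpreting single fits of real survey data:
treat cσ² as order-of-magnitude, b as ~20%, and γ qualitatively.

## Problem sizes in the shipped checks

The test suite runs the oracle comparisons at the full demonstration sizes
(N = 1000 communities, 512-point grids, single seed per interaction mix) and
the simulation comparison at N = 200, 10 seeds, t_max = 2⁹, h = 2⁻⁷ with
60-bin frequency averaging; the recovery study uses 10 fixture seeds. These
sizes keep every check well inside a few CPU-minutes while leaving
Monte-Carlo error comfortably below the tolerances being asserted.
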