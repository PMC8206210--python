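# ecospectra

Fluctuation power spectra of large random ecological networks: analytic
cavity-method theory, exact finite-size oracles, stochastic simulation, and a
fitter that reads the structure of a community out of abundance time series.

## The problem

Classical random-matrix ecology asks whether a large community is *stable*:
whether the rightmost eigenvalue of its community matrix **A** is negative.
Field ecologists, however, mostly observe *temporal* stability — how species
abundances fluctuate around their typical values. The bridge between the two
is the power spectral density (PSD) of demographic fluctuations. Around a
stable equilibrium the fluctuations ξ of a generalized Lotka–Volterra
community obey an Ornstein–Uhlenbeck process dξ/dt = **A**ξ + ζ(t) with noise
correlator **B**, and the matrix PSD is

    Φ(ω) = (A − iωI)⁻¹ B (Aᵀ + iωI)⁻¹ .

For a *random* community — N species, mean degree c, interaction rates with
second moment σ², symmetry parameter γ = E[AᵢⱼAⱼᵢ]/σ² encoding the proportion
of predator–prey pairs, self-regulation b — the mean spectrum
φ(ω) = E[Φᵢᵢ] closes on the mean resolvent r(ω):

    1/r = b + iω − r·c·γσ² ,
    φ   = |r|² (2b + cμ) / (1 − |r|²·c·σ²) ,      μ = σ√(2/π).

The shape of φ is a fingerprint of the interaction structure: predation-
dominated communities (γ = −1) have a quarter-circle spectrum confined to
ω² < 4cσ²; mixed communities (γ = 0) are Lorentzian with a 1/ω² pole at the
stability boundary b² = cσ²; purely symmetric ones (γ = +1) develop a 1/√ω
pole at their margin. A two-trophic-level (bipartite) community confines its
fluctuations to a band ω ∈ [ω₋, ω₊] with
ω± = √(bd(1/cₓ + 1/c_y ± 2/√(cₓc_y))). A single-defect approximation gives
per-species spectra from one species' actual couplings embedded in the mean
field. Running the logic backwards, fitting φ(ω; b, cσ², γ, scale) to an
empirical mean spectrum estimates how symmetric the interactions of a real
community are and how close it sits to instability.

Intended users: theoretical/quantitative ecologists and anyone studying noisy
fluctuations of large random dynamical systems (the machinery is model-
agnostic: any stable **A**, **B** pair works).

## Worked example

Theory in three lines — the spectral edge implied by a fitted parameter set,
and the mixed-community spectrum at zero frequency:

```python
>>> import numpy as np, ecospectra as es
>>> es.stability_edge(0.6643, 0.1316, 0.8078)
-0.008489558985220191
>>> p = es.LVParams(N=1000, c=50, sigma2=0.5, gamma=0.0, b=7.0)
>>> es.psd_mean_field(np.array([0.0]), es.lv_moment_map(p)).phi[0]
1.7587282990578255
```

The first number says the fitted community sits just inside its stability
boundary (edge ≈ −0.0085, barely negative); the second is the closed form
(2b + cμ)/(b² − cσ²) of a mixed community's zero-frequency power.

The survey pipeline, end to end — generate a synthetic 88-day, 3-samples/day,
100-species abundance table from a simulated community near its stability
margin, estimate its mean spectrum by 8th-order autoregression, and fit:

```python
>>> from ecospectra.simulate import generate_abundance_fixture
>>> from ecospectra.fitting import LVSpectrumModel
>>> table = generate_abundance_fixture(seed=8)      # 264 rows x 100 species
>>> res = LVSpectrumModel.from_abundance(table, samples_per_day=3).fit(seed=8)
>>> print(res.summary())
Mean-field spectrum fit
============================================
grid points                              200
multi-starts kept                         20
constraint                              None
--------------------------------------------
b (self-regulation)                 0.786007
c*sigma^2                           0.190325
gamma (symmetry)                    0.797166
scale                             0.00024053
--------------------------------------------
sum sq. residual                 3.20045e-08
spectral edge                    -0.00197064
============================================
```

The generator behind this table used b ≈ 0.70/day (per-instance value),
cσ² = 0.1316 and γ = 0.8078: the fit reads back the mostly symmetric
interaction structure (γ ≈ 0.80) and the near-marginal spectral edge. The
same pipeline runs from a shell:

```bash
ecospectra fixture --seed 8 --out fx
ecospectra fit fx/abundances.csv --samples-per-day 3 --seed 8 --out fitdir
```

Other entry points: `sample` (serialize a random community),
`spectrum`/`sda`/`bipartite` (analytic spectra), `simulate` (Euler–Maruyama
plus FFT spectrum). Everything is seeded and writes plain-text TSV/CSV/YAML.

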