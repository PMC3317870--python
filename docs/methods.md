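# Methods

## Model family and estimation

The package estimates balanced-panel regressions for N spatial units
over T periods, stacked period-major so that every per-period spatial
operation is the block-diagonal `I_T ⊗ W`. `W` is binary contiguity
(rook or queen on a lattice; arbitrary symmetric adjacency from a GAL
file), row-standardised so `Wx` is a neighbour average. Islands are
kept with all-zero rows and a warning rather than dropped: removing a
unit would unbalance the panel, and a zero lag is the natural
convention for a unit with no neighbours.

**Within estimation.** Fixed effects are eliminated by subtracting each
region's time mean; the constant and the effects are recovered
afterwards from the stored means under the sum-to-zero normalisation
`Σ μ_i = 0` (any other normalisation only shifts the constant). The FE
σ̂² uses the classic NT − N − K within-estimator degrees of freedom.

**Spatial ML.** The SEA (`φ_t = ρWφ_t + ε_t`) and SAR
(`y_t = δWy_t + X_tβ + μ + ε_t`) models are fitted on the demeaned data
by concentrated maximum likelihood. Both objectives reduce to a scalar
problem in the spatial parameter with the Jacobian term
`T·ln|I − ρW| = T·Σ_i ln(1 − ρλ_i)` evaluated from the cached spectrum
of the standardised `W` (computed through the similarity to a symmetric
matrix, so the eigenvalues are exactly real; islands contribute zeros).
The SEA fit alternates spatial GLS for β given ρ with a bounded scalar
maximisation (Brent) for ρ given β, starting from ρ₀ = 0 — the FE model
is the natural null; the SAR fit needs a single scalar maximisation
because β(δ) = b₀ − δb₁ from two fixed regressions.

**Degrees-of-freedom conventions.** Demeaning leaves N(T−1) effective
observations; the exact likelihood of the demeaned data (the
orthonormal forward-transform argument) carries T−1 cross-sections and
σ² = e'e/(N(T−1)). Because that objective is proportional to the NT
form, the two conventions share the same maximiser for β and the
spatial parameter — only σ², the likelihood value and the standard
errors differ. The package reports σ̂² = e'e/NT and the NT-convention
log-likelihood by default (the `effective_df_correction` switch selects
the N(T−1) convention), but computes standard errors from the
information matrix of the exact demeaned-data likelihood: with the NT
information the Wald intervals for the spatial parameter are too narrow
by a factor √((T−1)/T) and their coverage is systematically below
nominal. The analytic information matrix uses `W_B = W(I − ρW)^{-1}`
(SEA) and the full (β, δ, σ²) block form with `W_A = W(I − δW)^{-1}`
(SAR); a numerical Hessian of the same likelihood is available as
`se_method="numerical_hessian"` and agrees with the analytic form to a
few percent on test problems.

Both likelihood conventions are reported (`loglik`, and the same value
without the ½NT·ln 2π constant as `loglik_no_constant`), since
published tables are ambiguous about the constant.

**Numerical choices.** The admissible interval for ρ/δ is
`(1/λ_min + 1e-6, 1 − 1e-6)`; the scalar optimiser runs with
`xatol ≤ 1e-9`. The SEA alternation stops when successive ρ iterates
agree within `tol` (default 1e-8) **or** when the monotone block ascent
improves the profile objective by less than `1e-9·(1+|L|)`: near the
optimum the likelihood is flat at floating-point resolution
(L changes by ~L''·δ², so ρ cannot be localised below ~1e-8), and
without the objective test the loop can circle the noise floor
indefinitely. Estimates pinned within 1e-5 of a bound raise a warning;
non-convergence raises an error carrying the iterate trace.

**Fit statistics.** `r2 = 1 − SSE/SST` on the estimation (within)
scale; `corr2` is the squared Pearson correlation of observed and
fitted outcomes on the original scale, with fitted values built from
the recovered constant, effects, slopes and (for SAR) the observed
spatial lag; `aic = −2·loglik + 2k` with k counting slopes, the spatial
parameter and σ² (fixed effects concentrated out). Significance stars
follow the ***/**/* convention at 1/5/10%, with boundary p-values
taking the stronger mark.

## LM diagnostics

The LM-lag and LM-error score tests (and their robust
Anselin–Bera–Florax–Yoon variants) are the standard cross-sectional
statistics assembled from panel quadratic forms with `I_T ⊗ W`:
`LM_err = [e'(I_T⊗W)e/σ̂²]²/T̃` with `T̃ = T_eff·tr(WW + W'W)`, and
`LM_lag = [e'(I_T⊗W)y/σ̂²]²/J`,
`J = (Wŷ)'M(Wŷ)/σ̂² + T̃`. On pooled residuals `T_eff = T` and
σ̂² = e'e/NT; on within residuals `T_eff = T − 1` and
σ̂² = e'e/(N(T−1)), because demeaning removes one cross-section of
variation — with the raw-T form the statistics are inflated by
T/(T−1) and the nominal-5% test rejects a true null about twice too
often at T = 3. The robust variants satisfy the algebraic identity
`LM_lag + LM_err^robust = LM_err + LM_lag^robust`, which the test suite
asserts. The reported decision rule flags a spatial specification as
warranted when both plain tests reject at 5%.

The homoscedasticity check is a Breusch–Pagan auxiliary regression
(statsmodels' studentised n·R² form) of squared residuals on the
covariates, χ²(K); constant residuals return the degenerate (0, 1).

## First-difference (temporal-trend) model

`build_first_difference` rewrites the panel as
`Δy_t = y_t − y_{t−1}` with covariates frozen at their period-`t−1`
values (copied, not differenced — they enter as exogenous initial
conditions). A T = 3 panel yields exactly 2 difference periods, the
minimum for a within fit; the FE machinery then absorbs one difference
per region, which leaves little within variation and is the reason the
difference models fit much more loosely than the level models.
`sign_flip_interpretation` tabulates sign oppositions between a levels
fit and a difference fit on the shared covariates: under convergence
dynamics (larger improvements where initial conditions are worse, as
with a zero-bounded outcome) the signs systematically flip; the
comparison is sign-only by design.

## Synthetic data

`simulate_panel` draws covariates as spatially smoothed Gaussian fields
`(I − κW)^{-1}u`, exactly rescaled to per-period target means/sds taken
from published Brazilian census marginals (water coverage rising
0.24 → 0.43 → 0.63, etc.); region effects are exactly centred and
scaled, optionally correlated with the first covariate's region mean to
produce a visible pooled-vs-FE contrast; disturbances follow the
chosen reduced form, `(I − ρW)^{-1}ε` for SEA or the full
`(I − δW)^{-1}(α_t + X_tβ + μ + ε)` solve for SAR. Defaults are a
20×20 rook lattice, T = 3, slope vector
(−0.048, −0.166, −0.259, −0.222), ρ = 0.786 / δ = 0.7789, ε-sd 0.14
(matching a disturbance variance near 0.02) and effect-sd 0.15
(comparable to the outcome's cross-sectional spread). The `imr` preset
adds period intercepts `α_t = target_t − m_t'β` so simulated
log-outcome period means land on 1.89 / 1.64 / 1.46; the `paper-scale`
preset trims a 61×60 lattice to 3,659 units, the size of the Brazilian
Minimum Comparable Areas system.

What the generator does *not* emulate: bounded supports and skewness of
rate covariates (fields are Gaussian), irregular adjacency graphs
(lattices only, though arbitrary GAL structures are accepted),
measurement error and under-registration, endogenous covariates, and
common time shocks outside the preset intercepts. Passing recovery
tests therefore demonstrates estimator correctness under the model's
own assumptions, not robustness to those real-data features.

## Validation problem sizes

The test suite checks the estimators against independent oracles
(dummy-variable OLS; 10⁻⁴-step grid searches of the concentrated
likelihoods at N = 49; dense log-determinants up to 10×10), runs
200-replicate recovery studies at N = 400, T = 3 for both spatial
models (means within 3 Monte-Carlo SEs of truth, 95% Wald coverage
required in [90%, 99%]), calibrates the LM battery with 1000 null
replicates at N = 100 (size within [3.5%, 6.5%] at nominal 5%) and 200
power replicates at ρ = 0.7, and verifies the simulator against a
50-term Neumann series for |ρ| ≤ 0.5. `scripts/acceptance.py` repeats
the same computations with 100/400/200 replicates, which reproduces the
quantities to Monte-Carlo accuracy in under a minute.

## Known limitations

- Estimation assumes a balanced panel; unbalanced data are rejected at
  validation rather than accommodated.
- Spectra and the SEA/SAR information matrices use dense N×N algebra;
  practical up to a few thousand units (a full 3,659-unit ML fit takes
  minutes), beyond which sparse log-determinant methods would be needed.
- No endogeneity controls (GMM/IV) and no random-effects estimator —
  the latter is inappropriate when an exhaustively sampled set of
  irregular areas is analysed, which is the intended use case.
- The SAR `corr2` uses the observed spatial lag in the fitted values
  (naive prediction), not the reduced-form predictor.
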