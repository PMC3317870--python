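# spanel — spatial panel econometrics for ecological health outcomes

`spanel` implements the spatial panel regression toolkit used in
ecological (area-level) studies of health outcomes such as regional
infant mortality: fixed-effects panel estimation with spatially lagged
covariates, maximum-likelihood spatial-error and spatial-lag panel
models, Lagrange-multiplier spatial-dependence diagnostics, a
first-difference temporal-trend specification, and a synthetic
municipality-panel generator with known parameters for validation.

It is written for epidemiologists and regional scientists who have a
balanced panel of N contiguous areas observed over T periods (a long
CSV) and a contiguity structure (a GAL file or a programmatic lattice),
and who need estimates that remain reliable when outcomes and omitted
factors are spatially autocorrelated.

## Models

With `y_t` the (log) outcome cross-section in period `t`, `X_t` the
covariates, `W` a row-standardised contiguity matrix (so `W x` is the
neighbour average of `x`), `μ` region fixed effects and `ε_t` white
noise:

- **Pooled**: `y_t = α + X_t β + ε_t`
- **Fixed effects (FE)**: `y_t = X_t β + μ + ε_t`, estimated by the
  within (de-trending) transformation; `α` and `μ` are recovered
  afterwards under `Σ_i μ_i = 0`.
- **Spatial error (SEA)**: `y_t = α + X_t β + μ + φ_t` with
  `φ_t = ρ W φ_t + ε_t` — spatial dependence in the disturbance,
  estimated by ML with an iterative two-stage procedure (spatial GLS
  for `β` given `ρ`; concentrated-likelihood maximisation for `ρ` given
  `β`).
- **Spatial lag (SAR)**: `y_t = δ W y_t + X_t β + μ + ε_t`, estimated
  by concentrated ML over `δ`.

The log-determinant `ln|I − ρW|` in both likelihoods is evaluated from
the (real) spectrum of the standardised `W`. Spatially lagged
covariates `W*x` (neighbour spillovers) are ordinary extra columns.
Model choice is guided by the LM-lag / LM-error tests and their robust
variants on pooled and FE residuals, plus R², corr², σ², log-likelihood
and AIC. The first-difference model regresses `y_t − y_{t−1}` on the
period `t−1` covariates to read the effect of initial conditions on
subsequent change.

## Worked example

Simulate a 12×12-municipality panel (T = 3, spatial-error disturbances
with ρ = 0.786, covariate and outcome marginals emulating the Brazilian
1980/1991/2000 log-IMR decline), then fit all four models with two
spillover columns:

```sh
spanel simulate --preset imr --rows 12 --cols 12 --seed 1 --out demo
cat > demo/cfg.json <<'EOF'
{
  "panel_path": "demo/panel.csv",
  "weights_path": "demo/weights.gal",
  "covariates": ["pub_hospit", "priv_hospit", "water_access", "sanitation"],
  "slx": ["water_access", "sanitation"],
  "output_dir": "demo/out"
}
EOF
spanel run --config demo/cfg.json
cat demo/out/report.txt
```

which prints (abridged):

```
                         Pooled model     Fixed Effects      FE SEA model      FE SAR model
-------------------------------------------------------------------------------------------
pub_hospit                 -0.1296**         -0.0945           -0.0273           -0.0276
priv_hospit                -0.3993***        -0.4031**         -0.1203           -0.1401*
water_access               -0.3251***        -0.3605***        -0.3308***        -0.3093***
sanitation                 -0.2542***        -0.2533***        -0.2310***        -0.2127***
W*water_access             -0.3403***        -0.4065***        -0.0492            0.2244***
W*sanitation                0.0373            0.0635           -0.0804            0.1653***
Spatial parameter                                               0.8833***         0.8673***
-------------------------------------------------------------------------------------------
R2                             0.2964            0.4339            0.3543            0.8498
sigma2_eps                     0.0845            0.0698            0.0120            0.0121
Loglikelihood                -75.8220           54.1937          275.5211          278.2236
AIC                          167.6441          -94.3873         -535.0423         -540.4473
N                                 432               432               432               432
-------------------------------------------------------------------------------------------
LM test - spatial lag         161.16***         247.89***
LM test - spatial error       143.47***         228.65***
```

Reading it: water and sanitation coverage reduce the log outcome in
every specification; both LM tests reject independence on the
least-squares residuals, so the spatial models are warranted; they
estimate a strong positive spatial parameter (the DGP's true ρ is
0.786 — a single 144-region draw lands near it), cut the disturbance
variance from 0.070 to 0.012, and dominate on AIC. `report.json` holds
the same content machine-readably, including recovered fixed effects.

The same pipeline is available as a library (`spanel.validate_panel`,
`fit_fe_sea`, `lm_tests`, …); `spanel.simulate_panel` returns the truth
record (β, μ, ρ) alongside the panel for recovery studies.

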