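# Methods

## The problem and the models

Industrial enzymes (the package was built around microbial lipases, but
nothing in it is lipase-specific) lose catalytic activity when held at
elevated temperature. The observable is the residual-activity fraction
A/A0(t) at a fixed temperature, measured at sampling times t and usually in
triplicate. `thermokin` fits a bank of eight closed-form inactivation
models to such curves:

| id | A/A0(t) | parameters |
|---|---|---|
| `first_order` | exp(−kt) | k |
| `weibull` | exp(−b·tⁿ) | b, n |
| `distinct_isoenzymes` | A_L·exp(−k_L t) + A_S·exp(−k_R t) | A_L, A_S, k_L, k_R |
| `two_fraction` | a·exp(−k_L t) + (1−a)·exp(−k_R t) | a, k_L, k_R |
| `multicomponent` | [exp(−k₁t) + r·exp(−k₂t)]/(1+r) | k₁, k₂, r |
| `series_type` | sequential E → E₁ → E_D with intermediate activity α₁ | α₁, k₁, k₂ |
| `nth_order` | [1 + (n−1)kt]^{1/(1−n)} | k, n |
| `fractional_conversion` | A_r + (1−A_r)·exp(−kt) | A_r, k |

Conventions and their rationale:

* **All rates are min⁻¹.** Thermal-inactivation experiments are sampled in
  minutes and every derived quantity (t½, D, t_R) is conventionally quoted
  in minutes; conversion to s⁻¹ happens exactly once, inside the Eyring
  step, where the rate is compared against the k_BT/h attempt frequency.
* **Curves are normalised to A/A0(0)=1** before fitting. This fixes A0=1 in
  the nth-order model and makes the fractional-conversion plateau A_r a
  fraction of the initial activity.
* **Series-type end state.** The general series-type solution has
  A/A0(0) = 1+α₂, which violates normalisation unless α₂=0 (a fully
  inactive end state). The α₂=0 restriction is therefore the default
  three-parameter form used in fitting; the general form can be evaluated
  by passing `alpha_2` explicitly.
* **Distinct isoenzymes vs two-fraction.** The amplitude pair (A_L, A_S) is
  left unconstrained while the two-fraction model uses a single fraction
  a; this is the only reading under which the two models are genuinely
  different parameterisations.

## Estimation

`fit_model` minimises the unweighted residual sum of squares over all
individual observations (replicates are *not* averaged by default; a
`fit_replicate_means` option exists). The optimizer is unconstrained
Levenberg–Marquardt (`scipy.optimize.least_squares`, `method="lm"`,
ftol=xtol=gtol=1e−12, ≤1200 function evaluations per start). Fits are
deliberately unconstrained: negative parameter estimates are informative —
they are a rejection criterion, not an error — so positivity must not be
enforced by bounds.

Initial values come from closed-form linearisations: the log-linear
regression of ln A on t for first-order-like rates, the log-log regression
of ln(−ln A) on ln t for the Weibull pair, and a split of the curve at the
median time for the two-phase models (fast rate from the early half, slow
rate from the late half). Ten starts are used per model: the heuristic
start plus nine multiplicatively jittered copies (log-normal jitter,
σ=0.35; fractions jittered additively and clipped to (0,1)), with a fixed
internal jitter seed so a fit is a pure function of its inputs. The best
SS_res among converged starts wins.

Standard errors come from the Jacobian at the optimum,
cov = (JᵀJ)⁻¹·SS_res/(m−p). A rank-deficient JᵀJ (smallest singular value
below 10⁻¹⁰ of the largest) means the data cannot identify the parameters
— the typical signature of a two-phase model collapsing onto a
single-exponential dataset — and is reported as non-convergence
(`converged=False`), never as an exception.

Goodness of fit: r² = 1 − SS_res/SS_tot (SS_tot about the observation
mean), reduced chi-square χ² = SS_res/(m−p) and SEM = SS_res/m, so
χ²·(m−p) = SEM·m identically.

## Model selection

The screen applies, in order:

1. **no_convergence** — any temperature failed to fit (or had singular
   covariance);
2. **negative_params** — any estimated rate, fraction, amplitude, shape or
   scale is negative (and two-fraction a>1, i.e. a negative stable
   fraction);
3. **equal_rate_constants** — distinct-isoenzymes with k_L = k_R within 1%
   relative at every temperature (the model has degenerated to first
   order); the 1% figure is ours, chosen as a generous reading of "equal"
   at the precision these rates are estimable;
4. **reduces_to_first_order** — Weibull with |n−1| ≤ SE(n) at every
   temperature;
5. survivors are ranked by mean χ², ties by SEM then r². χ² is ranked
   first on purpose: r² and SEM are both monotone in SS_res and therefore
   *always* prefer the model with more parameters, while the
   degrees-of-freedom correction in χ² is the only parsimony-aware
   statistic of the three.
6. Survivors within 25% relative χ² of the best form a **tie group**
   ("statistically indistinguishable"; between nested models on m≈40
   observations, noise alone moves χ² by a few percent, and a genuinely
   better model — e.g. Weibull vs first-order on concave curves — beats
   this margin by an order of magnitude). With ≥2 temperatures the tie is
   broken by the r² of the secondary temperature-dependence regression —
   Arrhenius (ln k vs 1/T) for rate-type models, log-logistic for the
   Weibull scale b — because a model whose parameters behave lawfully in
   temperature is the physically preferable one. If the secondary r²s are
   themselves within 0.005, or only one temperature is available, the most
   parsimonious model (fewest parameters, then catalogue order) wins.

Exactly one model is accepted whenever any model survives; an all-rejected
dataset produces a report with a warning and no derived parameters.

## Derived kinetic parameters

For an accepted rate-type model (rate k, min⁻¹):

* half-life t½ = ln 2/k; decimal reduction time D = 2.303/k (the 2.303 is
  the conventional rounding of ln 10 and is kept as printed convention);
* z-value from the OLS slope of log₁₀(D) vs temperature, z = −1/slope.

For an accepted Weibull model:

* reliable life t_R = (2.303/b)^{1/n}, the 90th percentile of the
  inactivation-time distribution (A/A0(t_R) = e^{−2.303} ≈ 0.1);
* time scale α = b^{−1/n}; 1/α is the apparent rate surrogate;
* z′-value from the slope of log(t_R) vs temperature. **Log-base caveat:**
  the standard z convention uses log₁₀ (default); published z′ values near
  44 °C for fungal-lipase data are only reproducible with natural log
  (|slope| ≈ 0.023 °C⁻¹ → z′ ≈ 44 vs ≈ 101 under log₁₀). Both bases are
  implemented (`zprime_base` option) and the report records which was used.
* the log-logistic temperature model b(T) = ln(1+exp[k′(T−T_c)]). Because
  b spans four orders of magnitude over 30 °C, this fit minimises
  residuals of **ln b**, initialised from the log-linear regression of
  ln b on T (exact in the k′(T−T_c) ≪ 0 regime where b ≈ e^{k′(T−T_c)}).
  Raw-scale least squares would let the largest b dominate and drift to a
  different optimum; the log-scale fit also reproduces the published
  r² ≈ 0.93 for the reference dataset, confirming it is the convention in
  use in this literature.

## Activation thermodynamics

Ea from OLS of ln(rate) on 1/T (kelvin): Ea = −slope·R with
R = 8.314 J mol⁻¹ K⁻¹. Ea is invariant to the rate unit; for Weibull
kinetics the 1/α surrogate is conventionally entered in h⁻¹, which shifts
only the intercept. Per temperature, with the rate in s⁻¹:

* ΔH‡ = Ea − RT (so ΔH falls by exactly R·ΔT between temperatures),
* ΔG‡ = −RT·ln(k_s·h/(k_B·T)),
* ΔS‡ = (ΔH‡ − ΔG‡)/T, and the reported ratio is TΔS‡/ΔH‡.

ΔG‡ = ΔH‡ − TΔS‡ holds identically by construction. `eyring_units` selects
between proper unit conversion (`si`, default: min⁻¹/60 → s⁻¹) and a
`paper-compat` mode that inserts the min⁻¹ number unconverted; the two
differ by exactly RT·ln 60 ≈ 10.7 kJ mol⁻¹ in ΔG‡ at 40 °C. The compat
mode exists because published apparent ΔG‡/ΔS‡ tables for Weibull-derived
rates are reproducible only under it; it is clearly labelled and off by
default. Everything derived from 1/α is flagged `apparent` — a Weibull
scale is not a rate constant and these numbers are comparative, not
mechanistic.

## Synthetic data

The generator emulates the isothermal study design: four temperatures
(40/50/60/70 °C), a sampling grid of t=0 plus 12 log-spaced times spanning
2–240 min (the real studies report only the 2–240 range, not the grid, so
log-spacing was chosen to resolve the fast early decay), three replicates,
and additive homoscedastic Gaussian noise on the activity fraction.
The default noise SD of 0.02 sits inside the replicate-SD envelopes
reported for the two reference enzymes (<0.058 bacterial, <0.038 fungal);
heteroscedasticity and assay-calibration structure of real
spectrophotometric data are *not* emulated, so passing recovery tests
demonstrates estimator correctness under the stated noise model, not
robustness to assay artefacts. Negative noisy observations are kept by
default (`clip_policy="none"`) so the fitting layer sees realistic
near-zero scatter; clipping is available.

Presets encode the two reference conditions: `lipase_ps` (first-order,
k = 0.0136–0.0440 min⁻¹) and `palatase` (Weibull, b = 1.97×10⁻⁷–4.22×10⁻⁴
min⁻ⁿ, n = 4.357–2.869).

## Numerical choices and degenerate inputs

* Optimizer failures and domain violations (nth-order base ≤ 0, series
  k₁=k₂) during search are penalised, re-checked at the optimum, and
  reported as non-convergence; direct evaluation raises typed errors.
* Reports round floats to 10 significant digits and sort JSON keys, so a
  rerun on identical input is byte-identical.
* Reading absolute-unit activity tables: values with max > 1.5 are
  normalised per temperature by the replicate mean at the earliest time
  (threshold and overrides `--already-normalized` / `--normalize-by`).
* Recovery checks in the test suite use 200 simulated datasets of the
  single-temperature study design; the full-bank selection suite is the
  dominant cost of the test run (a few minutes on one CPU).

## Known limitations

* Point estimates ± asymptotic SEs only: no weighted least squares, no
  bootstrap or Bayesian uncertainty.
* Isothermal curves only; no dynamic temperature profiles or F-value
  process calculations.
* Derived-parameter reproduction from printed-precision inputs carries the
  rounding of those inputs (≈0.2% for the steep-n Weibull reliable life,
  where t_R is exponentially sensitive to n).
* The biological interpretation of model choice (lid-domain stability,
  aggregation mechanisms) is outside the package's scope.
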