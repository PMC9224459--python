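# thermokin

Kinetic and thermodynamic analysis of **enzyme thermal inactivation** from
residual-activity decay curves.

When an enzyme preparation is held at a fixed temperature and assayed over
time, its residual activity A/A0(t) decays. Which kinetic law governs that
decay — and how its parameters move with temperature — determines the
quantities process engineers and biocatalysis researchers actually use:
half-life t½, decimal reduction time D, z-value, activation energy Ea and
the transition-state parameters ΔG‡, ΔH‡, ΔS‡. `thermokin` automates the
whole chain for tabular activity data:

1. **Model bank** — eight closed-form inactivation models: first-order
   exp(−kt), Weibull exp(−b·tⁿ), distinct isoenzymes, two-fraction,
   multicomponent, series-type, nth-order and fractional conversion.
2. **Fitting** — unconstrained multi-start Levenberg–Marquardt least
   squares per model per temperature, with r², reduced χ² = SS/(m−p) and
   SEM = SS/m.
3. **Selection** — a physical/statistical screen (negative estimates,
   degenerate rate pairs, Weibull n ≈ 1, non-convergence, then χ²-ranked
   statistics with a temperature-dependence tie-break) that accepts
   exactly one model.
4. **Derived parameters** — first-order branch: t½ = ln2/k, D = 2.303/k,
   z from log₁₀D vs T, Arrhenius Ea, Eyring ΔG‡/ΔH‡/ΔS‡; Weibull branch:
   reliable life t_R = (2.303/b)^(1/n), time scale α = b^(−1/n), z′, the
   log-logistic b(T) = ln(1+exp[k′(T−T_c)]) model and *apparent*
   thermodynamics via the 1/α rate surrogate.
5. **Synthetic data** — a generator reproducing the canonical study design
   (40–70 °C, 2–240 min, 3 replicates, Gaussian noise) with presets for a
   bacterial (first-order) and a fungal (Weibull) lipase.

The API follows the statsmodels idiom: build a model object from data,
`fit()` it, work with the results object.

## Worked example

```python
from thermokin import ThermalInactivation
from thermokin.synthetic import generate_dataset, paper_presets

curves = generate_dataset(paper_presets("lipase_ps", seed=7))
results = ThermalInactivation(curves, label="lipase_ps").fit()
print(results.summary())
```

or equivalently from the shell:

```bash
thermokin simulate --enzyme lipase_ps --seed 7 -o lp.csv
thermokin fit lp.csv -o report.json --label lipase_ps
```

which prints:

```
Thermal inactivation analysis — lipase_ps
=========================================
Temperatures (degC): 40, 50, 60, 70
Accepted model: first_order

Model screening
---------------
first_order            accepted best_statistics          r2 [0.9970; 0.9981]
weibull                rejected low_r2_high_error        r2 [0.9976; 0.9982]
distinct_isoenzymes    rejected no_convergence           r2 [0.9976; 0.9983]
two_fraction           rejected no_convergence           r2 [0.9976; 0.9982]
multicomponent         rejected no_convergence           r2 [0.9976; 0.9978]
series_type            rejected no_convergence           r2 [0.9976; 0.9978]
nth_order              rejected low_r2_high_error        r2 [0.9973; 0.9981]
fractional_conversion  rejected negative_params          r2 [0.9971; 0.9982]

Kinetic parameters
------------------
 temperature_C     r2       k  t_half_min  d_min   z_C
            40  0.997 0.01391       49.84  165.6 58.87
            50 0.9975  0.0196       35.37  117.5 58.87
            60 0.9981 0.02957       23.44  77.87 58.87
            70 0.9977 0.04466       15.52  51.57 58.87

Activation thermodynamics
-------------------------
Ea = 34.88 kJ/mol (Arrhenius r2 = 0.9952, rates in per_min)
 temperature_C  Ea_kJ_mol  dH_kJ_mol  dG_kJ_mol  dS_J_mol_K  TdS_over_dH
            40      34.88      32.28      98.61      -211.8       -2.055
            50      34.88       32.2      100.9      -212.7       -2.135
            60      34.88      32.11        103      -212.8       -2.207
            70      34.88      32.03        105      -212.6       -2.278
```

Reading this: the data were simulated from first-order decay with
k = 0.0136…0.0440 min⁻¹, and the screen recovers that — the two-phase
models collapse (singular covariance → `no_convergence`), the
fractional-conversion plateau fits noise and goes negative, and Weibull,
though statistically indistinguishable from first-order, loses the
Arrhenius-vs-log-logistic tie-break. The fitted rates give a half-life
falling from ~50 min at 40 °C to ~16 min at 70 °C, z ≈ 59 °C,
Ea ≈ 35 kJ mol⁻¹, and a large negative ΔS‡ with ΔG‡ rising in temperature —
the signature of an enzyme whose inactivation transition state is more
ordered than its native state.

For a Weibull-type enzyme, run `--enzyme palatase`: the screen then accepts
`weibull` with shape factors n > 1 (downward-concave semilog curves),
reports t_R, α, z′ (log₁₀ by default; `--zprime-base ln` for the
natural-log convention) and the log-logistic b(T) parameters, and labels
the Eyring block *apparent* because 1/α is a rate surrogate, not a rate
constant.

Real data enter through a delimited table with columns
`temperature_C, time_min, replicate, activity`
(`ThermalInactivation.from_csv` / `from_dataframe`, or `thermokin fit`);
absolute-unit activities are normalised automatically.

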