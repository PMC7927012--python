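# mortcomp — do richer Lee-Carter models change forecast mortality indicators?

`mortcomp` is an analysis pipeline for a question actuaries and demographers
keep running into: extensions of the Lee-Carter mortality model fit
historical data better, but do they actually *forecast different mortality
indicators*?  The package fits three models of the logit death probability
for age *x* and year *t*,

| model | predictor for logit *q<sub>xt</sub>* |
|-------|------------------------------------|
| LC1   | *a<sub>x</sub>* + *b<sub>x</sub>k<sub>t</sub>* |
| LC2   | *a<sub>x</sub>* + *b<sub>x</sub><sup>(1)</sup>k<sub>t</sub><sup>(1)</sup>* + *b<sub>x</sub><sup>(2)</sup>k<sub>t</sub><sup>(2)</sup>* |
| H1    | *a<sub>x</sub>* + *b<sub>x</sub>k<sub>t</sub>* + *γ<sub>t−x</sub>* (cohort effect) |

by quasi-binomial maximum likelihood (death counts *d<sub>xt</sub>* binomial
given exposures *E<sub>xt</sub>*, with an estimated dispersion φ), projects
the period indices *k<sub>t</sub>* and cohort series *γ<sub>c</sub>* with
ARIMA processes, and converts every forecast *q* column into a period life
table to obtain four indicators: life expectancy at birth (e0) and at 65
(e65), the modal age at death, and the Gini index of lifespan inequality.

Forecast uncertainty comes from a **2-D residual block bootstrap**: the
deviance-residual array is resampled in contiguous age × year blocks
(preserving the local dependence visible in Lee-Carter residuals), inverted
back to pseudo death counts, and refitted.  Crucially, the model that
*generates* the residuals (the "sample", RLC1/RLC2/RH1) is crossed with the
model that is *refitted* — a 3 × 3 design with N replicate indicator curves
per cell.  A **random-projection functional ANOVA** (curves projected onto
K Brownian-motion directions; per-projection two-way ANOVAs combined by the
false-discovery-rate rule min<sub>i</sub> K p<sub>(i)</sub>/i) then tests
the model effect, the sample effect, and their interaction, with pairwise
level comparisons.

All stages are exercised on synthetic surfaces with known structure
(`mortcomp.synthetic`), so the pipeline is fully testable without external
mortality data; real surfaces can be supplied as CSV matrices
(`mortcomp.read_surface`).

## Worked example

The `analysis/` scripts run the whole study on a synthetic surface (ages
0–99, years 1993–2012, exposure 10⁵ per cell, binomial deaths around an LC1
truth with period drift −0.8):

```sh
python analysis/01_simulate_surface.py
python analysis/02_fit_models.py
python analysis/03_residual_diagnostics.py
python analysis/04_bootstrap_forecast.py   # N = 50 replicates, ~1 min
python analysis/05_functional_anova.py
```

`02_fit_models.py` prints the goodness-of-fit table (and writes it to
`results/goodness_of_fit.csv`):

```
model  deviance  n_params  dispersion  sweeps
  LC1   1762.49       220        0.99       5
  LC2   1574.43       340        0.95      37
   H1   1698.80       339        1.04      99
```

The richer models reduce the deviance (2000 cells), and dispersion ≈ 1
matches the binomial generator.  `04_bootstrap_forecast.py` reports the 95%
percentile intervals, e.g. mean across cells for e0 rising from
[81.26, 81.43] years in 2013 to [81.79, 82.22] in 2032 while the Gini index
falls — mortality improves and lifespans equalize, as the drifting period
index implies.  `05_functional_anova.py` prints the decision table, e.g.
for e0: model effect p ≈ 10⁻¹⁶³ (rejected — the three models genuinely
forecast different life-expectancy paths), sample effect p ≈ 0.004 and
interaction p ≈ 0.004 (the residual source leaks slightly into the
forecasts), plus all pairwise model/sample comparisons.

The same machinery is available programmatically:

```python
import mortcomp as mc

surface, truth = mc.make_scenario_surface(mc.ScenarioSpec(seed=11))
result = mc.run_experiment(surface, mc.ExperimentConfig(n_replicates=10, seed=42))
result.intervals          # indicator, model, residual_source, year, lower, upper
result.fanova["e0"].p_model
```

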