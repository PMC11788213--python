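# twinproj

Estimation of maternal-age-specific twinning probabilities from
retrospective birth histories, and projection of future twinning rates and
twin-birth counts under changing maternal age structures and population
growth.

The package is aimed at demographers and reproductive epidemiologists
working with survey-based birth histories (DHS/WFS-style individual
recodes) and population projections (WPP-style extracts): populations where
medically assisted reproduction plays little role, so that the maternal-age
gradient in (dizygotic) twinning and sheer population change drive future
twin births.

## The model

Each *delivery* (a birth event, producing one or two children) of mother
*i* in country *c* is twin or singleton. A linear probability model with
country fixed effects,

    twin_{i,c} = beta_{a(i)} + gamma_c + eps_{i,c},

gives probability-scale maternal-age effects `beta_a` (5-year categories
15–19 … 45–49, reference 15–19; 1- and 2-year schemes available) and
country levels `gamma_c`. A country-indicators-only variant yields each
country's average twinning rate `tr` (its observed twin fraction, exactly).
Flat-prior posteriors of both coincide with the OLS sampling distribution
(heteroskedasticity-robust covariance), from which the package draws.

For projection, births `b`, deliveries `d` and twin deliveries `dt` in a
population-year obey

    b = d + dt,    tr = dt / d    =>    d = b / (1 + tr).

Per posterior draw, a projected birth count and maternal age-share vector
`s_a` give `d = b/(1+tr)`, `d_a = d s_a`, and expected twin deliveries
`dt = sum_a d_a p_{c,a}` with `p_{c,a} = gamma_c + beta_a` (recentred per
draw so the baseline-year mix reproduces `tr`). Scenario results are
reported as per-draw percent changes versus the baseline year, summarised
by median and IQR, alongside a country × period panel regression of period
twinning rates on mean maternal age at birth, and a counterfactual
decomposition of changes into population-scale, age-composition and
age-specific-fertility contributions.

A synthetic-data module generates birth histories and projection tables
from known ground truth, so every stage is testable without survey access.

## Worked example

```python
import twinproj as tp

params = tp.SynthParams(n_countries=2, mothers_per_country=10_000, seed=10)
histories = tp.generate_birth_histories(params)
deliveries = tp.collapse_to_deliveries(tp.apply_recall_window(histories, 10))
print("deliveries:", len(deliveries))

fit = tp.fit_lpm(deliveries)
print("age effect 35-39: %.4f" % fit.age_coefficients["35-39"])

rates = tp.fit_country_rates(deliveries, n_draws=1000, seed=1)
print("rates per 1000:", rates.per_1000().round(1).to_dict())

posterior = tp.draw_posterior(fit, n_draws=1000, seed=2)
bundle = tp.PosteriorBundle(rates, posterior)
table = tp.generate_projection_tables(params, [2010, 2100])
base = tp.ProjectionInput.from_frame(table, "S00", 2010)
scn = tp.ProjectionInput.from_frame(table, "S00", 2100)
res = tp.run_scenario(base, scn, bundle)
s = res.summary()
for m in ["pct_change_rate", "pct_change_count", "children_per_twin_sibling"]:
    print(m, s.loc[m].round(2).to_dict())
```

prints

```
deliveries: 56014
age effect 35-39: 0.0109
rates per 1000: {'S00': 11.0, 'S01': 32.3}
pct_change_rate {'median': 8.63, 'q1': 7.38, 'q3': 10.0}
pct_change_count {'median': 166.0, 'q1': 162.93, 'q3': 169.34}
children_per_twin_sibling {'median': 42.36, 'q1': 40.83, 'q3': 43.92}
```

The fitted 35–39 effect (+0.0109) recovers the generating +0.01 increase in
twin probability relative to ages 15–19. Country `S00` was generated with a
low baseline and `S01` with a high one; their estimated average rates (11.0
and 32.3 per 1000 deliveries) are their observed twin fractions under the
simulated age mix. Under the older-shifted 2100 age structure, `S00`'s
twinning rate rises by a posterior-median 8.6% (IQR 7.4–10.0); its twin
*deliveries* rise 166% because projected births also grow. By 2100 roughly
1 in 42 children in `S00` has a twin sibling.

The same steps run as a pipeline from the shell:

```bash
twinproj run --config config.yaml --seed 1   # simulate -> prep -> fit -> panel -> project -> report
twinproj validate births.csv birth_history
```

Every run writes a `manifest.json` with SHA-256 hashes of all outputs;
identical config + seed reproduces identical hashes.

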