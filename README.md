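# nightresp

Tools for analysing and modelling the **nocturnal decline of plant dark
respiration** — for plant ecophysiologists working with leaf or whole-plant
CO₂-efflux time series, and for land-surface modellers who want to quantify
what a time-varying basal respiration rate does to plant respiration and NPP.

## The science

Plant respiration at any temperature T is conventionally modelled with a
constant basal rate and an exponential temperature response (the *standard
model*):

    R_T = R_To · Q10^((T − T_o)/10)

with Q10 either fixed (≈ 2) or temperature dependent,
TDQ10(T) = 3.09 − 0.0435·T. But respiration measured **at constant
temperature** is not constant through the night: the basal rate declines
monotonically with hours of darkness h, following a universal power law
across species

    R_To / R_To-initial = 1 − a·h^b,     a = 0.08, b = 0.54

— about a 25 % decrease after 8 h of darkness. Merging the two gives the
night-time formulation anchored at sunset:

    R_T,t = R_T,sunset · Q10^(0.1·(T_t − T_sunset)) · (1 − 0.08·h^0.54)

This package implements, with seeded synthetic-data generators so every
stage is testable end to end:

- the closed-form models above, plus the land-surface respiration chain
  (logistic high/low temperature limits on leaf respiration, nitrogen-ratio
  scaling to whole-plant maintenance respiration, growth respiration as
  0.25·(GPP − R_m));
- the fitting pipeline: normalization to the initial rate (with a 30-min
  exclusion window against light-enhanced dark respiration), hourly
  binning per replicate, species aggregation with SEMs, and the
  SEM-weighted nonlinear fit of 1 − a·h^b with confidence intervals;
- slope statistics for species-group comparisons (log-linearized slopes,
  Welch t-tests, Bonferroni-corrected pairwise tests);
- the Q10 decomposition: inherent vs apparent Q10, the α/β partition of a
  night's respiration decrease and the temperature-control statistic
  TC = α/(α+β), plus analytic curves of Q10_app and TC versus cooling rate
  and the cumulated overestimation of nightly respiration by
  constant-basal-rate models;
- a four-formulation model evaluation (one-to-one regression excluding the
  first point, standardized residuals, RMSE, Taylor statistics);
- a single-site simulator stepping leaf/maintenance/growth/plant
  respiration, GPP and NPP through days at a 15-min timestep, with and
  without the nocturnal decline.

## Worked example

```python
from nightresp import (gen_dataset, species_aggregates, fit_power_law,
                       decline_fraction, gen_forcing, SiteConfig, run_site,
                       compare_runs, Formulation)

# recover the universal decline from a synthetic 31-species campaign
traces = gen_dataset(n_species=31, replicates=(4, 20), noise_sd=0.03, seed=1)
fit = fit_power_law(species_aggregates(traces, exclusion_min=0))
ci = fit.param_ci()
print(f"a = {fit.a:.4f} (95% CI {ci['a'][0]:.4f}-{ci['a'][1]:.4f})")
print(f"b = {fit.b:.4f} (95% CI {ci['b'][0]:.4f}-{ci['b'][1]:.4f})")
print(f"r2 = {fit.r2:.3f}, pooled bins = {fit.n}")
print(f"decline after 8 h: {100*(1-decline_fraction(8.0)):.1f}%")

# effect of the decline on site-scale plant respiration and NPP
forcing = gen_forcing(latitude=5.0, n_days=30, seed=1)
base = run_site(forcing, SiteConfig(formulation=Formulation.from_name("standard")))
var = run_site(forcing, SiteConfig(formulation=Formulation.from_name("new")))
d = compare_runs(base, var)
print(f"delta R_p = {d.d_rp_pct:.2f}%  delta NPP = +{d.d_npp_pct:.2f}%")
```

prints

```
a = 0.0783 (95% CI 0.0763-0.0803)
b = 0.5521 (95% CI 0.5389-0.5653)
r2 = 0.991, pooled bins = 341
decline after 8 h: 24.6%
delta R_p = -4.45%  delta NPP = +4.00%
```

The fitted coefficients recover the generating universal model within their
confidence intervals; at a tropical site the nocturnal decline lowers
month-mean plant respiration by ~4.5 % and raises NPP by the identical
absolute amount (~4 % relative), because NPP = GPP − R_p step for step.

A `nightresp` command exposes the same pipeline from the shell
(`generate`, `fit`, `tc`, `curves`, `evaluate`, `simulate`); every
subcommand logs its parameters and seed to stderr and writes data to files.

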