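# Methods

This note records the models implemented in `nightresp`, the assumptions and
parameter choices behind them, what the synthetic-data generators do and do
not emulate, and the numerical decisions a maintainer would want to know.

## Models

**Temperature response.** Respiration is CO₂ efflux, positive everywhere.
The standard model is `R_T = R_ref · Q10^((T − T_ref)/10)` with a fixed
Q10 (default 2.0) or the temperature-dependent form
`TDQ10(T) = 3.09 − 0.0435·T` (dimensionless, T in °C, supported over
−10…45 °C; outside that range the function warns but still evaluates).
Where the night-time formulation uses TDQ10, the Q10 is evaluated at the
instantaneous temperature `T_t` — the merged expression's exponent notation
does not disambiguate between `T_t`, the sunset temperature, or their mean,
and the instantaneous reading is the literal one. Over a typical 4 °C
nocturnal cooling the three choices differ by < 1 % in the predicted ratio.

**Nocturnal decline.** The basal-rate ratio is `1 − a·h^b` with defaults
`a = 0.08`, `b = 0.54` and `h` the hours since the onset of darkness. The
value is clamped to [0, 1]: the default curve would cross zero only near
h ≈ 107 h, far outside any night, but the clamp guards pathological
configurations. Disabled, the factor is identically 1, which makes the
merged formulation collapse exactly onto the standard model — a degeneracy
several tests rely on.

**Land-surface respiration chain.** Leaf respiration divides the Q10
response by `(1 + e^{0.3(T − T_upp)})(1 + e^{0.3(T_low − T)})`; the
smoothing constant 0.3 is fixed, not user-configurable. Whole-plant
maintenance respiration multiplies canopy leaf respiration by
`β_sw + (N_r + N_s)/N_l`; only the nitrogen ratio matters, so the contents
are treated as a single dimensionless ratio (defaults N_r = N_s = 0.5,
N_l = 1, β_sw = 1). Because this factor is linear, any nocturnal decline of
leaf respiration propagates unchanged to root and stem maintenance
respiration. Growth respiration is `0.25 · max(GPP − R_m, 0)`: the clamp is
our choice — at night GPP = 0 and the unclamped expression would be
negative, which has no physiological reading for a construction cost.

## Q10 decomposition and temperature control

The α/β partition uses endpoint pairs (night start vs night end): the
temperature-only endpoint is `R_start · Q10_inh^(ΔT/10)`, α is the decrease
explained by it, β the further observed decrease, and TC = α/(α+β). Warming
nights and net respiration increases raise an explicit undefined-TC error
rather than returning a negative number: the construct assumes nocturnal
cooling. Inherent-Q10 estimates carry a ≤ 30 min elapsed-time validation,
mirroring the short-term-manipulation definition. The analytic cooling-rate
curves follow from the same endpoint algebra:
`Q10_app(c) = Q10_inh · (1 − a·L^b)^(−10/(cL))` and
`TC(c) = (1 − g)/(1 − gD)` with `g = Q10_inh^{−cL/10}`, `D = 1 − a·L^b`.
TC at exactly zero cooling is reported as its limit, 0.

The cumulated-overestimation integrator is trapezoidal on the model
timestep (default 0.25 h); at constant temperature the relative reduction
has the closed form `(a/(b+1))·L^b` (19.88 % for a 12-h night), which the
tests use as the integration oracle together with a fine-grid run.

## Fitting pipeline

Normalization takes the first sample at or after the exclusion window
(default 30 min, guarding against light-enhanced dark respiration) as
`R_To-initial` and drops earlier samples; the first retained ratio is 1.
Hourly bins cover `h ∈ [k, k+1)`. Each bin records both its index and the
**empirical mean hour of its samples, which is the abscissa used for
fitting**. A fixed centre-of-bin label (k + 0.5) was considered and
rejected: with on-the-hour or otherwise non-uniform sampling it shifts every
point systematically off the curve and biases the exponent, whereas the
empirical mean hour makes the noiseless pipeline reproduce the generating
curve exactly. Species aggregation averages replicate-level hourly means,
with SEM = sd/√n over replicates and SEM = 0 for a single replicate.

The universal fit minimises `Σ w_i (y_i − (1 − a·h_i^b))²` with
`w_i = 1/SEM_i` — the weighting is 1/SEM, not 1/SEM², so it is implemented
through `scipy.optimize.curve_fit` with `sigma = √SEM`. Zero-SEM bins
receive the largest finite weight present, avoiding infinite weights.
The intercept is pinned at 1 by the functional form. The covariance is
scaled by the reduced chi-square; r² is `1 − SS_res/SS_tot` on weighted
residuals; parameter CIs and the curve band use Student-t critical values
with n − 2 degrees of freedom, the band via the delta method. The default
pools species-level bins (not replicate bins) weighted by 1/SEM.

Log-linearization regresses `log(1 − ratio + ε)` on `log h` with
ε = 1e−6, dropping h = 0 and filtering ratio ≥ 1 bins with a warning; for
an exact power law the slope equals the exponent b. This convention is
stated prominently because group-slope magnitudes depend entirely on the
transform chosen; alternative transforms (e.g. log ratio vs time) give
different numbers. Group comparisons use Welch t-tests with
Welch–Satterthwaite df, and pairwise slope tests use
`t = Δslope/√(SE₁²+SE₂²)` on `n₁+n₂−4` df with Bonferroni correction over
the total comparison count m across all groupings. The default 31-species
generator tags species 15 lab / 16 field, 20 tree / 11 herbaceous and
18 temperate / 13 tropical, a grouping whose within-group pairwise count is
m = 701.

The whole-tree-chamber filter retains the `max(1, floor(0.10·n))` nights
with the strongest initial signal (6 of 62 nights).

## Synthetic data

The generators emulate: per-species power-law decline with multiplicative
Gaussian measurement noise (relative noise is the natural invariant when
leaf and whole-tree magnitudes differ fifty-fold; the noise structure of
real analysers is not documented, so multiplicative Gaussian is our
choice), between-replicate variation of the initial rate, constant-T_o lab
and field basal-rate campaigns, naturally cooling field nights with an
inherent Q10 response, optional LEDR transients (additive exponential,
10-min decay, hard-confined to the first 30 min — only the confinement
matters for testing the exclusion rule), noisy whole-tree chamber nights
with log-normal night-to-night signal variation (CV 0.4), and sinusoidal
diurnal forcing (temperature peaking at 14:00 solar, half-sine GPP between
sunrise and sunset). Defaults are the study conditions: 31 species,
universal coefficients (0.08, 0.54), measurement noise sd 0.03,
replicate CV 0.15, Q10_inh = 2, cooling 0.5 °C/h, nights ≤ 16 h, 15-min
forcing timestep.

Not emulated: instrument-specific artifacts (IRGA drift, leak signatures),
thermal acclimation across days, daytime light inhibition, real weather.
Passing tests therefore demonstrate that the pipeline recovers what it
assumes — power-law decline plus multiplicative noise — not that real
campaigns are free of structured biases the generators omit.

Every generator is a pure function of (parameters, seed).

## Model evaluation

Predictions are anchored at the first retained sample: its temperature
stands in for the sunset temperature, elapsed time counts from it, and the
prediction there is exactly 1. One-to-one statistics regress predicted on
observed ratios excluding that first point (it is 1 by construction on both
axes); RMSE is the root-mean-square departure from the 1:1 line, not the
regression residual. Standardized residuals follow
`S_i = r_i / √(Σ r²/df)` with `r_i` the difference of the renormalized
series and df = N − 1 — the degrees of freedom are not uniquely determined
for an unfitted model comparison, and N − 1 (one shared unit anchor) is our
documented default. Taylor statistics use population (ddof = 0) standard
deviations so the geometric identity holds exactly.

## Site simulator

Leaf temperature equals air temperature (no energy-balance model at this
scale) and GPP is prescribed from forcing rather than computed, isolating
the respiration effect. Sun times come from the declination approximation
`δ = −23.44°·cos(2π(doy+10)/365)` and `cos H = −tanφ·tanδ`, with polar
clamps. The night clock starts at each day's astronomical sunset (the run's
opening partial night is anchored at the previous day's sunset); the step
at or immediately preceding sunset is logged with its temperature and leaf
respiration as the sunset anchor. The decline factor multiplies the full
logistic-limited leaf respiration at the instantaneous temperature — i.e.
outside the temperature denominator — which makes the decline-off run
coincide bit-for-bit with the standard run; anchoring the literal
sunset-referenced expression instead would differ only by the ratio of
logistic denominators at `T_t` vs `T_sunset`, negligible inside the
temperature limits. Steps straddling sunset or sunrise are split pro-rata,
and the decline is evaluated at the midpoint of each step's night portion,
which keeps the nightly integral within 0.1 % of the closed form at the
15-min timestep despite the h^0.54 kink at sunset. Percentage deltas are
masked for sites whose baseline NPP is below 50 g C m⁻² yr⁻¹ (flux-to-mass
conversion at 12.011 g C/mol over a 365-day year) to avoid huge
percentages at near-zero NPP.

Problem sizes used in the test suite and acceptance script — 31 species ×
4–20 replicates × 11 hourly samples for the fit, a few days to a month of
15-min forcing for site runs, 10⁴ replicates for the Welch null — are
chosen as the smallest sizes at which the statistical checks are stable.

## Known limitations

- No gridded or multi-site simulation, no PFT mosaic, no soil-moisture
  dynamics (β_sw is a fixed scalar), no CO₂ trajectory: global-scale
  percentages are out of reach by design.
- The decline model is purely empirical; no mechanism (substrate depletion,
  circadian control) is represented, and no acclimation of Q10 or of the
  initial rate across days.
- TC is an endpoint statistic; within-night trajectories of α and β are not
  decomposed.
- The power-law fit assumes independent bin errors; within-replicate serial
  correlation (present in real traces, absent in the generators' i.i.d.
  noise) would narrow the reported CIs relative to the truth.
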