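# Methods

## The model

`qsoc` implements a first-order soil organic carbon (SOC) model built on
continuous-quality theory. Instead of discrete pools, every carbon atom
carries a dimensionless *quality* q — inversely related to its persistence —
and decomposers preferentially consume high-quality material, returning it
at lower quality. Under a bare fallow (carbon inputs held at zero) the model
closes analytically. With

- `u0` — decomposer metabolic rate (per year on the quality scale; the carbon
  concentration of decomposer biomass is absorbed into it),
- `eta11` — rate of decrease in quality per pass through the decomposers,
- `q0` — quality of the litter inputs that built the stock,
- `e0` — decomposer carbon-use efficiency (fraction in (0, 1)),
- `beta = beta0 + 0.01 * clay%` — shape parameter linking decomposer growth
  rate to quality, with an additive clay term,
- `re` — dimensionless climate scalar rescaling `u0`,

the stock-average quality is

    q_bar(t) = q0 * (1 + beta * eta11 * u0 * re * q0^beta * t)^(-1/beta)

and the SOC stock is

    C(t) = C_ss * (q_bar(t)/q0)^[(1-e0)/(eta11*e0) - beta]

where `C_ss` is the stock at the start of the fallow, assumed at steady
state with the pre-fallow inputs. The average quality at that steady state
is

    q_bar(0) = q0 * (1 - e0 - eta11*e0*beta) / (1 - e0 - eta11*e0*(beta-1))

The pool of carbon still at input quality ("plant-derived" material) obeys
`dCp/dt = I - (u0*re*q0^beta/e0) * Cp`; with inputs switched off its
surviving fraction is `exp(-u0*re*q0^beta/e0 * t)`. A typeset variant with
the reciprocal exponent `e0/(u0*re*q0^beta)` circulates; both are available
behind `rate_convention` (`"eq4_consistent"`, the default and the rate the
mass balance implies, vs `"eq6_printed"`). The climate scalar `re` rescales
`u0` wherever `u0` appears, including the plant-pool dynamics.

Structural consequences the tests exercise: the stock is strictly
decreasing and positive at every finite time (no inert pool — only a
continuously slowing decline), quality trajectories of sites that start at
different `q0` converge over decades, and the model is singular at
`beta = 0`, where the quality expression switches to its exponential limit
below `beta < 1e-8`.

### Validity rules

The closed forms describe decay only when the decay exponent
`(1-e0)/(eta11*e0) - beta` and the equilibrium-quality numerator
`1 - e0 - eta11*e0*beta` are positive, on top of positivity of all
parameters. `validate_parameters` returns a verdict listing violated rules;
the likelihood maps invalid sets to `-inf` instead of raising, so samplers
treat them as zero-probability.

## Climate scalars

Weather enters only through `re`. Per site-year:

- temperature response: Arrhenius form with activation energy 59.46 kJ/mol
  (the average measured on bare-fallow soils), normalised to 1 at 35.14 °C
  and clamped above; a Lloyd–Taylor parameterisation is available behind
  `form="lloyd_taylor"`.
- moisture response: driven by the saturation fraction of a single-bucket
  annual water balance (precipitation in; actual evapotranspiration =
  potential demand throttled linearly by bucket fullness; overflow drains).
  Potential evapotranspiration is Penman–Monteith on annual means times an
  empirical 0.9 scaling, falling back to the Holdridge temperature rule
  (58.93 mm per °C of positive mean temperature) when radiation, humidity
  or wind are missing. Water-holding capacity comes from a linear texture
  pedotransfer rule (available water fraction `0.20*clay + 0.25*silt +
  0.06*sand`, times depth).
- the default moisture curve rises as `(s/0.65)^1.3` to an optimum at
  saturation 0.65, then declines linearly to 0.6 at full saturation
  (oxygen limitation reduces, but does not stop, decomposition). The curve
  is pluggable; coefficients of laboratory-derived alternatives can be
  supplied as a callable.

`re_raw = re_temp * r_moist` is averaged over years within a site and
divided by the grand mean over sites, so the across-site mean of `re_norm`
is exactly 1 — only relative climate differences reach the kinetics.
Projections use each site's constant mean `re_norm`.

## Calibration

Hierarchical structure: `u0` and `eta11` are generic (shared by all sites,
assumed thermodynamically constrained); `q0`, `e0`, `beta0` are local (site
history, stoichiometry and soil). Priors:

| parameter | prior | rationale |
|---|---|---|
| `u0` | Uniform(0, 0.98) | ±100 % of the literature value 0.49 (= 0.5 × 0.98 with the decomposer carbon concentration absorbed) |
| `eta11` | Uniform(0, 0.72) | ±100 % of the literature value 0.36 |
| `q0` | Normal(1.08, 0.108) trunc [0.5, 1.5] | literature centre, CV 10 %, prudently wide bounds |
| `e0` | Normal(0.3, 0.03) trunc [0, 0.6] | carbon-use-efficiency range |
| `beta0` | Normal(0.7, 0.07) trunc [0.469, 0.931] | literature centre, CV 10 %, ±33 % bounds |

The error model is independent Gaussian with one standard deviation per
series (the average replicate SD); SOC stocks and plant fractions enter the
likelihood simultaneously. Irregular SOC series are linearly interpolated
to annual resolution before fitting (endpoints preserved exactly); a
`use_raw_times` flag restricts the likelihood to raw observation times for
sensitivity checks. The plant-fraction error SD defaults to the series'
replicate SD when present, else 10 % of the initial fraction.

### Sampler

A seeded random-walk Metropolis–Hastings scheme with block updates per
sweep: the generic pair against the pooled likelihood, each site's local
triple against its own site, plus three full-vector updates that carry the
global correlations (notably `eta11` with every site's `e0` through the
shared decay exponent). Proposals are multivariate Gaussian; during burn-in
only, per-block scales adapt toward 20–40 % acceptance (Robbins–Monro on
the log scale) and proposal covariances are refreshed every 100 iterations
from the running sample covariance, which is reset halfway through burn-in
to drop the initial transient. After burn-in the kernel is frozen, so
retained draws come from a fixed Markov kernel. Chains start at independent
prior draws rejection-resampled to validity; everything is reproducible
from a single seed (chains use generators spawned from one seed sequence).

Defaults are 4 chains × 100 000 iterations with 10 000 burn-in;
the bundled analyses and tests run a scaled-down 4 × 20 000 / 5 000
configuration, which the convergence diagnostics show is sufficient for the
synthetic networks used here (max R-hat ≈ 1.01 across seeds). Convergence
is summarised by the Gelman–Rubin potential-scale-reduction statistic
`sqrt(Vhat/W)` with `Vhat = (n-1)/n W + B/n` on post-burn-in draws; values
below 1.1 are conventionally taken as adequate mixing.

With a `flat_likelihood` switch the sampler targets the prior alone, which
is used to verify that the MCMC machinery reproduces every prior marginal.

## HSY sensitivity analysis

Given any chain with per-element RMSE, elements are split at the 5 % RMSE
quantile (empirical order statistic, lower interpolation; the behavioral
bin holds exactly `ceil(0.05 n)` elements, ties resolved by first
occurrence). Per parameter, the Kolmogorov–Smirnov distance between the
behavioral and non-behavioral empirical distributions measures sensitivity;
per-site distances are averaged and sorted to rank parameters. The bundled
two-stage protocol (all-generic calibration → HSY → local calibration)
reproduces the design logic: `q0` dominates the ranking, motivating its
local calibration.

## Synthetic data

Real multi-decadal bare-fallow series are held by the experiment custodians
and available on request only, so the package generates statistically
analogous data: 4–7 sites with initial stocks 40–100 Mg C/ha, clay 7–36 %,
mean annual temperature 5.4–10.7 °C, precipitation 533–862 mm and durations
of 30–80 years; annual weather as Gaussian fluctuations around site means
(precipitation truncated at zero); observations as the closed-form
trajectories plus homoscedastic Gaussian noise (default SD 1.5 Mg C/ha,
within the replicate-SD range of real bare fallows; stocks clipped at zero,
plant fractions truncated to [0, 1]).

True parameters default to shared `u0 = 0.05`, `eta11 = 0.36`, site
`q0` of 0.9 / 1.0 / 1.15 / 1.3, and `e0 = 0.3`, `beta0 = 0.7` everywhere —
heterogeneous initial quality over shared kinetics, the structural
hypothesis the calibration is designed around, with a pronounced decay
signal inside a 40-year window. Sampling schedules are annual by default;
an irregular mode draws years without replacement, always keeping the
first and last.

What the generator does **not** emulate: input pulses and priming,
erosion, equivalent-soil-mass corrections, serially correlated or
heteroscedastic measurement error, daily weather, and model misspecification
(data are generated by the same closed forms that are fitted). Passing
recovery tests therefore demonstrate that the pipeline is self-consistent
and well calibrated statistically — not that the model is structurally
correct for any particular field site.

## Projections and fit reports

Projections evaluate every (default every 10th) post-burn-in draw at the
requested horizons (default 300 / 1000 / 3000 years) with the site's
constant mean `re_norm`, reporting empirical medians and central 95 %
intervals. Fit reports give the minimum-RMSE trajectory, the envelope of
draws within the 95 % RMSE quantile, and RMSE summaries (mode via a
Freedman–Diaconis histogram, mean, and mean as a percent of the final
observed stock).

## Numerical choices and edge cases

- `beta < 1e-8` switches quality to its exponential limit; the relative
  discrepancy of the two forms grows as `beta*(rate*t)^2/2`, which the
  tests check at `beta = 1e-6` on decadal scales.
- Extremely fast-decay parameter corners underflow double precision at
  millennial horizons; stocks are mathematically positive at all finite
  times and the property tests verify positivity wherever doubles can
  represent the value (log-stock above −700).
- Truncated-normal log-densities are normalised over their bounds; uniform
  priors over theirs.
- The HSY tie rule keeps the behavioral bin size exact under fully tied
  RMSE values.
- Degenerate Gelman–Rubin input (zero within-chain variance) returns 1.

## Problem sizes used in the bundled analyses

The analysis drivers and the test suite use the four-site network with 40
annual observations per site and 4 × 20 000 / 5 000 chains (the flat-prior
check uses 4 × 102 500 thinned to 10 000 near-independent draws). These
sizes give stable diagnostics (R-hat ≤ ~1.01, coverage and ranking
recovery across ten repeated networks) while each full calibration stays
under a minute on a single core.

## Known limitations

- The moisture curve and pedotransfer coefficients are documented defaults,
  not fitted to any specific soil database; swap in laboratory-derived
  curves via the pluggable hooks for site-specific work.
- The annual water balance ignores snow storage and sub-annual dynamics.
- The Gaussian likelihood treats interpolated annual points as independent
  observations (mirroring the calibration protocol this package follows);
  `use_raw_times=True` quantifies the effect of that choice.
- `Css` is fixed at the observed initial stock rather than calibrated; its
  measurement error is not propagated.
- The sampler is a random-walk MH; posteriors with much higher dimension
  (many tens of sites) would warrant gradient-based samplers, which are out
  of scope.
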