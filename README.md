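# qsoc — continuous-quality modelling of soil organic carbon decay

`qsoc` is a Python package and analysis pipeline for studying how soil
organic carbon (SOC) decays over decades to millennia when carbon inputs
stop, as in long-term bare fallow experiments. It asks a simple question
with policy weight: how far can plain first-order kinetics go in describing
SOC persistence across very different soils and climates?

The core is the closed-form *Q model*. Each carbon atom carries a
dimensionless quality q (inversely related to persistence); decomposers
consume high-quality carbon fastest and return it at lower quality, so the
stock-average quality q̄ drifts down and decay slows continuously — there
is no "inert" pool, only an ever-slowing decline. Under zero input:

    q̄(t) = q0 · (1 + β η11 u0 re q0^β t)^(−1/β)
    C(t)  = C_ss · (q̄(t)/q0)^[(1−e0)/(η11 e0) − β],     β = β0 + 0.01·clay%

with generic kinetics `u0` (decomposer metabolic rate) and `η11` (rate of
quality decrease) shared by all sites, and local parameters `q0` (initial
litter quality), `e0` (carbon-use efficiency) and `β0` (edaphic term) per
site. A climate scalar `re` (temperature × moisture reduction functions,
normalised so its across-site mean is 1) rescales `u0`.

The package provides:

- `qsoc.model` — the closed forms above, plus the surviving plant-derived
  fraction and parameter-validity rules;
- `qsoc.climate` — Arrhenius temperature response (Ea = 59.46 kJ/mol,
  capped at 35.14 °C), bucket water balance + moisture response,
  Penman–Monteith PET, and cross-site normalisation of `re`;
- `qsoc.calibrate` — hierarchical Bayesian calibration (generic vs local
  parameters) with a seeded blocked adaptive Metropolis–Hastings sampler,
  Gaussian error model, annual interpolation and Gelman–Rubin diagnostics;
- `qsoc.sensitivity` — Hornberger–Spear–Young analysis: behavioral split at
  the 5 % RMSE quantile and Kolmogorov–Smirnov sensitivity ranking;
- `qsoc.synthetic` — generator of multi-site bare-fallow datasets with
  known parameters (real bare-fallow series are only available on request
  from their custodians);
- `qsoc.projection` — millennial projections with 95 % credible intervals
  and fit-band reports;
- a `qsoc` command-line interface (`simulate`, `climate`, `calibrate`,
  `sensitivity`, `project`, `report`) and numbered drivers under
  `analysis/` that run the full study on synthetic data.

See `docs/methods.md` for the model assumptions, priors, sampler design
and limitations.

## Worked example

Calibrate a four-site synthetic network (40 annual observations per site,
noise SD 1.5 Mg C/ha, true shared u0 = 0.05, η11 = 0.36, site q0 spread
0.9–1.3) and check recovery:

```bash
python analysis/01_simulate_network.py
python analysis/02_generic_calibration_hsy.py
python analysis/03_local_calibration.py
```

The first stage (one parameter set for all sites) feeds the HSY analysis,
which prints the sensitivity ranking — initial litter quality dominates,
which is why `q0` is then calibrated locally:

```
averaged sensitivity ranking (descending):
q0       0.235
eta11    0.228
beta0    0.199
e0       0.069
u0       0.055

most sensitive parameter: q0
```

The hierarchical calibration (4 chains × 20 000, 5 000 burn-in) then
recovers the generating truth:

```
recovery check (truth vs posterior median):
  u0    true 0.050 median 0.050
  eta11 true 0.360 median 0.365
  q0[site01] true 0.90 median 0.991
  q0[site02] true 1.00 median 1.055
  q0[site03] true 1.15 median 1.124
  q0[site04] true 1.30 median 1.120

max R-hat over monitored parameters: 1.001 (threshold 1.1)
```

The generic kinetics are recovered almost exactly and every true value
falls inside its 95 % credible interval; the q0 medians track the true
spread (with the top two sites overlapping in this single realisation —
pooled over repeated networks the test suite shows rank correlation
≥ 0.9). All chains mix below the conventional R-hat threshold of 1.1.
`analysis/04_fit_report.py` and `analysis/05_projections.py` then write the
fit bands and the 300 / 1000 / 3000 / 10 000-year projection table; the
projected stocks decline at every horizon — the model never settles on an
inert floor.

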