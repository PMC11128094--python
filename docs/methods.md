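# Methods

## Model

`rtfbayes` fits *retarded transient functions* (RTFs) to sparse, noisy
replicate time series.  The RTF is a closed-form response curve

```
f(t) = Asus * (1 - exp(-t/t1))                       (sustained response)
     + Atrans * (1 - exp(-t/t11)) * exp(-t/t2)       (transient response)
     + p0                                            (baseline)
```

evaluated at a transformed time

```
t = Trange * ( log10(10^(t_real/Trange) + 10^Tshift) - log10(1 + 10^Tshift) )
```

The transformation delays the response by `Tshift` (log10 domain) while
leaving `t_real = 0` invariant; as `Tshift -> -inf` it reduces to the
identity, i.e. an immediate response.  `Tshift = -2` is effectively
immediate and is fixed at that value by default; `Trange` is a constant set
to the observation range `max(t) - min(t)` of each dataset.  The form above
was chosen so that both defining properties (zero invariance, identity
limit) hold exactly and timescales stay in the units of the data; it is
pinned by regression tests against a 30-digit symbolic evaluation.

RTFs describe single-peak responses: one activation, optionally decaying to
a new steady state.  Oscillations and multiple peaks are out of scope.  A
first-order absorption/elimination pharmacokinetic model (`pk2c`) is
registered as an alternative evaluator, with the `ka = ke` degenerate case
handled by the analytic limit and an `expm1` formulation guarding the
near-degenerate case against cancellation.  Further models can be plugged in
through `register_model`.

## Data model and posterior

Measurements are modelled as the simulation trajectory plus additive i.i.d.
Gaussian noise with a single pooled standard deviation per dataset:

```
m_j(t_k) = s(t_k, theta) + eps,   eps ~ N(0, sigma^2)
```

`sigma` is estimated jointly with `theta` by default (it can be fixed in the
run configuration).  Priors are independent uniforms; timescales and
`sigma` are sampled uniformly on log10 (positivity plus scale-spanning
bounds), amplitudes and the baseline on the linear scale.  The data-informed
defaults, with `delta = max(m) - min(m)` and `R = Trange`:

| parameter      | bounds                         | scale |
|----------------|--------------------------------|-------|
| Asus, Atrans   | [-2 delta, 2 delta]            | lin   |
| p0             | [min(m) - delta, max(m) + delta] | lin |
| t1, t11, t2    | [R/100, 10 R]                  | log10 |
| sigma          | [delta/1000, 2 delta]          | log10 |

The prior support additionally imposes **t11 <= t2** (the transient must
rise at least as fast as it decays).  This is an identifiability constraint:
a transient with slow decay relative to its rise is numerically exchangeable
with a second sustained term, and without the constraint the three
timescales are not individually recoverable even from clean data.  It does
not restrict the family of curve shapes the RTF can express.

Individual-parameter recovery is only well-posed when the data actually
express both terms at separated timescales.  A near-monotone saturating
course constrains the *curve* tightly but splits arbitrarily between the
sustained and transient terms; recovery tests therefore use a ground truth
with a sharp early peak on a slow rise and a sampling grid that is denser at
early times, which is also how such experiments are designed in practice.

## Sampling

The posterior is sampled by an adaptive Metropolis algorithm: Gaussian
random-walk proposals whose covariance is the running chain covariance
scaled by `2.38^2/d` (re-estimated every 50 steps after an initial 500-step
window, regularized by `1e-10 I`), with a global step-size factor tuned
towards the 0.234 target acceptance rate.  Chains start at the best of 1000
prior draws with finite posterior.  Defaults: 2 chains of 50,000 steps, 30%
burn-in, no thinning (the ensemble summaries are percentile-based and
tolerate autocorrelation; the effective sample size is reported so users can
judge).  A seed is mandatory — there is no silent nondeterminism, and
identical (seed, config, data) reproduce draws bit for bit.

At low noise the RTF posterior is multimodal and plain adaptive MH can
stall in a local mode (recognizable by split-R-hat well above 1.1 and a
depressed log-posterior).  For such targets the parallel-tempering sampler
runs adaptive-MH chains against the likelihood tempered by an ascending
temperature ladder, with even/odd adjacent swap proposals each step; only
the cold chain is returned and swap acceptance rates are logged.  A
geometric ladder `1.8^k` with 6–9 rungs works well for the synthetic
studies shipped here; the single-temperature ladder degenerates exactly to
plain adaptive MH.

Diagnostics: per-parameter effective sample size `P / (1 + 2 sum rho_t)`
with Geyer's initial-positive-sequence truncation, and split-R-hat (each
chain halved, between/within variance ratio over the half-chains;
single-chain fits are split in two).  `R-hat > 1.1` logs a warning but does
not fail a run.

## Ensembles, tubes and comparison

Parameter uncertainty is pushed into the data space by evaluating the model
at every retained draw, `s_i(t) = s(t, theta_i)`, *without* adding noise.
The `(1-alpha)` credible tube takes, per grid point, the empirical
`alpha/2` and `1-alpha/2` percentiles (and median) of the ensemble using
linear interpolation between order statistics (the type-7 convention,
pinned exactly by an independent sort-based oracle); between grid points the
tube is linearly interpolated.  The default grid has 201 evenly spaced
points over the observation interval and the default level is 95%.

Posterior-predictive draws add `N(0, sigma_i^2)` noise per draw and grid
point; their pointwise variance therefore dominates the ensemble variance,
which is a lower bound for predictive variability.  Tubes are computed on
the noiseless ensemble by default — the tube then summarizes uncertainty in
the model *state*, not in future observations — with PPD tubes available by
passing the predictive ensemble to the same tube function.

Conditions are fitted independently (one posterior per condition) and
compared by (i) pointwise tube disjointness — tubes disjoint at a grid
point when one upper bound lies strictly below the other lower bound — with
the fraction of disjoint grid points reported per pair, never
auto-thresholded; and (ii) per-parameter 95% highest-density intervals
(shortest contiguous interval containing 95% of sorted draws) with overlap
flags, so a condition whose interval lies entirely below all others can be
read off as credibly lower.

## Synthetic data

The generator realizes exactly the assumed data model (RTF trajectory plus
i.i.d. Gaussian noise) and stores the ground truth next to the data.  Two
presets emulate common sparse in-vivo designs: `pvl-like` (5 conditions x 5
time points x 5 replicates on a 0–5 day grid; transiently hyper-perfused
and persistently hypo-perfused shapes around a shared baseline) and
`steatosis-like` (3 conditions on a 0–6 h grid, 8 time points, 4/6/6
replicates; peak-and-elimination shapes with delayed clearance in the
severe condition).  Negative values are kept by default — excluding
physically meaningless negatives (`drop_negative`) is an application-level
preprocessing step, not part of the data model.

What the generator does *not* emulate: inter-individual random effects
(replicates are exchangeable within a condition, as the pooled error model
assumes), time-varying noise variance, and correlated measurement error.
Passing tests therefore demonstrate correctness of the machinery under the
model's own assumptions, not robustness to their violation.

## Problem sizes and numerical choices

The test suite runs its statistical checks at sizes chosen to keep the full
suite in the tens of minutes on one CPU: the conjugate-sampler check uses 2
x 25,000 steps; parameter recovery one tempered run of 150,000 steps over 9
rungs (T = 10 time points, N = 20 replicates, noise 2% of signal range);
tube calibration 100 datasets with 25,000-step tempered chains over 6 rungs
(N = 5, noise 5% of range), against a nominal-coverage floor of 88% for the
95% tube (measured ~96%).  Ensembles subsample at most 1000–2000 draws for
tube construction.

Other numerical choices: exponent clipping at |700| in the public model
evaluators (MCMC excursions return finite saturated values, never overflow);
likelihood evaluation once per distinct time point, reused across
replicates; non-finite model output yields log-likelihood `-inf` (point
rejected) rather than an exception; constant chains report ESS 0 with a
warning; HDI ties resolve to the smallest lower bound.

## Known limitations

Single-peak, non-oscillatory responses only.  Tubes are pointwise
percentile bands, not simultaneous (joint highest-posterior-density) bands.
The disjoint-fraction summary is a reporting convention, not a calibrated
test.  The pooled-sigma error model understates uncertainty when noise
varies strongly across time points.  SBML support is an export-only stub;
no SBML import or simulation.
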