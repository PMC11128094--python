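# rtfbayes

Bayesian fitting of **retarded transient functions** (RTFs) to sparse,
highly variable biological time series, with time-continuous **95%
credible-interval tubes** for comparing experimental conditions.

Much biomedical time-series data — perfusion courses, drug elimination
profiles, regeneration curves — comes with few time points, few replicates
and large scatter.  Pointwise hypothesis tests waste power on multiple
testing, and summary statistics such as the area under the curve discard the
dynamics.  `rtfbayes` instead fits a flexible single-peak response model to
all replicates of a condition at once, samples the full parameter posterior
by MCMC, and pushes that uncertainty back into the data space as an ensemble
of trajectories.  Percentile bands over the ensemble give a smooth,
model-informed credible tube per condition; conditions whose tubes separate
are credibly different without any per-time-point testing.

## Model

The RTF is a closed-form curve with a saturating sustained term and a
rise-then-decay transient term,

    f(t) = Asus (1 − e^(−t/t1)) + Atrans (1 − e^(−t/t11)) e^(−t/t2) + p0,

evaluated at a nonlinearly transformed time that can delay the response via
a shift parameter `Tshift` while leaving t = 0 invariant (fixed to −2, an
immediate response, by default).  Measurements are modelled as
`m = f(t) + ε`, `ε ~ N(0, σ²)` with one pooled σ per condition, estimated
jointly.  Priors are wide uniforms placed around the data; the posterior is
sampled with an adaptive Metropolis algorithm, optionally wrapped in
parallel tempering for multimodal targets.  See `docs/methods.md` for the
full account.

## Worked example

Simulate a three-condition pharmacokinetic-style study (control plus two
diet groups with 4/6/6 replicates over 8 time points), fit each condition,
and compare:

```sh
rtfbayes simulate --preset steatosis-like --seed 1 -o data
rtfbayes fit --measurements data/measurements.tsv --config run.yaml -o fits
rtfbayes predict fits/* -o tubes
rtfbayes compare fits/* -o cmp
```

with `run.yaml`:

```yaml
seed: 2
chain_length: 30000
n_chains: 1
temperature_ladder: [1.0, 1.8, 3.24, 5.832, 10.4976, 18.89568]
```

The fit stage logs one line per condition:

```
INFO rtfbayes: fitted control/concentration: 21000 draws, acceptance 0.228, max R-hat 1.049
INFO rtfbayes: fitted diet_2wk/concentration: 21000 draws, acceptance 0.228, max R-hat 1.045
INFO rtfbayes: fitted diet_4wk/concentration: 21000 draws, acceptance 0.228, max R-hat 1.227
```

21000 draws are what remain of a 30000-step tempered chain after 30%
burn-in; acceptance ≈ 0.23 is the adaptive sampler's target.  R-hat near 1
indicates converged chains (the 1.23 for the severe condition flags a
slow-mixing clearance timescale — visible again below in its wide HDI).
`predict` writes one tube table per condition (`time`, `median`, `lower`,
`upper` at 201 grid points) plus an overlay figure, and `compare` reports,
for every pair of conditions, the fraction of the time grid on which the
95% tubes are disjoint:

```
control  vs diet_2wk  disjoint fraction 0.109
control  vs diet_4wk  disjoint fraction 0.816
diet_2wk vs diet_4wk  disjoint fraction 0.806
```

The severe (4-week) condition separates from both others over ~80% of the
observed course — its simulated clearance is genuinely delayed — while
control and the mild condition overlap almost everywhere.  The marginal
95% highest-density interval of the decay timescale tells the same story on
the parameter level: `t2` spans [0.40, 1.35] h for control, [0.48, 1.19] h
for the mild group, and [1.28, 26.2] h for the severe group.  The
disjoint fraction is reported, never auto-thresholded: judging what counts
as "credibly different" stays with the analyst.

The same workflow runs on real data: `fit` reads tab-separated measurement
tables (`observableId`, `simulationConditionId`, `time`, `measurement`,
optional `replicateId`) and optional parameter tables in the PEtab dialect,
fitting one posterior per (condition, observable).

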