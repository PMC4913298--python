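# vetowalk

Time-locked classification of veto-gated random-walk decisions.

A random walker on a small network of states presses a button whenever it
reaches one of the two boundary ("button") states; an independent random
switch — the *veto* — decides whether that press actually produces a light
flash. Trials are the N-step trajectory windows ending at a flash,
time-locked so the flash sits at `t = 0` and labelled "left"/"right" by
which wall flashed. Although the trajectory carries **zero** predictive
information about the eventual flash side (the switch is independent of the
walk), a standard time-resolved SVM classifies the time-locked trials well
above chance long before `t = 0`. The package reproduces this effect and
explains it analytically through time-locked mutual information and the
chain's relaxation timescales.

## What's inside

| module                | contents |
|-----------------------|----------|
| `vetowalk.chains`     | line / complete-graph / custom transition matrices, stationary distribution, t-step powers, eigen-spectrum with relaxation timescales, time reversal, JSON/CSV (de)serialization |
| `vetowalk.trials`     | veto-switch simulation, the literal long-series trial generator, the fast time-reversed generator, average-position curves, CSV/NPZ persistence, the next-step flash-probability worked example |
| `vetowalk.classify`   | leave-one-pair-out linear-SVM accuracy per time point, accuracy time courses, the analytic Bayes-optimal accuracy bound |
| `vetowalk.info`       | Shannon entropy, time-locked distribution/mutual information (exact), unconstrained MI (identically zero), plug-in MI estimator with bias correction, MI time courses |
| `vetowalk.pipeline`   | declarative `ExperimentConfig` (YAML), seeded end-to-end runs writing CSV/JSON bundles, qualitative-claims checker |
| `vetowalk.cli`        | the `vetowalk` command-line tool |

## CLI

```sh
# trials on a 7-state line (n=5 interior states), desk-scale profile
vetowalk simulate --topology line --n 5 --profile desk --seed 1 --out trials.csv

# leave-one-pair-out SVM accuracy time course
vetowalk classify --trials trials.csv --out accuracy.csv

# analytic mutual-information and spectral summaries
vetowalk inform  --topology line --n 5 --N 60 --out mi.csv
vetowalk spectra --topology line --n 5 --n 10 --out spectra.json

# everything at once, then verify the qualitative claims
vetowalk run-all --topology line --n 5 --n 10 --profile desk --seed 1 --out bundle/
vetowalk check bundle/
```

`--profile desk` is k=50, M=20, N=60; `--profile paper` is the nominal
full-scale k=500, M=50, N=100. Custom chains are supported via
`--topology custom --matrix chain.csv` (header-free row-stochastic CSV).

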