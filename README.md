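# gonogo-iiv

Simulation and Bayesian analysis of intraindividual reaction-time
variability in classical and prospective Go/NoGo tasks.

The package implements a complete, self-contained pipeline:

1. **`gonogo_iiv.synthetic_data`** — generates task designs (117-trial
   blocks with balanced digits, no consecutive NoGo/Prospective trials) and
   trial-level datasets with the exact statistical structure the model
   assumes: per-person lognormal AR(1) reaction times with person-varying
   mean (`mu`), lag-1 coefficient (`phi`) and stationary fluctuation
   amplitude (`iSD`), plus commission-error / prospective-omission counts
   from a level-2 linear regression on those parameters.
2. **`gonogo_iiv.preprocessing`** — fixed pipeline per person × block:
   drop the first trial, mask incorrect-trial RTs, trim raw RTs outside
   mean ± 3 SD (single pass), natural-log transform, compute the
   intraindividual SD of the observed log-RTs.
3. **`gonogo_iiv.stationarity`** — gap-aware augmented Dickey–Fuller
   screening (sequential trend → constant → none rule, AIC lag selection,
   MacKinnon p-values) classifying each series as stationary around zero /
   mean / trend or nonstationary, plus the exclusion rule (any
   zero-stationary series excludes the person).
4. **`gonogo_iiv.dsem`** — two-level AR(1) dynamic structural equation
   models fitted by a Gibbs sampler with full missing-data augmentation.
   Named variants `m1`–`m10`: plain single-block models, single-block
   models with error-count regressions, a two-block model with cross-block
   regressions and chained error equations, and a covariate-adjusted
   two-block model. Outputs posterior means, 95% credible intervals,
   standardized estimates (correlations, standardized weights), per-outcome
   R² and the between/within-chain PSR convergence diagnostic.
5. **`gonogo_iiv.reporting`** — error-rate descriptives, paired Wilcoxon
   signed-rank block contrasts (Pratt zeros, continuity correction,
   Bonferroni multiplication), log→ms back-transformation, and
   publication-style CSV tables.

## Command-line usage

```sh
gonogo-iiv simulate --n-persons 87 --seed 1 --out-dir scratch/sim
gonogo-iiv preprocess --trials scratch/sim/trials.csv --out-dir scratch/prep
gonogo-iiv stationarity --clean scratch/prep/clean.csv --out-dir scratch/adf
gonogo-iiv fit --model m5 --clean scratch/prep/clean.csv \
    --persons scratch/sim/persons.csv --exclusions scratch/adf/exclusions.json \
    --iterations 10000 --thin 10 --chains 2 --seed 1 --out-dir scratch/fit_m5
gonogo-iiv report --persons scratch/sim/persons.csv --out-dir scratch/report
```

`simulate` accepts a YAML/JSON `--config` mirroring the
`PopulationParameters` fields (fixed effects, level-2 covariance, error
regression weights).

## Python API sketch

```python
from gonogo_iiv import dsem, preprocessing
from gonogo_iiv.synthetic_data import PopulationParameters, assemble_dataset

ds = assemble_dataset(PopulationParameters(), n_persons=87, seed=1)
clean, isd_table, trim_report = preprocessing.preprocess_dataset(ds.trials)
model = dsem.build_model(dsem.model_spec("m5"), clean, ds.persons)
draws = dsem.gibbs_sample(model, dsem.SamplerConfig(n_chains=2, n_iterations=10_000,
                                                    thinning=10, seed=1))
print(dsem.summarize(draws))              # raw scale
print(dsem.summarize(dsem.standardize(draws)))  # correlations / std weights
```

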