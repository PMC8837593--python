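# mtpa

Multi-timepoint pattern analysis (MTPA) of time-varying functional
connectivity. The package estimates framewise dynamic connectivity between
regional time series with flexible least squares (FLS), trains one
L2-regularised logistic classifier per connection to decode task vs. rest
from the temporal coefficient pattern (or from a single static Pearson
correlation), summarises decoding accuracy at network level with a 70%
threshold and dice overlap, and screens behavioral measures against
per-subject task-identifiability scores with partial correlations.

Because real paired rest/task recordings of this kind are access-restricted,
the package ships a first-class synthetic cohort generator with known
ground-truth time-varying coupling, so every stage is testable offline.

## Layout

| module | role |
| --- | --- |
| `mtpa.simulate` | synthetic cohorts: AR(1) regional signals, planted pairs with exact coupling `w(t)`, HRF/block designs, confounds, behavior tables |
| `mtpa.preprocess` | per-region GLM residualisation (FD, tissue means, HRF-convolved task regressors), standardisation, rest trimming |
| `mtpa.fls` | FLS framewise connectivity: exact O(T) tridiagonal minimiser of the measurement + mu x dynamic cost; static Pearson FC |
| `mtpa.classify` | per-connection logistic decoding with grouped 70/30 split and 10-fold CV, probability estimates |
| `mtpa.networks` | network-block accuracy averaging, thresholding (>= 0.70), dice similarity |
| `mtpa.behavior` | task identifiability, partial correlation, Bonferroni + effect-size screening, PC-partialled variant |
| `mtpa.io` / `mtpa.cli` / `mtpa.pipeline` | TSV/HDF5/JSON formats, CLI, end-to-end orchestration |
| `mtpa.evaluation` | desk-scale benchmark cohorts used by the acceptance report |

## CLI

Every stage is a subcommand of `mtpa`; `run` executes the whole chain on a
simulated cohort and writes a manifest of content-hashed artifacts:

```sh
mtpa run --subjects 40 --regions 20 --frames 120 --seed 1 --out demo_out
```

Stage-by-stage:

```sh
mtpa simulate  --subjects 40 --regions 20 --frames 120 --planted 5 --seed 1 --out raw/
mtpa preprocess --input raw/ --out prep/            # add --raw to skip all regressions
mtpa dfc       --input prep/ --mu 100 --out dfc.h5
mtpa staticfc  --input prep/ --out static.tsv
mtpa classify  --features dfc --dfc dfc.h5 --train-frac 0.7 --folds 10 --seed 1 --out results.json
mtpa summarize --results results.json --networks networks.tsv --threshold 0.70 --out net.json
mtpa dice      --a net_task1.json --b net_task2.json
mtpa behavior  --summary net.json --proba results.proba.tsv --networks networks.tsv \
               --behavior behavior.tsv --covariates age,sex --m 192 --out associations.tsv
```

## Notes

- The threshold convention for "exceeding 70%" is inclusive (`>= 0.70`).
- The FLS regression direction per pair is not canonical; the default uses
  the lower-index region as predictor, `--direction average` averages both.
- Task coupling modulation is mean-preserving by default
  (`CohortSpec.mean_preserve`), so planted effects live purely in the
  temporal pattern and are invisible to time-averaged connectivity.
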