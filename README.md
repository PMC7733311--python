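# gazeclass

Classify viewers of paintings as **art experts vs. laymen** from their eye
fixations.  The pipeline:

1. **ROI discovery** — fit a bivariate Gaussian mixture to all fixation
   positions of an image by expectation-maximization, choose the number of
   clusters with the Bayesian information criterion, and assign each
   fixation to a cluster (maximum-responsibility or responsibility-to-mass
   ratio rule).
2. **Features** — per subject and cluster: fixation count `l_k` and mean
   fixation duration `t_k` (ms), i.e. 2K features per image.
3. **Normalization** — `Z0` (raw), `Z1` (per feature over subjects),
   `Z2` (per subject across all images), `Z3` (per subject within one
   image); count and duration features are standardized separately.
4. **Feature selection** — two-sample t-statistic ranking or sequential
   forward selection (SFS) on leave-one-subject-out accuracy.
5. **Classification** — 3-NN (Euclidean) or soft-margin SVM (linear / RBF /
   sigmoid "MLP" kernel), evaluated by leave-one-subject-out
   cross-validation.
6. **Reporting** — per-cluster group statistics (means, pooled t, p),
   per-image summaries, and picture × normalization accuracy grids.

Since the original recordings are not public, `gazeclass.synth` generates
two-cohort synthetic datasets (23 experts / 21 laymen by default, 14
ground-truth clusters, Poisson fixation counts, lognormal durations) with
configurable group effects, used throughout the test suite.

## CLI

```bash
gazeclass simulate --seed 7 --out data/            # synthetic cohort
gazeclass validate data/fixations.csv              # schema / sanity report
gazeclass cluster data/fixations.csv --image P2 --kmin 2 --kmax 20 \
    --seed 7 --out model.json
gazeclass features data/fixations.csv --model model.json \
    --normalization Z1 --out features.csv
gazeclass select features.csv --method sfs --n 5 --classifier svm-mlp
gazeclass classify features.csv --classifier svm-mlp --select sfs --n 5
gazeclass run --seed 7 --out run_out/              # full pipeline
gazeclass report run_out/                          # accuracy grids
```

Fixation tables are CSV/TSV with header
`subject_id,group,image_id,x,y,duration_ms` (pixels, origin top-left;
milliseconds; `group` ∈ {expert, layman}, case-insensitive on input).

`gazeclass run` accepts a YAML config (`--config cfg.yaml`) mirroring
`gazeclass.pipeline.PipelineConfig`; every stage writes its artifact plus a
manifest with SHA-256 hashes, and reruns at a fixed seed are bit-identical.

Two evaluation modes: `replicate_paper` (default) performs normalization
and feature selection once on all subjects before the outer leave-one-out
loop — this mirrors the original evaluation but leaks selection information
into the test folds; `strict` re-runs both inside every fold.

## Layout

```
src/gazeclass/
  io.py         fixation records, CSV/TSV I/O, validation
  mixture.py    EM Gaussian mixture, BIC selection, assignment, ellipses
  features.py   l_k / t_k extraction and Z0-Z3 normalizations
  selection.py  t-statistic ranking, sequential forward selection
  classify.py   k-NN, kernel SVM, leave-one-subject-out harness
  report.py     group statistics, accuracy grids, aggregation
  synth.py      synthetic cohort generator with ground truth
  datasets.py   published reference tables (worked-example inputs)
  pipeline.py   staged end-to-end runner with manifest
  cli.py        click CLI
```
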