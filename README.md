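# topf

Shared-response PCA feature extraction ("topography-based" loading features),
inter-subject synchrony statistics, and family-aware phenotype prediction for
naturalistic (movie-watching style) ROI time-series cohorts — with a fully
synthetic data generator so every stage is testable end to end against
planted ground truth.

## What it does

- **`topf.synthdata`** — generates cohorts with family structure and balanced
  phenotypes, clip datasets (subjects × ROIs × TRs) with a planted shared
  temporal component whose population synchrony is calibrated exactly to a
  target fraction, loading–phenotype couplings in designated predictive
  ROIs, cross-clip loading correlations, and low-rank semantic annotation
  matrices. All generators are seed-deterministic and expose their ground
  truth.
- **`topf.dataio`** — TSV/CSV readers and writers (one tab-delimited file
  per subject per clip), the initial-volume trimming rule, and YAML run
  configuration.
- **`topf.synchrony`** — per-ROI PCA of z-scored series with subjects as
  variables; the PC1 explained-variance fraction is the inter-subject
  synchrony. Spatial-pattern and PC1-loading similarity between clips,
  per-network summaries.
- **`topf.features`** — loading feature matrices: PCA loadings for training
  subjects, correlation-projected features for held-out subjects, strictly
  leakage-free (training statistics only).
- **`topf.prediction`** — repeated family-aware nested cross-validation
  (ridge / linear-SVM / RBF-SVM / random forest; balanced accuracy or
  Pearson r), subject-level permutation tests, Benjamini–Hochberg FDR, the
  corrected resampled paired t-test, data-length sweeps and clip
  concatenation.
- **`topf.interpret`** — permutation feature importance, predictive-ROI
  sets, Jaccard overlap, cross-clip consistency, sign harmonisation, and
  cross-clip model transfer.
- **`topf.stimulus`** — per-ROI linear/quadratic regressions of prediction
  performance on synchrony with BIC model selection and effect
  classification, film-group contrasts, movie-feature summaries with
  haemodynamic-delay shifting, semantic-label frequencies with non-negative
  matrix factorisation, and validation correlations.
- **`topf.cli`** — a `topf` command gluing the stages into reproducible
  workspace runs.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (calibration,
power, leakage, transfer, BIC and NMF recovery) at their stated tolerances;
the remaining files are per-module unit and property tests.

## CLI

Every stage operates on a workspace directory and records a manifest:

```sh
topf simulate  --out runs/demo --seed 0        # synthetic cohort + clips
topf synchrony --out runs/demo                 # per-ROI synchrony maps
topf predict   --out runs/demo                 # nested-CV prediction
topf syncreg   --out runs/demo                 # synchrony ~ performance fits
topf demo      --out runs/demo --seed 0        # all stages, reduced settings
```

Stages check their dependencies (`topf syncreg` before `topf predict` is an
error). A YAML config (`--config`) can override any simulation or run
parameter; see `topf.cli.DEFAULT_CONFIG` for the schema. The full reduced
demo takes roughly 8–10 minutes on one CPU.

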