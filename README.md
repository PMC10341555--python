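# tugfall

Fall-risk feature analysis for waist-worn accelerometer recordings of the
Timed-Up-and-Go (TUG) test: phase segmentation, a 79-feature vector
(including multiscale sample entropy and permutation entropy), Relief-F
and extra-trees feature ranking, random-forest classification under three
clinical labelings, and intersection of the features used by the best
models. A synthetic-cohort generator makes every stage testable without
any recorded data.

## Package layout

| module | contents |
| --- | --- |
| `tugfall.core` | `Recording`, `PhaseBounds`, `SubjectLabels`, CSV I/O, TUG phase segmentation (annotated or automatic) |
| `tugfall.synth` | `CohortSpec` and the synthetic two-cohort TUG signal generator |
| `tugfall.entropy` | coarse-graining, sample entropy, multiscale-entropy profile and complexity index, ordinal patterns and permutation entropy |
| `tugfall.features` | the canonical 79-feature schema and `extract_features` |
| `tugfall.relieff` | from-scratch Relief-F weighting plus extra-trees impurity importance |
| `tugfall.pipeline` | clinical labeling, resampled selector x label x top-k evaluation grid, best-model selection by mean AUC, repeated-feature intersections, report rendering |

## Data formats

* Recording: headered CSV with columns `time,ML,V,AP` (`time` optional);
  axes are mediolateral, vertical and anterior-posterior.
* Annotations: CSV with `phase,start,end` rows for the five phases
  `sist, walk_out, turn, walk_back, stsi` (0-based half-open sample
  intervals).
* Cohort: one recording + one annotations CSV per subject, a
  `labels.csv` (`subject_id, tug_seconds, sfbbs_score`, derived labels)
  and a `manifest.json`.
* Feature schema: `src/tugfall/data/feature_schema.yaml` (also via
  `tugfall schema --out schema.yaml`).

Clinical labels: TUG criterion flags subjects slower than 12.47 s, SFBBS
criterion flags scores below 23, and the multifactor label is their union.

## CLI

```sh
tugfall synth --preset community --n 65 --seed 1 --out cohort/
tugfall features --in cohort/ --out features.csv
tugfall rank --features features.csv --labels cohort/labels.csv \
             --criterion tug --selector relieff --out ranking.csv
tugfall pipeline run --features features.csv --labels cohort/labels.csv \
                     --config cfg.yaml --seed 1 --out report/
tugfall pipeline compare --report-a a/ --report-b b/ --out joint.json
tugfall entropy --in cohort/sub_000_recording.csv --fs 30 --axis V --measure pe
```

`cfg.yaml` mirrors `CvConfig` (`n_splits`, `test_fraction`, `k_grid`,
`rf_trees`, ...); `synth --config` accepts `CohortSpec` fields.

## Notes on conventions

* Sample entropy: Chebyshev distance, self-matches excluded; the MSE
  tolerance is `r x SD` of the original series, fixed across scales;
  coarse-graining averages non-overlapping blocks.
* Ordinal patterns are rank vectors with ties broken by temporal order;
  permutation entropy is reported in bits.
* Walk-block features use both walking bouts concatenated (turn
  excluded) and a configurable 3 m one-way walkway; CVs are in percent;
  SDs are population SDs.
* Feature selection always runs inside the training portion of each
  resampling split; missing values are imputed with training-fold
  medians.
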