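# ibap

Individual brain abnormality pattern (IBAP) analysis for parcellated cortical
morphometry, exercised end-to-end on a synthetic multi-cohort generator with
recorded ground truth.

The pipeline covers:

- **Normative charts** — per-region, per-sex sinh-arcsinh distributional
  charts (location quadratic in log-age, log-scale linear in log-age,
  constant skewness) fitted by penalized maximum likelihood on term-born
  subjects, with additive per-study location offsets adapted on term data
  only.  Deviation scores are chart CDF values in (0, 1); scores < 0.05 are
  infranormal, > 0.95 supranormal (strict thresholds).
- **Heterogeneity** — per-region group-average regression (OLS with age/sex
  covariates, BH-FDR), extranormal overlap percentages, and cross-subject
  Spearman similarity of binarized deviation profiles.
- **Consistency** — extranormal-count vs gestational-age correlations with
  bootstrap CIs, GA-threshold subgrouping, two-timepoint persistence, and
  per-region ICC(3,1).
- **Cell maps** — scaled-robust-sigmoid gene normalization and marker-set
  mean aggregation into 8 cell-type abundance maps; hemisphere collapsing.
- **Spatial nulls** — spin tests: uniform SO(3) rotations of parcel
  centroids with one-to-one minimum-cost matching, shared permutation
  schedules, two-sided p with +1 smoothing; subject x cell-type spatial
  correlations and their association with GA.
- **Plasticity/outcomes** — PC1 of the deviation matrix, environment and
  cognition correlations, and the GA x SES moderation regression with
  conditional effects and bootstrap CIs.
- **Synthetic cohort** — a generator that simulates all of the above
  structure (term/preterm groups, GA-dependent deviation counts,
  cell-map-aligned placement, two-timepoint persistence, SES x GA
  moderation, cognition coupling) with every parameter recorded for
  parameter-recovery testing.

## CLI

```sh
ibap simulate --seed 7 --out sim/                # synthetic bundle (CSV/JSON)
ibap fit-normative --morphometry sim/morphometry.csv --out chart.json
ibap adapt-offset --chart chart.json --morphometry sim/morphometry.csv \
    --study synth --out chart.json
ibap score --chart chart.json --morphometry sim/morphometry.csv --out profiles.csv
ibap heterogeneity --profiles profiles.csv --morphometry sim/morphometry.csv --out het/
ibap consistency  --profiles profiles.csv --morphometry sim/morphometry.csv --out con/
ibap cellmaps --expression sim/expression.csv --markers sim/marker_sets.json --out maps.csv
ibap spin --centroids sim/centroids.csv --map-a a.csv --map-b b.csv --n-spins 1000 --seed 11
ibap plasticity --profiles profiles.csv --morphometry sim/morphometry.csv --out pla/
ibap run --config run.yaml --seed 7              # full pipeline + manifest
```

`ibap run` executes fit -> adapt -> score -> heterogeneity -> consistency ->
cellmaps -> spin -> plasticity (simulating inputs when none are configured)
and writes `manifest.json` with per-stage seeds and sha256 checksums of every
output; rerunning with the same config and seed reproduces all outputs
bit-exactly.

## Data formats

All interchange formats are plain text: tidy long CSV for morphometry
(`subject_id, study, timepoint, age, age_unit, sex, group, ga_weeks, ses,
piri, cognition, region, measure, value`), gene x region CSV for expression,
JSON for marker sets, charts, ground truth and manifests, and a
`region, x, y, z` CSV for unit-sphere parcel centroids.
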