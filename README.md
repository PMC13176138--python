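# brainaging

Analysis pipeline linking brain-aging imaging markers to cognitive and
motor performance in population cohort tables: marker estimation,
partial least squares (PLS) correlation with permutation and bootstrap
inference, and bootstrap mediation of vascular-risk effects — plus a
synthetic cohort generator with planted ground truth so every stage is
testable as a parameter-recovery problem.

## What it does

- **cohort I/O** (`brainaging.cohort`) — read/write wide per-subject
  CSV/TSV tables (demographics, vascular risk factors, region-level
  morphometry, WMH volume, skeletonized-MD values or precomputed PSMD,
  raw test scores), with schema mapping, validation and rule-based
  subject exclusion (SD-outlier screens, boolean flags) reconciled in
  an `ExclusionReport`.
- **synthetic cohorts** (`brainaging.synth`) — generate cohorts whose
  marginals match published population moments and which carry a single
  latent brain-aging deviation coupling imaging to behavior plus
  risk → brain-aging → performance mediation paths; the realized
  latents are returned as `GroundTruth`.
- **aging markers** (`brainaging.markers`) — relative brain age
  (sex-stratified 5-fold out-of-fold OLS age prediction followed by an
  expected-age regression, orthogonal to chronological age by
  construction), log WMH load (log of the WMH/ICV percentage), PSMD
  (p95 − p5 of skeletonized mean diffusivity), and gap variants of the
  scalar markers.
- **phenotype prep** (`brainaging.prep`) — invert-and-log transforms
  for timed tests, z-scored domain scores, height-normalized grip
  strength, confound residualization, Benjamini–Hochberg FDR.
- **PLS correlation** (`brainaging.pls`) — SVD of the cross-covariance
  of the two blocks; covariance explained, permutation p-values
  (row-shuffling the imaging block), bootstrap ratios and loading CIs,
  subject scores, cross-validated score correlation, and per-marker
  adjusted regressions.
- **mediation** (`brainaging.mediation`) — single-mediator models with
  covariates; standardized paths a, b, c, c′, indirect effect ab with
  percentile-bootstrap CI, per-path-family FDR, and partial/full/none
  classification.
- **pipeline** (`brainaging.pipeline`, `brainaging.cli`) — one-command
  orchestration with per-stage seeds derived from a master seed and a
  JSON manifest.

## CLI

```sh
# simulate a cohort (cohort.csv + ground_truth.csv + resolved config)
brainaging simulate --n 2000 --seed 1 --out out/sim

# compute the marker panel
brainaging markers out/sim/cohort.csv --out out/panel.csv --seed 1

# full pipeline: simulate -> exclusions -> markers -> prep -> PLS -> mediation
brainaging run-all --n 2000 --seed 1 --out out/full
cat out/full/manifest.json
```

Other subcommands: `prep`, `pls`, `mediate`, `report`; see
`brainaging --help`.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit and property tests per module (hypothesis for
the invariants) and `tests/test_acceptance.py` with the calibration
suites (permutation type-I error, bootstrap CI coverage, full-pipeline
parameter recovery). The full run takes a few minutes on one CPU.

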