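# fmripattern

Simulation and analysis of block-design task fMRI with a focus on the
dissociation between *mean activation level* and *multi-voxel pattern*
effects in shared regions of interest.

The package provides, end to end:

- **`fmripattern.synth`** — synthetic BOLD cohorts: a two-run block design
  (TR = 2 s; per run, twelve task blocks of 2 s cue + six trials of 1 s
  fixation + 1.5 s stimulus for three conditions NA/NV/NR, interleaved
  with twelve 10 s rest blocks → 162 volumes/run, 324 total), spherical
  parcel atlases, and 4D volume series with region-specific amplitude and
  zero-mean pattern effects plus white + AR(1) + cosine-drift +
  motion-leakage noise. Ground truth is returned for recovery oracles.
- **`fmripattern.glm`** — subject-level GLM: double-gamma HRF, microtime
  boxcar convolution (a code path shared with the simulator), Gaussian
  smoothing, discrete-cosine high-pass nuisance columns, motion
  regressors, pooled two-pass AR(1) prewhitening, and contrast t maps.
- **`fmripattern.group`** — one-sample group t maps, cluster-level FWE by
  sign-flip permutation of maximum cluster extent (26-connectivity by
  default), conjunction masks, and shared-ROI segmentation by atlas label.
- **`fmripattern.roimean`** — ROI mean contrast effects, paired t tests,
  Bonferroni adjustment, and the behavioral recall comparison.
- **`fmripattern.mvpa`** — ROI voxels × time extraction, two-step
  (temporal-then-spatial) z-normalization, TR-level sample labeling with a
  hemodynamic shift, leave-one-block-pair-out 8-fold linear SVM
  classification, and the group test of accuracy against 50% chance.
- **`fmripattern.norming`** — stimulus norming: action-consistency ratios
  (largest / second-largest response count, with an "unanimous" sentinel)
  and quota-based stimulus selection.
- **`fmripattern.pipeline` / CLI** — stagewise orchestration with JSON
  config, provenance (config hash, seed, version) and TSV/JSON/NIfTI
  outputs.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the headline criteria (design arithmetic,
null chance level, type-I calibration of both the group accuracy test and
cluster FWE, amplitude-vs-pattern dissociation recovery, oracle
equivalences, structural invariants). The full suite runs in a few
minutes on one CPU.

## CLI

Every stage runs standalone on the previous stage's outputs; `run`
executes them all. Chained stages are byte-identical to the monolithic
run.

```sh
fmripattern run --config examples/demo_config.json --out report/
fmripattern simulate --config examples/demo_config.json --out report/
fmripattern fit      --config examples/demo_config.json --out report/
fmripattern group    --config examples/demo_config.json --out report/
fmripattern rois     --config examples/demo_config.json --out report/
fmripattern meanlevel --config examples/demo_config.json --out report/
fmripattern mvpa     --config examples/demo_config.json --out report/
fmripattern norming --ratings ratings.csv --quota hold=8 --quota pinch=8 \
    --quota press=8 --out selection.tsv
```

The report directory contains `cohort/` (NIfTI volumes, events/motion
TSVs, ground truth), `firstlevel/` (per-subject contrast effect maps),
`group/` (t maps, FWE-thresholded masks, cluster report), `rois/`
(conjunction mask + ROI manifest), `meanlevel/mean_level.tsv` and
`mvpa/mvpa.tsv`.

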