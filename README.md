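# taskbold

Simulation and analysis of trial-entrained, stimulus-independent ("task-related")
BOLD activity in early visual cortex.

The package provides, as importable modules and a `taskbold` command line:

- **`taskbold.synth`** — a generative model of periodic-task fMRI sessions with
  full ground truth: a double-gamma impulse response convolved with per-trial
  impulses on a fine time grid, three dissociable noise sources (per-voxel 1/f
  noise, sigmoid-transformed per-trial amplitude jitter, gaussian per-trial
  onset jitter), a foveal sign-inverted voxel subpopulation, a globally shared
  heart-rate-driven component, and tonic+phasic pupil traces with blinks.
- **`taskbold.preprocess`** — first-trial discard, mean-normalization,
  z-scoring, global-signal regression, concatenation and trial segmentation.
- **`taskbold.metrics`** — per-voxel cosine fits (coherence + phase maps),
  trial averaging, std- and Fourier-based response amplitude/latency, and
  exponential eccentricity binning.
- **`taskbold.variability`** — time-point, amplitude, and temporal (circular
  std of per-trial Fourier phase) trial-to-trial variability.
- **`taskbold.permutation`** — group-level label-permutation tests.
- **`taskbold.simstudy`** — the noise-source sweep study (independent vs
  amplitude vs temporal noise signatures) and a signature classifier.
- **`taskbold.physio`** — instantaneous heart rate from pulse-oximeter peaks,
  trial-locked heart-rate responses, FIR pulse-to-BOLD kernels.
- **`taskbold.pupil`** — blink removal (±3 samples), trial segmentation, tonic
  and phasic pupil quantification.
- **`taskbold.fieldmap`** — gaussian-pRF-weighted projection of complex voxel
  responses into the visual field.
- **`taskbold.pipeline`** — end-to-end orchestration with a single fan-out seed.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (protocol arithmetic,
binning, pRF sigma, foveal phase inversion, noise-signature dissociation,
estimator oracles against brute-force/closed-form references, permutation
calibration, parameter recovery, and the end-to-end reward sign pattern).

## CLI

```sh
taskbold simulate --out session_dir --seed 1 --pupil      # synthetic bundle
taskbold preprocess --in session_dir --out preproc_dir    # [--no-gsr --no-zscore]
taskbold metrics --in session_dir --bins 12 --range 0.2:70 --out tables
taskbold variability --in session_dir --out variability.tsv
taskbold permtest --in session_dir --stat amp_std --n-perm 10000 --sided two --seed 1
taskbold physio --in session_dir --max-lag 30 --out physio_tables
taskbold pupil --in session_dir --out pupil.tsv
taskbold fieldmap --in tables/voxel_cosine.tsv --grid 121 --extent 12 --out map
taskbold simstudy --irf A --noise all --out sweeps
taskbold run --config pipeline.toml --out report_dir
```

Session bundles are one directory per session: run matrices as flat binary
arrays with JSON text sidecars, voxel metadata / ground truth / physio / pupil
as tab-separated text.

A minimal `pipeline.toml` for `taskbold run`:

```toml
seed = 1
n_participants = 4
n_voxels = 24
runs_per_condition = 2
n_perm = 1000
include_physio = true
include_pupil = true
```

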