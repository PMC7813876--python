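# trimodal

Analysis pipeline for trimodal resting-state brain data: EEG
microstates and their cortical source networks, PET receptor/metabolism
quantification, and voxel-wise resting-state fMRI measures — plus the
statistics that compare the three modalities voxel by voxel. A
synthetic-data generator with known ground truth makes every stage
testable without access to subject data.

Intended for researchers who work with simultaneous or co-registered
EEG/PET/fMRI resting-state acquisitions and want a small, fully tested,
scriptable implementation of the standard measures.

## What it computes

- **EEG microstates** — global field power (GFP, the per-sample spatial
  SD across channels), topographies at GFP peaks, modified
  atomize-and-agglomerate hierarchical clustering (AAHC) into four maps,
  sorting to the canonical classes A–D, and polarity-invariant
  backfitting into a label sequence with coverage and dwell statistics.
- **Source imaging** — the sLORETA standardized minimum-norm inverse
  (zero localisation error on noiseless point sources) and TESS network
  identification: per-source GLM on microstate indicator + GFP
  regressors, Benjamini–Hochberg FDR at q = 0.01, Z-scored significant
  betas, and ≥ 50 %-of-subjects group masks.
- **PET** — duration-weighted frame averaging,
  `SUV = C /(dose/weight)` in g/ml, reference-region binding potential
  `BP_ND = (C_T − C_REF)/C_REF`, and FWHM-parameterised Gaussian
  smoothing.
- **fMRI** — nuisance regression (motion, WM/CSF, trends), zero-phase
  0.01–0.08 Hz band-pass, ReHo (Kendall's W over 27-voxel
  neighbourhoods), degree centrality (r > 0.25), and fALFF
  (0.01–0.1 Hz amplitude fraction).
- **Intermodal statistics** — Z standardisation over grey-matter masks
  (strict GM probability > 0.5), regional Pearson correlations with
  max-statistic permutation FWER control, stepdown (Holm) Dunn rank
  tests, and one-sample Kolmogorov–Smirnov normality checks.

See `docs/methods.md` for the formulas, defaults, and design choices.

## Worked example

```python
import numpy as np
from trimodal.synth import make_templates, simulate_eeg
from trimodal.microstates import segment, spatial_correlation

templates, truth = make_templates(32)          # canonical maps A-D
rec, states = simulate_eeg(truth, duration_s=60.0, fs=125.0, snr=4.0, seed=11)
seg = segment(rec, templates, k=4)             # GFP peaks -> AAHC -> sort -> backfit

corr = spatial_correlation(seg.maps.maps, templates.maps)
print(np.round(np.abs(np.diag(corr)), 3))      # [1. 1. 1. 1.]
print(round((seg.labels == states).mean(), 3)) # 0.955
print(round(seg.gev, 3))                       # 0.858
for k in "ABCD":
    s = seg.stats[k]
    print(k, round(s["coverage"], 3), round(s["mean_duration_ms"], 1))
# A 0.248 70.6
# B 0.248 65.9
# C 0.267 78.8
# D 0.237 71.7
```

Each recovered map correlates perfectly (to 3 decimals) with its
generating template, 95.5 % of samples receive the generating state
label, and the four maps explain 85.8 % of the GFP-weighted variance.
Coverages are near-uniform by construction (symmetric transition
matrix) and mean dwell times sit below the generator's 100 ms because
noise occasionally splits a dwell.

The same stages are exposed as a CLI:

```bash
trimodal simulate --kind eeg --seed 1 --out data/
trimodal microstates --in data/eeg.tsv --k 4 --out seg.json
trimodal pet --frames f0.nii --frames f1.nii --frames f2.nii \
    --mode bpnd --ref-mask cereb.nii --out bpnd.nii
trimodal fmri --in bold.nii --measure reho --out reho.nii
trimodal run --out demo/        # full pipeline + manifest
```

`trimodal run` executes the bundled demo configuration end to end and
writes a manifest (parameters, derived seeds, package versions, SHA-256
of every output); re-running the same config reproduces every file
bit-for-bit.

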