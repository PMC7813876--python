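# Methods

`trimodal` implements a complete desk-scale analysis chain for trimodal
resting-state data — EEG microstates with source-network localisation,
PET parametric quantification, and voxel-wise fMRI measures — together
with the intermodal statistics that relate the three modalities, and a
synthetic-data generator that provides ground truth for every stage.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## EEG microstates

Resting EEG alternates between a small number of quasi-stable scalp
topographies ("microstates", typically ~80–120 ms long), conventionally
reduced to four classes: A (right-frontal / left-posterior axis),
B (left-frontal / right-posterior), C (midline frontal–occipital), and
D (midline frontal).

**GFP.** Global field power at sample *t* is the spatial standard
deviation across the *C* channels,
`GFP(t) = sqrt( (1/C) Σ_c (v_c(t) − v̄(t))² )`, computed on
average-referenced data. Topographies are most stable at GFP maxima, so
clustering uses only the maps at strict local GFP maxima
(`find_gfp_peaks`, default minimum separation 10 ms — comfortably below
the ~80–120 ms stability scale, so no genuine peak is suppressed).

**Clustering.** `aahc_cluster` implements the modified
atomize-and-agglomerate hierarchical clustering: every peak map starts
as a singleton cluster; at each step the cluster contributing least
global explained variance (GEV) is dissolved and its members reassigned
to the cluster with the highest polarity-invariant spatial correlation;
cluster centroids are the first principal direction of their member
maps. GEV weights each peak map by its squared GFP:
`GEV = Σ_i gfp_i² corr(x_i, c_{a(i)})² / Σ_i gfp_i²`. Ties resolve to
the lowest index, making the procedure deterministic.

**Sorting and backfitting.** The four cluster maps are assigned to the
canonical classes by the permutation maximising total |spatial
correlation| (solved exactly via the Hungarian algorithm) and
polarity-aligned to their templates. `backfit` labels each sample with
the map of highest |correlation|; zero-variance samples stay unassigned.
A `peaks_only` mode restricts the competition to GFP peaks and extends
labels by nearest-peak interpolation — both modes are provided because
segmentation practice varies on this point.

**Built-in templates.** Canonical template maps are synthesised by
placing Gaussian poles at the four class orientations on the scalp disc,
average-referencing, and orthonormalising. We use Löwdin (symmetric)
orthonormalisation rather than Gram–Schmidt: it treats the four maps
symmetrically, so mirroring the electrode layout left–right exactly
swaps classes A and B, as their definitions demand; Gram–Schmidt is
order-dependent and breaks that symmetry. User-supplied templates are
accepted anywhere built-ins are used.

## Source imaging

**sLORETA.** With leadfield `K` (average-referenced, scalar sources)
the minimum-norm inverse is `T = Kᵀ (K Kᵀ + α H)⁺` (`H` the centering
matrix, `⁺` the pseudo-inverse). sLORETA standardises the estimate by
the model resolution matrix `R = T K`: the reported activity is
`ŝ_j = (T x)_j / sqrt(R_jj)`. For noiseless point sources this has
exactly zero localisation error — the test suite sweeps every source of
a toy leadfield. The default `α` is scale-free:
`1e−4 · tr(K Kᵀ)/C`. Sources are scalar (fixed orientation); the
3-component dipole case reduces to this by taking component norms.

**TESS.** Each source time series is regressed on a microstate
indicator and the GFP. The indicators of a complete 4-state labelling
sum to one and are collinear with an intercept, so a single design with
all indicators is rank-deficient by construction; the GLM is therefore
fit once per state with design `[indicator_k, GFP, 1]`. Per state, the
indicator coefficient's two-sided t p-values are adjusted across sources
with Benjamini–Hochberg; the network mask keeps q ≤ 0.01 (default), and
significant betas are Z-scored within the significant set. Group masks
keep sources with z > 0 in at least 50% of subjects (inclusive
boundary: "at least").

FDR p-values are computed per subject and the 50% rule is applied to
the per-subject Z-maps afterwards; this follows the stated order of the
procedure (subject-level inference, then group mask).

## PET quantification

Frames are averaged voxel-wise with duration weights
(`frame_average`). `SUV = C / (dose / weight)` in g/ml — with C in
kBq/ml, dose in MBq and weight in kg this is
`C · weight / dose` (5 kBq/ml at 200 MBq / 80 kg gives exactly
2.0 g/ml). `BP_ND = (C_T − C_REF) / C_REF` with `C_REF` the mean of the
duration-weighted average over the reference mask; the reference region
stands in for tissue with negligible specific binding (cerebellum or
pons in practice). Averaging precedes the ratio, matching the stated
order of operations. BP_ND is dimensionless and invariant to global
rescaling of the frames.

Gaussian smoothing (default 2.5 mm for PET maps, 3 mm for Z maps)
interprets "kernel size" as FWHM (`σ = FWHM / 2√(2 ln 2)`), the
neuroimaging convention; a flag switches to σ. Boundaries are handled
by renormalised truncation (smoothing the indicator and dividing), so a
constant volume stays exactly constant; a periodic mode is available
and preserves the volume mean to machine precision.

## fMRI measures

Nuisance regression projects each voxel on the standard design — six
motion parameters, WM and CSF mean signals, and constant/linear/
quadratic trends — and keeps the residual. Band-pass filtering
(0.01–0.08 Hz default, zero-phase Butterworth) precedes ReHo and DC;
fALFF uses unfiltered (trend-removed) data, following the stated
ordering of the original pipeline.

**ReHo** is Kendall's coefficient of concordance over the 27-voxel
cubic neighbourhood: with rank sums `R_t` across the K neighbourhood
series, `W = 12 Σ_t (R_t − R̄)² / (K²(n³−n) − K ΣT)`, midranks for ties
and the standard tie correction `T = Σ(t³−t)` per series.
Neighbourhoods shrink to the in-mask subset at mask edges (K adjusted)
rather than zero-padding, which would inject artificial rank structure.

**DC** counts, per voxel, the in-mask voxels whose Pearson correlation
exceeds 0.25 (strict, positive correlations only — binary degree; a
weighted variant is available behind a flag). Zero-variance voxels are
treated as uncorrelated and logged.

**fALFF** is the ratio of summed amplitude-spectrum values
(square-root periodogram) inside 0.01–0.1 Hz to the sum over all
positive frequencies. For white noise its expectation is the in-band
fraction of the positive frequency grid; for an on-bin sinusoid it is 1.

All three are invariant to per-voxel affine rescaling of the time
series (ranks and correlations ignore gain and offset; fALFF removes
the mean and cancels gain in the ratio).

## Intermodal statistics

Maps are standardised to Z over an analysis mask
(`z = (x − mean)/SD`, population SD — the standardisation is
descriptive; test statistics use sample SDs), restricted to grey matter
with the strict rule `gm_prob > 0.5`, and smoothed (3 mm FWHM).

**Permutation FWER.** For a family of regional Pearson correlations,
the null is built by permuting the voxel order of one map in each pair;
per permutation the maximum |r| across the family is recorded, and
`p_adj = (1 + #{max ≥ |r_obs|}) / (n_perm + 1)` (the +1 makes the
estimate never exactly zero, standard permutation practice). This
scheme assumes exchangeable voxels: spatial autocorrelation violates it
and inflates false positives, which is why Z maps should be interpreted
with that caveat; a contiguous-block permutation mode (`block > 1`)
blunts the effect. The default family size and 10⁵ permutations match
routine use; tests calibrate the procedure at 2 000 permutations.

**Dunn's stepdown test.** All observations are jointly midranked;
pairwise `z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − ΣT/(12(N−1)))(1/n_i +
1/n_j)]`; two-sided normal p-values are adjusted by the Holm stepdown
ordering over the k(k−1)/2 comparisons. "Stepdown" admits several
formulations; Holm over the pairwise family is the one implemented, and
the z statistics are cross-checked against a brute-force rank oracle.

**KS normality.** D is the supremum distance between the empirical CDF
and a normal fitted with the sample's own mean and SD; p comes from the
asymptotic Kolmogorov distribution. With estimated parameters this p is
conservative toward non-rejection (the Lilliefors effect); it is
reported as defined.

## Synthetic data

The generator plants exactly the structure each downstream measure
detects, with every output a pure function of its seed:

- **EEG**: a 4-state Markov chain (mean dwell 100 ms) drives the
  templates; each dwell is enveloped by a half-wave sine so GFP peaks
  fall mid-state, where the topography is cleanest. Sensor noise is
  i.i.d. Gaussian scaled to a total signal-power/noise-power ratio
  (`snr`, default 4). In the noiseless limit backfitting reproduces the
  generated state sequence exactly.
- **BOLD**: white Gaussian noise (flat spectrum — the correct null for
  fALFF's band-fraction expectation) with three planted structures:
  a contiguous block sharing a band-limited latent signal (ReHo), a hub
  voxel coupled to ~30% of background voxels with pairwise r ≈ 0.4
  against a partner–partner r ≈ 0.17, i.e. above vs below the 0.25 DC
  threshold (DC), and voxels carrying large 0.02–0.07 Hz sinusoids
  (fALFF). Default TR 2.2 s.
- **PET**: frames with target concentration `c_t[f]` inside a target
  box and `c_ref[f]` elsewhere (so the noiseless BP_ND map is exactly
  `(c̄_t − c̄_ref)/c̄_ref` in the target and 0 outside), 2-minute
  durations, optional Gaussian noise.
- **Atlas/leadfield**: four disjoint box regions standing in for DMN,
  SN, ECN and SMN; a GM probability map high inside the regions; a
  leadfield coupling dome-mounted channels to GM voxel sources with an
  inverse-square falloff.

What the generator does **not** emulate: hemodynamic response shapes,
spatial autocorrelation of real BOLD noise, MR gradient and
ballistocardiogram artifacts in EEG, radioactive decay, scanner drift,
and anatomical realism of the head model. Passing tests therefore
demonstrate correctness of the estimators and calibration of the
inferential procedures under their stated assumptions — not robustness
to every artifact of acquired data.

The simulated EEG already lives inside the 2–20 Hz analysis band;
`prepare_eeg` (filter + average reference + resample to 125 Hz) is
exercised on its own contract and in the demo pipeline, but recovery
benchmarks segment the generator output directly, since re-filtering
in-band synthetic data only smears state boundaries without modelling
any real artifact.

## Problem sizes and numerics

Default grids are ≤ 20³ voxels and recordings ≤ 60 s so the full
pipeline and its calibration studies run in well under a minute on one
core; Monte-Carlo studies use 200 replicates (FDR) and 500 replicates ×
2 000 permutations (FWER), sizes at which the Monte-Carlo standard
error is small against the quantities checked. Numerical choices:
population SD in GFP and Z maps, sample SD in test statistics;
correlation ties broken toward the lowest index; zero-variance samples
and voxels excluded (never NaN-propagated); permutation p-values use
the +1 correction; Gaussian kernels truncate at 6σ.

## Known limitations

- Voxel-order permutation ignores spatial autocorrelation (see above).
- The KS p-value is asymptotic and parameter-estimated (conservative).
- Scalar sources only; no realistic head model — the leadfield is an
  input, and anatomical registration is out of scope (inputs must share
  a grid; nothing is resampled).
- No EEG artifact correction: the segmentation assumes cleaned data.
- EDF output is 16-bit by format; round-trips are exact only to the
  per-channel quantisation step.
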