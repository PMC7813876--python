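# Demo configuration for the end-to-end pipeline.
# Sizes are desk-scale: the whole run takes well under a minute.
seed: 7
eeg:
  n_channels: 32
  duration_s: 40.0
  fs: 125.0
  snr: 4.0
  band: [2.0, 20.0]
microstates:
  k: 4
  min_separation_ms: 10.0
  peaks_only: false
tess:
  q: 0.01
  min_fraction: 0.5
bold:
  shape: [12, 12, 12]
  n_vols: 120
  tr_s: 2.2
bandpass:
  low: 0.01
  high: 0.08
fmri:
  falff_band: [0.01, 0.1]
  dc_threshold: 0.25
  neighbourhood: 27
pet:
  n_frames: 3
  noise_sd: 0.2
  smooth_fwhm_mm: 2.5
atlas:
  gm_threshold: 0.5
stats:
  n_perm: 2000
  alpha: 0.05
  smooth_fwhm_mm: 3.0
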