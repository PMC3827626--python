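# alphabold

Source-localization-driven simultaneous EEG-fMRI integration as a tested,
desk-scale pipeline:

1. **`alphabold.synth`** — synthetic multimodal sessions with known ground
   truth: a blocked audiovisual paradigm (default full design: 32 blocks of
   12 trials, 96 auditory / 96 visual / 192 audiovisual stimuli, 19–21 s
   jittered pauses), occipital alpha generators (10.5 Hz) with event-locked
   suppression 200–400 ms post-stimulus, a frontal alpha increase for
   emotionally congruent trials, MR gradient artifacts exactly periodic at
   TR = 2 s (34 slice bursts), ballistocardiogram artifacts locked to a
   synthetic ECG, eye blinks, movement spikes, behaviour, and BOLD voxels
   negatively coupled to the trial-alpha regressor.
2. **`alphabold.clean`** — in-scanner EEG cleaning: sliding-template
   gradient subtraction, 70 Hz zero-phase IIR low-pass (order 8 ≙ 48
   dB/octave), downsampling 500 → 250 Hz, template-matched R-peak detection
   plus BCG subtraction, ±300 µV amplitude rejection, 63-component ICA with
   automatic artifact-component classification, average reference with
   spherical-spline synthesis of the AFz/FCz pseudo-electrodes (65-channel
   montage). Stage order is enforced.
3. **`alphabold.timefreq`** — stimulus-locked segmentation (−2000…+1000 ms,
   exclusion rules logged by reason), complex Morlet induced power
   (c = f0/σf = 4.2, so ±2.5 Hz at 10.5 Hz), baseline correction
   (−1500…−500 ms), topographic alpha statistics, and short-time FFT band
   power (500 ms windows, 100 ms hop → 80 % overlap).
4. **`alphabold.inverse`** — four-shell concentric-sphere lead fields
   (Legendre series with boundary matching), fiducial-based electrode
   co-registration, 65×65 pre-stimulus noise covariance, depth-weighted
   minimum-norm inverse with noise-based normalization
   (λ² = tr(LRLᵀ)/(tr(C)·SNR²), default SNR 5), and across-trial source
   contrast maps (audiovisual vs baseline; CON > INC).
5. **`alphabold.coupling`** — patch-of-interest definition from source
   maps, single-trial POI alpha values (inverse-weighted electrodes),
   trial scoring/confound assignment, double-gamma HRF regressors
   (events-only, zero elsewhere), minimal BOLD preprocessing (discard 2
   volumes, 4 mm FWHM smoothing, linear + DCT high-pass), per-voxel GLM,
   and Monte-Carlo cluster-extent thresholding.
6. **`alphabold.io_core`** — containers plus BrainVision (.vhdr/.vmrk/.eeg,
   binary IEEE float32 multiplexed dialect), NIfTI-1, TSV stimulus-log and
   electrode-TSV I/O, FFT resampling and IIR filtering.

## CLI

```bash
alphabold --seed 1 --out-dir out simulate            # session: EEG triplet, log, BOLD, truth JSON
alphabold --seed 1 --out-dir out clean out/session.vhdr
alphabold --out-dir out tfr out/cleaned.vhdr out/session_log.tsv
alphabold --out-dir out inverse out/cleaned.vhdr out/session_log.tsv --sources-per-hemi 400
alphabold --seed 1 --out-dir out couple out/session_bold.nii.gz regressor.tsv
alphabold report out/session_truth.json
```

Global flags: `--config` (YAML with per-subcommand defaults), `--seed`,
`--log-level`, `--out-dir`. The default `simulate` session is a reduced
4-block layout for desk-scale runtimes; `--full-paradigm` emits the full
32-block design.

### Stimulus-log schema (TSV)

`onset_s  kind  modality  visual_emotion  auditory_emotion  response_code
uncertainty_ms` — rows with presentation uncertainty above 10 ms are
flagged (not dropped) so downstream exclusion stays explicit.

## Notes

- All randomness is seeded; generators are bit-reproducible.
- Simulated alpha carriers carry a random-walk phase (≈1 Hz linewidth):
  a phase-locked 10.5 Hz carrier would be exactly TR-periodic and the
  gradient template subtraction would cancel it.
- `scratch/` is for throwaway output and is not part of the package.
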