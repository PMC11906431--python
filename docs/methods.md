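# Methods

## Generative model

**VEP kernel.** The flash-evoked response is a sum of five unit-peak
Gaussians, one per component, at the canonical latencies 30 (N1), 100
(P1), 200 (N2), 300 (P2) and 400 ms (N3), with signed amplitudes −80,
+60, −100, +50, −40 µV and widths (Gaussian σ) 8, 22, 30, 30, 30 ms. The
latencies are the anatomy of the paradigm; amplitudes and widths are
generator configuration, not biological truth. The widths were chosen so
that neighbouring components do not interact at the windowed extrema: with
σ ≤ 30 ms the leak of one Gaussian into its neighbour's window is below
0.4% of peak, so the peak detector recovers every planted latency to the
sample and every amplitude to <2%. Wider late components (e.g. σ = 50–60
ms) look plausible but shift the summed-kernel N2 minimum by ~4 ms and
bias P2 by tens of percent — they would make the detector appear broken
when it is the stimulus that moved. The kernel decays below 1% of its
maximum well before 600 ms.

**Two-phase gain.** A potentiated component's gain is

    g(d, i, pathway) = 1 + s·[(C_pathway − 1)(1 − e^{−(d−1)/τ_d})
                             + (R − 1)(1 − e^{−i/τ_i})]

with defaults C_contra = 1.5, C_ipsi = 1.25, τ_d = 1.5 days (plateau by
day 4), R = 2.5, τ_i = 20 trials, and the rapid counter `i` persisting
across sessions and days (so day-2 session 1 starts at the day-1 final
level). N1 is excluded by construction. Day-1 initial responses are
"weak" purely because the rapid term starts at gain 1 — there is no
separate attenuation parameter. The condition presets (WT 1.0, NR2A het
0.5, NR2A KO 0.0, MK801 0.0) multiply the model's own plasticity scale,
so a model configured with scale 0 stays off under any preset.

**Pathway routing.** Each flash adds the kernel to every visual channel;
the contralateral pathway (eye opposite the hemisphere) receives the full
amplitude, the ipsilateral one is scaled by 0.7 (configurable) and uses
the ipsilateral cumulative ceiling. This base asymmetry plus the
contra/ipsi ceiling difference is the only eye information in the signal
— it is what the decoder exploits, and setting `ipsi_scale=1` with
plasticity off makes the two eyes statistically identical (the chance
control). The ACC channel receives a small (20%) static, non-potentiating
copy of the kernel — whether such a response is volume conduction or
local is left open, so the scale is configurable down to 0. The
somatosensory EEG receives no evoked component.

**Background.** Channels carry Gaussian 1/f noise (spectral exponent 1.0,
SD 20 µV). The noise SD was fixed at design time by two constraints: the
single-trial rectified-area metric carries a rectification bias toward 1
in ratio indices that grows with noise (−8% at SD 20, −16% at SD 40 for
the rapid index, evaluated analytically/by simulation during design), and
awake V1 flash VEPs are genuinely large relative to background (peak SNR
≈ 4–5 for the fully potentiated N2 at SD 20). State oscillations are
sinusoids with per-block random phase: NREM delta 2.25 Hz at 100 µV, REM
theta 8 Hz at 40 µV, wake gamma 50 Hz at 15 µV. After the end of the
first stimulation day the NREM delta amplitude on V1/V2 channels is
multiplied by √1.3 (a 1.3× power gain); the EEG delta is day-invariant.
The EMG channel is white noise with state-dependent SD (wake 60, NREM 15,
REM 4 µV — atonia). Spontaneous spike-wave events (3.5–5.5 Hz fundamental
plus a 0.4-amplitude second harmonic under a Tukey taper, 1–2 s, ~150 µV)
are planted on visual channels during waking at base 1/min growing by
0.5/min per day. Spike trains are inhomogeneous Poisson: a homogeneous
background rate (5 Hz) plus an evoked rate proportional to the
negative-going part of that channel's gained kernel (peak 80 Hz), so
perievent histograms peak at the N1 and N2 latencies and the N2-aligned
peak grows with potentiation.

**What the generator does not emulate.** Real LFPs have non-Gaussian,
non-stationary backgrounds, behavioral artifacts, electrode drift,
imperfect state boundaries, trial-to-trial latency jitter, and VEP shapes
that change (not just rescale) with potentiation. Passing recovery tests
on this generator therefore validates the *estimators and protocol logic*
— window conventions, split handling, threshold rules, pathway
bookkeeping — not robustness to real-data artifacts.

## Analysis conventions

* Time 0 is flash onset; windows are half-open [lo, hi) ms; extremum ties
  break to the earliest sample.
* Baseline: mean of the 100 ms immediately pre-stimulus, per epoch or per
  average (standard evoked-potential practice; removes slow drift). The
  epoch span is −100 to +600 ms.
* Peak windows: N1 0–100, N2 100–300, N3 300–500, P1 0–200, P2 200–400
  ms; rectified area over 0–500 ms.
* Day ratios use each day's full triggered average per (site, pathway);
  sites with day-1 magnitude below 1 µV are flagged and excluded. The
  rapid index pools both eyes in presentation order and compares mean
  single-trial areas over pulses 0–10 vs 190–200 of day 1.
* Decoding: uniform unstratified 75/25 splits (class balance is
  guaranteed by the alternating design), features standardized by
  training-set mean/SD, linear SVM at cost C = 1 (a conventional default;
  accuracies on this generator are insensitive to C over 0.1–10 because
  the day-4 classes are nearly separable), 1000 repetitions, mean
  accuracy reported. Window scans are anchored [0, b) by default; an
  all-pairs [a, b) mode exists.
* Sleep staging: 4 s epochs; wake when EMG RMS exceeds a threshold fitted
  as the log-scale midpoint of the bimodal EMG RMS distribution
  (2-means), else REM when EEG theta/delta > 1, else NREM.
* Band power: Welch, 2 s Hann segments, 50% overlap, integrated over the
  band. Delta 0.5–4, theta 6–10, beta 20–30, narrow gamma 40–60, broad
  gamma 30–100 Hz; the 4–6 Hz gap between delta and theta is deliberate
  and no interpolation is applied.
* Normalized delta: per 60 s bin, V1 delta / EEG delta, keeping only bins
  that are entirely NREM and stimulation-free. Band contrasts for the
  specificity controls (REM theta, wake gamma) are computed at staging-
  epoch resolution with state-transition epochs excluded — fixed-length
  60 s bins almost never fit inside unaligned REM bouts, and transition
  epochs carry mixed-state power that biases the contrast.
* Spike-wave detection: zero-phase 4th-order Butterworth band-pass 3–6
  Hz, Hilbert envelope, threshold mean + 3 SD pooled over the analyzed
  spans, minimum duration 3 cycles of the band center, events merged when
  closer than 0.2 s. The published work does not state a counting
  criterion; this detector is a documented surrogate with exposed
  parameters.

## Estimating the cumulative ceiling

The raw late-day/day-1 amplitude ratio does not equal the cumulative
ceiling C, because the rapid phase saturates within day 1: with the
default model the expected day-5/day-1 contralateral N2 ratio is ≈1.21
even though C_contra = 1.5. The package therefore recovers C by a
model-based fit: the mean amplitude of a block of trials is
A·(1 + (C−1)·u_d + (R−1)·v_b), where u_d and v_b are the known cumulative
and rapid saturation terms given the two time constants, so (A, A(C−1),
A(R−1)) drop out of weighted linear least squares on block-average peak
amplitudes. Blocks of 50 presentations resolve the rapid rise inside day
1, which is what identifies R and decorrelates it from the across-day
term; the time constants are supplied as known (conditional estimation).

## Numerical and protocol choices

* Rendering uses a precomputed (5 × n) Gaussian basis; evoked gain is
  exact per trial, so triggered averages are exactly proportional to mean
  planted gain (used by the recovery oracles).
* Pink noise is generated by spectral shaping of white Gaussian noise
  with the DC bin zeroed, rescaled to the target SD.
* Determinism: one `numpy` Generator seeded per simulation, drawn in a
  fixed order (per-channel noise, per-block oscillation phases and EMG,
  spike-wave events, spikes); identical (config, seed) pairs are
  bit-identical, and the ground-truth JSON regenerates the experiment.
* Desk-scale problem sizes: simulations compress the inter-session gap to
  10 s (the gap carries no analyzed signal; the paradigm's 300 s / 400 s
  gaps remain the schedule defaults), and sleep runs use a compact day —
  stimulation sessions with sleep cycles (NREM 180 s, REM 60 s, wake 60
  s) filling the gaps, plus a 600 s pre-stimulation baseline.
* EDF files are written by a minimal 16-bit writer (1 s records, µV
  physical dimension, fixed header date for byte determinism) and read
  through `mne`; round trips are exact to one quantization step of the
  per-channel physical range. HDF5 round trips are bit exact.

## Known limitations

* The rectified-area metric is biased toward 1 in ratio indices by noise
  rectification (≈−8% on the rapid index at the default SD). This is a
  property of the published metric itself, not of the implementation; the
  recovery tolerance (±15%) absorbs it at the default noise level.
* The repeated-split decoding protocol re-samples a single finite
  dataset, so its mean accuracy carries a dataset-level SD of ≈2 points
  at 600 events and 36 features even for eye-symmetric data. Chance-level
  checks therefore average per-mouse accuracies over several simulated
  mice, as the published protocol averages per-mouse means.
* The sleep stager is a three-state surrogate with two thresholds; it is
  validated against the generator's state schedule (≈97% epoch
  agreement), not against manual scoring of real recordings.
* The estimator for C assumes the two-phase functional form and known
  time constants; misspecified τ values bias C̄ (a sensitivity the tests
  do not explore).
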