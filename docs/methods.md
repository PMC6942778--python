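# Methods notes

This note records the models implemented by `cpcca`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data experiments can and cannot establish.

## Frequency-recognition problem

An SSVEP epoch is a matrix `X ∈ R^{h×i}` of h channels × i samples at
sampling rate `fs` (128 Hz default), recorded while the user gazes at a
stimulus flickering at one of m known frequencies
(default m = 5: 6.67, 7.5, 8.57, 10, 12 Hz — a 60 Hz display renders
these as frame-quantized flicker at 60/9, 60/8, 60/7, 60/6, 60/5).  The
classifier must output one member of the stimulus set.  All methods are
amplitude-invariant after per-channel mean removal, so voltage units are
by convention microvolts but never checked.  Ties are broken toward the
lowest candidate frequency, everywhere, so outputs are deterministic.

## Reference signals

`Y_{f}` stacks `sin(2π q f t), cos(2π q f t)` for harmonics `q = 1..j`
on the one-based grid `t = k/fs, k = 1..i` (a zero-based grid is
available for interoperability; the two differ by a one-sample shift).
Every harmonic must lie strictly below Nyquist.  Harmonic counts: j = 4
for the plain CCA classifier; j = 2 for CP-CCA training, where the
learned reference needs only to lock onto the fundamental and second
harmonic — the projection of the trials retains whatever further
structure the trials share.

## CCA engine

Rows are variables, columns samples; each row is centered.  Rather than
inverting covariance matrices, both data matrices are reduced by SVD and
the canonical correlations are the singular values of the whitened
cross-covariance `D_x (V_xᵀ V_y) D_y` — numerically stable for short
windows and near-collinear trial stacks.  Options and conventions:

* `ridge` (default 1e-8, relative): inflates each within-set covariance
  diagonal by `ridge ×` its mean eigenvalue.  With `ridge = 0` a
  zero-variance row raises a singularity error; other rank deficiencies
  fall back to pseudo-inverse whitening (small singular values below
  `max(p,i)·eps·s₁` are dropped).
* Sign convention: `w_y`'s first nonzero entry is positive and `w_x` is
  flipped so that `corr(x̂, ŷ) ≥ 0`.
* Canonical variates are returned centered with unit sample variance.
* `all_rhos` is clipped to [0, 1] and zero-padded to length `min(p, q)`.

The engine is verified against an independently coded solution of the
covariance eigenproblem `C_xx⁻¹ C_xy C_yy⁻¹ C_yx a = ρ² a` (agreement
≤ 1e-8 over random instances) and against `|Pearson r|` in the 1-D case
(≤ 1e-12).

## Classifiers

**PSDA.** Periodogram per channel on the analysis window, zero-padded so
the frequency grid is at least as fine as `resolution_hz` (default
0.05 Hz), averaged across channels; each candidate frequency is scored
by the summed power within `bin_tolerance_hz` (default 0.1 Hz) of its
fundamental (and optionally harmonics below Nyquist,
`harmonics_scored > 1`).  A tolerance below half the grid spacing is
rejected with advice to zero-pad further.  Windows below 1 s are
rejected: a periodogram cannot separate 6.67 from 7.5 Hz there.

**CCA.** Maximal canonical correlation between the windowed epoch and
`Y_{f_k}` (j = 4) per candidate frequency; argmax wins.

**CP-CCA.** Training stacks, per channel and frequency, the n training
trials into an `n × i` matrix and runs CCA against `Y_{f_k}` (j = 2);
the projected variate (stored centered, unit variance) is the learned
reference for that (channel, frequency) pair — m × h references in all.
References are learned at full trial length (5 s) and truncated at
classification time, so a single model serves every window length.
Test scoring is the absolute Pearson correlation per channel (the 1×1
CCA, hence in [0, 1]) summed over channels; the summed score lies in
[0, h].  The absolute value makes the sum sign-stable; whether signed or
absolute correlations were intended in the original description is
ambiguous, and the CCA convention was chosen.  The montage defaults to
the four posterior sites O1, O2, P7, P8, where the SSVEP is strongest;
the CCA and PSDA baselines use the same default subset for parity.
Preprocessing is per-channel mean removal only; an optional zero-phase
4–45 Hz Butterworth band-pass (`bandpass=(4, 45)`) is off by default.

Models persist to a single JSON file (hyperparameter header +
per-(channel, frequency) reference arrays); loading is round-trip exact.

## Evaluation protocols

**Leave-one-trial-out CV.** With n trials per class, fold k holds out
trial k of every class (trials must be balanced and index-aligned);
CP-CCA retrains per fold, CCA/PSDA classify directly.  Sweeps over
window length, training-set size (seeded subsampling without
replacement, default 20 repeats, averaged) and channel subsets reuse the
same machinery and emit one tidy row per (method, window, n_train,
subset, fold) plus per-condition confusion counts.

**ITR.** `R = (60/T)[log2 N + P log2 P + (1−P) log2((1−P)/(N−1))]`
bit/min with the `0·log 0 = 0` convention at P ∈ {0, 1}; chance accuracy
gives exactly 0.  T is the full selection time in seconds — for the
online protocol, the 4 s analysis window plus the 0.5 s gaze-shift
interval, i.e. 4.5 s; that value is validated by recomputing all ten
published per-subject ITRs exactly.

**Online sessions.** A task needing `n_required` correct commands with
`e` errors costs `n_required + 2e` commands (each error adds a wrong
command and a corrective cancel) of which `n_required + e` count as
correct, so accuracy is `(n_required+e)/(n_required+2e)`.  This model is
adopted because it reproduces every published (commands, accuracy) pair
of the ten-subject helicopter study from the error count alone; it is a
reconstruction, not a protocol quoted from the study.  Two reporting
quirks of the published table are reproduced only to one unit in the
last printed digit: subject S7's accuracy was truncated (22/26 → 84.61
rather than 84.62, propagating to an 18.59 vs 18.60 ITR), and the
table's stated mean number of commands (23.60) is inconsistent with its
own column (arithmetic mean 24.2) — the package reproduces the per-row
values and the accuracy/ITR summary statistics, not that mean.
Summary statistics follow the study's convention of aggregating the
2-decimal per-subject values.

## Synthetic EEG generator

Each trial is `clean + noise`, deterministic given
(seed, frequency, trial index); per-trial substreams derive from
`SeedSequence((seed, round(f·1000), trial_index))` so partial
regeneration is stable.

*Signal*: `Σ_q gain[ch][q] · sin(2π q f t + φ_{ch,q} + jitter)` with
q up to `n_harmonics_signal` (default 2).  Phases `φ_{ch,q}` are drawn
once per subject seed, so the response is phase-locked across trials up
to a per-trial jitter (`phase_jitter_sd`, default 0.1 rad) — the
property CP-CCA's cross-trial projection exploits.  Default gains give
occipital channels (O1, O2: 1.0, 0.5 per harmonic) a stronger response
than parietal ones (P7, P8: 0.7, 0.35).

*Noise*: per channel, `1/f^α`-shaped Gaussian noise (spectral-domain
shaping, `noise_alpha_exponent`) plus an 8–13 Hz alpha-band component
carrying an `alpha_band_power` fraction of the noise power.  Channels
mix a shared source with private ones so that the pairwise noise
correlation equals `noise_spatial_corr` — background EEG at neighboring
posterior electrodes is strongly correlated, and omitting this is the
single largest distortion of the method comparison: spatially
independent noise lets periodogram averaging cut PSDA's noise variance
by h while giving CCA's spatial filter nothing to cancel.

*SNR*: the noise is scaled per epoch so that total clean-signal power
over total noise power equals `snr_db` exactly (`±inf` give noiseless /
signal-free epochs).  Calibration checks confirm the realized ratio to
0.5 dB and the fitted log–log noise slope to ±0.3 of −α (slope measured
with the alpha resonance disabled, since the bump biases a power-law
fit).

Two named conditions are used throughout:

* **Default recording regime** (`SimConfig()`): snr −16 dB, slope α = 1,
  alpha fraction 0.2, spatial correlation 0.6 — a pessimistic consumer
  dry-electrode setting used for data-model, calibration and
  chance-level tests.
* **Moderate-noise comparison condition** (`moderate_snr_config()`):
  snr −10 dB, slope α = 2, alpha fraction 0.4, spatial correlation 0.2 —
  background power concentrated in the stimulation band with a
  prominent spontaneous alpha rhythm.  Here 1 s windows put all three
  classifiers mid-range and the trained method's advantage is visible,
  while 5 s windows approach ceiling.

Problem sizes follow the emulated study design: 4 channels, 5
frequencies, 10 trials × 5 s at 128 Hz per condition (50 epochs);
Monte-Carlo assertions average a handful of such datasets with fixed
seeds and use slacks of roughly two binomial standard errors.

## What the synthetic experiments do and do not show

Passing tests establish the *relative, qualitative* claims on data whose
generative assumptions match the methods: phase-locked response, known
candidate frequencies, stationary colored noise.  They show that the
cross-trial projection denoises references (learned-reference
correlation with the true waveform beats single trials in ≥ 90% of
replicates), that CP-CCA ≥ CCA ≥ PSDA at 1 s windows under the moderate
condition, that accuracy rises with window length and training-set
size, and that signal-free data classify at chance.

They do not reproduce absolute accuracies from real recordings, and one
structural difference matters: the generated clean signal lies exactly
in the sine–cosine span, so plain multichannel CCA is correctly
specified and near-optimal here — at windows ≥ 2 s it overtakes CP-CCA
in this simulation, whereas on real recordings (idiosyncratic waveforms,
nonstationary interference) the learned-reference advantage persists
across windows.  The generator also omits eye-blink/movement artifacts,
volume-conduction forward modeling, inter-subject variability, and
SSVEP amplitude nonstationarity.

## Known limitations

* EDF input is read-only and optional (labels from `stim_<freq>`
  annotations or a sidecar table); no other acquisition formats.
* No filter-bank CCA, multiway CCA, or artifact rejection.
* The session model assumes every error is followed by exactly one
  successful corrective cancel.
* `train_size_sweep` subsampling is seeded and shared across classes;
  other subsampling schemes would give slightly different curves.
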