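# cpcca — channel-projection CCA for SSVEP frequency recognition

`cpcca` implements target identification for steady-state visual evoked
potential (SSVEP) brain–computer interfaces: given a few seconds of
multichannel EEG recorded while a user gazes at one of several flickering
stimuli, decide which stimulus frequency they attended.  It is written
for BCI researchers who want a compact, fully reproducible reference
implementation of the **channel-projection CCA (CP-CCA)** method next to
the two classical baselines, exercisable end to end on synthetic EEG so
that no recordings are required.

## Methods

Let an epoch be `X ∈ R^{h×i}` (h channels, i samples at rate `fs`), and
for each candidate frequency `f_k` let `Y_{f_k}` be the sine–cosine
reference with j harmonics, rows `sin(2π q f_k t), cos(2π q f_k t)`,
`q = 1..j`, on the grid `t = 1/fs, …, i/fs`.

* **PSDA** — channel-averaged periodogram power at each `f_k`
  (zero-padded grid, ±0.1 Hz tolerance); argmax wins.
* **CCA** — for each `f_k`, the maximal canonical correlation
  `ρ_k = max_{w_x,w_y} corr(w_xᵀX, w_yᵀY_{f_k})` with j = 4 harmonics;
  the predicted frequency is `argmax_k ρ_k`.
* **CP-CCA** — a trained variant.  For every channel `h` and frequency
  `f_k`, the n training trials of that single channel are stacked into
  `X_{h,f_k} ∈ R^{n×i}` and a CCA against `Y_{f_k}` (j = 2) yields the
  projected variate `X̂_{h,f_k} = w_{h,x}ᵀ X_{h,f_k}` — a learned
  reference carrying the phase-locked response common to the trials.  A
  test epoch is scored per channel by `ρ_{h,f_k} = |corr(X_h, X̂_{h,f_k})|`
  and classified by `argmax_k Σ_h ρ_{h,f_k}`.

Classifiers follow the scikit-learn estimator protocol
(`fit`/`predict`/`get_params`) over epoch stacks of shape
`(n_epochs, n_channels, n_samples)`, with stimulus frequencies as class
labels.  Evaluation utilities provide leave-one-trial-out
cross-validation, window/training-size/montage sweeps, the Wolpaw
information transfer rate `R = (60/T)[log2 N + P log2 P +
(1−P) log2((1−P)/(N−1))]` (bit/min), and an online command-session model
with error correction.  A synthetic generator produces phase-locked
SSVEP epochs in 1/f^α background noise with a spontaneous alpha rhythm
and controlled SNR (see `docs/methods.md`).

## Worked example

```python
import cpcca as cp
from cpcca.simulate import moderate_snr_config

ds = cp.generate_dataset(moderate_snr_config(seed=21))    # 50 labeled epochs
rep = cp.window_sweep(ds, methods=("psda", "cca", "cpcca"),
                      windows_seconds=(1.0, 3.0, 5.0))
print(rep.mean_table()[["method", "window_seconds", "accuracy"]])
```

prints the leave-one-trial-out accuracy grid (10 folds × 5 epochs each):

```
method  window_seconds  accuracy
   cca             1.0      0.64
   cca             3.0      0.90
   cca             5.0      0.98
 cpcca             1.0      0.72
 cpcca             3.0      0.92
 cpcca             5.0      0.98
  psda             1.0      0.62
  psda             3.0      0.98
  psda             5.0      0.98
```

At the 1 s window the trained CP-CCA classifier leads (0.72 vs 0.64 vs
0.62): its learned references are estimated from 45 s of training data,
whereas CCA and PSDA must characterize the epoch from 128 samples alone.
All methods improve with window length, the behavior that drives the
accuracy/ITR trade-off in online use.

The online command-session model reproduces a session's bookkeeping from
its error count alone:

```python
>>> led = cp.online_session(n_required=18, error_count=3,
...                         selection_seconds=4.5, n_targets=5)
>>> led.total_commands, round(led.accuracy_pct, 2), round(led.itr_bits_per_min, 2)
(24, 87.5, 20.38)
```

Every error costs one wrong command plus one corrective cancel, so 18
required commands with 3 errors takes 24 commands at 87.5% accuracy,
worth 20.38 bit/min at a 4.5 s selection time.

A command-line interface mirrors the library:

```sh
cpcca simulate --out ds/ --seed 21     # synthetic dataset
cpcca train --data ds/ --out model.json
cpcca evaluate --data ds/ --method cpcca --window-seconds 2
cpcca itr --n 5 --p 0.875 --t 4.5      # -> 20.38
```

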