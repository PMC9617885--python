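# Methods

This note records the models the package implements, the parameters that
matter, and the choices made where the design was genuinely open.

## Reservoir update semantics

The update `R[n] = H(G_i·W·X[n] + G_f·R[n-1])` is applied **once per
D-sample segment**: `W` is `N × D`, so a whole segment is consumed per
step, and `n` indexes segments. Independent segments start from the zero
state (`run_reservoir(..., reset_per_segment=True)`, the default);
consecutive segments of one record can carry state instead. With
reset-per-segment and a single update, the feedback term contributes
nothing to classification — it exists because the hardware loop exists,
and it is exercised by the multi-step contraction and stability analyses.

The echo-state requirement is `G_f · max|H'| < 1`. With the default
nonlinearity (`α = 1 V`, `κ = 2 /V`, `p = 2`) `max|H'| = α = 1`, so
`G_f = 0.1` gives a contraction factor of at least 10 per step.

### Nonlinearity

Only the family ("Mackey-Glass-like") of the on-chip activation is
known, not its parameterization, so the package uses the standard
delay-reservoir form `H(u) = α·(u−o) / (1 + |κ·(u−o)|^p)` with all four
parameters configurable. Defaults `α = 1 V`, `κ = 2 /V`, `p = 2`,
`o = 0`: odd-symmetric, compressive, peak gain `α` at the origin —
the single-peaked-gain shape the worst-case stability analysis assumes.

### Behavioral mode

* **Settling.** Each charge transfer is scaled by `1 − exp(−t_slot/τ)`
  with `t_slot = T_s/D` and `τ = T_s/8/D` by default, i.e. eight time
  constants per transfer (a 3.4·10⁻⁴ deficit). Slewing is not modeled.
* **Noise.** One zero-mean Gaussian draw per sample, variance equal to
  the closed-form input-referred noise (below), injected input-referred
  (multiplied by the `C_in/C_intg` transfer gain).
* **Loop quantization.** The fed-back state passes through a mid-rise
  `adc_quantize → dac_reconstruct` pair (10-bit default, ±1 V full
  scale). Mid-rise convention: exact boundaries floor toward the
  negative rail; out-of-range inputs clip to the end codes; the code for
  0 V reconstructs at +LSB/2, the inherent mid-rise offset.
* **Clipping.** The neuron output clips at ±full_scale (the ADC range).

The loop ADC is 10 bits, following the circuit description; a
table-format source lists 12-bit reservoir input precision, and the
discrepancy is unresolved — `adc_bits` is a config field, so either
choice is one line.

ECG segments (millivolt scale) are normalized so the dataset's peak maps
to half of full scale before the input layer; the source material is
silent on this scaling, and half-scale keeps the accumulator inside the
quantizer range with margin.

### Randomness

One root seed fans out into fixed named substreams (`weights`, `noise`,
`mismatch`, `train`, `dataset`), so e.g. toggling noise never changes
the drawn weight matrix.

## Noise model

`input_noise_variance` evaluates
`kT/C_in · 1/(1−β) + (1/β)·(kT/C_eq)·(4/3)·(C_intg/C_in)²` with
`C_eq = C_L + (1−β)·C_intg` exactly (Boltzmann constant from
scipy.constants). β defaults to the standard SC-integrator feedback
factor `C_intg/(C_in+C_intg)`; β ∈ {0, 1} is rejected as singular.
Defaults `C_in = 10 fF`, `C_intg = 400 fF`, `C_L = 100 fF`, `T = 300 K`
give 9.98 mV rms per sample. The input-layer energy model is `C·V²` per
charge event (one event per sample per active weight, 1.2 V supply):
86.4 pJ per inference at defaults — the underlying published energy
curve's model is not printed, so plain CV² switching energy is used.

## Stability analysis

The loop is linearized at worst case: loop gain `G_f·G_h` with
`G_h = max|H'|` (found by grid scan + bounded refinement;
analytically `α` for the default form). Three cascaded stages map to
discrete poles `k = exp(−ω_eff/rate)` at the time-multiplexed update
rate `N·F_s`: the summing amplifier settles at its closed-loop bandwidth
`β·ω₁`, the unity-gain buffer at `ω₁`, the nonlinearity stage at `ω₂`.
Each stage carries one update-cycle delay, hence `z⁻³`, and the
characteristic cubic is `(z−k₁)(z−k₂)(z−k₃) + G_f·G_h = 0`.

Two choices here were open. The printed form of this equation repeats a
single pole three times and carries no explicit gain; the package
generalizes to three distinct poles (equal poles recover the printed
form) and places `G_f·G_h` on the delay path — without the gain term the
stable region could not depend on `G_f`, contradicting the documented
behavior that it shrinks as `G_f` grows, which the contour tests verify
by nesting. The root solver is cross-checked against the analytic
wide-bandwidth limit `|z| = (G_f·G_h)^{1/3}` and against time-domain
impulse decay of the same difference equation.

## Read-out and training

Activations are parametric amplifier curves: hidden layers
`s·tanh(g·(v−o)/s)` (bounded by saturation `s`, slope `g` at the
operating point); the output "softmax" stage of the differential pair is
modeled as the same bounded odd sigmoidal of the pair difference,
yielding one differential score compared against a threshold (a
two-node normalized-exponential output is out of scope). Ties at the
threshold go to label 0, the conservative default.

Weights are snapped to a symmetric signed grid with `2^b − 1` levels
spanning `[−w_max, +w_max]` (odd count ⇒ exact zero level; round to
nearest, ties away from zero), `b` = 4/4/6 per layer; layer inputs are
quantized by the mid-rise clipping quantizer at 10/8/8 bits. `w_max` is
implied by the float shadow weights frozen at training time, so
inference is bit-exact after serialization (integer codes + per-layer
scale in a flat JSON text file).

Training is SGD with binary cross-entropy on a logistic map of the
score (logit scale 4; hinge loss available), analytic activation
derivatives, and straight-through gradients through both quantizers.
Defaults: learning rate 0.1, 40 epochs, batch 16. The decision threshold
is calibrated after training by an exhaustive sweep over midpoints of
sorted unique training scores (plus sentinels), exactly the objective a
per-chip calibration maximizes; under Pelgrom-scaled weight mismatch and
neuron offsets (`apply_mismatch`), re-running only this sweep models
per-chip foreground calibration. Class re-weighting is off by default
(the intended deployment split is near-balanced).

## Synthetic ECG

A sum-of-Gaussians phantom: five Gaussian bumps (P, Q, R, S, T) per
beat, beats concatenated with truncated-Gaussian RR jitter, plus
sinusoidal baseline wander and white noise; amplitudes in mV, 300 Sa/s,
6000-sample (20 s) segments. Class 0 ("normal"): RR 0.85 ± 0.06 s,
T = 0.3 mV. Class 1 ("sepsis-like" surrogate): RR 0.55 ± 0.008 s,
T = 0.12 mV — elevated rate, depressed variability, flattened T wave,
the physiology-motivated direction for pre-sepsis ECG, chosen to be
cleanly separable in the "easy" preset. The "hard" preset
(0.78 ± 0.045 s vs 0.72 ± 0.03 s, T 0.3 vs 0.24 mV) overlaps the
classes for stress-testing. Dataset metadata regenerates segments
bit-exactly.

What the phantom does **not** emulate: real beat-morphology diversity,
arrhythmias, motion/electrode artifacts, drift between patients, or any
validated sepsis signature. Passing the end-to-end tests therefore shows
the architecture can learn a temporal contrast through its quantized
analog path — not that it predicts sepsis.

Supported input formats are delimited text (one segment per row) with a
JSON sidecar; state matrices, contours and ledgers are delimited text.

## Problem sizes and numerical notes

The end-to-end experiments use 100 segments/class with a stratified
50/50 split, five seeds; Monte-Carlo noise checks use 10⁵ draws
(1000 accumulations of 100 samples); stability contours are 50×50.
These sizes put sampling error well below the margins being tested
while keeping any run at laptop scale (seconds).

Degenerate inputs are contracts, not surprises: all-zero weight matrices
quantize to themselves; single-class label sets raise (threshold
calibration, AUC, training); β ∈ {0,1} raises; NaN propagates through
the activation quantizer rather than being laundered by the integer
cast, so a NaN loss raises a divergence error naming the epoch.

## Known limitations

* One reservoir update per segment means the digital-delay feedback path
  matters mainly for stability/contraction analyses, not accuracy, under
  the default reset policy.
* The amplifier activation curves are parametric stand-ins for measured
  transfer curves; co-design training is exercised against the models,
  not silicon.
* The energy ledger's "digital baseline" comparison requires the user to
  supply the baseline's compute energy (no published default exists);
  only the conventional-vs-proposed comparison has defaults.
* kT/C noise is white and per-sample; flicker noise, clock feedthrough
  and charge injection are not modeled.
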