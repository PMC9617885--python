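# ecgrc

Behavioral simulator and analysis library for an **in-sensor analog
reservoir computer**: an analog-to-information converter for wearable ECG
sensors that classifies 20 s ECG segments on-chip and transmits a single
13-bit prediction score instead of the 72000-bit digitized waveform.

It is written for mixed-signal and neuromorphic-computing researchers who
want to study this architecture — its circuit nonidealities, its loop
stability, its noise/energy trade-offs, and hardware-matched training of
its read-out — without fabricating silicon or downloading clinical data.

## The model

The reservoir has `N` virtual neurons, updated once per `D`-sample segment:

```
R[n] = H( G_i · W · X[n] + G_f · I · R[n-1] )
```

where `W` is a fixed random binary {0,1} `N × D` input weight matrix
(multiplication becomes addition in the switched-capacitor input layer),
the identity interconnect is realized as a single-cycle delayed
self-feedback of one time-multiplexed physical neuron, and `H` is a
Mackey-Glass-style compressive nonlinearity
`H(u) = α·u / (1 + |κ·u|^p)`. Defaults: `N = 63`, `D = 6000` (20 s at
300 Sa/s), `G_i = 0.6`, `G_f = 0.1`, a 10-bit SAR ADC / R-DAC pair in the
feedback delay loop.

Around the reservoir the package models:

* **behavioral circuit effects** — per-sample first-order incomplete
  settling (amplifier time constant `τ = T_s/8/D`), sampled kT/C noise,
  loop quantization, output clipping;
* **input-referred noise** (closed form):
  `V²ₙ = kT/C_in · 1/(1−β) + (1/β)·(kT/C_eq)·(4/3)·(C_intg/C_in)²`,
  `C_eq = C_L + (1−β)·C_intg`;
* **loop stability** — linearized worst-case loop gain `G_f·G_h` with three
  cascaded one-pole stages and a 3-cycle delay; stable iff all roots of
  `(z−k₁)(z−k₂)(z−k₃) + G_f·G_h = 0` lie inside the unit circle;
* **read-out** — a quantized 63-20-6-1 ANN with amplifier-shaped
  activations (4/4/6-bit weights, 10/8/8-bit layer inputs), trained by
  SGD through the activation curves with quantization inside the loop,
  plus per-chip decision-threshold calibration under mismatch;
* **sensor energy ledger** — Walden-FoM ADC energy, radio energy per bit,
  and the conventional-vs-in-sensor comparison;
* **synthetic ECG** — a sum-of-Gaussians two-class beat phantom
  ("normal" vs a low-HRV, flattened-T "sepsis-like" surrogate).

## Worked example

```bash
python examples/05_end_to_end.py
```

```
held-out accuracy    1.000
held-out sensitivity 1.000
held-out specificity 1.000
held-out AUC         1.000
decision threshold   -0.0025 V
final training loss  0.0232
```

100 segments per class are synthesized, projected through the fixed
random reservoir, and the quantized read-out is trained on half. The
easy synthetic classes are fully separable by design, so held-out
accuracy saturates at 1.0; the threshold near 0 V says the calibrated
decision boundary sits at the differential score's midpoint. The other
examples print the energy ledger (`2858.88 nJ → 17.93 nJ` per inference,
a 159.4× reduction; 72000 → 13 transmitted bits), the stability verdict
at the operating point (`max |z| = 0.4659`, stable), and the noise model
(9.98 mV rms per sample at 10 fF, Monte-Carlo within a few percent).

The same experiments are scriptable from the shell:

```bash
ecgrc energy   --out out/            # itemized energy ledger
ecgrc stability --out out/           # contour + operating-point verdict
ecgrc pipeline --out out/ --seed 1   # full synthetic experiment
```

Every run writes its fully-resolved configuration next to its outputs, so
any artifact is reproducible from that file alone.

## What this package is not

No transistor-level (SPICE) simulation, no slewing or charge-injection
models, no RF link model, and no clinical claims: the measured
performance of the fabricated chip on credentialed ICU waveforms is out
of scope, and the synthetic classes are an architectural test signal,
not a sepsis model. See `docs/methods.md` for the modeling assumptions
and design choices.
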