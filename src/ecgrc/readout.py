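"""Hardware-matched quantized ANN read-out.

A 3-layer feed-forward read-out (63 -> 20 -> 6 -> 1 by default) whose
activations model the analog amplifier transfer curves of the chip:
hidden layers use a bounded tanh-like curve, the output stage is a
bounded sigmoidal of the differential pair voltage, producing a single
differential score that is compared against a calibrated threshold.

Weights live on signed uniform integer grids (4-bit hidden, 6-bit
output by default), realized on-chip as capacitor ratios with a 4 fF
unit capacitor. Layer inputs are themselves quantized (10-8-8 bits) by
the same mid-rise clipping quantizer the reservoir loop uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .reservoir import adc_quantize, dac_reconstruct


@dataclass(frozen=True)
class ActivationModel:
    """Parametric amplifier transfer curve.

    ``hidden_tanh``: saturation * tanh(gain * (v - offset) / saturation).
    ``output_softmax``: the same bounded odd sigmoidal applied to the
    differential-pair input; the output is the single differential score.
    Both are continuous, bounded by +/- saturation, and have slope
    ``gain`` at the offset point.
    """

    kind: str = "hidden_tanh"
    gain: float = 1.0
    saturation: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("hidden_tanh", "output_softmax"):
            raise ValueError(f"unknown activation kind {self.kind!r}")
        if not self.gain > 0:
            raise ValueError("gain must be > 0")
        if not self.saturation > 0:
            raise ValueError("saturation must be > 0")


def activation_eval(v, model: ActivationModel):
    """Evaluate the amplifier transfer curve at input voltage(s) v."""
    x = np.asarray(v, dtype=float) - model.offset
    out = model.saturation * np.tanh(model.gain * x / model.saturation)
    return out if out.ndim else float(out)


def activation_deriv(v, model: ActivationModel):
    """Analytic slope of the transfer curve (used by co-design training)."""
    x = np.asarray(v, dtype=float) - model.offset
    t = np.tanh(model.gain * x / model.saturation)
    out = model.gain * (1.0 - t**2)
    return out if out.ndim else float(out)


def quantize_weights(w, bits: int):
    """Snap weights to the signed uniform grid of the given bit width.

    The grid has 2**bits - 1 levels spanning [-w_max, +w_max] where
    w_max is the largest absolute weight of the matrix (odd level count
    guarantees an exact zero level). Round to nearest, ties away from
    zero. An all-zero matrix is returned unchanged.
    """
    if bits < 2:
        raise ValueError("bits must be >= 2")
    w = np.asarray(w, dtype=float)
    w_max = np.abs(w).max() if w.size else 0.0
    if w_max == 0.0:
        return w.copy()
    step = 2.0 * w_max / (2**bits - 2)
    codes = np.sign(w) * np.floor(np.abs(w) / step + 0.5)
    return codes * step


def _weight_codes(w, bits: int):
    """Integer codes and grid step for serialization; (codes, step)."""
    w = np.asarray(w, dtype=float)
    w_max = np.abs(w).max() if w.size else 0.0
    if w_max == 0.0:
        return np.zeros(w.shape, dtype=np.int64), 0.0
    step = 2.0 * w_max / (2**bits - 2)
    codes = (np.sign(w) * np.floor(np.abs(w) / step + 0.5)).astype(np.int64)
    return codes, step


@dataclass(frozen=True)
class AnnLayer:
    """One affine + activation stage with its quantization contract."""

    weights: np.ndarray            # float weights, pre-quantization
    bias: np.ndarray
    weight_bits: int
    input_bits: int
    activation: ActivationModel
    input_full_scale: float = 1.0
    # set after mismatch injection: the stored weights already ARE the
    # physical (perturbed) capacitor ratios, so do not re-snap them
    frozen_quantized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "bias", np.asarray(self.bias, dtype=float))
        if self.weights.ndim != 2:
            raise ValueError("layer weights must be 2-D (out x in)")
        if self.bias.shape != (self.weights.shape[0],):
            raise ValueError("bias shape must match output dimension")

    @property
    def quantized_weights(self) -> np.ndarray:
        if self.frozen_quantized:
            return self.weights
        return quantize_weights(self.weights, self.weight_bits)


@dataclass(frozen=True)
class AnnModel:
    """The full read-out: chained layers plus the decision threshold."""

    layers: tuple
    decision_threshold: float = 0.0
    unit_cap: float = 4e-15

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        sizes = self.layer_sizes
        for a, b in zip(self.layers[:-1], self.layers[1:]):
            if b.weights.shape[1] != a.weights.shape[0]:
                raise ValueError(f"layer shapes do not chain: {sizes}")

    @property
    def layer_sizes(self) -> tuple:
        return (self.layers[0].weights.shape[1],) + tuple(
            lyr.weights.shape[0] for lyr in self.layers
        )


@dataclass(frozen=True)
class ClassDecision:
    """Differential score (volts) and thresholded binary label."""

    score: float
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def make_ann_template(
    layer_sizes=(63, 20, 6, 1),
    weight_bits=(4, 4, 6),
    input_bits=(10, 8, 8),
    hidden_gain: float = 2.0,
    saturation: float = 1.0,
    init_scale: float = 0.5,
    seed: int = 0,
) -> AnnModel:
    """Randomly initialized model with the chip's default architecture."""
    if len(weight_bits) != len(layer_sizes) - 1 or len(input_bits) != len(weight_bits):
        raise ValueError("need one weight/input bit width per layer")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    layers = []
    for i, (n_in, n_out) in enumerate(zip(layer_sizes[:-1], layer_sizes[1:])):
        last = i == len(layer_sizes) - 2
        act = ActivationModel(
            kind="output_softmax" if last else "hidden_tanh",
            gain=1.0 if last else hidden_gain,
            saturation=saturation,
        )
        w = rng.normal(0.0, init_scale / np.sqrt(n_in), size=(n_out, n_in))
        layers.append(
            AnnLayer(
                weights=w,
                bias=np.zeros(n_out),
                weight_bits=weight_bits[i],
                input_bits=input_bits[i],
                activation=act,
            )
        )
    return AnnModel(layers=tuple(layers))


def _quantize_activations(x, bits: int, full_scale: float):
    x = np.asarray(x, dtype=float)
    # the integer cast inside the quantizer would silently launder NaN
    # into a rail code; keep NaN NaN so divergence stays detectable
    bad = ~np.isfinite(x)
    q = dac_reconstruct(adc_quantize(np.where(bad, 0.0, x), bits, full_scale),
                        bits, full_scale)
    return np.where(bad, x, q)


def ann_score(state, model: AnnModel, quantize_inputs: bool = True) -> float:
    """Forward pass returning the raw differential score in volts."""
    x = np.asarray(state, dtype=float)
    if x.shape != (model.layer_sizes[0],):
        raise ValueError(
            f"state length {x.shape} does not match input layer {model.layer_sizes[0]}"
        )
    for lyr in model.layers:
        if quantize_inputs:
            x = _quantize_activations(x, lyr.input_bits, lyr.input_full_scale)
        z = lyr.quantized_weights @ x + lyr.bias
        x = activation_eval(z, lyr.activation)
    return float(x[0])


def ann_forward(state, model: AnnModel) -> ClassDecision:
    """Score the state and threshold it; ties break to label 0 (non-event)."""
    score = ann_score(state, model)
    return ClassDecision(score=score, label=int(score > model.decision_threshold))


def calibrate_threshold(scores, labels) -> float:
    """Threshold maximizing training accuracy, by exhaustive midpoint sweep.

    Candidates are midpoints of consecutive sorted unique scores plus
    below-minimum and above-maximum sentinels; returns the midpoint of
    the widest-accuracy candidate set's best interval (ties resolved to
    the first maximizing candidate in sweep order).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D sequences")
    if labels.min() == labels.max():
        raise ValueError("threshold calibration needs both classes present")
    uniq = np.unique(scores)
    span = max(uniq[-1] - uniq[0], 1.0)
    candidates = np.concatenate(
        [[uniq[0] - span], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + span]]
    )
    acc = [( (scores > t).astype(int) == labels).mean() for t in candidates]
    return float(candidates[int(np.argmax(acc))])


def apply_mismatch(
    model: AnnModel, sigma0: float, rng: np.random.Generator
) -> AnnModel:
    """Inject fabrication mismatch into a quantized model.

    Each weight receives a Gaussian relative error whose sigma follows
    Pelgrom-style area scaling, sigma0 / sqrt(levels * unit_cap / 4 fF),
    and every neuron receives a Gaussian input-referred offset of
    standard deviation sigma0 volts.
    """
    if sigma0 < 0:
        raise ValueError("sigma0 must be >= 0")
    if sigma0 == 0:
        return model
    new_layers = []
    for lyr in model.layers:
        levels = 2**lyr.weight_bits - 1
        sigma_w = sigma0 / np.sqrt(levels * model.unit_cap / 4e-15)
        wq = lyr.quantized_weights
        w = wq * (1.0 + rng.normal(0.0, sigma_w, size=wq.shape))
        b = lyr.bias + rng.normal(0.0, sigma0, size=lyr.bias.shape)
        new_layers.append(replace(lyr, weights=w, bias=b, frozen_quantized=True))
    return replace(model, layers=tuple(new_layers))


# --- serialization: flat structured text, bit-exact round trip ----------

def save_model(model: AnnModel, path) -> None:
    """Write the model as structured text (integer grids + per-layer scale)."""
    payload = {
        "format": "ecgrc-ann-v1",
        "decision_threshold": model.decision_threshold,
        "unit_cap": model.unit_cap,
        "layers": [],
    }
    for lyr in model.layers:
        codes, step = _weight_codes(lyr.weights, lyr.weight_bits)
        payload["layers"].append(
            {
                "weight_codes": codes.tolist(),
                "weight_step": step,
                "weights_float": lyr.weights.tolist(),
                "bias": lyr.bias.tolist(),
                "weight_bits": lyr.weight_bits,
                "input_bits": lyr.input_bits,
                "input_full_scale": lyr.input_full_scale,
                "frozen_quantized": lyr.frozen_quantized,
                "activation": {
                    "kind": lyr.activation.kind,
                    "gain": lyr.activation.gain,
                    "saturation": lyr.activation.saturation,
                    "offset": lyr.activation.offset,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> AnnModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "ecgrc-ann-v1":
        raise ValueError(f"{path} is not an ecgrc ANN model file")
    layers = []
    for ld in payload["layers"]:
        act = ActivationModel(**ld["activation"])
        layers.append(
            AnnLayer(
                weights=np.asarray(ld["weights_float"], dtype=float),
                bias=np.asarray(ld["bias"], dtype=float),
                weight_bits=ld["weight_bits"],
                input_bits=ld["input_bits"],
                activation=act,
                input_full_scale=ld["input_full_scale"],
                frozen_quantized=ld.get("frozen_quantized", False),
            )
        )
    return AnnModel(
        layers=tuple(layers),
        decision_threshold=payload["decision_threshold"],
        unit_cap=payload["unit_cap"],
    )


__all__ = [
    "ActivationModel",
    "AnnLayer",
    "AnnModel",
    "ClassDecision",
    "activation_eval",
    "activation_deriv",
    "quantize_weights",
    "make_ann_template",
    "ann_score",
    "ann_forward",
    "calibrate_threshold",
    "apply_mismatch",
    "save_model",
    "load_model",
]
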