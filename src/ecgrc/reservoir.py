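"""Delay-feedback reservoir with binary input weights.

The reservoir update is

    R[n] = H(G_i * W @ X[n] + G_f * R[n-1])

with an N x D binary {0,1} input weight matrix W, identity reservoir
interconnect (realized in hardware as a single-cycle delayed feedback of
a time-multiplexed physical neuron), and a Mackey-Glass-style saturating
nonlinearity H. One update consumes one whole D-sample segment.

Two modes are provided:

* ``ideal`` — exact arithmetic, for oracle checks and fast experiments.
* ``behavioral`` — mirrors the switched-capacitor implementation:
  per-sample first-order incomplete settling in the input accumulator,
  optional sampled kT/C noise, the feedback path passed through an
  ADC-quantize / R-DAC-reconstruct pair (the digital delay loop), and
  the neuron output clipped to the ADC full scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import InputLayerCircuit, NonlinearityParams, ReservoirConfig
from .energy import input_noise_variance


@dataclass(frozen=True)
class BinaryWeightMatrix:
    """Fixed random binary {0,1} input weight matrix."""

    entries: np.ndarray
    seed: int
    density: float

    def __post_init__(self) -> None:
        e = np.asarray(self.entries)
        if e.ndim != 2:
            raise ValueError("weight matrix must be 2-D")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("weight entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


@dataclass(frozen=True)
class ReservoirState:
    """Length-N vector of virtual-neuron outputs after ``step_index`` updates."""

    values: np.ndarray
    step_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("state must be a 1-D vector")
        if not np.isfinite(v).all():
            raise ValueError("state values must be finite")
        object.__setattr__(self, "values", v)


def make_input_weights(
    n_neurons: int, segment_len: int, density: float = 0.5, seed: int = 0
) -> BinaryWeightMatrix:
    """Draw the N x D binary input weight matrix, i.i.d. Bernoulli(density)."""
    if n_neurons < 1 or segment_len < 1:
        raise ValueError("n_neurons and segment_len must be >= 1")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    entries = (rng.random((n_neurons, segment_len)) < density).astype(np.int8)
    return BinaryWeightMatrix(entries=entries, seed=seed, density=density)


def mackey_glass_nl(u, params: NonlinearityParams):
    """Saturating odd-symmetric nonlinearity a*(u-o) / (1 + |k*(u-o)|**p)."""
    x = np.asarray(u, dtype=float) - params.input_offset
    out = params.amplitude * x / (1.0 + np.abs(params.sharpness * x) ** params.exponent)
    return out if out.ndim else float(out)


def mackey_glass_deriv(u, params: NonlinearityParams):
    """Analytic slope dH/du (used by the stability analysis)."""
    x = np.asarray(u, dtype=float) - params.input_offset
    k, p, a = params.sharpness, params.exponent, params.amplitude
    t = np.abs(k * x) ** p
    out = a * (1.0 + (1.0 - p) * t) / (1.0 + t) ** 2
    return out if out.ndim else float(out)


def adc_quantize(v, bits: int, full_scale: float):
    """Mid-rise uniform quantizer on [-full_scale, +full_scale).

    Returns integer codes in [0, 2**bits - 1]; out-of-range inputs clip
    to the end codes. Exact level boundaries round toward the negative
    rail (floor), the mid-rise convention.
    """
    if bits < 1:
        raise ValueError("bits must be >= 1")
    lsb = 2.0 * full_scale / 2**bits
    code = np.floor((np.asarray(v, dtype=float) + full_scale) / lsb)
    code = np.clip(code, 0, 2**bits - 1).astype(np.int64)
    return code if code.ndim else int(code)


def dac_reconstruct(code, bits: int, full_scale: float):
    """Reconstruction level of a mid-rise code: -FS + (code + 1/2) * LSB."""
    if bits < 1:
        raise ValueError("bits must be >= 1")
    lsb = 2.0 * full_scale / 2**bits
    v = -full_scale + (np.asarray(code, dtype=float) + 0.5) * lsb
    return v if v.ndim else float(v)


def input_accumulate(
    segment,
    w_row,
    circuit: InputLayerCircuit,
    config: ReservoirConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Charge-domain accumulation of one weighted segment onto C_intg.

    Ideal mode returns (C_in/C_intg) * sum_j w[j] * x[j]. Behavioral
    mode scales each charge transfer by the first-order settling factor
    1 - exp(-t_slot/tau) and, if the circuit has noise enabled, adds one
    zero-mean Gaussian draw per sample whose variance is the
    input-referred noise of the switched-capacitor input layer.
    """
    segment = np.asarray(segment, dtype=float)
    w_row = np.asarray(w_row, dtype=float)
    if segment.shape != w_row.shape:
        raise ValueError(
            f"segment and weight-row lengths differ: {segment.shape} vs {w_row.shape}"
        )
    if config.mode == "ideal":
        return float(circuit.gain * np.dot(w_row, segment))
    acc = config.settling_factor * circuit.gain * np.dot(w_row, segment)
    if circuit.noise_enabled:
        if rng is None:
            rng = config.rng_stream("noise")
        sigma = np.sqrt(input_noise_variance(circuit))
        acc += circuit.gain * rng.normal(0.0, sigma, size=segment.size).sum()
    return float(acc)


def reservoir_update(
    segment,
    state: ReservoirState,
    weights: BinaryWeightMatrix,
    circuit: InputLayerCircuit,
    config: ReservoirConfig,
    rng: np.random.Generator | None = None,
    nonlinearity=None,
) -> ReservoirState:
    """One reservoir update: consume a D-sample segment, emit the new state.

    The N virtual neurons are computed by a single time-multiplexed
    physical neuron; each uses only the previous update's state (the
    N-cycle delay), so the update is a plain vector map. In behavioral
    mode the fed-back state traverses the loop ADC/R-DAC and the neuron
    output clips at the ADC full scale.

    ``nonlinearity`` overrides H (callable on arrays); by default the
    Mackey-Glass form from ``config.nl_params`` is used.
    """
    segment = np.asarray(segment, dtype=float)
    n, d = weights.shape
    if state.values.size != n:
        raise ValueError(f"state length {state.values.size} != n_neurons {n}")
    if segment.size != d:
        raise ValueError(f"segment length {segment.size} != segment_len {d}")
    if nonlinearity is None:
        nonlinearity = lambda u: mackey_glass_nl(u, config.nl_params)

    behavioral = config.mode == "behavioral"
    if behavioral:
        if rng is None:
            rng = config.rng_stream("noise")
        acc = np.array(
            [
                input_accumulate(segment, weights.entries[i], circuit, config, rng)
                for i in range(n)
            ]
        )
        fb = dac_reconstruct(
            adc_quantize(state.values, config.adc_bits, config.full_scale),
            config.dac_bits,
            config.full_scale,
        )
    else:
        acc = circuit.gain * (weights.entries @ segment)
        fb = state.values

    new = nonlinearity(config.input_gain * acc + config.feedback_gain * fb)
    new = np.asarray(new, dtype=float)
    if behavioral:
        new = np.clip(new, -config.full_scale, config.full_scale)
    return ReservoirState(values=new, step_index=state.step_index + 1)


def run_reservoir(
    segments,
    weights: BinaryWeightMatrix,
    circuit: InputLayerCircuit,
    config: ReservoirConfig,
    reset_per_segment: bool = True,
) -> np.ndarray:
    """Batch the reservoir over segments; one length-N state row each.

    By default the state resets to zero between segments (independent
    windows); ``reset_per_segment=False`` carries the state across
    consecutive segments of one record.
    """
    segments = [np.asarray(s, dtype=float) for s in segments]
    n, d = weights.shape
    for i, s in enumerate(segments):
        if s.ndim != 1 or s.size != d:
            raise ValueError(f"segment {i} has length {s.size}, expected {d}")
    rng = config.rng_stream("noise")
    out = np.empty((len(segments), n))
    state = ReservoirState(values=np.zeros(n))
    for i, s in enumerate(segments):
        if reset_per_segment:
            state = ReservoirState(values=np.zeros(n))
        state = reservoir_update(s, state, weights, circuit, config, rng=rng)
        out[i] = state.values
    return out


__all__ = [
    "BinaryWeightMatrix",
    "ReservoirState",
    "make_input_weights",
    "mackey_glass_nl",
    "mackey_glass_deriv",
    "adc_quantize",
    "dac_reconstruct",
    "input_accumulate",
    "reservoir_update",
    "run_reservoir",
]
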