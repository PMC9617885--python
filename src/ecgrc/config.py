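"""Configuration containers for the reservoir and its circuit model.

All physical quantities are SI unless noted: capacitances in farads,
voltages in volts, times in seconds, rates in hertz. The reservoir
defaults reproduce the operating point of the prototype chip the package
models: N = 63 virtual neurons, D = 6000-sample (20 s) ECG segments,
input gain G_i = 0.6, feedback gain G_f = 0.1, a 10-bit loop ADC and an
amplifier time constant of T_s/8/D.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import numpy as np
import yaml


@dataclass(frozen=True)
class NonlinearityParams:
    """Parameters of the Mackey-Glass-style saturating nonlinearity.

    H(u) = amplitude * (u - input_offset) / (1 + |sharpness * (u - input_offset)|**exponent)

    ``amplitude`` is in volts, ``sharpness`` in 1/volt, ``exponent`` is
    dimensionless (>= 1), ``input_offset`` in volts.
    """

    amplitude: float = 1.0
    sharpness: float = 2.0
    exponent: float = 2.0
    input_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if not self.sharpness > 0:
            raise ValueError(f"sharpness must be > 0, got {self.sharpness}")
        if not self.exponent >= 1:
            raise ValueError(f"exponent must be >= 1, got {self.exponent}")


@dataclass(frozen=True)
class InputLayerCircuit:
    """Switched-capacitor input-layer circuit parameters.

    ``feedback_factor`` (beta) is the feedback factor of the integrating
    amplifier; by the standard SC-integrator definition it defaults to
    C_intg / (C_in + C_intg). The equivalent capacitance used by the
    noise model is C_eq = C_L + (1 - beta) * C_intg.
    """

    c_in: float = 10e-15
    c_intg: float = 400e-15
    c_load: float = 100e-15
    feedback_factor: float | None = None
    temperature: float = 300.0
    noise_enabled: bool = False

    def __post_init__(self) -> None:
        for name in ("c_in", "c_intg", "c_load"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.feedback_factor is None:
            object.__setattr__(
                self, "feedback_factor", self.c_intg / (self.c_in + self.c_intg)
            )
        if not 0 < self.feedback_factor < 1:
            raise ValueError(
                f"feedback_factor must lie in (0, 1), got {self.feedback_factor}"
            )
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0 kelvin")

    @property
    def gain(self) -> float:
        """Charge-transfer gain C_in / C_intg of one accumulation step."""
        return self.c_in / self.c_intg

    @property
    def c_eq(self) -> float:
        """Equivalent load capacitance seen by the amplifier noise."""
        return self.c_load + (1.0 - self.feedback_factor) * self.c_intg


@dataclass(frozen=True)
class ReservoirConfig:
    """Hyper-parameters of the delay-feedback reservoir.

    ``mode`` selects between the ideal mathematical update (exact
    arithmetic, no circuit effects) and the behavioral update
    (incomplete settling, sampled kT/C noise, loop ADC/DAC
    quantization, output clipping).
    """

    n_neurons: int = 63
    segment_len: int = 6000
    input_gain: float = 0.6
    feedback_gain: float = 0.1
    op_rate: float = 1000.0
    nl_params: NonlinearityParams = field(default_factory=NonlinearityParams)
    adc_bits: int = 10
    dac_bits: int = 10
    full_scale: float = 1.0
    settling_tau: float | None = None
    settle_time_per_sample: float | None = None
    mode: Literal["ideal", "behavioral"] = "ideal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.segment_len < 1:
            raise ValueError("segment_len must be >= 1")
        if not self.input_gain > 0:
            raise ValueError("input_gain must be > 0")
        if not 0 <= self.feedback_gain < 1:
            raise ValueError(
                "feedback_gain must satisfy 0 <= G_f < 1 (echo-state contraction)"
            )
        if self.adc_bits < 1 or self.dac_bits < 1:
            raise ValueError("adc_bits and dac_bits must be >= 1")
        if not self.op_rate > 0:
            raise ValueError("op_rate must be > 0")
        if not self.full_scale > 0:
            raise ValueError("full_scale must be > 0")
        # default amplifier time constant tau = T_s / 8 / D, and one
        # charge-transfer slot of T_s / D per input sample
        ts = 1.0 / self.op_rate
        if self.settling_tau is None:
            object.__setattr__(self, "settling_tau", ts / 8.0 / self.segment_len)
        if not self.settling_tau > 0:
            raise ValueError("settling_tau must be > 0")
        if self.settle_time_per_sample is None:
            object.__setattr__(self, "settle_time_per_sample", ts / self.segment_len)
        if not self.settle_time_per_sample > 0:
            raise ValueError("settle_time_per_sample must be > 0")
        if self.mode not in ("ideal", "behavioral"):
            raise ValueError(f"mode must be 'ideal' or 'behavioral', got {self.mode!r}")

    @property
    def t_s(self) -> float:
        return 1.0 / self.op_rate

    @property
    def settling_factor(self) -> float:
        """Fraction of charge transferred in one settling slot, 1 - exp(-t/tau)."""
        return -np.expm1(-self.settle_time_per_sample / self.settling_tau)

    def rng_stream(self, name: str) -> np.random.Generator:
        """Derive an independent, named random stream from the root seed.

        Separate streams for weight generation and noise mean toggling
        noise on does not change the input weight matrix.
        """
        return derive_rng(self.seed, name)


_STREAM_IDS = {
    "weights": 1,
    "noise": 2,
    "mismatch": 3,
    "train": 4,
    "dataset": 5,
}


def derive_rng(seed: int, name: str) -> np.random.Generator:
    """Named substream of a root seed (stable across sessions)."""
    try:
        stream = _STREAM_IDS[name]
    except KeyError:
        raise ValueError(f"unknown stream name {name!r}") from None
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _dataclass_from_mapping(cls, mapping, name):
    fields = set(cls.__dataclass_fields__)
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown keys in {name} config: {sorted(unknown)}")
    return cls(**mapping)


def reservoir_config_from_dict(d: dict) -> ReservoirConfig:
    d = dict(d)
    if "nl_params" in d and isinstance(d["nl_params"], dict):
        d["nl_params"] = _dataclass_from_mapping(
            NonlinearityParams, d["nl_params"], "nl_params"
        )
    return _dataclass_from_mapping(ReservoirConfig, d, "reservoir")


def circuit_from_dict(d: dict) -> InputLayerCircuit:
    return _dataclass_from_mapping(InputLayerCircuit, d, "circuit")


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def dump_yaml_config(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_to_dict(cfg) -> dict:
    return asdict(cfg)


__all__ = [
    "NonlinearityParams",
    "InputLayerCircuit",
    "ReservoirConfig",
    "derive_rng",
    "reservoir_config_from_dict",
    "circuit_from_dict",
    "load_yaml_config",
    "dump_yaml_config",
    "config_to_dict",
    "replace",
]
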