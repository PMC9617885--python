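"""Linearized discrete-time stability analysis of the reservoir loop.

The reservoir loop — summing amplifier, nonlinearity stage, unity-gain
buffer, ADC/DAC delay — is linearized around its operating point at the
worst case for stability: loop gain G_f * G_h, where G_h is the largest
small-signal gain of the nonlinearity H (attained at its offset point
for the compressive default form). Each amplifier stage contributes a
discrete-time pole k_i = exp(-omega_eff / rate) from its closed-loop
bandwidth at the time-multiplexed update rate, and one update-cycle
delay, giving the characteristic equation

    1 + G_f * G_h * z^-3 / ((1-k1 z^-1)(1-k2 z^-1)(1-k3 z^-1)) = 0,

a cubic in z. The loop is stable iff all roots lie inside the unit
circle. Setting k1 = k2 = k3 recovers the single-pole-repeated form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .config import NonlinearityParams
from .reservoir import mackey_glass_deriv


@dataclass(frozen=True)
class LoopModel:
    """Small-signal model of the reservoir loop.

    ``omega1``: unity-gain bandwidth (rad/s) of the shared OTA used by
    the summing amplifier (feedback factor ``beta``) and the unity-gain
    buffer. ``omega2``: 3-dB bandwidth of the nonlinearity stage.
    ``rate``: loop update rate in Hz (N * F_s after time-multiplexing).
    """

    omega1: float
    omega2: float
    beta: float = 1.0
    feedback_gain: float = 0.1
    nl_gain: float = 1.0
    rate: float = 63e3

    def __post_init__(self) -> None:
        if not (self.omega1 > 0 and self.omega2 > 0):
            raise ValueError("bandwidths must be > 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        if not self.nl_gain > 0:
            raise ValueError("nl_gain must be > 0")
        if not self.rate > 0:
            raise ValueError("rate must be > 0")


@dataclass(frozen=True)
class StabilityResult:
    roots: np.ndarray
    max_root_magnitude: float

    @property
    def stable(self) -> bool:
        return self.max_root_magnitude < 1.0


def estimate_nl_gain(params: NonlinearityParams, span: float = 5.0) -> float:
    """Worst-case (largest) small-signal gain max |dH/du|.

    Dense-grid scan over ``span`` characteristic widths around the
    offset, refined by bounded local search. For the compressive
    default form the maximum sits at the offset point with value
    ``amplitude``.
    """
    half = span / params.sharpness
    grid = params.input_offset + np.linspace(-half, half, 2001)
    g = np.abs(mackey_glass_deriv(grid, params))
    i = int(np.argmax(g))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda u: -abs(mackey_glass_deriv(u, params)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(max(g[i], -res.fun))


def discretize_poles(model: LoopModel) -> tuple[float, float, float]:
    """Map the three stage bandwidths to discrete-time pole magnitudes.

    k_i = exp(-omega_eff / rate): the summing amplifier settles at its
    closed-loop bandwidth beta * omega1, the buffer at omega1, the
    nonlinearity stage at omega2.
    """
    k1 = float(np.exp(-model.beta * model.omega1 / model.rate))
    k2 = float(np.exp(-model.omega1 / model.rate))
    k3 = float(np.exp(-model.omega2 / model.rate))
    return (k1, k2, k3)


def char_roots(model: LoopModel) -> StabilityResult:
    """Roots of the loop characteristic equation.

    Multiplying through by z^3 gives
    (z - k1)(z - k2)(z - k3) + G_f * G_h = 0.
    """
    k1, k2, k3 = discretize_poles(model)
    gain = model.feedback_gain * model.nl_gain
    # expanded cubic coefficients
    coeffs = [
        1.0,
        -(k1 + k2 + k3),
        k1 * k2 + k1 * k3 + k2 * k3,
        -k1 * k2 * k3 + gain,
    ]
    if not any(coeffs):
        raise ValueError("degenerate all-zero characteristic polynomial")
    roots = np.roots(coeffs)
    return StabilityResult(roots=roots, max_root_magnitude=float(np.abs(roots).max()))


def loop_impulse_response(model: LoopModel, n_steps: int = 400) -> np.ndarray:
    """Small-signal impulse response of the linearized loop.

    Direct simulation of the difference equation whose characteristic
    polynomial ``char_roots`` solves; used as the time-domain
    cross-check of the root-locus verdict.
    """
    k1, k2, k3 = discretize_poles(model)
    gain = model.feedback_gain * model.nl_gain
    e1 = k1 + k2 + k3
    e2 = k1 * k2 + k1 * k3 + k2 * k3
    e3 = k1 * k2 * k3
    y = np.zeros(n_steps)
    for n in range(n_steps):
        x = 1.0 if n == 0 else 0.0
        y[n] = x
        if n >= 1:
            y[n] += e1 * y[n - 1]
        if n >= 2:
            y[n] -= e2 * y[n - 2]
        if n >= 3:
            y[n] += (e3 - gain) * y[n - 3]
    return y


def stability_contour(
    omega1_grid, omega2_grid, beta: float, feedback_gain: float, nl_gain: float,
    rate: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stability verdict over an (omega1, omega2) grid.

    Returns (stable, max_mag) arrays of shape (len(omega1_grid),
    len(omega2_grid)). Grids are in rad/s at the given loop rate; pass
    ``rate=1.0`` with grids in rad/update for normalized sweeps.
    """
    omega1_grid = np.asarray(omega1_grid, dtype=float)
    omega2_grid = np.asarray(omega2_grid, dtype=float)
    if (omega1_grid <= 0).any() or (omega2_grid <= 0).any():
        raise ValueError("bandwidth grids must be positive")
    stable = np.zeros((omega1_grid.size, omega2_grid.size), dtype=bool)
    max_mag = np.zeros_like(stable, dtype=float)
    for i, w1 in enumerate(omega1_grid):
        for j, w2 in enumerate(omega2_grid):
            res = char_roots(
                LoopModel(
                    omega1=w1, omega2=w2, beta=beta,
                    feedback_gain=feedback_gain, nl_gain=nl_gain, rate=rate,
                )
            )
            stable[i, j] = res.stable
            max_mag[i, j] = res.max_root_magnitude
    return stable, max_mag


def chip_operating_point(
    feedback_gain: float = 0.1, nl_gain: float = 1.0, beta: float = 1.0,
    rate: float = 63e3,
) -> LoopModel:
    """Chip operating point: omega1 = omega2 = 2*pi*0.9*rate."""
    w = 2 * np.pi * 0.9 * rate
    return LoopModel(
        omega1=w, omega2=w, beta=beta,
        feedback_gain=feedback_gain, nl_gain=nl_gain, rate=rate,
    )


__all__ = [
    "LoopModel",
    "StabilityResult",
    "estimate_nl_gain",
    "discretize_poles",
    "char_roots",
    "loop_impulse_response",
    "stability_contour",
    "chip_operating_point",
]
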