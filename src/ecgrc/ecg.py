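"""Synthetic two-class ECG segment generator.

A sum-of-Gaussians beat phantom (ECGSYN-style): each beat is five
Gaussian bumps at the P, Q, R, S, T positions, beats are concatenated
with per-beat RR-interval jitter, and baseline wander plus white noise
are added. Two classes are generated: class 0 ("normal") with ordinary
heart-rate variability, and class 1 (the "sepsis-like" surrogate) with
elevated heart rate, depressed RR variability and a flattened T wave —
the physiology-motivated contrast that gives the reservoir's temporal
kernel signal to separate. No claim of clinical realism is made; the
phantom exists to exercise the pipeline without clinical data.

Amplitudes are in millivolts; segments are D samples at ``sample_rate``
Hz (defaults 6000 samples at 300 Hz, a 20 s window).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .config import derive_rng

# (center, width) as fractions of the beat; amplitudes in mV
_WAVE_CENTERS = {"p": 0.18, "q": 0.34, "r": 0.38, "s": 0.42, "t": 0.62}
_WAVE_WIDTHS = {"p": 0.035, "q": 0.012, "r": 0.018, "s": 0.012, "t": 0.06}


@dataclass(frozen=True)
class BeatParams:
    """Morphology and rhythm parameters of one beat class."""

    amplitudes: dict = field(
        default_factory=lambda: {"p": 0.12, "q": -0.12, "r": 1.0, "s": -0.2, "t": 0.3}
    )
    centers: dict = field(default_factory=lambda: dict(_WAVE_CENTERS))
    widths: dict = field(default_factory=lambda: dict(_WAVE_WIDTHS))
    rr_mean: float = 0.85        # seconds
    rr_sigma: float = 0.06       # seconds, beat-to-beat jitter
    wander_amplitude: float = 0.05   # mV
    wander_freq: float = 0.25        # Hz
    noise_sigma: float = 0.02        # mV additive white noise

    def __post_init__(self) -> None:
        if not self.rr_mean > 0:
            raise ValueError("rr_mean must be > 0")
        if self.rr_sigma < 0 or self.noise_sigma < 0 or self.wander_amplitude < 0:
            raise ValueError("sigmas and wander amplitude must be >= 0")
        if any(w <= 0 for w in self.widths.values()):
            raise ValueError("wave widths must be > 0")


# sepsis-like surrogate: tachycardic, low HRV, flattened T wave
SEPSIS_LIKE = BeatParams(
    amplitudes={"p": 0.10, "q": -0.10, "r": 1.0, "s": -0.2, "t": 0.12},
    rr_mean=0.55,
    rr_sigma=0.008,
)
NORMAL = BeatParams()

# "hard" preset: classes nearly overlap
NORMAL_HARD = BeatParams(rr_mean=0.78, rr_sigma=0.045)
SEPSIS_LIKE_HARD = BeatParams(
    amplitudes={"p": 0.12, "q": -0.12, "r": 1.0, "s": -0.2, "t": 0.24},
    rr_mean=0.72,
    rr_sigma=0.03,
)


@dataclass(frozen=True)
class EcgDataset:
    """Labeled fixed-length segments plus the metadata to regenerate them."""

    segments: np.ndarray          # (n, D) in mV
    labels: np.ndarray            # (n,) in {0, 1}
    sample_rate: float = 300.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seg = np.asarray(self.segments, dtype=float)
        lab = np.asarray(self.labels, dtype=int)
        if seg.ndim != 2 or seg.shape[0] != lab.size:
            raise ValueError("segments must be (n, D) with one label per row")
        if lab.size and not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        object.__setattr__(self, "segments", seg)
        object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return self.labels.size


def synth_beat(params: BeatParams, n_points: int) -> np.ndarray:
    """One beat: sum of five Gaussians at the P-QRS-T positions."""
    if n_points < 5:
        raise ValueError("n_points must be >= 5")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    beat = np.zeros(n_points)
    for wave, amp in params.amplitudes.items():
        c = params.centers[wave]
        w = params.widths[wave]
        beat += amp * np.exp(-0.5 * ((t - c) / w) ** 2)
    return beat


def synth_segment(
    class_id: int,
    params0: BeatParams,
    params1: BeatParams,
    segment_len: int,
    sample_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One D-sample segment of the given class.

    Beats are concatenated with truncated-Gaussian RR jitter (RR
    intervals clipped to >= 0.2 s so a beat always fits), then baseline
    wander and white noise are added; the output is truncated or
    zero-padded to exactly ``segment_len`` samples.
    """
    params = params1 if class_id == 1 else params0
    samples: list[np.ndarray] = []
    total = 0
    while total < segment_len:
        rr = params.rr_mean + params.rr_sigma * rng.standard_normal()
        rr = max(rr, 0.2)
        n = max(int(round(rr * sample_rate)), 5)
        samples.append(synth_beat(params, n))
        total += n
    seg = np.concatenate(samples)[:segment_len]
    if seg.size < segment_len:  # pragma: no cover - loop guarantees length
        seg = np.pad(seg, (0, segment_len - seg.size))
    t = np.arange(segment_len) / sample_rate
    if params.wander_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        seg = seg + params.wander_amplitude * np.sin(
            2 * np.pi * params.wander_freq * t + phase
        )
    if params.noise_sigma > 0:
        seg = seg + params.noise_sigma * rng.standard_normal(segment_len)
    return seg


def make_dataset(
    n_per_class: int,
    separation: str = "easy",
    segment_len: int = 6000,
    sample_rate: float = 300.0,
    seed: int = 0,
) -> EcgDataset:
    """Balanced, shuffled, seed-reproducible two-class dataset."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if separation == "easy":
        params0, params1 = NORMAL, SEPSIS_LIKE
    elif separation == "hard":
        params0, params1 = NORMAL_HARD, SEPSIS_LIKE_HARD
    else:
        raise ValueError("separation must be 'easy' or 'hard'")
    rng = derive_rng(seed, "dataset")
    labels = np.repeat([0, 1], n_per_class)
    segments = np.stack(
        [
            synth_segment(int(c), params0, params1, segment_len, sample_rate, rng)
            for c in labels
        ]
    )
    order = rng.permutation(labels.size)
    metadata = {
        "n_per_class": n_per_class,
        "separation": separation,
        "segment_len": segment_len,
        "sample_rate": sample_rate,
        "seed": seed,
        "class0": asdict(params0),
        "class1": asdict(params1),
    }
    return EcgDataset(
        segments=segments[order],
        labels=labels[order],
        sample_rate=sample_rate,
        metadata=metadata,
    )


def regenerate_dataset(metadata: dict) -> EcgDataset:
    """Rebuild a dataset bit-exactly from its generation metadata."""
    params0 = BeatParams(**metadata["class0"])
    params1 = BeatParams(**metadata["class1"])
    rng = derive_rng(metadata["seed"], "dataset")
    labels = np.repeat([0, 1], metadata["n_per_class"])
    segments = np.stack(
        [
            synth_segment(
                int(c), params0, params1,
                metadata["segment_len"], metadata["sample_rate"], rng,
            )
            for c in labels
        ]
    )
    order = rng.permutation(labels.size)
    return EcgDataset(
        segments=segments[order],
        labels=labels[order],
        sample_rate=metadata["sample_rate"],
        metadata=dict(metadata),
    )


def normalize_segments(segments, full_scale: float = 1.0) -> np.ndarray:
    """Scale the whole dataset so amplitudes fit within half full-scale.

    The front-end normalizes the millivolt-scale ECG into the analog
    input range of the reservoir (peak maps to full_scale / 2).
    """
    segments = np.asarray(segments, dtype=float)
    peak = np.abs(segments).max()
    if peak == 0:
        return segments.copy()
    return segments * (0.5 * full_scale / peak)


def detect_rr_intervals(segment, sample_rate: float, min_rr: float = 0.2) -> np.ndarray:
    """RR intervals (s) via a simple threshold-and-refractory R-peak detector."""
    from scipy.signal import find_peaks

    segment = np.asarray(segment, dtype=float)
    height = 0.5 * segment.max()
    peaks, _ = find_peaks(
        segment, height=height, distance=max(int(min_rr * sample_rate), 1)
    )
    return np.diff(peaks) / sample_rate


__all__ = [
    "BeatParams",
    "EcgDataset",
    "NORMAL",
    "SEPSIS_LIKE",
    "NORMAL_HARD",
    "SEPSIS_LIKE_HARD",
    "synth_beat",
    "synth_segment",
    "make_dataset",
    "regenerate_dataset",
    "normalize_segments",
    "detect_rr_intervals",
]
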