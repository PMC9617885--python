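"""End-to-end experiment: synthesize ECG, run the reservoir, train, evaluate.

This is the glue the CLI ``pipeline`` subcommand and the acceptance
checks use: generate (or load) a two-class dataset, normalize it into
the reservoir's analog input range, project every segment through the
fixed random reservoir, train the quantized read-out on the training
half, calibrate the decision threshold on training scores, and report
held-out metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import InputLayerCircuit, ReservoirConfig, derive_rng
from .ecg import EcgDataset, make_dataset, normalize_segments
from .readout import AnnModel, make_ann_template
from .reservoir import make_input_weights, run_reservoir
from .training import Metrics, TrainConfig, evaluate, train_ann


@dataclass(frozen=True)
class PipelineResult:
    model: AnnModel
    metrics: Metrics
    train_metrics: Metrics
    history: list
    states_train: np.ndarray
    states_test: np.ndarray
    labels_train: np.ndarray
    labels_test: np.ndarray


def split_dataset(dataset: EcgDataset, train_fraction: float, seed: int):
    """Stratified shuffled split; returns (train_idx, test_idx)."""
    rng = derive_rng(seed, "dataset")
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(dataset.labels == cls)
        idx = idx[rng.permutation(idx.size)]
        n_train = int(round(train_fraction * idx.size))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(train_idx), np.sort(test_idx)


def reservoir_states(
    dataset: EcgDataset,
    config: ReservoirConfig,
    circuit: InputLayerCircuit | None = None,
    weight_density: float = 0.5,
) -> np.ndarray:
    """Normalize segments and project them through the fixed reservoir."""
    circuit = circuit if circuit is not None else InputLayerCircuit()
    weights = make_input_weights(
        config.n_neurons, config.segment_len, density=weight_density, seed=config.seed
    )
    segments = normalize_segments(dataset.segments, full_scale=config.full_scale)
    return run_reservoir(segments, weights, circuit, config)


def run_pipeline(
    dataset: EcgDataset | None = None,
    config: ReservoirConfig | None = None,
    circuit: InputLayerCircuit | None = None,
    ann_template: AnnModel | None = None,
    train_cfg: TrainConfig | None = None,
    n_per_class: int = 100,
    separation: str = "easy",
    train_fraction: float = 0.5,
    seed: int = 0,
) -> PipelineResult:
    """Full synthetic experiment; every random element derives from ``seed``."""
    if config is None:
        config = ReservoirConfig(seed=seed)
    if circuit is None:
        circuit = InputLayerCircuit()
    if dataset is None:
        dataset = make_dataset(
            n_per_class,
            separation=separation,
            segment_len=config.segment_len,
            seed=seed,
        )
    if ann_template is None:
        ann_template = make_ann_template(
            layer_sizes=(config.n_neurons, 20, 6, 1), seed=seed
        )
    if train_cfg is None:
        train_cfg = TrainConfig(seed=seed)

    states = reservoir_states(dataset, config, circuit)
    train_idx, test_idx = split_dataset(dataset, train_fraction, seed)
    x_tr, y_tr = states[train_idx], dataset.labels[train_idx]
    x_te, y_te = states[test_idx], dataset.labels[test_idx]

    model, history = train_ann(x_tr, y_tr, ann_template, train_cfg)
    return PipelineResult(
        model=model,
        metrics=evaluate(model, x_te, y_te),
        train_metrics=evaluate(model, x_tr, y_tr),
        history=history,
        states_train=x_tr,
        states_test=x_te,
        labels_train=y_tr,
        labels_test=y_te,
    )


__all__ = ["PipelineResult", "split_dataset", "reservoir_states", "run_pipeline"]
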