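"""Hardware-software co-design training of the quantized read-out.

Stochastic gradient descent through the parametric amplifier transfer
curves: the forward pass uses quantized weights and quantized layer
inputs exactly as inference does, the backward pass uses the analytic
derivatives of the activation curves and straight-through gradients
through both quantizers. Quantizing inside the loop lets the float
shadow weights compensate the quantization error, which is the point of
doing it during training rather than after.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.stats import rankdata

from .config import derive_rng
from .readout import (
    AnnModel,
    activation_deriv,
    activation_eval,
    calibrate_threshold,
    _quantize_activations,
)


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes NaN."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.1
    epochs: int = 40
    batch_size: int = 16
    seed: int = 0
    quantize_every_step: bool = True
    loss: str = "bce"
    logit_scale: float = 4.0

    def __post_init__(self) -> None:
        if not self.learning_rate >= 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in ("bce", "hinge"):
            raise ValueError("loss must be 'bce' or 'hinge'")


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float


def _forward_batch(x, model: AnnModel, quantize: bool):
    """Vectorized forward pass keeping per-layer inputs and preactivations."""
    inputs, preacts = [], []
    for lyr in model.layers:
        if quantize:
            x = _quantize_activations(x, lyr.input_bits, lyr.input_full_scale)
        inputs.append(x)
        w = lyr.quantized_weights if quantize else lyr.weights
        z = x @ w.T + lyr.bias
        preacts.append(z)
        x = activation_eval(z, lyr.activation)
    return x[:, 0], inputs, preacts


def ann_scores_batch(states, model: AnnModel, quantize: bool = True) -> np.ndarray:
    """Differential scores for a matrix of states (one row per segment)."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    scores, _, _ = _forward_batch(states, model, quantize)
    return scores


def _loss_and_grad(scores, y, cfg: TrainConfig):
    """Per-sample loss and d(loss)/d(score)."""
    if cfg.loss == "bce":
        t = cfg.logit_scale * scores
        # stable log(1 + exp(-|t|)) formulation
        p = 1.0 / (1.0 + np.exp(-t))
        loss = np.log1p(np.exp(-np.abs(t))) + np.maximum(t, 0) - y * t
        grad = cfg.logit_scale * (p - y)
    else:  # hinge on +/-1 targets
        s = 2.0 * y - 1.0
        margin = 1.0 - s * scores
        loss = np.maximum(margin, 0.0)
        grad = np.where(margin > 0, -s, 0.0)
    return loss, grad


def train_ann(
    states, labels, arch: AnnModel, cfg: TrainConfig | None = None
) -> tuple[AnnModel, list[dict]]:
    """SGD-train the read-out on reservoir states; returns model + history.

    The returned model's decision threshold is calibrated on the
    training scores. History holds one dict per epoch (epoch, loss,
    train accuracy), mirroring the training log the CLI writes.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    states = np.asarray(states, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if states.ndim != 2 or states.shape[0] != labels.size:
        raise ValueError("states must be (n_samples, n_features) matching labels")
    if labels.min() == labels.max():
        raise ValueError("training needs both classes present")

    rng = derive_rng(cfg.seed, "train")
    weights = [lyr.weights.copy() for lyr in arch.layers]
    biases = [lyr.bias.copy() for lyr in arch.layers]
    model = _rebuild(arch, weights, biases)
    history: list[dict] = []

    n = states.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = states[idx], labels[idx]
            scores, inputs, preacts = _forward_batch(
                xb, model, quantize=cfg.quantize_every_step
            )
            loss, dscore = _loss_and_grad(scores, yb, cfg)
            if not np.isfinite(loss).all():
                raise DivergenceError(f"training loss diverged at epoch {epoch}")
            epoch_loss += loss.sum()

            # backward pass: analytic activation slopes, straight-through
            # gradients for the weight and activation quantizers
            delta = dscore[:, None]  # d loss / d activation output
            grads_w, grads_b = [None] * len(model.layers), [None] * len(model.layers)
            for li in range(len(model.layers) - 1, -1, -1):
                lyr = model.layers[li]
                dz = delta * activation_deriv(preacts[li], lyr.activation)
                grads_w[li] = dz.T @ inputs[li] / len(idx)
                grads_b[li] = dz.mean(axis=0)
                if li:
                    w = lyr.quantized_weights if cfg.quantize_every_step else lyr.weights
                    delta = dz @ w
            for li in range(len(model.layers)):
                weights[li] -= cfg.learning_rate * grads_w[li]
                biases[li] -= cfg.learning_rate * grads_b[li]
            model = _rebuild(arch, weights, biases)

        scores = ann_scores_batch(states, model)
        train_acc = float(((scores > 0).astype(int) == labels).mean())
        history.append(
            {"epoch": epoch, "loss": float(epoch_loss / n), "train_accuracy": train_acc}
        )

    thr = calibrate_threshold(ann_scores_batch(states, model), labels)
    model = _dc_replace(model, decision_threshold=thr)
    return model, history


def _rebuild(arch: AnnModel, weights, biases) -> AnnModel:
    layers = tuple(
        _dc_replace(lyr, weights=w, bias=b)
        for lyr, w, b in zip(arch.layers, weights, biases)
    )
    return _dc_replace(arch, layers=layers)


def rank_auc(scores, labels) -> float:
    """AUC as the Wilcoxon-Mann-Whitney rank statistic, midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(model: AnnModel, states, labels) -> Metrics:
    """Accuracy / sensitivity / specificity at the model threshold, plus AUC."""
    states = np.asarray(states, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if states.size == 0 or labels.size == 0:
        raise ValueError("evaluation set must be non-empty")
    scores = ann_scores_batch(states, model)
    pred = (scores > model.decision_threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = (tp + tn) / labels.size
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return Metrics(
        accuracy=acc, sensitivity=sens, specificity=spec, auc=rank_auc(scores, labels)
    )


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from confusion counts."""
    total = tp + tn + fp + fn
    return (tp + tn) / total, tp / (tp + fn), tn / (tn + fp)


__all__ = [
    "TrainConfig",
    "Metrics",
    "DivergenceError",
    "train_ann",
    "evaluate",
    "rank_auc",
    "ann_scores_batch",
    "metrics_from_counts",
]
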