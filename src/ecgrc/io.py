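"""Delimited-text I/O for segments, state matrices and ledgers.

Segments are stored one per row (D columns, comma-separated) with a
sidecar JSON metadata file; state matrices carry a header row of neuron
indices. All formats are plain text so runs stay portable and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ecg import EcgDataset


def write_segments(dataset: EcgDataset, path) -> None:
    """Write segments (one per row) plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, dataset.segments, delimiter=",", fmt="%.9g")
    sidecar = {
        "labels": dataset.labels.tolist(),
        "sample_rate": dataset.sample_rate,
        "metadata": dataset.metadata,
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_segments(path) -> EcgDataset:
    path = Path(path)
    segments = np.atleast_2d(np.loadtxt(path, delimiter=","))
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            sidecar = json.load(fh)
        labels = np.asarray(sidecar["labels"], dtype=int)
        rate = sidecar["sample_rate"]
        metadata = sidecar.get("metadata", {})
    else:
        labels = np.zeros(segments.shape[0], dtype=int)
        rate = 300.0
        metadata = {}
    return EcgDataset(
        segments=segments, labels=labels, sample_rate=rate, metadata=metadata
    )


def write_states(states, path) -> None:
    """State matrix with a header row of neuron indices."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    header = ",".join(f"neuron_{i}" for i in range(states.shape[1]))
    np.savetxt(path, states, delimiter=",", fmt="%.17g", header=header, comments="")


def read_states(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))


def write_contour(omega1_grid, omega2_grid, stable, max_mag, path) -> None:
    """Flattened (omega1, omega2, stable, max|z|) table."""
    rows = []
    for i, w1 in enumerate(omega1_grid):
        for j, w2 in enumerate(omega2_grid):
            rows.append((w1, w2, int(stable[i, j]), max_mag[i, j]))
    np.savetxt(
        path,
        np.asarray(rows),
        delimiter=",",
        header="omega1,omega2,stable,max_root_magnitude",
        comments="",
        fmt=("%.9g", "%.9g", "%d", "%.9g"),
    )


def write_ledger(ledger, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("side,component,energy_joules\n")
        for side, name, value in ledger.to_rows():
            fh.write(f"{side},{name},{value:.12g}\n")
        fh.write(f"summary,bits_conventional,{ledger.bits_conventional}\n")
        fh.write(f"summary,bits_proposed,{ledger.bits_proposed}\n")
        fh.write(f"summary,bit_ratio,{ledger.bit_ratio:.12g}\n")
        fh.write(f"summary,energy_ratio,{ledger.energy_ratio:.12g}\n")


__all__ = [
    "write_segments",
    "read_segments",
    "write_states",
    "read_states",
    "write_contour",
    "write_ledger",
]
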