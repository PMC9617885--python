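import numpy as np
import pytest

from ecgrc.config import InputLayerCircuit, NonlinearityParams, ReservoirConfig


@pytest.fixture
def default_circuit():
    return InputLayerCircuit()


@pytest.fixture
def unit_gain_circuit():
    """C_in == C_intg so one charge transfer has gain exactly 1."""
    return InputLayerCircuit(c_in=400e-15, c_intg=400e-15)


@pytest.fixture
def small_ideal_config():
    return ReservoirConfig(n_neurons=2, segment_len=3, seed=1)


def direct_reservoir_eq(segment, state, w, gain, g_i, g_f, nl):
    """Textbook evaluation of the reservoir update, written independently
    of the implementation: R[n] = H(G_i * W @ X + G_f * I @ R[n-1])."""
    segment = np.asarray(segment, dtype=float)
    state = np.asarray(state, dtype=float)
    n = w.shape[0]
    out = np.empty(n)
    for i in range(n):
        acc = 0.0
        for j in range(w.shape[1]):
            acc += w[i, j] * segment[j]
        out[i] = nl(g_i * gain * acc + g_f * state[i])
    return out


def brute_force_threshold(scores, labels):
    """Exhaustive accuracy sweep over all inter-score midpoints + sentinels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(scores)
    cands = [uniq[0] - 1.0, uniq[-1] + 1.0] + list((uniq[:-1] + uniq[1:]) / 2)
    best_acc, best_t = -1.0, None
    for t in cands:
        acc = float(((scores > t).astype(int) == labels).mean())
        if acc > best_acc:
            best_acc, best_t = acc, t
    return best_t, best_acc
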