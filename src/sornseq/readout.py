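"""Linear readout trained online with the delta rule; winner-take-all output.

The readout maps the full excitatory state (including input units) to one
output unit per symbol of the active alphabet.  At every training step the
weights move down the gradient of the squared difference between output
activity and the one-hot target; the network's prediction is the output unit
with the highest activity (ties broken by lowest index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ReadoutWeights:
    """w_out: (n_outputs, n_excitatory); mu: delta-rule learning rate."""

    w_out: np.ndarray
    mu: float = 2e-5

    @classmethod
    def zeros(cls, n_outputs: int, n_excitatory: int, mu: float = 2e-5) -> "ReadoutWeights":
        return cls(np.zeros((n_outputs, n_excitatory)), mu)


@dataclass
class TrialRecord:
    """Per-position predictions and targets of one word presentation."""

    trial: int
    task: str
    predictions: np.ndarray   # int indices, one per position
    targets: np.ndarray
    cross_word: np.ndarray    # bool mask of positions excluded by default


def readout_activity(readout: ReadoutWeights, x: np.ndarray) -> np.ndarray:
    if readout.w_out.shape[1] != x.shape[0]:
        raise ValueError("reservoir state length does not match readout width")
    return readout.w_out @ x


def delta_rule_update(
    readout: ReadoutWeights, x: np.ndarray, target_one_hot: np.ndarray
) -> ReadoutWeights:
    """w_out <- w_out + mu * (target - output) x^T, in place."""
    output = readout_activity(readout, x)
    readout.w_out += readout.mu * np.outer(target_one_hot - output, x)
    return readout


def wta_predict(activity: np.ndarray) -> int:
    """Index of the maximum activity; the lowest index wins ties."""
    activity = np.asarray(activity)
    if activity.size == 0:
        raise ValueError("empty activity vector")
    return int(np.argmax(activity))


def trial_error_rate(record: TrialRecord, exclude_cross_word: bool = True) -> float:
    """Fraction of evaluated positions where prediction != target."""
    keep = ~record.cross_word if exclude_cross_word else np.ones_like(record.cross_word)
    keep = np.asarray(keep, dtype=bool)
    if not keep.any():
        raise ValueError("no positions left to evaluate")
    return float(np.mean(record.predictions[keep] != record.targets[keep]))
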