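"""SORN dynamics and plasticity rules.

The reservoir is a network of binary threshold units: ``n_excitatory``
excitatory units with sparse random recurrent connectivity and full
connectivity to/from a smaller inhibitory population.  One simulation step
consists of

1. a synchronous state update — an excitatory unit fires iff its total drive
   (recurrent excitation minus inhibition plus external input) strictly
   exceeds its threshold, then the inhibitory units respond to the *new*
   excitatory state;
2. STDP on existing excitatory-to-excitatory synapses (pre fires one step
   before post -> potentiation; the reverse order -> depression), clipped at
   zero;
3. synaptic normalization — each unit's incoming excitatory weights are
   rescaled to sum to one;
4. intrinsic plasticity — each excitatory threshold moves so the unit's
   long-run firing rate approaches the target ``h_ip``.

Weights between excitatory and inhibitory populations and the inhibitory
thresholds are fixed after initialization: plasticity only acts on the
excitatory sub-network.  Thresholds under intrinsic plasticity are not
clipped, so over-driven units can be silenced by arbitrarily high thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .params import ConfigurationError, SornParams

VALID_PLASTICITY_FLAGS = frozenset({"stdp", "sn", "ip"})


@dataclass
class NetworkState:
    """Binary activity and thresholds at one time step.

    ``x`` / ``y`` are 0/1 vectors over the excitatory / inhibitory units;
    only the excitatory thresholds change over time (intrinsic plasticity).
    """

    x: np.ndarray
    y: np.ndarray
    thresholds_e: np.ndarray
    thresholds_i: np.ndarray
    t: int = 0


@dataclass
class WeightMatrices:
    """The three connection matrices; entry (i, j) is the strength j -> i.

    ``w_ee`` is sparse with fixed support ``ee_mask`` (no self-connections,
    no structural plasticity); ``w_ei`` (inhibitory -> excitatory) and
    ``w_ie`` (excitatory -> inhibitory) are dense and static.  Every row of
    each matrix sums to one after initialization / normalization.
    """

    w_ee: np.ndarray
    ee_mask: np.ndarray
    w_ei: np.ndarray
    w_ie: np.ndarray

    def copy(self) -> "WeightMatrices":
        return WeightMatrices(
            self.w_ee.copy(), self.ee_mask.copy(), self.w_ei.copy(), self.w_ie.copy()
        )


@dataclass
class InputDrive:
    """External drive for one step: a 0/1 vector over the excitatory units."""

    v: np.ndarray
    active_symbol: str | None = None


def _row_normalize(w: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    return w / w.sum(axis=1, keepdims=True)


def init_network(params: SornParams, rng: np.random.Generator) -> tuple[NetworkState, WeightMatrices]:
    """Draw the initial network: random sparse E->E support, uniform weights
    row-normalized to sum one, uniform thresholds, all units silent.

    Rows of the E->E mask that come up empty are redrawn so synaptic
    normalization stays well defined for every unit.
    """
    params.validate()
    n_e, n_i = params.n_excitatory, params.n_inhibitory

    mask = rng.random((n_e, n_e)) < params.p_connect
    np.fill_diagonal(mask, False)
    # redraw any all-zero incoming row until it has at least one synapse
    for i in np.flatnonzero(~mask.any(axis=1)):
        while not mask[i].any():
            row = rng.random(n_e) < params.p_connect
            row[i] = False
            mask[i] = row

    w_ee = np.where(mask, rng.random((n_e, n_e)), 0.0)
    w_ee = _row_normalize(w_ee)
    w_ei = _row_normalize(rng.random((n_e, n_i)))
    w_ie = _row_normalize(rng.random((n_i, n_e)))

    state = NetworkState(
        x=np.zeros(n_e, dtype=np.int8),
        y=np.zeros(n_i, dtype=np.int8),
        thresholds_e=rng.uniform(0.0, params.t_max_e, size=n_e),
        thresholds_i=rng.uniform(0.0, params.t_max_i, size=n_i),
        t=0,
    )
    return state, WeightMatrices(w_ee, mask, w_ei, w_ie)


def update_state(state: NetworkState, weights: WeightMatrices, drive: InputDrive) -> NetworkState:
    """One synchronous state update (no plasticity).

    A unit fires iff its drive strictly exceeds its threshold; the inhibitory
    update uses the freshly computed excitatory state.
    """
    n_e = state.x.shape[0]
    if weights.w_ee.shape != (n_e, n_e) or drive.v.shape[0] != n_e:
        raise ValueError("inconsistent dimensions between state, weights and drive")
    total = weights.w_ee @ state.x - weights.w_ei @ state.y + drive.v - state.thresholds_e
    x_new = (total > 0).astype(np.int8)
    y_new = ((weights.w_ie @ x_new - state.thresholds_i) > 0).astype(np.int8)
    return NetworkState(
        x=x_new,
        y=y_new,
        thresholds_e=state.thresholds_e,
        thresholds_i=state.thresholds_i,
        t=state.t + 1,
    )


def stdp_update(
    weights: WeightMatrices,
    x_prev: np.ndarray,
    x_now: np.ndarray,
    eta_stdp: float,
) -> WeightMatrices:
    """Additive STDP on existing synapses, in place.

    dW_ij = eta * (x_i(t) x_j(t-1) - x_i(t-1) x_j(t)); weights clipped at 0.
    The support mask is never altered.
    """
    xp = np.asarray(x_prev, dtype=np.float64)
    xn = np.asarray(x_now, dtype=np.float64)
    dw = eta_stdp * (np.outer(xn, xp) - np.outer(xp, xn))
    weights.w_ee += np.where(weights.ee_mask, dw, 0.0)
    np.maximum(weights.w_ee, 0.0, out=weights.w_ee)
    return weights


def synaptic_normalize(weights: WeightMatrices) -> WeightMatrices:
    """Rescale each row of ``w_ee`` to sum to one, in place.

    A row whose synapses have all been driven to zero is left unchanged (with
    a warning): the degenerate unit keeps an empty weight vector rather than
    producing NaNs.
    """
    sums = weights.w_ee.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        warnings.warn(
            f"synaptic_normalize: {int(zero.sum())} row(s) sum to zero and were left unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
        sums = np.where(zero, 1.0, sums)
    weights.w_ee /= sums[:, None]
    return weights


def ip_update(
    thresholds_e: np.ndarray,
    x_now: np.ndarray,
    eta_ip: float,
    h_ip: float,
) -> np.ndarray:
    """Intrinsic plasticity: T_i <- T_i + eta_ip * (x_i - h_ip), unclipped."""
    return thresholds_e + eta_ip * (np.asarray(x_now, dtype=np.float64) - h_ip)


def sorn_step(
    state: NetworkState,
    weights: WeightMatrices,
    drive: InputDrive,
    params: SornParams,
    plasticity: Iterable[str] = ("stdp", "sn", "ip"),
) -> tuple[NetworkState, WeightMatrices]:
    """One composite step: state update, then STDP, normalization and
    intrinsic plasticity for whichever rules are enabled.

    ``weights`` is modified in place and returned.  Disabling all rules makes
    weights and thresholds constants of the run; the "without STDP and IP"
    control keeps synaptic normalization formally enabled (it is inert on
    already-normalized static weights).
    """
    flags = frozenset(plasticity)
    unknown = flags - VALID_PLASTICITY_FLAGS
    if unknown:
        raise ConfigurationError(f"unknown plasticity flags: {sorted(unknown)}")

    new_state = update_state(state, weights, drive)
    if "stdp" in flags:
        stdp_update(weights, state.x, new_state.x, params.eta_stdp)
    if "sn" in flags:
        synaptic_normalize(weights)
    if "ip" in flags:
        new_state.thresholds_e = ip_update(
            new_state.thresholds_e, new_state.x, params.eta_ip, params.h_ip
        )
    return new_state, weights
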