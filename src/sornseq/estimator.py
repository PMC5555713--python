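"""Scikit-learn style estimator wrapping the SORN reservoir and its readout.

:class:`SornSequenceLearner` is the package's central object: ``fit`` runs the
network through a training schedule (online plasticity plus delta-rule readout
training at every step), then evaluates any test blocks with plasticity and
readout frozen; ``predict`` returns winner-take-all next-element predictions
for a symbol sequence.  The functional plasticity rules in
:mod:`sornseq.network` define the semantics; the estimator's inner loop is an
algebraically equivalent fast path that exploits the sparsity of the binary
states (synaptic normalization only touches rows whose sums changed, which
leaves every other row's unit sum intact).

Fitted attributes follow sklearn conventions (``w_ee_``, ``thresholds_e_``,
``w_out_``, ``classes_``, ...), and the estimator composes with
``sklearn.base.clone`` and ``get_params``/``set_params``.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .metrics import ActivityRecord, WeightTrajectory
from .network import init_network, VALID_PLASTICITY_FLAGS
from .params import ConfigurationError, SornParams
from .tasks import SymbolSequence, TaskSet, TrainingSchedule, drive_stream


class SornSequenceLearner(BaseEstimator):
    """Self-organizing recurrent network with a winner-take-all readout.

    Parameters mirror :class:`~sornseq.params.SornParams` plus:

    plasticity : tuple of {"stdp", "sn", "ip"}
        Plasticity rules active during training.  The "without STDP and IP"
        control is ``("sn",)``.
    record_states : bool
        Record the binary excitatory state at every training/test step
        (required for separability, clustering, MI and PCA analyses).
    snapshot_times : iterable of int
        Training-step counts at which to store a copy of the E->E weight
        matrix (for weight-trajectory analyses).
    random_state : int, np.random.Generator or None
        Seed of the run's single random stream.

    Attributes (after ``fit``)
    --------------------------
    w_ee_, ee_mask_, w_ei_, w_ie_ : weight matrices
    thresholds_e_, thresholds_i_ : unit thresholds (excitatory ones adapt)
    w_out_ : readout weights, shape (n_symbols, n_excitatory)
    classes_ : the symbol alphabet, in encoding order
    n_steps_ : number of plasticity (training) steps performed
    snapshots_ : dict step -> copy of ``w_ee_``
    history_ : per-step records of the training run and frozen test blocks
    """

    def __init__(
        self,
        n_excitatory: int = 300,
        n_inhibitory: int | None = None,
        t_max_e: float = 0.5,
        t_max_i: float = 0.9,
        p_connect: float = 0.1,
        n_input_per_symbol: int = 10,
        eta_stdp: float = 1e-4,
        eta_ip: float = 0.002,
        h_ip: float = 0.1,
        mu_readout: float = 2e-5,
        plasticity: tuple = ("stdp", "sn", "ip"),
        readout_on_input_units: bool = False,
        record_states: bool = False,
        snapshot_times: tuple = (),
        random_state=None,
    ):
        self.n_excitatory = n_excitatory
        self.n_inhibitory = n_inhibitory
        self.t_max_e = t_max_e
        self.t_max_i = t_max_i
        self.p_connect = p_connect
        self.n_input_per_symbol = n_input_per_symbol
        self.eta_stdp = eta_stdp
        self.eta_ip = eta_ip
        self.h_ip = h_ip
        self.mu_readout = mu_readout
        self.plasticity = plasticity
        self.readout_on_input_units = readout_on_input_units
        self.record_states = record_states
        self.snapshot_times = snapshot_times
        self.random_state = random_state

    # ------------------------------------------------------------------ setup

    def _params(self) -> SornParams:
        return SornParams(
            n_excitatory=self.n_excitatory,
            n_inhibitory=self.n_inhibitory,
            t_max_e=self.t_max_e,
            t_max_i=self.t_max_i,
            p_connect=self.p_connect,
            n_input_per_symbol=self.n_input_per_symbol,
            eta_stdp=self.eta_stdp,
            eta_ip=self.eta_ip,
            h_ip=self.h_ip,
            mu_readout=self.mu_readout,
        )

    def _reset(self, task_set: TaskSet) -> None:
        flags = frozenset(self.plasticity)
        unknown = flags - VALID_PLASTICITY_FLAGS
        if unknown:
            raise ConfigurationError(f"unknown plasticity flags: {sorted(unknown)}")
        params = self._params()
        if isinstance(self.random_state, np.random.Generator):
            rng = self.random_state
        else:
            rng = np.random.default_rng(self.random_state)
        state, weights = init_network(params, rng)
        self._rng = rng
        self.task_set_ = task_set
        self.classes_ = np.asarray(task_set.alphabet, dtype=object)
        self._sym_index = {s: i for i, s in enumerate(task_set.alphabet)}
        self._units = [
            np.asarray(task_set.encoding.symbol_to_units[s], dtype=np.intp)
            for s in task_set.alphabet
        ]
        self.w_ee_ = weights.w_ee
        self.ee_mask_ = weights.ee_mask
        self.w_ei_ = weights.w_ei
        self.w_ie_ = weights.w_ie
        self.thresholds_e_ = state.thresholds_e
        self.thresholds_i_ = state.thresholds_i
        self.w_out_ = np.zeros((len(self.classes_), params.n_excitatory))
        # the readout reads the reservoir; input units are excluded by default
        self._readout_allowed = np.ones(params.n_excitatory, dtype=bool)
        if not self.readout_on_input_units:
            self._readout_allowed[list(task_set.encoding.all_units)] = False
        self._x = np.zeros(params.n_excitatory, dtype=bool)
        self._y = np.zeros(params.n_inhibitory, dtype=bool)
        self.n_steps_ = 0
        self.snapshots_: dict[int, np.ndarray] = {}
        self._snapshot_set = set(int(t) for t in self.snapshot_times)
        self.history_ = {"train": [], "tests": {}}
        self._warned_zero_rows = False
        if 0 in self._snapshot_set:
            self.snapshots_[0] = self.w_ee_.copy()

    # ------------------------------------------------------------- fast loop

    def _run_stream(
        self,
        steps: list,
        learn: bool,
        train_readout: bool,
        x: np.ndarray,
        y: np.ndarray,
        thresholds_e: np.ndarray,
        advance_clock: bool,
    ) -> dict:
        """Run the network over a materialized drive stream.

        Mutates ``x``/``y``/``thresholds_e`` in place; applies plasticity and
        readout training only when the corresponding flags are set.  Returns
        the per-step record arrays.
        """
        flags = frozenset(self.plasticity) if learn else frozenset()
        stdp_on = "stdp" in flags
        sn_on = "sn" in flags
        ip_on = "ip" in flags
        w_ee, mask = self.w_ee_, self.ee_mask_
        w_ei, w_ie, w_out = self.w_ei_, self.w_ie_, self.w_out_
        t_i = self.thresholds_i_
        eta, eta_ip, h_ip, mu = self.eta_stdp, self.eta_ip, self.h_ip, self.mu_readout
        n_e = w_ee.shape[0]
        T = len(steps)

        sym_idx = np.fromiter((self._sym_index[s.symbol] for s in steps), dtype=np.intp, count=T)
        tgt_idx = np.fromiter((self._sym_index[s.target] for s in steps), dtype=np.intp, count=T)
        preds = np.zeros(T, dtype=np.intp)
        states = np.zeros((T, n_e), dtype=np.int8) if self.record_states else None

        act = np.flatnonzero(x)
        y_act = np.flatnonzero(y)
        units = self._units
        ro_allowed = self._readout_allowed
        snap = self._snapshot_set if (learn and advance_clock) else ()
        t_clock = self.n_steps_

        for t in range(T):
            drive = w_ee[:, act].sum(axis=1) if act.size else np.zeros(n_e)
            if y_act.size:
                drive -= w_ei[:, y_act].sum(axis=1)
            drive[units[sym_idx[t]]] += 1.0
            x_new = drive > thresholds_e
            act_new = np.flatnonzero(x_new)
            inh = w_ie[:, act_new].sum(axis=1) if act_new.size else np.zeros(t_i.shape[0])
            y_act = np.flatnonzero(inh > t_i)

            if stdp_on and act.size and act_new.size:
                pot = np.ix_(act_new, act)
                dep = np.ix_(act, act_new)
                w_ee[pot] += eta * mask[pot]
                w_ee[dep] -= eta * mask[dep]
                w_ee[dep] = np.maximum(w_ee[dep], 0.0)
                if sn_on:
                    dirty = np.union1d(act_new, act)
                    sums = w_ee[dirty].sum(axis=1)
                    zero = sums <= 0
                    if zero.any() and not self._warned_zero_rows:
                        warnings.warn(
                            "synaptic normalization skipped rows whose weights are all zero",
                            RuntimeWarning,
                        )
                        self._warned_zero_rows = True
                    sums = np.where(zero, 1.0, sums)
                    w_ee[dirty] = w_ee[dirty] / sums[:, None]
            if ip_on:
                thresholds_e += eta_ip * (x_new - h_ip)

            r_act = act_new[ro_allowed[act_new]] if act_new.size else act_new
            out = w_out[:, r_act].sum(axis=1) if r_act.size else np.zeros(w_out.shape[0])
            preds[t] = np.argmax(out)
            if train_readout:
                err = -out
                err[tgt_idx[t]] += 1.0
                if r_act.size:
                    w_out[:, r_act] += mu * err[:, None]

            if states is not None:
                states[t, act_new] = 1
            act = act_new
            if snap:
                t_clock += 1
                if t_clock in snap:
                    self.snapshots_[t_clock] = w_ee.copy()

        x[:] = False
        x[act] = True
        y[:] = False
        y[y_act] = True
        if advance_clock and learn:
            self.n_steps_ += T

        return {
            "symbol": np.array([s.symbol for s in steps], dtype=object),
            "target": np.array([s.target for s in steps], dtype=object),
            "prediction": self.classes_[preds],
            "cross_word": np.array([s.cross_word for s in steps], dtype=bool),
            "task": np.array([s.task for s in steps], dtype=object),
            "trial": np.array([s.trial for s in steps], dtype=np.int64),
            "task_trial": np.array([s.task_trial for s in steps], dtype=np.int64),
            "position": np.array([s.position for s in steps], dtype=np.int64),
            "states": states,
        }

    # ------------------------------------------------------------ public API

    def fit(self, X: TaskSet, y=None, schedule: TrainingSchedule | None = None):
        """Train on the schedule of the task set ``X``, then run its test
        blocks with plasticity and readout frozen.

        Each test block starts from a copy of the end-of-training dynamic
        state, so the order of tested sequences is irrelevant.
        """
        if not isinstance(X, TaskSet):
            raise TypeError("X must be a TaskSet")
        schedule = schedule or X.schedule
        if schedule is None:
            raise ConfigurationError("the task set carries no training schedule")
        self._reset(X)
        self._fit_more(X, schedule)
        return self

    def partial_fit(self, X: TaskSet, y=None, schedule: TrainingSchedule | None = None):
        """Continue training on another schedule without reinitializing."""
        schedule = schedule or X.schedule
        if schedule is None:
            raise ConfigurationError("the task set carries no training schedule")
        if not hasattr(self, "w_ee_"):
            self._reset(X)
        self._fit_more(X, schedule)
        return self

    def _fit_more(self, task_set: TaskSet, schedule: TrainingSchedule) -> None:
        steps = list(drive_stream(task_set, schedule))
        rec = self._run_stream(
            steps,
            learn=True,
            train_readout=True,
            x=self._x,
            y=self._y,
            thresholds_e=self.thresholds_e_,
            advance_clock=True,
        )
        self.history_["train"].append(rec)
        for seq_name, reps in schedule.test_blocks:
            self.history_["tests"][seq_name] = self.evaluate(seq_name, reps)

    def evaluate(self, seq_name: str, n_words: int = 20) -> dict:
        """Frozen-plasticity evaluation of one sequence from a copy of the
        current dynamic state (the network itself is left untouched)."""
        sched = TrainingSchedule(blocks=[(seq_name, n_words)])
        steps = list(drive_stream(self.task_set_, sched))
        return self._run_stream(
            steps,
            learn=False,
            train_readout=False,
            x=self._x.copy(),
            y=self._y.copy(),
            thresholds_e=self.thresholds_e_.copy(),
            advance_clock=False,
        )

    def predict(self, X) -> np.ndarray:
        """Winner-take-all next-element prediction for each step of a symbol
        sequence, run with frozen weights from the current dynamic state."""
        symbols = tuple(X.symbols) if isinstance(X, SymbolSequence) else tuple(X)
        seq = SymbolSequence("_query", symbols)
        missing = set(symbols) - set(self.classes_)
        if missing:
            raise ValueError(f"symbols outside the fitted alphabet: {sorted(missing)}")
        ts = TaskSet(
            tuple(self.classes_),
            {**{s.name: s for s in self.task_set_.sequences.values()}, "_query": seq},
            self.task_set_.encoding,
        )
        sched = TrainingSchedule(blocks=[("_query", 1)])
        steps = list(drive_stream(ts, sched))
        rec = self._run_stream(
            steps,
            learn=False,
            train_readout=False,
            x=self._x.copy(),
            y=self._y.copy(),
            thresholds_e=self.thresholds_e_.copy(),
            advance_clock=False,
        )
        return rec["prediction"]

    def score(self, X, y=None) -> float:
        """Next-element prediction accuracy over within-word transitions."""
        preds = self.predict(X)
        symbols = tuple(X.symbols) if isinstance(X, SymbolSequence) else tuple(X)
        truth = np.asarray(symbols[1:], dtype=object)
        return float(np.mean(preds[:-1] == truth))

    # --------------------------------------------------------------- outputs

    def _concat_train(self) -> dict:
        segs = self.history_["train"]
        if not segs:
            raise RuntimeError("estimator has no training history; call fit first")
        out = {}
        for key in segs[0]:
            if key == "states":
                parts = [s["states"] for s in segs]
                out[key] = np.concatenate(parts) if parts[0] is not None else None
            else:
                out[key] = np.concatenate([s[key] for s in segs])
        # make trial indices globally increasing across segments
        offset, trials = 0, []
        for s in segs:
            trials.append(s["trial"] + offset)
            offset += s["trial"][-1] + 1 if len(s["trial"]) else 0
        out["trial"] = np.concatenate(trials)
        return out

    def training_record(self) -> ActivityRecord:
        """The training run as an :class:`ActivityRecord` (needs record_states)."""
        rec = self._concat_train()
        if rec["states"] is None:
            raise RuntimeError("states were not recorded; construct with record_states=True")
        return ActivityRecord(
            states=rec["states"],
            symbols=rec["symbol"].astype(str),
            positions=rec["position"],
            words=rec["trial"],
            tasks=rec["task"].astype(str),
            input_units=np.asarray(self.task_set_.encoding.all_units, dtype=int),
        )

    def test_record(self, seq_name: str) -> ActivityRecord:
        rec = self.history_["tests"][seq_name]
        if rec["states"] is None:
            raise RuntimeError("states were not recorded; construct with record_states=True")
        return ActivityRecord(
            states=rec["states"],
            symbols=rec["symbol"].astype(str),
            positions=rec["position"],
            words=rec["trial"],
            tasks=rec["task"].astype(str),
            input_units=np.asarray(self.task_set_.encoding.all_units, dtype=int),
        )

    def steps_frame(self, phase: str = "train", seq_name: str | None = None) -> pd.DataFrame:
        """Tidy per-step table (symbol, target, prediction, labels)."""
        if phase == "train":
            rec = self._concat_train()
        elif phase == "test":
            if seq_name is None:
                frames = []
                for name in self.history_["tests"]:
                    df = self.steps_frame("test", name)
                    frames.append(df)
                return pd.concat(frames, ignore_index=True)
            rec = self.history_["tests"][seq_name]
        else:
            raise ValueError("phase must be 'train' or 'test'")
        df = pd.DataFrame({k: v for k, v in rec.items() if k != "states"})
        df["correct"] = df["prediction"] == df["target"]
        df["phase"] = phase
        return df

    def trial_errors(self, phase: str = "train", exclude_cross_word: bool = True) -> pd.DataFrame:
        """Per-trial readout error rate (cross-word transitions excluded by default)."""
        df = self.steps_frame(phase)
        if exclude_cross_word:
            df = df[~df["cross_word"]]
        g = df.groupby(["task", "trial", "task_trial"], sort=True)["correct"]
        out = (1.0 - g.mean()).rename("error_rate").reset_index()
        return out.sort_values("trial").reset_index(drop=True)

    def weight_trajectory(self) -> WeightTrajectory:
        if len(self.snapshots_) < 2:
            raise RuntimeError("need at least two weight snapshots")
        return WeightTrajectory.from_dict(self.snapshots_)
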