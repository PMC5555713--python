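"""Reproducible drivers for the five simulation protocols.

* ``run_panzer_exp1`` / ``run_panzer_exp2`` — the two-arm-movement-sequence
  protocols: train S1 then S2 (equal training, or S1 twice as long), with
  single-sequence control arms, frozen-plasticity test blocks, and per-word
  separability as the performance proxy.
* ``run_koedijker`` — the 8-button finger-tapping pairs, analyzed per target
  position to expose button-specific proactive facilitation.
* ``run_blocked_vs_interleaved`` — three disjoint 8-element sequences trained
  either in three contiguous blocks or fully interleaved, compared on test
  error rates.
* ``run_similarity_schedule_grid`` — the task-similarity x schedule grid of
  mean anterograde and retrograde effects on readout error rates.
* ``robustness_sweep`` — the main protocol re-run across connection
  probabilities and inhibitory/excitatory ratios.

Every driver is a pure function of its configuration and seeds: rerunning
with the same arguments reproduces results bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .estimator import SornSequenceLearner
from .metrics import ActivityRecord, separability
from .params import SornParams
from .tasks import (
    TaskSet,
    TrainingSchedule,
    build_schedule,
    canonical_koedijker_tasks,
    canonical_panzer_tasks,
    generate_task_set,
)

DEFAULT_PLASTICITY = ("stdp", "sn", "ip")

# For each button pair: which buttons differ between the sequences, and which
# target positions involve a changed movement (a changed button also alters
# the movement into the following button for adjacent changes).
KOEDIJKER_CHANGED = {
    "buttons_4_5": {"buttons": (4, 5), "unfacilitated": (4, 5, 6)},
    "buttons_4_7": {"buttons": (4, 7), "unfacilitated": (4, 7)},
}


@dataclass
class ExperimentConfig:
    params: SornParams = field(default_factory=SornParams)
    experiment: str = "panzer1"
    seeds: list[int] = field(default_factory=lambda: list(range(10)))
    options: dict = field(default_factory=dict)


@dataclass
class RunResult:
    """One seed of one experimental arm."""

    seed: int
    arm: str
    learner: SornSequenceLearner
    trials: pd.DataFrame       # per training word: task, trial, error_rate[, separability]
    tests: pd.DataFrame        # per test word: sequence, trial, error_rate[, separability]


@dataclass
class ExperimentResult:
    name: str
    runs: list[RunResult]

    def runs_for(self, arm: str) -> list[RunResult]:
        return [r for r in self.runs if r.arm == arm]

    @property
    def arms(self) -> list[str]:
        return sorted({r.arm for r in self.runs})


@dataclass
class EffectGrid:
    """Mean anterograde/retrograde effects over a similarity x schedule grid.

    Positive values are facilitation, negative interference, in units of
    error-rate difference.
    """

    similarities: np.ndarray
    n_blocks: np.ndarray
    anterograde: np.ndarray    # (n_similarities, n_schedules)
    retrograde: np.ndarray
    n_reps: int


# --------------------------------------------------------------------- helpers

def _sep_by_trial(record: ActivityRecord) -> np.ndarray:
    """Separability of each word-aligned window of a recorded run."""
    starts = np.flatnonzero(record.positions == 0)
    ends = np.append(starts[1:], len(record))
    return np.array(
        [separability(record, int(s), int(e - s)) for s, e in zip(starts, ends)]
    )


def _run_one(
    params: SornParams,
    task_set: TaskSet,
    schedule: TrainingSchedule,
    seed: int,
    arm: str,
    plasticity: tuple = DEFAULT_PLASTICITY,
    record_states: bool = False,
    snapshot_times: tuple = (),
) -> RunResult:
    learner = SornSequenceLearner(
        n_excitatory=params.n_excitatory,
        n_inhibitory=params.n_inhibitory,
        t_max_e=params.t_max_e,
        t_max_i=params.t_max_i,
        p_connect=params.p_connect,
        n_input_per_symbol=params.n_input_per_symbol,
        eta_stdp=params.eta_stdp,
        eta_ip=params.eta_ip,
        h_ip=params.h_ip,
        mu_readout=params.mu_readout,
        plasticity=plasticity,
        record_states=record_states,
        snapshot_times=snapshot_times,
        random_state=seed,
    )
    learner.fit(task_set, schedule=schedule)

    trials = learner.trial_errors("train")
    if record_states:
        trials = trials.copy()
        trials["separability"] = _sep_by_trial(learner.training_record())[trials["trial"].values]

    test_rows = []
    for seq_name in learner.history_["tests"]:
        df = learner.steps_frame("test", seq_name)
        df = df[~df["cross_word"]]
        err = (1.0 - df.groupby("trial")["correct"].mean()).rename("error_rate").reset_index()
        err.insert(0, "sequence", seq_name)
        if record_states:
            err["separability"] = _sep_by_trial(learner.test_record(seq_name))[err["trial"].values]
        test_rows.append(err)
    tests = pd.concat(test_rows, ignore_index=True) if test_rows else pd.DataFrame(
        columns=["sequence", "trial", "error_rate"]
    )
    return RunResult(seed=seed, arm=arm, learner=learner, trials=trials, tests=tests)


# -------------------------------------------------------- arm-movement protocols

def _panzer(
    params: SornParams | None,
    seeds: Sequence[int],
    words_s1: int,
    words_s2: int,
    arms: Sequence[str],
    plasticity: tuple,
    record_states: bool,
    snapshot_window: int,
    test_words: int,
    name: str,
) -> ExperimentResult:
    params = params or SornParams()
    task_set = canonical_panzer_tasks(params.n_input_per_symbol, params.n_excitatory)
    word_len = len(task_set.sequences["S1"])
    switch = words_s1 * word_len
    schedules = {
        "experimental": TrainingSchedule(
            blocks=[("S1", words_s1), ("S2", words_s2)],
            test_blocks=[("S1", test_words), ("S2", test_words)],
        ),
        "control_s1": TrainingSchedule(
            blocks=[("S1", words_s1)],
            test_blocks=[("S1", test_words), ("S2", test_words)],
        ),
        "control_s2": TrainingSchedule(
            blocks=[("S2", words_s2)],
            test_blocks=[("S1", test_words), ("S2", test_words)],
        ),
    }
    runs = []
    for seed in seeds:
        for arm in arms:
            snaps = ()
            if arm == "experimental" and snapshot_window > 0:
                snaps = (switch - snapshot_window, switch, switch + snapshot_window)
            runs.append(
                _run_one(
                    params,
                    task_set,
                    schedules[arm],
                    seed,
                    arm,
                    plasticity=plasticity,
                    record_states=record_states,
                    snapshot_times=snaps,
                )
            )
    return ExperimentResult(name=name, runs=runs)


def run_panzer_exp1(
    params: SornParams | None = None,
    seeds: Sequence[int] = tuple(range(10)),
    arms: Sequence[str] = ("experimental", "control_s1", "control_s2"),
    plasticity: tuple = DEFAULT_PLASTICITY,
    record_states: bool = True,
    snapshot_window: int = 1600,
    words_per_sequence: int = 400,
    test_words: int = 20,
) -> ExperimentResult:
    """Equal S1/S2 training (400 words = 8000 steps each)."""
    return _panzer(
        params, seeds, words_per_sequence, words_per_sequence, arms, plasticity,
        record_states, snapshot_window, test_words, "panzer1",
    )


def run_panzer_exp2(
    params: SornParams | None = None,
    seeds: Sequence[int] = tuple(range(10)),
    arms: Sequence[str] = ("experimental", "control_s1", "control_s2"),
    plasticity: tuple = DEFAULT_PLASTICITY,
    record_states: bool = True,
    snapshot_window: int = 1600,
    words_s2: int = 400,
    test_words: int = 20,
) -> ExperimentResult:
    """S1 trained twice as long (800 words = 16000 steps) before S2."""
    return _panzer(
        params, seeds, 2 * words_s2, words_s2, arms, plasticity,
        record_states, snapshot_window, test_words, "panzer2",
    )


def panzer_summary(result: ExperimentResult, early_words: int = 20, last_words: int = 20) -> pd.DataFrame:
    """Per-seed separability summary of the experimental arm.

    Columns: mean separability over the first ``early_words`` words of S1 and
    of S2 training, over the last words of S1 training, and over the test
    blocks of each sequence.
    """
    rows = []
    for run in result.runs_for("experimental"):
        tr = run.trials
        s1 = tr[tr["task"] == "S1"]
        s2 = tr[tr["task"] == "S2"]
        te = run.tests
        row = {"seed": run.seed}
        row.update(
            {
                "early_err_s1": s1.nsmallest(early_words, "task_trial")["error_rate"].mean(),
                "early_err_s2": s2.nsmallest(early_words, "task_trial")["error_rate"].mean(),
                "end_err_s1": s1.nlargest(last_words, "task_trial")["error_rate"].mean(),
                "end_err_s2": s2.nlargest(last_words, "task_trial")["error_rate"].mean(),
                "test_err_s1": te[te["sequence"] == "S1"]["error_rate"].mean(),
                "test_err_s2": te[te["sequence"] == "S2"]["error_rate"].mean(),
            }
        )
        if "separability" in tr.columns:
            row.update(
                {
                    "early_s1": s1.nsmallest(early_words, "task_trial")["separability"].mean(),
                    "early_s2": s2.nsmallest(early_words, "task_trial")["separability"].mean(),
                    "end_s1": s1.nlargest(last_words, "task_trial")["separability"].mean(),
                    "end_s2": s2.nlargest(last_words, "task_trial")["separability"].mean(),
                    "test_s1": te[te["sequence"] == "S1"]["separability"].mean(),
                    "test_s2": te[te["sequence"] == "S2"]["separability"].mean(),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ effect sizes

def anterograde_effect(
    run: RunResult, first_k_trials: int = 10, tasks: tuple[str, str] = ("S1", "S2")
) -> float:
    """err(first task, first k trials) - err(second task, first k trials);
    positive = facilitation of the later task."""
    a, b = tasks
    tr = run.trials
    early = {
        t: tr[tr["task"] == t].nsmallest(first_k_trials, "task_trial")["error_rate"]
        for t in (a, b)
    }
    for t, e in early.items():
        if len(e) < first_k_trials:
            raise ValueError(f"task {t!r} has fewer than {first_k_trials} training trials")
    return float(early[a].mean() - early[b].mean())


def retrograde_effect(run: RunResult, task: str = "S1", last_k_trials: int = 5) -> float:
    """err(end of training, last k trials) - err(test, last k trials);
    positive = facilitation (test better than end of training)."""
    tr = run.trials[run.trials["task"] == task]
    te = run.tests
    te = te[te["sequence"] == task] if "sequence" in te.columns else te.iloc[0:0]
    if te.empty:
        raise ValueError(f"no test block for task {task!r}")
    end_err = tr.nlargest(last_k_trials, "task_trial")["error_rate"].mean()
    test_err = te.nlargest(last_k_trials, "trial")["error_rate"].mean()
    return float(end_err - test_err)


# ------------------------------------------------------------- finger tapping

def run_koedijker(
    params: SornParams | None = None,
    pair: str = "buttons_4_5",
    seeds: Sequence[int] = tuple(range(10)),
    words_per_sequence: int = 200,
    plasticity: tuple = DEFAULT_PLASTICITY,
    test_words: int = 20,
) -> ExperimentResult:
    """Train S1 then S2 of a button pair; per-position errors expose
    button-specific proactive facilitation."""
    params = params or SornParams()
    task_set = canonical_koedijker_tasks(pair, params.n_input_per_symbol, params.n_excitatory)
    schedule = TrainingSchedule(
        blocks=[("S1", words_per_sequence), ("S2", words_per_sequence)],
        test_blocks=[("S1", test_words), ("S2", test_words)],
    )
    runs = [
        _run_one(params, task_set, schedule, seed, "experimental", plasticity=plasticity)
        for seed in seeds
    ]
    return ExperimentResult(name=f"koedijker_{pair}", runs=runs)


def koedijker_facilitation(result: ExperimentResult, first_trials: int = 20) -> pd.DataFrame:
    """Per-seed, per-target-position proactive facilitation.

    For each 1-based target position p (2..L), the difference between the
    early-S1 and early-S2 error rate of predicting the element at p
    (positive = S2 starts better than S1 did = facilitation).
    """
    rows = []
    for run in result.runs:
        df = run.learner.steps_frame("train")
        df = df[~df["cross_word"]]
        early = df[df["task_trial"] < first_trials]
        for p, sub in early.groupby("position"):
            e = 1.0 - sub.groupby("task")["correct"].mean()
            rows.append(
                {
                    "seed": run.seed,
                    "target_position": int(p) + 2,   # element being predicted, 1-based
                    "err_s1": float(e.get("S1", np.nan)),
                    "err_s2": float(e.get("S2", np.nan)),
                    "facilitation": float(e.get("S1", np.nan) - e.get("S2", np.nan)),
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------- blocked vs interleaved & grid

def run_blocked_vs_interleaved(
    params: SornParams | None = None,
    seeds: Sequence[int] = tuple(range(10)),
    trials_per_task: int = 200,
    sequence_length: int = 8,
    n_tasks: int = 3,
    test_words: int = 20,
) -> ExperimentResult:
    """Blocked vs fully interleaved training of disjoint sequences.

    Both schedules use the same tasks, trial counts and network seed; arms are
    named ``"blocked"`` and ``"interleaved"``.
    """
    params = params or SornParams()
    runs = []
    for seed in seeds:
        rng = np.random.default_rng([int(seed), 9000])
        task_set = generate_task_set(
            sequence_length, 0.0, n_tasks, rng,
            params.n_input_per_symbol, params.n_excitatory,
        )
        names = sorted(task_set.sequences)
        for kind in ("blocked", "interleaved"):
            sched = build_schedule(kind, trials_per_task, names, rng=rng, test_trials=test_words)
            runs.append(_run_one(params, task_set, sched, seed, kind))
    return ExperimentResult(name="blocked_vs_interleaved", runs=runs)


def mean_test_errors(result: ExperimentResult) -> pd.DataFrame:
    """Mean test error per (arm, seed, sequence)."""
    rows = []
    for run in result.runs:
        g = run.tests.groupby("sequence")["error_rate"].mean()
        for seq, err in g.items():
            rows.append({"arm": run.arm, "seed": run.seed, "sequence": seq, "error_rate": err})
    return pd.DataFrame(rows)


def run_similarity_schedule_grid(
    params: SornParams | None = None,
    similarities: Sequence[float] = tuple(np.arange(8) * 0.125),
    n_blocks: Sequence[int] = (3, 6, 12, 24, 50, 100, 200, 400, 600),
    n_reps: int = 40,
    base_seed: int = 0,
    trials_per_task: int = 200,
    sequence_length: int = 8,
    n_tasks: int = 3,
    first_k_trials: int = 10,
    last_k_trials: int = 5,
    test_words: int = 20,
) -> EffectGrid:
    """Mean anterograde and retrograde effects over the full similarity x
    schedule grid, averaged over ``n_reps`` randomly generated task families
    per cell."""
    params = params or SornParams()
    sims = np.asarray(similarities, dtype=float)
    blocks = np.asarray(n_blocks, dtype=int)
    antero = np.zeros((len(sims), len(blocks)))
    retro = np.zeros((len(sims), len(blocks)))
    for i, sim in enumerate(sims):
        for j, nb in enumerate(blocks):
            a_vals, r_vals = [], []
            for rep in range(n_reps):
                rng = np.random.default_rng([int(base_seed), i, j, rep])
                task_set = generate_task_set(
                    sequence_length, float(sim), n_tasks, rng,
                    params.n_input_per_symbol, params.n_excitatory,
                )
                names = sorted(task_set.sequences)
                sched = build_schedule(
                    "n_blocks", trials_per_task, names, rng=rng,
                    n_blocks=int(nb), test_trials=test_words,
                )
                net_seed = int(rng.integers(2**31))
                run = _run_one(params, task_set, sched, net_seed, f"sim{sim}_nb{nb}")
                a_vals.append(anterograde_effect(run, first_k_trials, ("S1", "S2")))
                r_vals.append(retrograde_effect(run, "S1", last_k_trials))
            antero[i, j] = np.mean(a_vals)
            retro[i, j] = np.mean(r_vals)
    return EffectGrid(
        similarities=sims, n_blocks=blocks,
        anterograde=antero, retrograde=retro, n_reps=n_reps,
    )


# ---------------------------------------------------------------- robustness

def exp1_contrasts(result: ExperimentResult, early_words: int = 20) -> pd.DataFrame:
    """Per-seed facilitation/interference contrasts of the main protocol.

    ``facilitation``: early-S2 minus early-S1 separability (expected > 0);
    ``interference``: tested S2 minus tested S1 separability (positive would
    indicate retroactive interference on S1 in the separability proxy);
    ``err_interference``: tested S1 minus tested S2 readout error (expected
    > 0 — the later-trained sequence is predicted better at test).
    """
    s = panzer_summary(result, early_words=early_words)
    out = {
        "seed": s["seed"],
        "err_interference": s["test_err_s1"] - s["test_err_s2"],
    }
    if "early_s1" in s.columns:
        out["facilitation"] = s["early_s2"] - s["early_s1"]
        out["interference"] = s["test_s2"] - s["test_s1"]
    return pd.DataFrame(out)


def robustness_sweep(
    params: SornParams | None = None,
    p_connect_values: Sequence[float] = (0.05, 0.1, 0.15),
    ratio_values: Sequence[float] = (0.1, 0.2, 0.4),
    seeds: Sequence[int] = tuple(range(10)),
    words_per_sequence: int = 400,
) -> dict[str, pd.DataFrame]:
    """Re-run the main protocol (experimental arm) across connection
    probabilities and inhibitory/excitatory ratios; returns per-setting
    contrast tables from :func:`exp1_contrasts`."""
    params = params or SornParams()
    out: dict[str, pd.DataFrame] = {}
    for p in p_connect_values:
        pp = replace(params, p_connect=p)
        res = run_panzer_exp1(
            pp, seeds, arms=("experimental",), snapshot_window=0,
            words_per_sequence=words_per_sequence,
        )
        out[f"p_connect={p}"] = exp1_contrasts(res)
    for r in ratio_values:
        pp = replace(params, n_inhibitory=int(round(r * params.n_excitatory)))
        res = run_panzer_exp1(
            pp, seeds, arms=("experimental",), snapshot_window=0,
            words_per_sequence=words_per_sequence,
        )
        out[f"ni_ratio={r}"] = exp1_contrasts(res)
    return out
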