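"""Configuration files, result serialization, checkpoints and test fixtures.

Configs are YAML mirrors of :class:`~sornseq.experiments.ExperimentConfig`
(omitted network parameters fall back to the model defaults).  Results are
written as human-diffable JSON summaries plus tidy CSV tables; network
checkpoints go into a compressed array container that round-trips the full
dynamic state including the random stream.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimator import SornSequenceLearner
from .experiments import ExperimentConfig, ExperimentResult, mean_test_errors
from .params import ConfigurationError, SornParams
from .tasks import TaskSet, TrainingSchedule, generate_task_set

KNOWN_EXPERIMENTS = (
    "panzer1",
    "panzer2",
    "koedijker45",
    "koedijker47",
    "blocked-vs-interleaved",
    "grid",
    "robustness",
)


@dataclass
class RunManifest:
    config_hash: str
    code_version: str
    seeds: list[int]
    created: str
    files: list[str] = field(default_factory=list)


def config_hash(config: ExperimentConfig) -> str:
    payload = {
        "params": config.params.to_dict(),
        "experiment": config.experiment,
        "seeds": list(config.seeds),
        "options": config.options,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    """Read and validate an experiment config; omitted network parameters
    take the model defaults."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} must contain a mapping")
    known = {"experiment", "seeds", "params", "options"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    experiment = raw.get("experiment", "panzer1")
    if experiment not in KNOWN_EXPERIMENTS:
        raise ConfigurationError(
            f"unknown experiment {experiment!r}; choose from {KNOWN_EXPERIMENTS}"
        )
    seeds = list(raw.get("seeds", range(10)))
    if not seeds:
        raise ConfigurationError("at least one seed is required")
    params = SornParams.from_dict(raw.get("params", {}) or {})
    options = raw.get("options", {}) or {}
    return ExperimentConfig(params=params, experiment=experiment, seeds=seeds, options=options)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    payload = {
        "experiment": config.experiment,
        "seeds": list(config.seeds),
        "params": config.params.to_dict(),
        "options": config.options,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def summarize(result: ExperimentResult) -> dict:
    """JSON-serializable summary: per-arm/seed test statistics and mean
    training error of the final trials."""
    test_df = mean_test_errors(result)
    summary: dict = {"experiment": result.name, "arms": {}}
    for arm in result.arms:
        runs = result.runs_for(arm)
        arm_summary: dict = {"seeds": [r.seed for r in runs]}
        sub = test_df[test_df["arm"] == arm]
        arm_summary["test_error_by_sequence"] = {
            seq: float(v) for seq, v in sub.groupby("sequence")["error_rate"].mean().items()
        }
        if "separability" in runs[0].tests.columns:
            seps = pd.concat([r.tests for r in runs])
            arm_summary["test_separability_by_sequence"] = {
                seq: float(v) for seq, v in seps.groupby("sequence")["separability"].mean().items()
            }
        summary["arms"][arm] = arm_summary
    return summary


def save_results(
    result: ExperimentResult, outdir: str | Path, config: ExperimentConfig | None = None
) -> RunManifest:
    """Write results.json plus tidy trials/tests CSVs; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []

    trials = pd.concat(
        [r.trials.assign(seed=r.seed, arm=r.arm) for r in result.runs], ignore_index=True
    )
    tests = pd.concat(
        [r.tests.assign(seed=r.seed, arm=r.arm) for r in result.runs], ignore_index=True
    )
    for name, df in (("trials.csv", trials), ("tests.csv", tests)):
        df.to_csv(outdir / name, index=False)
        files.append(name)

    with open(outdir / "results.json", "w") as fh:
        json.dump(summarize(result), fh, indent=2, sort_keys=True)
    files.append("results.json")

    manifest = RunManifest(
        config_hash=config_hash(config) if config else "",
        code_version=__version__,
        seeds=sorted({r.seed for r in result.runs}),
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        files=files,
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return manifest


# ----------------------------------------------------------------- checkpoints

def save_checkpoint(learner: SornSequenceLearner, path: str | Path) -> None:
    """Store weights, thresholds, dynamic state, readout, clock and the random
    stream of a fitted estimator."""
    rng_state = json.dumps(learner._rng.bit_generator.state)
    np.savez_compressed(
        path,
        w_ee=learner.w_ee_,
        ee_mask=learner.ee_mask_,
        w_ei=learner.w_ei_,
        w_ie=learner.w_ie_,
        thresholds_e=learner.thresholds_e_,
        thresholds_i=learner.thresholds_i_,
        w_out=learner.w_out_,
        x=learner._x,
        y=learner._y,
        n_steps=learner.n_steps_,
        params=json.dumps(learner._params().to_dict()),
        rng_state=rng_state,
    )


def load_checkpoint(path: str | Path, task_set: TaskSet) -> SornSequenceLearner:
    """Rebuild an estimator from a checkpoint; the task set supplies the
    alphabet and encoding (they are not stored in the container)."""
    with np.load(path, allow_pickle=False) as data:
        params = SornParams.from_dict(json.loads(str(data["params"])))
        learner = SornSequenceLearner(
            **{k: v for k, v in params.to_dict().items() if k != "seed"}
        )
        learner._reset(task_set)
        learner.w_ee_[:] = data["w_ee"]
        learner.ee_mask_[:] = data["ee_mask"]
        learner.w_ei_[:] = data["w_ei"]
        learner.w_ie_[:] = data["w_ie"]
        learner.thresholds_e_[:] = data["thresholds_e"]
        learner.thresholds_i_[:] = data["thresholds_i"]
        learner.w_out_[:] = data["w_out"]
        learner._x[:] = data["x"]
        learner._y[:] = data["y"]
        learner.n_steps_ = int(data["n_steps"])
        learner._rng.bit_generator.state = json.loads(str(data["rng_state"]))
    return learner


# -------------------------------------------------------------------- fixtures

FIXTURE_KINDS = ("tiny-network", "toy-tasks", "labeled-record")


def make_fixture(kind: str, rng: np.random.Generator):
    """Deterministic miniature instances for fast tests.

    ``tiny-network`` -> a 20-unit learner fitted on toy tasks for a few words;
    ``toy-tasks`` -> two length-4 sequences with similarity 0.5;
    ``labeled-record`` -> a small labeled :class:`ActivityRecord`.
    """
    if kind == "toy-tasks":
        seed = int(rng.integers(2**31))
        ts = generate_task_set(
            4, 0.5, 2, np.random.default_rng(seed), n_input_per_symbol=2, n_excitatory=20
        )
        names = sorted(ts.sequences)
        return ts.with_schedule(
            TrainingSchedule(blocks=[(n, 10) for n in names], test_blocks=[(n, 5) for n in names])
        )
    if kind in ("tiny-network", "labeled-record"):
        ts = make_fixture("toy-tasks", rng)
        learner = SornSequenceLearner(
            n_excitatory=20,
            n_input_per_symbol=2,
            record_states=True,
            random_state=int(rng.integers(2**31)),
        )
        learner.fit(ts)
        if kind == "tiny-network":
            return learner
        return learner.training_record()
    raise ConfigurationError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
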