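"""Symbol sequences, input encodings, canonical tasks and training schedules.

A *task set* bundles an alphabet of input symbols, one named sequence per
task, and an encoding that maps each symbol onto a disjoint group of
``n_input_per_symbol`` excitatory input units.  A *training schedule* is an
ordered list of blocks, each presenting one sequence for a number of word
repetitions, optionally followed by frozen-plasticity test blocks.

Two canonical task families are shipped with the package:

* the 20-element arm-movement sequences S1/S2 (lever task) with four
  lead-in context elements each, and
* the 8-button finger-tapping pairs that differ at buttons 4&5 or 4&7.

``generate_task_set`` creates families of equal-length sequences with an
exactly controlled pairwise similarity (the complement of the normalized
Hamming distance): a random subset of positions carries symbols shared by
*all* tasks, every other position carries a symbol unique to one task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Sequence

import numpy as np
import yaml

from .params import ConfigurationError


@dataclass(frozen=True)
class SymbolSequence:
    name: str
    symbols: tuple[str, ...]

    def __post_init__(self):
        if not self.symbols:
            raise ConfigurationError(f"sequence {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class InputEncoding:
    """Map symbol -> tuple of excitatory unit indices (pairwise disjoint)."""

    symbol_to_units: dict[str, tuple[int, ...]]

    def __post_init__(self):
        seen: set[int] = set()
        for sym, units in self.symbol_to_units.items():
            overlap = seen & set(units)
            if overlap:
                raise ConfigurationError(
                    f"input units of symbol {sym!r} overlap another symbol: {sorted(overlap)}"
                )
            seen |= set(units)

    @property
    def all_units(self) -> tuple[int, ...]:
        return tuple(sorted(u for units in self.symbol_to_units.values() for u in units))


@dataclass
class TrainingSchedule:
    """Ordered training blocks (sequence name, word repetitions) and test blocks."""

    blocks: list[tuple[str, int]]
    test_blocks: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        for name, reps in list(self.blocks) + list(self.test_blocks):
            if reps <= 0:
                raise ConfigurationError(f"block for {name!r} has non-positive repetitions")

    def trials(self) -> list[str]:
        """Task name of every training trial (word presentation), in order."""
        out: list[str] = []
        for name, reps in self.blocks:
            out.extend([name] * reps)
        return out

    def total_trials(self, name: str) -> int:
        return sum(reps for n, reps in self.blocks if n == name)


@dataclass
class TaskSet:
    alphabet: tuple[str, ...]
    sequences: dict[str, SymbolSequence]
    encoding: InputEncoding
    schedule: TrainingSchedule | None = None

    def __post_init__(self):
        missing = {s for seq in self.sequences.values() for s in seq.symbols} - set(self.alphabet)
        if missing:
            raise ConfigurationError(f"sequence symbols outside the alphabet: {sorted(missing)}")
        if set(self.encoding.symbol_to_units) != set(self.alphabet):
            raise ConfigurationError("encoding does not cover exactly the alphabet")
        if self.schedule is not None:
            for name, _ in list(self.schedule.blocks) + list(self.schedule.test_blocks):
                if name not in self.sequences:
                    raise ConfigurationError(f"schedule references unknown sequence {name!r}")

    def with_schedule(self, schedule: TrainingSchedule) -> "TaskSet":
        return TaskSet(self.alphabet, dict(self.sequences), self.encoding, schedule)

    def to_dict(self) -> dict:
        d = {
            "alphabet": list(self.alphabet),
            "sequences": {n: list(s.symbols) for n, s in self.sequences.items()},
            "encoding": {s: list(u) for s, u in self.encoding.symbol_to_units.items()},
        }
        if self.schedule is not None:
            d["schedule"] = {
                "blocks": [list(b) for b in self.schedule.blocks],
                "test_blocks": [list(b) for b in self.schedule.test_blocks],
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSet":
        schedule = None
        if "schedule" in d:
            schedule = TrainingSchedule(
                blocks=[tuple(b) for b in d["schedule"]["blocks"]],
                test_blocks=[tuple(b) for b in d["schedule"].get("test_blocks", [])],
            )
        return cls(
            alphabet=tuple(d["alphabet"]),
            sequences={n: SymbolSequence(n, tuple(s)) for n, s in d["sequences"].items()},
            encoding=InputEncoding({s: tuple(u) for s, u in d["encoding"].items()}),
            schedule=schedule,
        )

    def save(self, path) -> None:
        """Write the task set (and schedule, if any) as YAML."""
        from pathlib import Path

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "TaskSet":
        from pathlib import Path

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def make_encoding(
    alphabet: Sequence[str], n_input_per_symbol: int = 10, n_excitatory: int = 300
) -> InputEncoding:
    """Assign contiguous blocks of input units to symbols in alphabet order."""
    needed = len(alphabet) * n_input_per_symbol
    if needed > n_excitatory:
        raise ConfigurationError(
            f"alphabet of {len(alphabet)} symbols needs {needed} input units, "
            f"but the network has only {n_excitatory} excitatory units"
        )
    return InputEncoding(
        {
            sym: tuple(range(k * n_input_per_symbol, (k + 1) * n_input_per_symbol))
            for k, sym in enumerate(alphabet)
        }
    )


def _load_yaml(name: str) -> dict:
    with resources.files("sornseq.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def canonical_panzer_tasks(
    n_input_per_symbol: int = 10, n_excitatory: int = 300
) -> TaskSet:
    """The two 20-element arm-movement sequences with lead-in elements.

    S1 and S2 share their last 16 elements up to an internal reordering and
    differ in the four lead-in elements (A1-A4 vs B1-B4).  14 symbols total.
    """
    data = _load_yaml("panzer.yaml")
    alphabet = tuple(data["alphabet"])
    sequences = {
        name: SymbolSequence(name, tuple(sym)) for name, sym in data["sequences"].items()
    }
    return TaskSet(alphabet, sequences, make_encoding(alphabet, n_input_per_symbol, n_excitatory))


def canonical_koedijker_tasks(
    pair: str, n_input_per_symbol: int = 10, n_excitatory: int = 300
) -> TaskSet:
    """The 8-button finger-tapping pair ``buttons_4_5`` or ``buttons_4_7``."""
    data = _load_yaml("koedijker.yaml")
    if pair not in data["pairs"]:
        raise ConfigurationError(f"unknown pair {pair!r}; choose from {sorted(data['pairs'])}")
    sub = data["pairs"][pair]
    alphabet = tuple(sub["alphabet"])
    sequences = {
        name: SymbolSequence(name, tuple(sym)) for name, sym in sub["sequences"].items()
    }
    return TaskSet(alphabet, sequences, make_encoding(alphabet, n_input_per_symbol, n_excitatory))


def task_similarity(a: SymbolSequence, b: SymbolSequence) -> float:
    """Fraction of positions at which two equal-length sequences agree
    (one minus the normalized Hamming distance)."""
    if len(a) != len(b):
        raise ValueError(f"sequences have different lengths ({len(a)} vs {len(b)})")
    matches = sum(sa == sb for sa, sb in zip(a.symbols, b.symbols))
    return matches / len(a)


def generate_task_set(
    length: int,
    similarity: float,
    n_tasks: int,
    rng: np.random.Generator,
    n_input_per_symbol: int = 10,
    n_excitatory: int = 300,
) -> TaskSet:
    """Generate ``n_tasks`` sequences whose every pairwise similarity equals
    ``similarity`` exactly.

    A random set of ``similarity * length`` positions carries symbols common
    to all tasks; every remaining position carries a symbol unique to one
    task, so no accidental matches occur.
    """
    n_shared_f = similarity * length
    n_shared = int(round(n_shared_f))
    if abs(n_shared_f - n_shared) > 1e-9:
        raise ConfigurationError(
            f"similarity {similarity} x length {length} is not an integer number of positions"
        )
    if not 0 <= n_shared <= length:
        raise ConfigurationError("similarity must lie in [0, 1]")

    n_unique = length - n_shared
    n_symbols = n_shared + n_tasks * n_unique
    # feasibility against the network size is checked by make_encoding
    shared_positions = set(rng.choice(length, size=n_shared, replace=False).tolist())

    shared_syms = [f"c{i}" for i in range(n_shared)]
    alphabet: list[str] = list(shared_syms)
    seqs: dict[str, SymbolSequence] = {}
    for k in range(n_tasks):
        symbols: list[str] = []
        i_shared = 0
        for pos in range(length):
            if pos in shared_positions:
                symbols.append(shared_syms[i_shared])
                i_shared += 1
            else:
                sym = f"t{k + 1}u{pos}"
                symbols.append(sym)
                alphabet.append(sym)
        seqs[f"S{k + 1}"] = SymbolSequence(f"S{k + 1}", tuple(symbols))
    assert len(alphabet) == n_symbols
    encoding = make_encoding(alphabet, n_input_per_symbol, n_excitatory)
    return TaskSet(tuple(alphabet), seqs, encoding)


def build_schedule(
    kind: str,
    total_trials_per_task: int,
    task_names: Sequence[str],
    rng: np.random.Generator | None = None,
    n_blocks: int | None = None,
    test_trials: int = 20,
) -> TrainingSchedule:
    """Partition each task's trials into blocks.

    ``kind`` is ``"blocked"`` (one contiguous block per task), ``"interleaved"``
    (one trial per block, random order) or ``"n_blocks"`` (a given total number
    of blocks split evenly over tasks, random block order).  Test blocks with
    ``test_trials`` words per task are always appended.
    """
    n_tasks = len(task_names)
    if kind == "blocked":
        n_blocks = n_tasks
    elif kind == "interleaved":
        n_blocks = n_tasks * total_trials_per_task
    elif kind != "n_blocks":
        raise ConfigurationError(f"unknown schedule kind {kind!r}")
    if n_blocks is None:
        raise ConfigurationError("n_blocks is required for kind='n_blocks'")
    if not n_tasks <= n_blocks <= n_tasks * total_trials_per_task:
        raise ConfigurationError(
            f"{n_blocks} blocks is an indivisible partition of {n_tasks} tasks "
            f"x {total_trials_per_task} trials"
        )
    if n_blocks % n_tasks == 0 and total_trials_per_task % (n_blocks // n_tasks) == 0:
        blocks_per_task = n_blocks // n_tasks
        reps = total_trials_per_task // blocks_per_task
        blocks = [(name, reps) for name in task_names for _ in range(blocks_per_task)]
    else:
        # ragged partition (e.g. 50 blocks over 3 tasks): blocks of the nominal
        # size plus one remainder block per task; per-task totals are conserved
        size = max(1, round(n_tasks * total_trials_per_task / n_blocks))
        blocks = []
        for name in task_names:
            left = total_trials_per_task
            while left > 0:
                reps = min(size, left)
                blocks.append((name, reps))
                left -= reps
    if kind != "blocked" and len(blocks) > n_tasks:
        if rng is None:
            raise ConfigurationError("a random generator is required to shuffle block order")
        order = rng.permutation(len(blocks))
        blocks = [blocks[i] for i in order]
    tests = [(name, test_trials) for name in task_names]
    return TrainingSchedule(blocks=blocks, test_blocks=tests)


@dataclass(frozen=True)
class StepInput:
    """One time step of the drive stream."""

    symbol: str
    units: tuple[int, ...]
    target: str
    cross_word: bool
    task: str
    trial: int          # global trial (word) index
    task_trial: int     # per-task trial index
    position: int       # 0-based position within the word


def drive_stream(task_set: TaskSet, schedule: TrainingSchedule | None = None) -> Iterator[StepInput]:
    """Yield one :class:`StepInput` per time step of the training schedule.

    The readout target at each step is the *next* element of the current
    word; the last element of a word targets the first element of the next
    word and is flagged ``cross_word`` (excluded from error statistics by
    default, since the next word is unpredictable under interleaved
    schedules).
    """
    schedule = schedule or task_set.schedule
    if schedule is None:
        raise ConfigurationError("no training schedule given")
    trials = schedule.trials()
    enc = task_set.encoding.symbol_to_units
    per_task_counter: dict[str, int] = {}
    for trial_idx, name in enumerate(trials):
        word = task_set.sequences[name].symbols
        task_trial = per_task_counter.get(name, 0)
        per_task_counter[name] = task_trial + 1
        if trial_idx + 1 < len(trials):
            next_word = task_set.sequences[trials[trial_idx + 1]].symbols
        else:
            next_word = word
        for pos, sym in enumerate(word):
            cross = pos == len(word) - 1
            target = next_word[0] if cross else word[pos + 1]
            yield StepInput(
                symbol=sym,
                units=enc[sym],
                target=target,
                cross_word=cross,
                task=name,
                trial=trial_idx,
                task_trial=task_trial,
                position=pos,
            )
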