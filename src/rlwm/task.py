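"""RLWM task structure: block schedules, trial records, and trial-log I/O.

The task is an instrumental learning paradigm: in each block the subject sees a
fresh set of ``ns`` stimuli (the *set size*, 2-5) and must discover, from
correct/incorrect feedback, which of three response keys ("J", "K", "L") is
assigned to each stimulus.  Stimuli are presented 12-14 times each in a
pseudo-randomly interleaved order.  A session comprises one practice
(training) block followed by ten independent learning blocks; only learning
blocks enter analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

N_ACTIONS = 3
ACTION_LABELS = ("J", "K", "L")
_LABEL_TO_ACTION = {lab: i for i, lab in enumerate(ACTION_LABELS)}

#: Default learning-block composition.  The published session totals 468
#: trials (training + 10 learning blocks, set sizes 2-5, 12-14 presentations
#: per stimulus) without printing the per-block breakdown; this is one
#: feasible instantiation: ns=4 blocks use 13 presentations, all others 12,
#: giving 36 training + 432 learning trials.
DEFAULT_SET_SIZES = (2, 3, 4, 5, 2, 3, 4, 5, 3, 4)
DEFAULT_PRESENTATIONS = (12, 12, 13, 12, 12, 12, 13, 12, 12, 13)

TRIAL_COLUMNS = (
    "subject_id", "block", "trial", "set_size", "stimulus", "iteration",
    "action", "correct_action", "reward", "rt_ms", "valid",
)


class ScheduleConstraintError(ValueError):
    """Raised when the interleaving constraint cannot be satisfied."""


class TrialLogError(ValueError):
    """Raised for malformed or inconsistent trial-log files."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the RLWM session layout.

    ``set_sizes[i]`` and ``presentations[i]`` describe learning block ``i+1``
    (block 0 is the training block when ``include_training``).
    ``max_run_length`` bounds how many times the same stimulus may appear
    consecutively in the interleaved sequence.
    """

    n_learning_blocks: int = 10
    set_sizes: Sequence[int] = DEFAULT_SET_SIZES
    presentations: Sequence[int] = DEFAULT_PRESENTATIONS
    include_training: bool = True
    training_set_size: int = 3
    training_presentations: int = 12
    n_actions: int = N_ACTIONS
    response_window_s: float = 7.0
    max_run_length: int = 3

    def __post_init__(self) -> None:
        if self.n_actions != N_ACTIONS:
            raise ValueError("the task uses exactly 3 response keys")
        if len(self.set_sizes) != self.n_learning_blocks:
            raise ValueError("set_sizes must list one set size per learning block")
        if len(self.presentations) != self.n_learning_blocks:
            raise ValueError("presentations must list one count per learning block")
        for ns in self.set_sizes:
            if not 2 <= ns <= 5:
                raise ValueError(f"set size {ns} outside the task's range [2, 5]")
        for p in tuple(self.presentations) + ((self.training_presentations,) if self.include_training else ()):
            if not 12 <= p <= 14:
                raise ValueError(f"presentation count {p} outside [12, 14]")
        if self.max_run_length < 1:
            raise ValueError("max_run_length must be >= 1")

    @property
    def n_learning_trials(self) -> int:
        return int(sum(ns * p for ns, p in zip(self.set_sizes, self.presentations)))

    @property
    def n_trials(self) -> int:
        n = self.n_learning_trials
        if self.include_training:
            n += self.training_set_size * self.training_presentations
        return n


@dataclass(frozen=True)
class Block:
    """One block of the schedule: its stimuli, key map, and trial order."""

    index: int
    set_size: int
    is_training: bool
    stimuli: tuple[str, ...]
    correct_actions: tuple[int, ...]  # one action per stimulus
    sequence: tuple[int, ...]         # within-block stimulus indices, in order

    def __post_init__(self) -> None:
        if len(self.stimuli) != self.set_size or len(self.correct_actions) != self.set_size:
            raise ValueError("stimuli/correct_actions must match set_size")


@dataclass(frozen=True)
class TaskSchedule:
    config: TaskConfig
    seed: int
    blocks: tuple[Block, ...]

    @property
    def n_trials(self) -> int:
        return sum(len(b.sequence) for b in self.blocks)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "blocks": [
                {
                    "index": b.index,
                    "set_size": b.set_size,
                    "is_training": b.is_training,
                    "stimuli": list(b.stimuli),
                    "correct_actions": list(b.correct_actions),
                    "sequence": list(b.sequence),
                }
                for b in self.blocks
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @staticmethod
    def from_json(path: str | Path) -> "TaskSchedule":
        payload = json.loads(Path(path).read_text())
        cfg_d = payload["config"]
        cfg_d["set_sizes"] = tuple(cfg_d["set_sizes"])
        cfg_d["presentations"] = tuple(cfg_d["presentations"])
        cfg = TaskConfig(**cfg_d)
        blocks = tuple(
            Block(
                index=b["index"],
                set_size=b["set_size"],
                is_training=b["is_training"],
                stimuli=tuple(b["stimuli"]),
                correct_actions=tuple(b["correct_actions"]),
                sequence=tuple(b["sequence"]),
            )
            for b in payload["blocks"]
        )
        return TaskSchedule(config=cfg, seed=payload["seed"], blocks=blocks)


def _interleave(counts: Sequence[int], max_run_length: int,
                rng: np.random.Generator, max_tries: int = 2000) -> np.ndarray:
    """Seeded shuffle-with-rejection until no stimulus runs longer than allowed."""
    base = np.repeat(np.arange(len(counts)), counts)
    if len(counts) == 1:
        if len(base) > max_run_length:
            raise ScheduleConstraintError(
                "a single stimulus cannot satisfy the run-length constraint"
            )
        return base
    for _ in range(max_tries):
        seq = rng.permutation(base)
        # longest run of identical values
        change = np.flatnonzero(np.diff(seq) != 0)
        run_lengths = np.diff(np.concatenate(([-1], change, [len(seq) - 1])))
        if run_lengths.max() <= max_run_length:
            return seq
    raise ScheduleConstraintError(
        f"could not interleave counts={list(counts)} with max_run_length={max_run_length}"
    )


def generate_schedule(config: TaskConfig, seed: int) -> TaskSchedule:
    """Build a full session schedule; deterministic for a given (config, seed)."""
    rng = np.random.default_rng(seed)
    specs: list[tuple[int, int, int, bool]] = []
    if config.include_training:
        specs.append((0, config.training_set_size, config.training_presentations, True))
    for i, (ns, pres) in enumerate(zip(config.set_sizes, config.presentations), start=1):
        specs.append((i, ns, pres, False))

    blocks = []
    for index, ns, pres, is_training in specs:
        stimuli = tuple(f"b{index:02d}_s{j}" for j in range(ns))
        correct = tuple(int(a) for a in rng.integers(0, config.n_actions, size=ns))
        seq = _interleave([pres] * ns, config.max_run_length, rng)
        blocks.append(Block(index=index, set_size=ns, is_training=is_training,
                            stimuli=stimuli, correct_actions=correct,
                            sequence=tuple(int(s) for s in seq)))
    return TaskSchedule(config=config, seed=int(seed), blocks=tuple(blocks))


@dataclass
class TrialRecord:
    """One stimulus -> choice -> feedback event.

    ``iteration`` is the presentation index of this stimulus (1-based).
    Invalid (timeout) trials carry no action or reward.
    """

    subject_id: str
    block: int
    trial: int
    set_size: int
    stimulus: str
    iteration: int
    action: Optional[int]
    correct_action: int
    reward: Optional[int]
    rt_ms: Optional[float] = None
    valid: bool = True

    def __post_init__(self) -> None:
        if self.iteration < 1:
            raise ValueError("iteration is 1-based")
        if self.valid:
            if self.action not in (0, 1, 2):
                raise ValueError(f"action must be 0/1/2, got {self.action}")
            expected = int(self.action == self.correct_action)
            if self.reward != expected:
                raise ValueError(
                    f"reward={self.reward} inconsistent with action={self.action}, "
                    f"correct_action={self.correct_action}"
                )
        else:
            if self.action is not None or self.reward is not None:
                raise ValueError("invalid trials carry no action or reward")

    @property
    def is_training(self) -> bool:
        return self.block == 0


@dataclass
class SubjectDataset:
    """Demographics plus one subject's ordered trials.

    ``trials`` is a DataFrame with the canonical trial-log columns (actions as
    integers in memory).  ``params`` optionally records the generating agent
    parameters for simulated subjects.
    """

    subject_id: str
    trials: pd.DataFrame
    age: Optional[float] = None
    group: Optional[str] = None
    moca: Optional[int] = None
    params: Optional[object] = None  # rlwm.agent.RLWMParams for simulated data

    @property
    def learning_trials(self) -> pd.DataFrame:
        """Valid learning-block trials (training block excluded)."""
        df = self.trials
        return df[(df["block"] > 0) & (df["valid"].astype(bool))]


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    return df


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(TrialRecord(
                subject_id=str(row.subject_id),
                block=int(row.block),
                trial=int(row.trial),
                set_size=int(row.set_size),
                stimulus=str(row.stimulus),
                iteration=int(row.iteration),
                action=None if pd.isna(row.action) else int(row.action),
                correct_action=int(row.correct_action),
                reward=None if pd.isna(row.reward) else int(row.reward),
                rt_ms=None if pd.isna(row.rt_ms) else float(row.rt_ms),
                valid=bool(row.valid),
            ))
        except (ValueError, TypeError) as exc:
            raise TrialLogError(f"row {i}: {exc}") from exc
    return records


def write_trials(records: Sequence[TrialRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write a trial log as UTF-8 CSV; actions encoded as key labels J/K/L."""
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    out = df.loc[:, list(TRIAL_COLUMNS)].copy()
    out["action"] = out["action"].map(
        lambda a: "" if pd.isna(a) else ACTION_LABELS[int(a)])
    out["correct_action"] = out["correct_action"].map(lambda a: ACTION_LABELS[int(a)])
    out["reward"] = out["reward"].map(lambda r: "" if pd.isna(r) else int(r))
    out["rt_ms"] = out["rt_ms"].map(lambda x: "" if pd.isna(x) else f"{float(x):.3f}")
    out["valid"] = out["valid"].astype(bool).astype(int)
    out.to_csv(path, index=False, encoding="utf-8")


def _decode_action(value, row: int) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    s = str(value).strip().upper()
    if s in _LABEL_TO_ACTION:
        return _LABEL_TO_ACTION[s]
    if s in {"0", "1", "2"}:
        return int(s)
    raise TrialLogError(f"row {row}: unknown action label {value!r}")


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Parse a trial-log CSV, enforcing record invariants (errors name the row)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "stimulus": str},
                     keep_default_na=False, na_values=[""])
    extra = set(df.columns) - set(TRIAL_COLUMNS)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if extra or missing:
        raise TrialLogError(f"unknown columns {sorted(extra)}, missing {sorted(missing)}")
    if df.empty:
        return []
    records: list[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        action = _decode_action(row.action, i)
        try:
            records.append(TrialRecord(
                subject_id=str(row.subject_id),
                block=int(row.block),
                trial=int(row.trial),
                set_size=int(row.set_size),
                stimulus=str(row.stimulus),
                iteration=int(row.iteration),
                action=action,
                correct_action=_decode_action(row.correct_action, i),
                reward=None if pd.isna(row.reward) else int(row.reward),
                rt_ms=None if pd.isna(row.rt_ms) else float(row.rt_ms),
                valid=bool(int(row.valid)),
            ))
        except (ValueError, TypeError) as exc:
            raise TrialLogError(f"row {i}: {exc}") from exc
    _check_iterations(records)
    return records


def _check_iterations(records: Sequence[TrialRecord]) -> None:
    seen: dict[tuple[str, int, str], int] = {}
    for i, r in enumerate(records):
        key = (r.subject_id, r.block, r.stimulus)
        expected = seen.get(key, 0) + 1
        if r.iteration != expected:
            raise TrialLogError(
                f"row {i}: iteration {r.iteration} for stimulus {r.stimulus!r} "
                f"(expected {expected})"
            )
        seen[key] = expected


def compile_schedule(schedule: TaskSchedule) -> dict[str, np.ndarray]:
    """Flatten a schedule into per-trial arrays for the simulation kernel."""
    block_idx, stim_idx, set_size, correct, new_block, iteration, is_training = \
        [], [], [], [], [], [], []
    stim_names: list[str] = []
    for b in schedule.blocks:
        counts = [0] * b.set_size
        for j, s in enumerate(b.sequence):
            block_idx.append(b.index)
            stim_idx.append(s)
            set_size.append(b.set_size)
            correct.append(b.correct_actions[s])
            new_block.append(j == 0)
            counts[s] += 1
            iteration.append(counts[s])
            is_training.append(b.is_training)
            stim_names.append(b.stimuli[s])
    return {
        "block": np.asarray(block_idx, dtype=np.int64),
        "stim": np.asarray(stim_idx, dtype=np.int64),
        "set_size": np.asarray(set_size, dtype=np.int64),
        "correct": np.asarray(correct, dtype=np.int64),
        "new_block": np.asarray(new_block, dtype=np.bool_),
        "iteration": np.asarray(iteration, dtype=np.int64),
        "is_training": np.asarray(is_training, dtype=np.bool_),
        "stim_name": np.asarray(stim_names, dtype=object),
    }


def compile_trials(df: pd.DataFrame, include_training: bool = False) -> dict[str, np.ndarray]:
    """Flatten a trial-log DataFrame into arrays for the likelihood kernel.

    Within-block stimulus indices are assigned by order of first appearance.
    """
    if df.empty:
        raise ValueError("empty trial log")
    work = df if include_training else df[df["block"] > 0]
    if work.empty:
        raise ValueError("no learning-block trials")
    block = work["block"].to_numpy(dtype=np.int64)
    new_block = np.concatenate(([True], block[1:] != block[:-1]))
    stim = np.empty(len(work), dtype=np.int64)
    mapping: dict[str, int] = {}
    cur_block = None
    for i, (b, name) in enumerate(zip(block, work["stimulus"].to_numpy())):
        if b != cur_block:
            mapping = {}
            cur_block = b
        if name not in mapping:
            mapping[name] = len(mapping)
        stim[i] = mapping[name]
    valid = work["valid"].to_numpy(dtype=np.bool_)
    action = np.where(valid, work["action"].fillna(-1).to_numpy(dtype=np.float64), -1).astype(np.int64)
    reward = np.where(valid, work["reward"].fillna(0).to_numpy(dtype=np.float64), 0.0)
    return {
        "block": block,
        "stim": stim,
        "set_size": work["set_size"].to_numpy(dtype=np.int64),
        "new_block": new_block,
        "action": action,
        "reward": reward,
        "valid": valid,
    }
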