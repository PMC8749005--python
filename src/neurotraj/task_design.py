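"""n-back working-memory task schedules.

Generates block-structured n-back sessions (1-back = low load, 2-back =
high load): each run opens with a fixation period, then task blocks
(initiation cue + 13 trials each) interleaved with rest blocks.  Trials show
a 0.5-s stimulus followed by a jittered inter-trial fixation within
[1.5, 10] s.  Two run variants are supported: ``short`` (155-s runs, two
task blocks per run) and ``long`` (three task blocks per run).  Either way
a full session yields 78 trials per load condition.

Schedules serialize to BIDS-style events TSV files with a small JSON
sidecar for session-level fields, and parse back losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParseError

__all__ = [
    "CONDITIONS",
    "TaskConfig",
    "TaskSchedule",
    "generate_schedule",
    "label_accuracy",
    "write_events",
    "read_events",
]

CONDITIONS = ("1back", "2back")
ACCURACY_LEVELS = ("correct", "incorrect", "unset")

EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "stimulus_id",
    "is_target",
    "accuracy",
    "run",
    "block",
]

N_STIMULI = 120  # picture pool size (faces and buildings)


@dataclass(frozen=True)
class TaskConfig:
    """Timing and counts for one n-back session.

    Defaults correspond to the ``long`` variant: 4 runs of three 60-s task
    blocks interleaved with two 30-s rest blocks, 3-s initial and 10-s final
    fixation, 13 trials per block.
    """

    variant: str = "long"
    n_runs: int = 4
    blocks_per_run: int = 3
    trials_per_block: int = 13
    block_duration_s: float = 60.0
    rest_duration_s: float = 30.0
    initial_fixation_s: float = 3.0
    cue_duration_s: float = 2.0
    final_fixation_s: float = 10.0
    stim_duration_s: float = 0.5
    iti_range_s: tuple[float, float] = (1.5, 10.0)
    n_repeats_per_block: tuple[int, int] = (2, 4)
    seed: int = 0

    @classmethod
    def for_variant(cls, variant: str, *, n_runs: int | None = None, seed: int = 0) -> "TaskConfig":
        """Standard configuration for the ``short`` or ``long`` run variant."""
        if variant == "short":
            return cls(
                variant="short",
                n_runs=6 if n_runs is None else n_runs,
                blocks_per_run=2,
                rest_duration_s=25.0,
                final_fixation_s=7.0,
                seed=seed,
            )
        if variant == "long":
            return cls(variant="long", n_runs=4 if n_runs is None else n_runs, seed=seed)
        raise ConfigurationError(f"variant must be 'short' or 'long', got {variant!r}")

    def validate(self) -> None:
        if self.variant not in ("short", "long"):
            raise ConfigurationError(f"variant: must be 'short' or 'long', got {self.variant!r}")
        if self.n_runs < 0:
            raise ConfigurationError(f"n_runs: must be >= 0, got {self.n_runs}")
        if self.blocks_per_run <= 0:
            raise ConfigurationError(f"blocks_per_run: must be positive, got {self.blocks_per_run}")
        if self.trials_per_block < 1:
            raise ConfigurationError(
                f"trials_per_block: must be >= 1, got {self.trials_per_block}"
            )
        for name in (
            "block_duration_s",
            "rest_duration_s",
            "initial_fixation_s",
            "cue_duration_s",
            "final_fixation_s",
            "stim_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name}: must be positive, got {getattr(self, name)}")
        lo, hi = self.iti_range_s
        if not lo < hi:
            raise ConfigurationError(f"iti_range_s: lower bound must be < upper, got {self.iti_range_s}")
        if lo < 0:
            raise ConfigurationError(f"iti_range_s: lower bound must be >= 0, got {lo}")
        rep_lo, rep_hi = self.n_repeats_per_block
        if not (1 <= rep_lo <= rep_hi):
            raise ConfigurationError(
                f"n_repeats_per_block: must satisfy 1 <= lo <= hi, got {self.n_repeats_per_block}"
            )
        # trials must physically fit in a block at the minimum jitter
        min_needed = (
            self.cue_duration_s
            + self.trials_per_block * self.stim_duration_s
            + (self.trials_per_block - 1) * lo
        )
        if min_needed > self.block_duration_s:
            raise ConfigurationError(
                "block_duration_s: too short to fit "
                f"{self.trials_per_block} trials at minimum ITI ({min_needed:.1f}s needed)"
            )

    @property
    def run_duration_s(self) -> float:
        """Run duration by component arithmetic: initial fixation + task
        blocks + interleaved rest blocks + final fixation."""
        return (
            self.initial_fixation_s
            + self.blocks_per_run * self.block_duration_s
            + (self.blocks_per_run - 1) * self.rest_duration_s
            + self.final_fixation_s
        )


@dataclass
class TaskSchedule:
    """One session's trials plus run structure.

    ``trials`` is a DataFrame with columns ``onset`` (s from run start),
    ``duration``, ``trial_type`` (1back/2back), ``stimulus_id``,
    ``is_target``, ``accuracy``, ``run``, ``block``.
    """

    trials: pd.DataFrame
    run_duration_s: list[float]
    session_label: str = "baseline"
    extras: pd.DataFrame | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def condition_counts(self) -> dict[str, int]:
        counts = self.trials["trial_type"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CONDITIONS}

    def absolute_onsets(self) -> np.ndarray:
        """Trial onsets in seconds on the concatenated-session timeline."""
        if self.n_trials == 0:
            return np.empty(0)
        offsets = np.concatenate([[0.0], np.cumsum(self.run_duration_s)])[:-1]
        return self.trials["onset"].to_numpy() + offsets[self.trials["run"].to_numpy()]

    @property
    def total_duration_s(self) -> float:
        return float(np.sum(self.run_duration_s))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaskSchedule):
            return NotImplemented
        if self.session_label != other.session_label:
            return False
        if not np.allclose(self.run_duration_s, other.run_duration_s):
            return False
        a, b = self.trials, other.trials
        if len(a) != len(b):
            return False
        for col in ("onset", "duration"):
            if not np.allclose(a[col].to_numpy(), b[col].to_numpy(), atol=1e-9):
                return False
        for col in ("trial_type", "stimulus_id", "is_target", "accuracy", "run", "block"):
            if not (a[col].to_numpy() == b[col].to_numpy()).all():
                return False
        return True


def generate_schedule(config: TaskConfig, session_label: str = "baseline") -> TaskSchedule:
    """Generate a reproducible n-back session schedule.

    Load conditions alternate across blocks within a run and the starting
    condition alternates across runs, so any session with an even total
    block count is exactly balanced.  ITIs are drawn from the jitter range
    and, when a block's sampled jitters would overflow the fixed block
    duration, linearly squeezed toward the range minimum so that all trials
    fit inside the block window (jitter stays within [lo, hi]).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.iti_range_s
    rows = []
    for run in range(config.n_runs):
        for block in range(config.blocks_per_run):
            condition = CONDITIONS[(run + block) % 2]
            nback = 1 if condition == "1back" else 2
            block_start = config.initial_fixation_s + block * (
                config.block_duration_s + config.rest_duration_s
            )
            onsets = _block_onsets(config, rng, block_start, lo, hi)
            is_target = _place_targets(config, rng, nback)
            stimulus_id = _assign_stimuli(config, rng, is_target, nback)
            for j in range(config.trials_per_block):
                rows.append(
                    {
                        "onset": onsets[j],
                        "duration": config.stim_duration_s,
                        "trial_type": condition,
                        "stimulus_id": int(stimulus_id[j]),
                        "is_target": bool(is_target[j]),
                        "accuracy": "unset",
                        "run": run,
                        "block": block,
                    }
                )
    trials = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if len(trials) == 0:
        trials = pd.DataFrame(columns=EVENT_COLUMNS)
    run_durations = [config.run_duration_s] * config.n_runs
    return TaskSchedule(trials=trials, run_duration_s=run_durations, session_label=session_label)


def _block_onsets(config, rng, block_start, lo, hi):
    """Onsets of the trials of one block, cue first, jittered ITIs after."""
    n = config.trials_per_block
    itis = rng.uniform(lo, hi, size=n - 1)
    available = (
        config.block_duration_s - config.cue_duration_s - n * config.stim_duration_s
    )
    if n > 1:
        excess = itis - lo
        budget = available - (n - 1) * lo
        total_excess = excess.sum()
        if total_excess > 0:
            squeeze = min(1.0, budget / total_excess)
            itis = lo + excess * squeeze
    gaps = np.concatenate([[0.0], itis + config.stim_duration_s])
    return block_start + config.cue_duration_s + np.cumsum(gaps)


def _place_targets(config, rng, nback):
    """Choose 2-4 repeat (target) trials, non-adjacent, legal for the load."""
    n = config.trials_per_block
    rep_lo, rep_hi = config.n_repeats_per_block
    n_targets = int(rng.integers(rep_lo, rep_hi + 1))
    eligible = np.arange(nback, n)
    for _ in range(1000):
        pick = np.sort(rng.choice(eligible, size=min(n_targets, len(eligible)), replace=False))
        if len(pick) < 2 or np.all(np.diff(pick) > 1):
            mask = np.zeros(n, dtype=bool)
            mask[pick] = True
            return mask
    # fall back to a deterministic spread if rejection sampling fails
    pick = eligible[:: max(2, len(eligible) // max(1, n_targets))][:n_targets]
    mask = np.zeros(n, dtype=bool)
    mask[pick] = True
    return mask


def _assign_stimuli(config, rng, is_target, nback):
    """Assign picture ids so targets match the item n trials back and
    non-targets do not."""
    n = config.trials_per_block
    stim = rng.integers(0, N_STIMULI, size=n)
    for j in range(n):
        if is_target[j]:
            stim[j] = stim[j - nback]
        elif j >= nback:
            while stim[j] == stim[j - nback]:
                stim[j] = rng.integers(0, N_STIMULI)
    return stim


def label_accuracy(schedule: TaskSchedule, accuracy_rate: float, seed: int = 0) -> TaskSchedule:
    """Assign correct/incorrect labels i.i.d. with the given success rate."""
    if not 0.0 <= accuracy_rate <= 1.0:
        raise ConfigurationError(f"accuracy_rate: must be in [0, 1], got {accuracy_rate}")
    rng = np.random.default_rng(seed)
    trials = schedule.trials.copy()
    correct = rng.random(len(trials)) < accuracy_rate
    trials["accuracy"] = np.where(correct, "correct", "incorrect")
    return TaskSchedule(
        trials=trials,
        run_duration_s=list(schedule.run_duration_s),
        session_label=schedule.session_label,
        extras=schedule.extras,
    )


def write_events(schedule: TaskSchedule, path: str | Path) -> None:
    """Write a BIDS-style events TSV plus a JSON sidecar (run durations,
    session label).  Output is byte-deterministic for a given schedule."""
    path = Path(path)
    df = schedule.trials[EVENT_COLUMNS].copy()
    if schedule.extras is not None and len(schedule.extras) == len(df):
        for col in schedule.extras.columns:
            df[col] = schedule.extras[col].to_numpy()
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "run_duration_s": [float(d) for d in schedule.run_duration_s],
        "session_label": schedule.session_label,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_events(path: str | Path) -> TaskSchedule:
    """Parse an events TSV written by :func:`write_events` (or compatible).

    Unknown columns are preserved in ``schedule.extras``.  Raises
    :class:`ParseError` naming the first offending row for invalid values.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"could not parse events file {path}: {exc}") from exc
    missing = [c for c in ("onset", "duration", "trial_type") if c not in df.columns]
    if missing:
        raise ParseError(f"events file {path} missing required columns: {missing}")
    for col, default in (
        ("stimulus_id", 0),
        ("is_target", False),
        ("accuracy", "unset"),
        ("run", 0),
        ("block", 0),
    ):
        if col not in df.columns:
            df[col] = default
    for i, onset in enumerate(df["onset"]):
        if not np.isfinite(onset) or onset < 0:
            raise ParseError(f"events file {path}, row {i}: invalid onset {onset}")
    for i, acc in enumerate(df["accuracy"]):
        if acc not in ACCURACY_LEVELS:
            raise ParseError(f"events file {path}, row {i}: invalid accuracy {acc!r}")
    for run, grp in df.groupby("run"):
        onsets = grp["onset"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            bad = int(grp.index[np.argmax(np.diff(onsets) <= 0) + 1])
            raise ParseError(
                f"events file {path}, row {bad}: onsets not strictly increasing within run {run}"
            )
    extra_cols = [c for c in df.columns if c not in EVENT_COLUMNS]
    extras = df[extra_cols].copy() if extra_cols else None
    trials = df[EVENT_COLUMNS].copy()
    trials["is_target"] = trials["is_target"].astype(bool)
    trials["stimulus_id"] = trials["stimulus_id"].astype(int)
    trials["run"] = trials["run"].astype(int)
    trials["block"] = trials["block"].astype(int)

    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        run_durations = [float(d) for d in sidecar.get("run_duration_s", [])]
        session_label = sidecar.get("session_label", "unknown")
    else:
        # fall back: infer run duration as last offset rounded up
        n_runs = int(trials["run"].max()) + 1 if len(trials) else 0
        dur = float(np.ceil(trials["onset"].max() + 16.0)) if len(trials) else 0.0
        run_durations = [dur] * n_runs
        session_label = "unknown"
    return TaskSchedule(
        trials=trials,
        run_duration_s=run_durations,
        session_label=session_label,
        extras=extras,
    )
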