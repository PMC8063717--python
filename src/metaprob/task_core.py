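"""Canonical data model of the two-stage probability-comparison task.

Each trial offers a choice between an *internal* probability option — a
random-dot kinematogram (RDK) whose motion coherence determines how likely
the observer is to discriminate its direction correctly — and an *external*
probability option, an unambiguous RDK whose dot count signals the
probability that a correct discrimination is rewarded.  A reward is only
ever delivered after a correct perceptual response; for the internal option
the reward then follows with certainty, for the external option with the
advertised probability.

This module defines the task configuration (stimulus grids, reward rule),
the trial record and session log containers, the follow-up table that maps
coherence to empirical accuracy, and tab-separated readers/writers for all
of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "COHERENCE_LEVELS",
    "EXTERNAL_PROBABILITIES",
    "DOTS_PER_PROBABILITY",
    "TRIAL_LOG_COLUMNS",
    "FOLLOWUP_COLUMNS",
    "TaskConfig",
    "TrialRecord",
    "SessionLog",
    "FollowUpTable",
    "TrialLogFormatError",
    "TrialValidationError",
    "read_session_log",
    "write_session_log",
    "followup_table",
    "read_followup_table",
    "write_followup_table",
]

#: Motion-coherence ladder of the internal option (proportion of dots
#: moving coherently).
COHERENCE_LEVELS: tuple[float, ...] = (0.0, 0.03, 0.06, 0.12, 0.25, 0.37, 0.50, 0.75)

#: Reward probabilities signalled by the external option's dot count.
EXTERNAL_PROBABILITIES: tuple[float, ...] = (0.1, 0.3, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

#: Dot count advertising each external probability (10 dots per 0.1).
DOTS_PER_PROBABILITY: dict[float, int] = {p: round(p * 100) for p in EXTERNAL_PROBABILITIES}

TRIAL_LOG_COLUMNS = (
    "session_id",
    "trial_index",
    "coherence",
    "p_external",
    "chose_internal",
    "true_direction",
    "response_direction",
    "perceptual_correct",
    "rewarded",
)

FOLLOWUP_COLUMNS = ("coherence", "n_trials", "n_correct")

_DIRECTIONS = ("left", "right")


class TrialLogFormatError(ValueError):
    """The file does not match the documented trial-log format."""


class TrialValidationError(ValueError):
    """One or more rows violate a trial-level invariant."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class TaskConfig:
    """Stimulus grids and session structure of the task.

    The internal option always carries the maximum dot count and an
    external reward probability of exactly 1; only its coherence varies.
    The external option always moves at full coherence; only its dot
    count (reward probability) varies.
    """

    coherence_levels: tuple[float, ...] = COHERENCE_LEVELS
    external_probabilities: tuple[float, ...] = EXTERNAL_PROBABILITIES
    dots_per_probability: Mapping[float, int] = field(
        default_factory=lambda: dict(DOTS_PER_PROBABILITY)
    )
    n_trials_per_session: int = 195
    internal_dot_count: int = 100
    internal_external_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.n_trials_per_session <= 0:
            raise ValueError("n_trials_per_session must be positive")
        if not all(0.0 <= c <= 1.0 for c in self.coherence_levels):
            raise ValueError("coherences must lie in [0, 1]")
        if not all(0.0 <= p <= 1.0 for p in self.external_probabilities):
            raise ValueError("external probabilities must lie in [0, 1]")

    @property
    def grid(self) -> list[tuple[float, float]]:
        """Full cross of coherence levels and external probabilities."""
        return [
            (c, p) for c in self.coherence_levels for p in self.external_probabilities
        ]


@dataclass
class TrialRecord:
    """One two-stage trial: the metacognitive choice and its outcome.

    ``rewarded`` can only be true when ``perceptual_correct`` is true; for
    external-option trials the reward additionally depends on the
    advertised probability.
    """

    session_id: str
    trial_index: int
    coherence: float
    p_external: float
    chose_internal: bool
    true_direction: str
    response_direction: str
    perceptual_correct: bool
    rewarded: bool

    def validate(self, config: TaskConfig | None = None) -> list[str]:
        """Return human-readable descriptions of invariant violations."""
        problems: list[str] = []
        if self.trial_index < 1:
            problems.append(f"trial_index {self.trial_index} is not 1-based")
        if self.rewarded and not self.perceptual_correct:
            problems.append("rewarded=1 with perceptual_correct=0")
        if self.true_direction not in _DIRECTIONS:
            problems.append(f"true_direction {self.true_direction!r} not in {_DIRECTIONS}")
        if self.response_direction not in _DIRECTIONS:
            problems.append(
                f"response_direction {self.response_direction!r} not in {_DIRECTIONS}"
            )
        if self.perceptual_correct != (self.true_direction == self.response_direction):
            problems.append("perceptual_correct inconsistent with directions")
        if config is not None:
            if not _in_levels(self.coherence, config.coherence_levels):
                problems.append(f"coherence {self.coherence} not in task grid")
            if self.chose_internal:
                if self.p_external != config.internal_external_prob and not _in_levels(
                    self.p_external, config.external_probabilities
                ):
                    problems.append(f"p_external {self.p_external} not in task grid")
            elif not _in_levels(self.p_external, config.external_probabilities):
                problems.append(f"p_external {self.p_external} not in task grid")
        return problems


def _in_levels(x: float, levels: Iterable[float], tol: float = 1e-9) -> bool:
    return any(abs(x - lv) <= tol for lv in levels)


@dataclass
class SessionLog:
    """Ordered trials of one session plus provenance metadata."""

    config: TaskConfig
    trials: list[TrialRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = [t.trial_index for t in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("trial_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {col: getattr(t, col) for col in TRIAL_LOG_COLUMNS} for t in self.trials
        ]
        return pd.DataFrame(rows, columns=list(TRIAL_LOG_COLUMNS))


@dataclass
class FollowUpTable:
    """Per-coherence accuracy from internal-only follow-up trials.

    This is the participant's empirical internal-probability estimate:
    ``p_correct(c)`` is the baseline probability of performing the
    perceptual discrimination correctly at coherence ``c``.
    """

    counts: dict[float, tuple[int, int]]  # coherence -> (n_trials, n_correct)

    def __post_init__(self) -> None:
        for c, (n, k) in self.counts.items():
            if n <= 0 or not (0 <= k <= n):
                raise ValueError(f"invalid counts ({n}, {k}) at coherence {c}")
        levels = sorted(self.counts)
        accs = [self.p_correct(c) for c in levels]
        if any(b < a - 0.10 for a, b in zip(accs, accs[1:])):
            warnings.warn(
                "follow-up accuracy is markedly non-monotone in coherence",
                stacklevel=2,
            )

    def p_correct(self, coherence: float) -> float:
        for c, (n, k) in self.counts.items():
            if abs(c - coherence) <= 1e-9:
                return k / n
        raise KeyError(f"no follow-up entry for coherence {coherence}")

    def __contains__(self, coherence: float) -> bool:
        return any(abs(c - coherence) <= 1e-9 for c in self.counts)

    @property
    def n_total(self) -> int:
        return sum(n for n, _ in self.counts.values())


# ---------------------------------------------------------------------------
# Trial-log I/O.  UTF-8 TSV, one header line, booleans as 0/1, probabilities
# as decimals with at most six significant digits, so identical logs always
# serialize to identical bytes.


def _fmt_float(x: float) -> str:
    return format(x, ".6g")


def write_session_log(log: SessionLog, path: str | Path) -> None:
    """Write a session log as a deterministic UTF-8 TSV."""
    lines = ["\t".join(TRIAL_LOG_COLUMNS)]
    for t in log.trials:
        lines.append(
            "\t".join(
                [
                    t.session_id,
                    str(t.trial_index),
                    _fmt_float(t.coherence),
                    _fmt_float(t.p_external),
                    str(int(t.chose_internal)),
                    t.true_direction,
                    t.response_direction,
                    str(int(t.perceptual_correct)),
                    str(int(t.rewarded)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_session_log(
    path: str | Path,
    dialect: str = "tsv",
    config: TaskConfig | None = None,
) -> SessionLog:
    """Read and validate a trial log.

    Rows violating trial invariants are collected and reported together
    with their (1-based, header-exclusive) row numbers.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype={"session_id": str})
    missing = set(TRIAL_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise TrialLogFormatError(f"missing columns: {sorted(missing)}")

    cfg = config or TaskConfig()
    trials: list[TrialRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = TrialRecord(
            session_id=str(row.session_id),
            trial_index=int(row.trial_index),
            coherence=float(row.coherence),
            p_external=float(row.p_external),
            chose_internal=bool(int(row.chose_internal)),
            true_direction=str(row.true_direction),
            response_direction=str(row.response_direction),
            perceptual_correct=bool(int(row.perceptual_correct)),
            rewarded=bool(int(row.rewarded)),
        )
        for msg in rec.validate(cfg):
            problems.append(f"row {i}: {msg}")
        trials.append(rec)
    if problems:
        raise TrialValidationError(problems)
    return SessionLog(config=cfg, trials=trials)


def followup_table(followup_trials: Sequence[TrialRecord]) -> FollowUpTable:
    """Tabulate per-coherence accuracy from internal-only follow-up trials."""
    if not followup_trials:
        raise ValueError("no follow-up trials supplied")
    if not all(t.chose_internal for t in followup_trials):
        raise ValueError("follow-up trials must be internal-only perceptual trials")
    counts: dict[float, list[int]] = {}
    for t in followup_trials:
        cell = counts.setdefault(t.coherence, [0, 0])
        cell[0] += 1
        cell[1] += int(t.perceptual_correct)
    return FollowUpTable({c: (n, k) for c, (n, k) in sorted(counts.items())})


def write_followup_table(table: FollowUpTable, path: str | Path) -> None:
    lines = ["\t".join(FOLLOWUP_COLUMNS)]
    for c in sorted(table.counts):
        n, k = table.counts[c]
        lines.append(f"{_fmt_float(c)}\t{n}\t{k}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_followup_table(path: str | Path) -> FollowUpTable:
    df = pd.read_csv(path, sep="\t")
    missing = set(FOLLOWUP_COLUMNS) - set(df.columns)
    if missing:
        raise TrialLogFormatError(f"missing columns: {sorted(missing)}")
    return FollowUpTable(
        {
            float(r.coherence): (int(r.n_trials), int(r.n_correct))
            for r in df.itertuples(index=False)
        }
    )
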