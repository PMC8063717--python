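"""Parameterized synthetic observer for the two-stage task.

The generative model, per trial with offer ``(c, p_ext)``:

1. A signed perceptual evidence sample ``e ~ Normal(c, sigma_e)`` is drawn,
   oriented toward the true motion direction.  Negative ``e`` means the
   stimulus happened to carry evidence for the wrong direction.
2. At the metacognitive stage the observer reads the evidence strength
   ``|e|`` through the psychometric accuracy curve to form a subjective
   internal success probability ``p_int_hat``, distorts both probabilities
   with a Prospect-Theory weighting function, and chooses the internal
   option with probability

       sigmoid( choice_beta * [w(p_int_hat; g_int) - w(p_ext; g_ext)]
                + meta_noise * z ),   z ~ Normal(0, 1).

   ``meta_noise`` is a log-odds-scale readout noise: as it grows, the
   choice decouples from the evidence and the marginal choice probability
   tends to one half for every offer.
3. If the internal option is chosen, the perceptual outcome is driven by
   the SAME evidence sample ``e``: the response is correct with probability
   ``acc(|e|)`` when the evidence points the right way, ``1 - acc(|e|)``
   otherwise.  This shared-evidence channel is what makes metacognitive
   selection predictive of subsequent perceptual performance at a fixed
   coherence; it is one concrete mechanism among several that would
   produce trial-level metacognitive sensitivity.
4. External perceptual decisions are correct with a fixed ceiling
   probability (0.979, the empirical rate in this design where the
   external stimulus is fully coherent), and rewards follow the task rule:
   correct internal choices are always rewarded, correct external choices
   are rewarded with probability ``p_ext``.

A theta-burst-stimulation (cTBS) manipulation of the metacognitive stage
is modeled abstractly as a multiplicative inflation of ``meta_noise``;
the vertex control condition multiplies by exactly 1 and therefore
consumes the identical random stream as no stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy.special import expit

from .task_core import SessionLog, TaskConfig, TrialRecord
from .utility_fit import prospect_weight

__all__ = [
    "EXTERNAL_ACCURACY",
    "AgentParams",
    "SimulationSpec",
    "ScheduleWarning",
    "perceptual_accuracy",
    "simulate_trial",
    "simulate_followup_trial",
    "simulate_session",
    "simulate_study",
]

#: Probability of a correct perceptual response when the (fully coherent)
#: external option is performed.
EXTERNAL_ACCURACY = 0.979

_DIRECTIONS = ("left", "right")


class ScheduleWarning(UserWarning):
    """The session length does not divide the 8x8 offer grid evenly."""


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of the simulated observer.

    threshold, slope, lapse
        Weibull psychometric accuracy curve over coherence:
        ``acc(c) = 0.5 + (0.5 - lapse/2) * (1 - exp(-(c/threshold)**slope))``,
        anchored at chance for zero coherence.
    gamma_internal, gamma_external
        Prospect-Theory distortion exponents for the subjective internal
        and external probabilities; 1 means no distortion, smaller values
        mean stronger inverse-S distortion.
    choice_beta
        Inverse temperature of the metacognitive choice (log-odds per
        unit of weighted-probability difference).
    evidence_sd
        Standard deviation of the trial-level evidence sample, in
        coherence units.
    meta_noise
        Log-odds-scale noise added to the metacognitive readout.
    """

    threshold: float = 0.15
    slope: float = 1.3
    lapse: float = 0.02
    gamma_internal: float = 0.7
    gamma_external: float = 0.7
    choice_beta: float = 6.0
    evidence_sd: float = 0.08
    meta_noise: float = 1.5

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.slope <= 0:
            raise ValueError("psychometric threshold and slope must be positive")
        if not 0 <= self.lapse < 1:
            raise ValueError("lapse must lie in [0, 1)")
        if self.gamma_internal <= 0 or self.gamma_external <= 0:
            raise ValueError("distortion exponents must be positive")
        if self.choice_beta < 0:
            raise ValueError("choice_beta must be non-negative")
        if self.evidence_sd < 0 or self.meta_noise < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class SimulationSpec:
    """A complete study specification: task, observer, and conditions."""

    task: TaskConfig = field(default_factory=TaskConfig)
    agent: AgentParams = field(default_factory=AgentParams)
    n_sessions: int = 2
    include_followup: bool = True
    tms_condition: Literal["none", "alpfc", "vertex"] = "none"
    tms_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be at least 1")
        if self.tms_condition not in ("none", "alpfc", "vertex"):
            raise ValueError(f"unknown tms_condition {self.tms_condition!r}")
        if self.tms_factor <= 0:
            raise ValueError("tms_factor must be positive")

    @property
    def meta_noise_factor(self) -> float:
        # vertex stimulation is a true no-op: the factor is exactly 1, so
        # the random stream is byte-identical to the unstimulated run.
        return self.tms_factor if self.tms_condition == "alpfc" else 1.0

    def to_dict(self) -> dict:
        d = {
            "agent": asdict(self.agent),
            "n_sessions": self.n_sessions,
            "include_followup": self.include_followup,
            "tms_condition": self.tms_condition,
            "tms_factor": self.tms_factor,
            "n_trials_per_session": self.task.n_trials_per_session,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        task = TaskConfig(
            n_trials_per_session=int(d.get("n_trials_per_session", 195))
        )
        agent = AgentParams(**d.get("agent", {}))
        return cls(
            task=task,
            agent=agent,
            n_sessions=int(d.get("n_sessions", 2)),
            include_followup=bool(d.get("include_followup", True)),
            tms_condition=d.get("tms_condition", "none"),
            tms_factor=float(d.get("tms_factor", 3.0)),
        )


def perceptual_accuracy(c, params: AgentParams):
    """P(correct | coherence) of the observer's psychometric curve.

    Chance-anchored at zero coherence and saturating at ``1 - lapse/2``.
    Accepts scalars or arrays.
    """
    c = np.asarray(c, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("coherence must lie in [0, 1]")
    acc = 0.5 + (0.5 - params.lapse / 2.0) * (
        1.0 - np.exp(-((c / params.threshold) ** params.slope))
    )
    return float(acc) if acc.ndim == 0 else acc


def _trial_accuracy(e: float, params: AgentParams) -> float:
    """Per-trial correctness probability given signed evidence ``e``."""
    pa = perceptual_accuracy(min(abs(e), 1.0), params)
    return pa if e >= 0 else 1.0 - pa


def simulate_trial(
    offer: tuple[float, float],
    agent: AgentParams,
    rng: np.random.Generator,
    *,
    session_id: str = "sim",
    trial_index: int = 1,
    meta_noise_factor: float = 1.0,
) -> TrialRecord:
    """Simulate one two-stage trial at offer ``(coherence, p_external)``.

    Always consumes exactly six random draws, so runs under different
    condition labels with equal seeds stay stream-aligned.
    """
    c, p_ext = offer
    true_direction = _DIRECTIONS[int(rng.random() < 0.5)]
    e = rng.normal(c, agent.evidence_sd)
    z = rng.standard_normal()
    u_choice = rng.random()
    u_correct = rng.random()
    u_reward = rng.random()

    p_int_hat = perceptual_accuracy(min(abs(e), 1.0), agent)
    dv = prospect_weight(p_int_hat, agent.gamma_internal) - prospect_weight(
        p_ext, agent.gamma_external
    )
    logit = agent.choice_beta * dv + agent.meta_noise * meta_noise_factor * z
    chose_internal = u_choice < expit(logit)

    if chose_internal:
        correct = u_correct < _trial_accuracy(e, agent)
        rewarded = correct  # internal option pays with certainty
    else:
        correct = u_correct < EXTERNAL_ACCURACY
        rewarded = correct and (u_reward < p_ext)

    response = true_direction if correct else _DIRECTIONS[true_direction == "left"]
    return TrialRecord(
        session_id=session_id,
        trial_index=trial_index,
        coherence=c,
        p_external=p_ext,
        chose_internal=bool(chose_internal),
        true_direction=true_direction,
        response_direction=response,
        perceptual_correct=bool(correct),
        rewarded=bool(rewarded),
    )


def simulate_followup_trial(
    coherence: float,
    agent: AgentParams,
    rng: np.random.Generator,
    *,
    session_id: str = "sim-followup",
    trial_index: int = 1,
) -> TrialRecord:
    """One internal-only perceptual trial (no metacognitive stage)."""
    true_direction = _DIRECTIONS[int(rng.random() < 0.5)]
    e = rng.normal(coherence, agent.evidence_sd)
    correct = rng.random() < _trial_accuracy(e, agent)
    response = true_direction if correct else _DIRECTIONS[true_direction == "left"]
    return TrialRecord(
        session_id=session_id,
        trial_index=trial_index,
        coherence=coherence,
        p_external=1.0,
        chose_internal=True,
        true_direction=true_direction,
        response_direction=response,
        perceptual_correct=bool(correct),
        rewarded=bool(correct),
    )


def _offer_schedule(
    task: TaskConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Balanced, shuffled offer schedule covering the full grid.

    Full 8x8 blocks are repeated and independently shuffled; a trailing
    partial block takes the first offers of one more shuffled grid pass.
    """
    grid = task.grid
    n = task.n_trials_per_session
    if n % len(grid) != 0:
        warnings.warn(
            f"session length {n} is not a multiple of the {len(grid)}-offer "
            "grid; the final block is a truncated shuffled grid pass",
            ScheduleWarning,
            stacklevel=2,
        )
    schedule: list[tuple[float, float]] = []
    while len(schedule) < n:
        block = list(grid)
        perm = rng.permutation(len(block))
        schedule.extend(block[i] for i in perm)
    return schedule[:n]


def simulate_session(
    spec: SimulationSpec,
    seed: int,
    session_index: int = 0,
) -> tuple[SessionLog, SessionLog | None]:
    """Simulate one main session (and, optionally, its follow-up session).

    The follow-up uses the identical multiset of coherence levels as the
    main session's offers, in a freshly shuffled order, with no choice
    stage.  Fully reproducible: trial streams are keyed by
    ``(seed, session_index, trial_index)``.
    """
    session_id = f"s{session_index:02d}"
    sched_rng = np.random.default_rng([seed, session_index, 0])
    with warnings.catch_warnings():
        if spec.task.n_trials_per_session == 195:
            # the canonical session length; the partial grid block is by design
            warnings.simplefilter("ignore", ScheduleWarning)
        schedule = _offer_schedule(spec.task, sched_rng)

    factor = spec.meta_noise_factor
    trials = [
        simulate_trial(
            offer,
            spec.agent,
            np.random.default_rng([seed, session_index, i]),
            session_id=session_id,
            trial_index=i,
            meta_noise_factor=factor,
        )
        for i, offer in enumerate(schedule, start=1)
    ]
    meta = {
        "seed": seed,
        "session_index": session_index,
        "tms_condition": spec.tms_condition,
        "agent": asdict(spec.agent),
    }
    main_log = SessionLog(config=spec.task, trials=trials, metadata=meta)

    followup_log = None
    if spec.include_followup:
        coherences = [c for c, _ in schedule]
        order = np.random.default_rng([seed, session_index, 1_000_000]).permutation(
            len(coherences)
        )
        ftrials = [
            simulate_followup_trial(
                coherences[j],
                spec.agent,
                np.random.default_rng([seed, session_index, 1_000_001 + i]),
                session_id=session_id + "-followup",
                trial_index=i,
            )
            for i, j in enumerate(order, start=1)
        ]
        followup_log = SessionLog(
            config=spec.task, trials=ftrials, metadata=dict(meta, followup=True)
        )
    return main_log, followup_log


def simulate_study(
    spec: SimulationSpec, seed: int
) -> list[tuple[SessionLog, SessionLog | None]]:
    """Simulate all sessions of a study specification."""
    return [
        simulate_session(spec, seed, session_index=i) for i in range(spec.n_sessions)
    ]
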