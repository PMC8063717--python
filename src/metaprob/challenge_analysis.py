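"""Challenge vs inevitable trials and the cTBS behavioral contrast.

A *challenge* trial is one on which the rejected-able external option
carried, on average, a higher reward probability than the internal option
(the follow-up baseline accuracy times its certain payout): choosing the
internal option there means deliberately taking on a harder bet.  An
*inevitable* trial is the reverse.  The headline behavioral effect is
that, at moderate coherences where accuracy is off both floor and
ceiling, perceptual performance on internal-option trials is better in
challenge than in inevitable trials — evidence that observers pick their
internal battles using genuine trial-level metacognitive information.
Inflating the metacognitive readout noise (the abstract cTBS model)
abolishes this benefit and lowers type II A_ROC while sparing type I.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sdt_metrics import classify_optimality, sdt_summary
from .task_core import FollowUpTable, SessionLog, TrialRecord

__all__ = [
    "MODERATE_COHERENCES",
    "ChallengeLabel",
    "ChallengeContrast",
    "TmsReport",
    "classify_challenge",
    "challenge_contrast",
    "tms_contrast",
]

#: Coherence levels where accuracy is reliably above chance but below
#: ceiling, so a selection benefit can express itself.
MODERATE_COHERENCES: tuple[float, ...] = (0.06, 0.12)


@dataclass(frozen=True)
class ChallengeLabel:
    """Trial class and moderate-coherence flag."""

    clazz: str  # "challenge" | "inevitable" | "excluded"
    moderate: bool


@dataclass
class ChallengeContrast:
    acc_challenge: float
    acc_inevitable: float
    difference: float
    n_challenge: int
    n_inevitable: int


@dataclass
class TmsReport:
    """Per-condition challenge contrasts and SDT indices."""

    contrast_baseline: ChallengeContrast
    contrast_tms: ChallengeContrast
    type_two_baseline: float
    type_two_tms: float
    type_one_baseline: float
    type_one_tms: float

    @property
    def type_two_delta(self) -> float:
        return self.type_two_tms - self.type_two_baseline

    @property
    def type_one_delta(self) -> float:
        return self.type_one_tms - self.type_one_baseline

    @property
    def challenge_benefit_delta(self) -> float:
        return self.contrast_tms.difference - self.contrast_baseline.difference


def classify_challenge(
    trials: Sequence[TrialRecord],
    followup: FollowUpTable,
    moderate_coherences: Sequence[float] = MODERATE_COHERENCES,
) -> list[ChallengeLabel]:
    """Label every trial challenge, inevitable, or excluded (exact tie)."""
    labels = []
    for t in trials:
        if t.coherence not in followup:
            raise ValueError(f"follow-up table has no entry for coherence {t.coherence}")
        expected_internal = followup.p_correct(t.coherence) * 1.0
        if t.p_external > expected_internal:
            clazz = "challenge"
        elif t.p_external < expected_internal:
            clazz = "inevitable"
        else:
            clazz = "excluded"
        moderate = any(abs(t.coherence - c) <= 1e-9 for c in moderate_coherences)
        labels.append(ChallengeLabel(clazz=clazz, moderate=moderate))
    return labels


def challenge_contrast(
    trials: Sequence[TrialRecord],
    labels: Sequence[ChallengeLabel],
    coherence_set: Sequence[float] = MODERATE_COHERENCES,
    *,
    pool_coherences: bool = False,
) -> ChallengeContrast:
    """Internal-option accuracy difference, challenge minus inevitable.

    Restricted to trials where the internal option was actually chosen
    and the coherence is in ``coherence_set``.  By default the two class
    accuracies are computed within each coherence level and averaged
    with equal weight across levels — the same comparison as overlaying
    per-coherence challenge and inevitable performance lines.  This
    matters because the challenge class over-represents harder
    coherences (a low baseline accuracy makes more external offers
    exceed it), so pooling across coherences confounds the selection
    benefit with stimulus difficulty; ``pool_coherences=True`` gives the
    raw pooled version.
    """
    if len(trials) != len(labels):
        raise ValueError("trials and labels must be aligned")
    by_c: dict[float, dict[str, list[bool]]] = {}
    for t, lab in zip(trials, labels):
        if not t.chose_internal or lab.clazz == "excluded":
            continue
        if not any(abs(t.coherence - c) <= 1e-9 for c in coherence_set):
            continue
        by_c.setdefault(t.coherence, {"challenge": [], "inevitable": []})[
            lab.clazz
        ].append(t.perceptual_correct)

    n_ch = sum(len(d["challenge"]) for d in by_c.values())
    n_in = sum(len(d["inevitable"]) for d in by_c.values())
    if pool_coherences:
        if n_ch == 0 or n_in == 0:
            raise ValueError(
                f"empty class among chosen-internal moderate trials: "
                f"{n_ch} challenge, {n_in} inevitable"
            )
        a_ch = float(np.mean([x for d in by_c.values() for x in d["challenge"]]))
        a_in = float(np.mean([x for d in by_c.values() for x in d["inevitable"]]))
    else:
        accs_ch, accs_in = [], []
        for c in sorted(by_c):
            d = by_c[c]
            if not d["challenge"] or not d["inevitable"]:
                raise ValueError(
                    f"empty class at coherence {c}: "
                    f"{len(d['challenge'])} challenge, "
                    f"{len(d['inevitable'])} inevitable"
                )
            accs_ch.append(np.mean(d["challenge"]))
            accs_in.append(np.mean(d["inevitable"]))
        if not accs_ch:
            raise ValueError("no chosen-internal trials at the requested coherences")
        a_ch = float(np.mean(accs_ch))
        a_in = float(np.mean(accs_in))
    return ChallengeContrast(
        acc_challenge=a_ch,
        acc_inevitable=a_in,
        difference=a_ch - a_in,
        n_challenge=n_ch,
        n_inevitable=n_in,
    )


def check_label_consistency(
    trials: Sequence[TrialRecord],
    followup: FollowUpTable,
) -> bool:
    """Challenge/inevitable and optimality labels apply the same inequality.

    Wherever both labelings are defined and no tie occurs, a challenge
    trial is exactly an external-optimal trial.  Returns True when
    consistent (and raises AssertionError otherwise); exposed as a
    cross-module self-check.
    """
    ch = classify_challenge(trials, followup)
    opt = classify_optimality(trials, followup)
    for c_lab, o_lab in zip(ch, opt):
        if o_lab is None or c_lab.clazz == "excluded":
            continue
        assert (c_lab.clazz == "challenge") == (not o_lab.internal_optimal)
    return True


def _pool_trials(logs: Sequence[SessionLog]) -> list[TrialRecord]:
    return [t for log in logs for t in log.trials]


def tms_contrast(
    logs_tms: Sequence[SessionLog],
    logs_baseline: Sequence[SessionLog],
    followup_tms: FollowUpTable,
    followup_baseline: FollowUpTable | None = None,
    coherence_set: Sequence[float] = MODERATE_COHERENCES,
) -> TmsReport:
    """Stimulation-vs-baseline report: challenge benefit and both areas.

    The expected dissociation under metacognitive disruption: type II
    A_ROC drops, type I A_ROC is spared, and the challenge benefit at
    moderate coherence shrinks or reverses.
    """
    if followup_baseline is None:
        followup_baseline = followup_tms
    cfg_a = logs_tms[0].config
    cfg_b = logs_baseline[0].config
    if cfg_a.coherence_levels != cfg_b.coherence_levels or (
        cfg_a.external_probabilities != cfg_b.external_probabilities
    ):
        raise ValueError("stimulation and baseline task configurations differ")

    trials_tms = _pool_trials(logs_tms)
    trials_base = _pool_trials(logs_baseline)
    con_tms = challenge_contrast(
        trials_tms, classify_challenge(trials_tms, followup_tms), coherence_set
    )
    con_base = challenge_contrast(
        trials_base, classify_challenge(trials_base, followup_baseline), coherence_set
    )
    sdt_tms = sdt_summary(trials_tms, followup_tms)
    sdt_base = sdt_summary(trials_base, followup_baseline)
    return TmsReport(
        contrast_baseline=con_base,
        contrast_tms=con_tms,
        type_two_baseline=sdt_base.type_two.area,
        type_two_tms=sdt_tms.type_two.area,
        type_one_baseline=sdt_base.type_one.area,
        type_one_tms=sdt_tms.type_one.area,
    )
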