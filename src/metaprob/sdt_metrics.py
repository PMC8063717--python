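"""Signal-detection statistics for metacognitive and perceptual accuracy.

Type II A_ROC measures how well option selection tracked which option was
actually the better one.  Trials at the four intermediate coherence levels
are labelled internal-optimal or external-optimal by comparing the
expected internal reward (the follow-up baseline accuracy times the
internal option's certain payout) against the offered external
probability.  Choosing the internal option on an internal-optimal trial is
a hit; choosing it on an external-optimal trial is a false alarm.  One
(FA rate, hit rate) point per coherence level, plus the (0,0) and (1,1)
anchors, traces an ROC curve whose trapezoidal area is type II A_ROC.

Type I A_ROC measures first-order perceptual discrimination on
internal-option trials from the left/right hit and false-alarm rates via
the equal-variance Gaussian model:

    A = Phi( (Z(hit) - Z(fa)) / sqrt(2) ),     d' = Z(hit) - Z(fa)

Metacognitive efficiency is the M-ratio meta-d'/d', where both
sensitivities are read off their areas with the same transform
(d' = sqrt(2) * Z(A)), so M-ratio reduces to Z(A_II) / Z(A_I) and equals 1
when the two areas coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .task_core import FollowUpTable, TrialRecord

__all__ = [
    "ELIGIBLE_COHERENCES",
    "OptimalityLabel",
    "RocPoint",
    "TypeTwoResult",
    "TypeOneResult",
    "SDTResult",
    "DegenerateRocError",
    "classify_optimality",
    "type_two_aroc",
    "type_one_aroc",
    "m_ratio",
    "sdt_summary",
]

#: Coherence levels entering the type II analysis: levels at which the
#: optimal choice genuinely varies across external probabilities.
ELIGIBLE_COHERENCES: tuple[float, ...] = (0.03, 0.06, 0.12, 0.25)


class DegenerateRocError(ValueError):
    """The ROC area is undefined (all trials fall in one class)."""


@dataclass(frozen=True)
class OptimalityLabel:
    """Whether the internal option was the optimal choice on a trial."""

    internal_optimal: bool


@dataclass(frozen=True)
class RocPoint:
    coherence: float
    fa_rate: float
    hit_rate: float
    n_hit_opportunities: int
    n_fa_opportunities: int


@dataclass
class TypeTwoResult:
    area: float
    points: list[RocPoint]


@dataclass
class TypeOneResult:
    area: float
    d_prime: float
    hit_rate: float
    fa_rate: float
    n_signal: int
    n_noise: int


@dataclass
class SDTResult:
    """Full signal-detection report for one participant/log."""

    type_two: TypeTwoResult
    type_one: TypeOneResult
    meta_d_prime: float
    d_prime: float
    m_ratio: float
    extras: dict = field(default_factory=dict)


def classify_optimality(
    trials: Sequence[TrialRecord],
    followup: FollowUpTable,
    eligible_coherences: Sequence[float] = ELIGIBLE_COHERENCES,
) -> list[OptimalityLabel | None]:
    """Label each trial internal- or external-optimal; None if ineligible.

    A trial is internal-optimal when the expected internal reward
    (follow-up accuracy at its coherence, times the internal option's
    certain payout of 1) is at least the offered external probability;
    ties favor the internal option.
    """
    for c in eligible_coherences:
        if c not in followup:
            raise ValueError(f"follow-up table has no entry for coherence {c}")
    labels: list[OptimalityLabel | None] = []
    for t in trials:
        if not any(abs(t.coherence - c) <= 1e-9 for c in eligible_coherences):
            labels.append(None)
            continue
        expected_internal = followup.p_correct(t.coherence) * 1.0
        labels.append(OptimalityLabel(expected_internal >= t.p_external))
    return labels


def type_two_aroc(
    trials: Sequence[TrialRecord],
    labels: Sequence[OptimalityLabel | None],
    *,
    include_anchors: bool = True,
) -> TypeTwoResult:
    """Area under the per-coherence (FA rate, hit rate) ROC curve.

    Coherence levels lacking either hit or FA opportunities are dropped
    with a warning; if no trial of one class exists anywhere the area is
    undefined and a :class:`DegenerateRocError` is raised rather than
    silently returning 0.5.
    """
    if len(trials) != len(labels):
        raise ValueError("trials and labels must be aligned")
    by_c: dict[float, list[tuple[bool, bool]]] = {}
    for t, lab in zip(trials, labels):
        if lab is None:
            continue
        by_c.setdefault(t.coherence, []).append((lab.internal_optimal, t.chose_internal))
    n_opt = sum(int(o) for cells in by_c.values() for o, _ in cells)
    n_nonopt = sum(int(not o) for cells in by_c.values() for o, _ in cells)
    if n_opt == 0 or n_nonopt == 0:
        raise DegenerateRocError(
            "type II ROC undefined: "
            f"{n_opt} internal-optimal vs {n_nonopt} external-optimal trials"
        )

    points: list[RocPoint] = []
    for c in sorted(by_c):
        cells = by_c[c]
        hits = [chose for opt, chose in cells if opt]
        fas = [chose for opt, chose in cells if not opt]
        if not hits or not fas:
            warnings.warn(
                f"coherence {c}: no {'hit' if not hits else 'FA'} opportunities; "
                "point dropped",
                stacklevel=2,
            )
            continue
        points.append(
            RocPoint(
                coherence=c,
                fa_rate=float(np.mean(fas)),
                hit_rate=float(np.mean(hits)),
                n_hit_opportunities=len(hits),
                n_fa_opportunities=len(fas),
            )
        )
    xy = [(p.fa_rate, p.hit_rate) for p in points]
    area = roc_area(xy, include_anchors=include_anchors)
    return TypeTwoResult(area=area, points=points)


def roc_area(
    points: Sequence[tuple[float, float]], *, include_anchors: bool = True
) -> float:
    """Trapezoidal area under sorted ROC points, optionally anchored."""
    pts = [(float(x), float(y)) for x, y in points]
    if include_anchors:
        pts += [(0.0, 0.0), (1.0, 1.0)]
    if len(pts) < 2:
        raise DegenerateRocError("need at least two ROC points")
    pts.sort()
    xs = np.array([x for x, _ in pts])
    ys = np.array([y for _, y in pts])
    return float(np.trapezoid(ys, xs))


def _edge_corrected_rate(k: int, n: int) -> float:
    # log-linear style correction keeping Z finite at observed 0 or 1
    return (k + 0.5) / (n + 1.0)


def type_one_aroc(
    trials: Sequence[TrialRecord],
    *,
    exclude_zero_coherence: bool = True,
    edge_correction: bool = True,
) -> TypeOneResult:
    """Perceptual-discrimination area for internal-option trials.

    Hit: responding "left" when the dots moved leftward; false alarm:
    responding "left" when they moved rightward.  Rates at observed 0 or 1
    are pulled inside (0,1) with a (k+0.5)/(n+1) correction so the normal
    quantile stays finite.  Zero-coherence trials, whose correct direction
    is objectively ambiguous, are excluded by default.
    """
    perceptual = [t for t in trials if t.chose_internal]
    if exclude_zero_coherence:
        perceptual = [t for t in perceptual if t.coherence > 1e-9]
    signal = [t for t in perceptual if t.true_direction == "left"]
    noise = [t for t in perceptual if t.true_direction == "right"]
    if not signal or not noise:
        raise ValueError(
            f"need trials of both directions: {len(signal)} left, {len(noise)} right"
        )
    k_hit = sum(t.response_direction == "left" for t in signal)
    k_fa = sum(t.response_direction == "left" for t in noise)
    if edge_correction:
        hit = _edge_corrected_rate(k_hit, len(signal))
        fa = _edge_corrected_rate(k_fa, len(noise))
    else:
        hit = k_hit / len(signal)
        fa = k_fa / len(noise)
        if hit in (0.0, 1.0) or fa in (0.0, 1.0):
            raise ValueError("rate of 0 or 1 without edge correction")
    d_prime = float(norm.ppf(hit) - norm.ppf(fa))
    area = float(norm.cdf(d_prime / np.sqrt(2.0)))
    return TypeOneResult(
        area=area,
        d_prime=d_prime,
        hit_rate=hit,
        fa_rate=fa,
        n_signal=len(signal),
        n_noise=len(noise),
    )


def m_ratio(type_two_area: float, type_one_area: float) -> float:
    """Metacognitive efficiency meta-d'/d' from the two ROC areas.

    With d' = sqrt(2) * Z(A_I) and meta-d' = sqrt(2) * Z(A_II) the ratio
    reduces to Z(A_II)/Z(A_I); it equals 1 whenever the areas coincide.
    """
    for name, a in (("type II", type_two_area), ("type I", type_one_area)):
        if not 0.0 < a < 1.0:
            raise ValueError(f"{name} area must lie strictly in (0, 1), got {a}")
    if type_one_area == 0.5:
        raise ValueError("M-ratio undefined at chance type I area (d' = 0)")
    return float(norm.ppf(type_two_area) / norm.ppf(type_one_area))


def sdt_summary(
    trials: Sequence[TrialRecord], followup: FollowUpTable
) -> SDTResult:
    """Full SDT report: both areas, sensitivities, and M-ratio."""
    labels = classify_optimality(trials, followup)
    t2 = type_two_aroc(trials, labels)
    t1 = type_one_aroc(trials)
    meta_d = float(np.sqrt(2.0) * norm.ppf(t2.area))
    d = float(np.sqrt(2.0) * norm.ppf(t1.area))
    ratio = m_ratio(t2.area, t1.area) if t1.area != 0.5 else float("nan")
    return SDTResult(
        type_two=t2,
        type_one=t1,
        meta_d_prime=meta_d,
        d_prime=d,
        m_ratio=ratio,
    )
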