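"""Prospect-Theory probability weighting and risk metrics.

The one-parameter weighting function

    w(p; gamma) = p**gamma / (p**gamma + (1-p)**gamma) ** (1/gamma)

maps objective to subjective probability.  ``gamma = 1`` is the identity;
``gamma < 1`` produces the classic inverse-S distortion (overweighting of
low probabilities, underweighting of high ones), and smaller gamma means
stronger distortion.

The empirical choice curve pairs, per option level, the proportion of
trials on which the option *should* have been chosen by an optimal
observer (objective probability ``p``) with the proportion on which it
*was* chosen (subjective probability ``w``).  ``fit_gamma`` then recovers
the distortion exponent by bounded scalar least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .task_core import FollowUpTable, SessionLog

__all__ = [
    "UtilityFit",
    "prospect_weight",
    "empirical_choice_curve",
    "fit_gamma",
    "risk_metrics",
]

GAMMA_BOUNDS = (0.05, 20.0)


@dataclass
class UtilityFit:
    """Fitted probability-weighting curve and its data."""

    gamma: float
    log_gamma: float
    sse: float
    pairs: list[tuple[float, float]]  # (objective p, observed w) per bin


def prospect_weight(p, gamma: float):
    """Evaluate the one-parameter weighting function ``w(p; gamma)``.

    Accepts scalars or arrays; exact at the boundaries (w(0)=0, w(1)=1).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    num = p**gamma
    den = (p**gamma + (1.0 - p) ** gamma) ** (1.0 / gamma)
    w = num / den
    return float(w) if w.ndim == 0 else w


def _optimal_internal(coherence: float, p_external: float, followup: FollowUpTable) -> bool:
    # expected internal reward = baseline accuracy x certain payout (1.0);
    # ties favor the internal option (its payout carries no extra risk)
    return followup.p_correct(coherence) * 1.0 >= p_external


def empirical_choice_curve(
    log: SessionLog | Sequence,
    followup: FollowUpTable,
    side: Literal["internal", "external"] = "internal",
) -> list[tuple[float, float, float, int]]:
    """Per-level (level, p, w, n) pairs for one option side.

    ``p`` is the optimal-choice proportion in the bin (how often that side
    was the better option), ``w`` the observed-choice proportion.  Internal
    bins are coherence levels, external bins are offered reward
    probabilities.
    """
    if side not in ("internal", "external"):
        raise ValueError(f"unknown side {side!r}")
    trials = log.trials if isinstance(log, SessionLog) else list(log)
    if not trials:
        raise ValueError("no trials supplied")
    bins: dict[float, list] = {}
    for t in trials:
        level = t.coherence if side == "internal" else t.p_external
        bins.setdefault(level, []).append(t)
    curve = []
    for level in sorted(bins):
        ts = bins[level]
        internal_opt = np.array(
            [_optimal_internal(t.coherence, t.p_external, followup) for t in ts]
        )
        chose_internal = np.array([t.chose_internal for t in ts])
        if side == "internal":
            p = internal_opt.mean()
            w = chose_internal.mean()
        else:
            p = 1.0 - internal_opt.mean()
            w = 1.0 - chose_internal.mean()
        curve.append((level, float(p), float(w), len(ts)))
    return curve


def fit_gamma(
    pairs: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> UtilityFit:
    """Least-squares fit of the distortion exponent gamma.

    Minimizes ``sum (w_obs - w(p; gamma))**2`` over ``gamma`` in
    ``GAMMA_BOUNDS`` by bounded scalar search (tolerance 1e-6).  Pass
    per-pair ``weights`` (e.g. bin counts) for a weighted fit; the default
    is unweighted.
    """
    pairs = [(float(p), float(w)) for p, w in pairs]
    if len(pairs) < 3:
        raise ValueError("need at least 3 (p, w) pairs")
    p = np.array([x for x, _ in pairs])
    w_obs = np.array([y for _, y in pairs])
    if np.ptp(p) == 0:
        raise ValueError("gamma is not identifiable: all objective p equal")
    wt = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)

    def sse(g: float) -> float:
        return float(np.sum(wt * (w_obs - prospect_weight(p, g)) ** 2))

    # the SSE landscape can be multimodal when the p placements are
    # narrow, so scan a log-spaced grid first and refine the best cell
    grid = np.geomspace(GAMMA_BOUNDS[0], GAMMA_BOUNDS[1], 80)
    best = int(np.argmin([sse(g) for g in grid]))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(
        sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
    )
    g = float(res.x)
    return UtilityFit(gamma=g, log_gamma=float(np.log(g)), sse=sse(g), pairs=pairs)


def risk_metrics(
    log: SessionLog | Sequence, side: Literal["internal", "external"]
) -> tuple[float, float]:
    """Reward rate and Bernoulli outcome variance for one option side."""
    trials = log.trials if isinstance(log, SessionLog) else list(log)
    subset = [t for t in trials if t.chose_internal == (side == "internal")]
    if not subset:
        raise ValueError(f"no trials on the {side} side")
    r = float(np.mean([t.rewarded for t in subset]))
    return r, r * (1.0 - r)
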