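"""Beta-timecourse machinery for region-of-interest (ROI) signals.

The analysis reproduced here regresses, at every post-onset time point, an
epoched ROI signal across trials on trial-level parametric regressors —
the internal reward probability of the option when it was chosen, and
when it was left unchosen (each regressor is defined on its own,
mutually exclusive, subset of trials).  The resulting beta timecourse
``beta(t)`` is summarized by

    slope     = (beta_max - beta_min) / (t_max - t_min)
    magnitude =  beta_max - beta_min

with ``beta_min`` the minimum over 0 < t < 4 s and ``beta_max`` the
maximum over t_min < t < 11 s (ties broken to the earliest time).  A
faster ramp-up of evidence-related activity yields a steeper slope even
at matched peak height — the signature of faster evidence accumulation
for chosen options.

A synthetic generator stands in for preprocessed BOLD: each event
contributes a gamma-variate response scaled by its regressor value, with
a per-condition time-to-peak (the ramp rate) and additive Gaussian noise.
Signals are z-scored and oversampled by a factor of 20 (linear
interpolation) before epoching, and regressors are z-scored across
trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiEvent",
    "RoiTimecourse",
    "RampParams",
    "BetaTimecourse",
    "SlopeResult",
    "SlopeContrast",
    "simulate_roi_timecourse",
    "random_event_schedule",
    "beta_timecourse",
    "slope_stat",
    "chosen_unchosen_slope_contrast",
    "read_roi_files",
    "write_roi_files",
]

OVERSAMPLING = 20
EPOCH_WINDOW = (0.0, 11.0)  # seconds post-onset
TMIN_WINDOW = (0.0, 4.0)


@dataclass(frozen=True)
class RoiEvent:
    """One trial onset with its parametric regressor values.

    Exactly one of the two regressors is defined per trial: the chosen
    internal probability on internal-choice trials, the unchosen internal
    probability on external-choice trials.
    """

    onset_s: float
    chosen_internal_prob: float | None = None
    unchosen_internal_prob: float | None = None


@dataclass
class RoiTimecourse:
    """Regularly sampled ROI signal with its event schedule."""

    dt: float  # sampling interval, seconds
    signal: np.ndarray
    events: list[RoiEvent]
    oversampling: int = OVERSAMPLING

    @property
    def duration(self) -> float:
        return (len(self.signal) - 1) * self.dt


@dataclass(frozen=True)
class RampParams:
    """Shape of the synthetic event-related response.

    ``time_to_peak_chosen/unchosen`` control how quickly the response
    ramps up in each condition; ``amplitude`` is the (matched) peak
    height of the unit-regressor response; ``shape`` the gamma-variate
    sharpness.
    """

    time_to_peak_chosen: float = 3.0
    time_to_peak_unchosen: float = 5.5
    amplitude: float = 1.0
    shape: float = 3.0


def _gamma_variate(t: np.ndarray, time_to_peak: float, amplitude: float, shape: float):
    """Gamma-variate response peaking at ``time_to_peak`` with height ``amplitude``."""
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / time_to_peak
    out[pos] = amplitude * tp**shape * np.exp(shape * (1.0 - tp))
    return out


def random_event_schedule(
    n_events: int,
    rng: np.random.Generator,
    *,
    p_internal: float = 0.5,
    prob_levels: Sequence[float] = (0.1, 0.3, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    start_s: float = 10.0,
) -> list[RoiEvent]:
    """Event onsets with Poisson-distributed SOAs (mean 3 s, range 2.5-8.5 s).

    Each event randomly carries a chosen- or unchosen-internal-probability
    regressor value drawn uniformly from ``prob_levels``.
    """
    onset = start_s
    events = []
    for _ in range(n_events):
        value = float(rng.choice(prob_levels))
        if rng.random() < p_internal:
            events.append(RoiEvent(onset_s=onset, chosen_internal_prob=value))
        else:
            events.append(RoiEvent(onset_s=onset, unchosen_internal_prob=value))
        onset += float(np.clip(rng.poisson(3.0), 2.5, 8.5))
    return events


def simulate_roi_timecourse(
    events: Sequence[RoiEvent],
    ramp: RampParams = RampParams(),
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    dt: float = 2.0,
    padding_s: float = 20.0,
) -> RoiTimecourse:
    """Synthesize an ROI signal from an event schedule.

    Each event adds a gamma-variate response scaled by its regressor
    value; chosen and unchosen events use their own time-to-peak, so a
    ramp-rate difference between conditions can be planted and recovered
    downstream.  White Gaussian noise is added on the sampling grid.
    """
    onsets = [e.onset_s for e in events]
    if len(set(onsets)) != len(onsets):
        raise ValueError("overlapping identical onsets in event schedule")
    t_end = max(onsets) + padding_s
    t = np.arange(0.0, t_end + dt, dt)
    signal = np.zeros_like(t)
    for e in events:
        if e.chosen_internal_prob is not None:
            signal += e.chosen_internal_prob * _gamma_variate(
                t - e.onset_s, ramp.time_to_peak_chosen, ramp.amplitude, ramp.shape
            )
        if e.unchosen_internal_prob is not None:
            signal += e.unchosen_internal_prob * _gamma_variate(
                t - e.onset_s, ramp.time_to_peak_unchosen, ramp.amplitude, ramp.shape
            )
    rng = np.random.default_rng(seed)
    signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return RoiTimecourse(dt=dt, signal=signal, events=list(events))


@dataclass
class BetaTimecourse:
    """Per-timepoint regression weights on the post-onset grid."""

    times: np.ndarray
    beta_chosen: np.ndarray | None
    beta_unchosen: np.ndarray | None

    def beta(self, which: str) -> np.ndarray:
        b = {"chosen": self.beta_chosen, "unchosen": self.beta_unchosen}[which]
        if b is None:
            raise ValueError(f"no {which!r} regressor in this timecourse")
        return b


def _epoch_betas(
    fine_t: np.ndarray,
    fine_sig: np.ndarray,
    onsets: np.ndarray,
    values: np.ndarray,
    taus: np.ndarray,
) -> np.ndarray:
    x = values - values.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("regressor is constant across trials (rank deficient)")
    x = x / sd
    betas = np.empty_like(taus)
    for i, tau in enumerate(taus):
        y = np.interp(onsets + tau, fine_t, fine_sig)
        betas[i] = float(np.mean(x * (y - y.mean())))
    return betas


def beta_timecourse(
    tc: RoiTimecourse,
    *,
    window: tuple[float, float] = EPOCH_WINDOW,
    min_events: int = 10,
) -> BetaTimecourse:
    """Per-timepoint OLS of the epoched signal on the trial regressors.

    The signal is z-scored (so the result is invariant to adding a
    constant) and oversampled by the recorded factor with linear
    interpolation; per-timepoint regressions include an intercept, and
    regressor values are z-scored across trials.  Events too close to the
    end of the recording for a full epoch are dropped with a warning.
    """
    sig = np.asarray(tc.signal, dtype=float)
    sig = (sig - sig.mean()) / sig.std()
    coarse_t = np.arange(len(sig)) * tc.dt
    fine_dt = tc.dt / tc.oversampling
    fine_t = np.arange(0.0, coarse_t[-1] + fine_dt / 2, fine_dt)
    fine_sig = np.interp(fine_t, coarse_t, sig)
    taus = np.arange(window[0], window[1] + fine_dt / 2, fine_dt)

    usable = [e for e in tc.events if e.onset_s + window[1] <= coarse_t[-1]]
    if len(usable) < len(tc.events):
        warnings.warn(
            f"dropped {len(tc.events) - len(usable)} events lacking a full epoch",
            stacklevel=2,
        )

    out: dict[str, np.ndarray | None] = {}
    for which, attr in (
        ("chosen", "chosen_internal_prob"),
        ("unchosen", "unchosen_internal_prob"),
    ):
        evs = [e for e in usable if getattr(e, attr) is not None]
        if not evs:
            out[which] = None
            continue
        if len(evs) < min_events:
            raise ValueError(
                f"need at least {min_events} events for the {which} regressor, "
                f"got {len(evs)}"
            )
        onsets = np.array([e.onset_s for e in evs])
        values = np.array([getattr(e, attr) for e in evs], dtype=float)
        out[which] = _epoch_betas(fine_t, fine_sig, onsets, values, taus)
    return BetaTimecourse(
        times=taus, beta_chosen=out["chosen"], beta_unchosen=out["unchosen"]
    )


@dataclass
class SlopeResult:
    t_min: float
    beta_min: float
    t_max: float
    beta_max: float
    slope: float
    magnitude: float


def slope_stat(
    times: np.ndarray,
    beta: np.ndarray,
    *,
    tmin_window: tuple[float, float] = TMIN_WINDOW,
    tmax_limit: float = EPOCH_WINDOW[1],
) -> SlopeResult:
    """Slope and magnitude of a beta timecourse.

    ``beta_min`` is the minimum over the strictly open early window
    (0, 4) s; ``beta_max`` the maximum over (t_min, 11) s.  Strict
    inequalities exclude the onset sample itself; ties break to the
    earliest time point.
    """
    times = np.asarray(times, dtype=float)
    beta = np.asarray(beta, dtype=float)
    early = (times > tmin_window[0]) & (times < tmin_window[1])
    if not early.any():
        raise ValueError("no time points in the beta-minimum search window")
    i_candidates = np.flatnonzero(early)
    i_min = i_candidates[int(np.argmin(beta[early]))]
    t_min, b_min = float(times[i_min]), float(beta[i_min])

    late = (times > t_min) & (times < tmax_limit)
    if not late.any():
        raise ValueError("no time points in the beta-maximum search window")
    j_candidates = np.flatnonzero(late)
    j_max = j_candidates[int(np.argmax(beta[late]))]
    t_max, b_max = float(times[j_max]), float(beta[j_max])

    return SlopeResult(
        t_min=t_min,
        beta_min=b_min,
        t_max=t_max,
        beta_max=b_max,
        slope=(b_max - b_min) / (t_max - t_min),
        magnitude=b_max - b_min,
    )


@dataclass
class SlopeContrast:
    """Session-averaged chosen-vs-unchosen slope and peak comparison."""

    slope_chosen: float
    slope_unchosen: float
    slope_difference: float
    peak_chosen: float
    peak_unchosen: float
    peak_difference: float
    n_sessions: int
    per_session: list[dict] = field(default_factory=list)


def chosen_unchosen_slope_contrast(
    timecourses: Sequence[RoiTimecourse],
) -> SlopeContrast:
    """Average the per-session slope and peak statistics across sessions.

    Sessions are the unit of averaging, mirroring how per-participant
    values are formed from repeated recordings before any group
    comparison.
    """
    if not timecourses:
        raise ValueError("no timecourses supplied")
    rows = []
    for tc in timecourses:
        bt = beta_timecourse(tc)
        if bt.beta_chosen is None or bt.beta_unchosen is None:
            raise ValueError("both chosen and unchosen regressors are required")
        s_ch = slope_stat(bt.times, bt.beta_chosen)
        s_un = slope_stat(bt.times, bt.beta_unchosen)
        rows.append(
            {
                "slope_chosen": s_ch.slope,
                "slope_unchosen": s_un.slope,
                "peak_chosen": s_ch.beta_max,
                "peak_unchosen": s_un.beta_max,
            }
        )
    mean = {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}
    return SlopeContrast(
        slope_chosen=mean["slope_chosen"],
        slope_unchosen=mean["slope_unchosen"],
        slope_difference=mean["slope_chosen"] - mean["slope_unchosen"],
        peak_chosen=mean["peak_chosen"],
        peak_unchosen=mean["peak_unchosen"],
        peak_difference=mean["peak_chosen"] - mean["peak_unchosen"],
        n_sessions=len(rows),
        per_session=rows,
    )


# ---------------------------------------------------------------------------
# TSV I/O: timecourse (time_s, value) and events (onset_s,
# chosen_internal_prob, unchosen_internal_prob; empty cell = undefined).


def write_roi_files(
    tc: RoiTimecourse, timecourse_path: str | Path, events_path: str | Path
) -> None:
    t = np.arange(len(tc.signal)) * tc.dt
    pd.DataFrame({"time_s": t, "value": tc.signal}).to_csv(
        timecourse_path, sep="\t", index=False, float_format="%.6g"
    )
    rows = [
        {
            "onset_s": e.onset_s,
            "chosen_internal_prob": e.chosen_internal_prob,
            "unchosen_internal_prob": e.unchosen_internal_prob,
        }
        for e in tc.events
    ]
    pd.DataFrame(rows).to_csv(events_path, sep="\t", index=False, float_format="%.6g")


def read_roi_files(
    timecourse_path: str | Path, events_path: str | Path
) -> RoiTimecourse:
    tdf = pd.read_csv(timecourse_path, sep="\t")
    if not {"time_s", "value"} <= set(tdf.columns):
        raise ValueError("timecourse file needs columns time_s, value")
    times = tdf["time_s"].to_numpy(dtype=float)
    dts = np.diff(times)
    if len(dts) and not np.allclose(dts, dts[0]):
        raise ValueError("timecourse must be regularly sampled")
    edf = pd.read_csv(events_path, sep="\t")
    events = [
        RoiEvent(
            onset_s=float(r.onset_s),
            chosen_internal_prob=(
                None if pd.isna(r.chosen_internal_prob) else float(r.chosen_internal_prob)
            ),
            unchosen_internal_prob=(
                None
                if pd.isna(r.unchosen_internal_prob)
                else float(r.unchosen_internal_prob)
            ),
        )
        for r in edf.itertuples(index=False)
    ]
    return RoiTimecourse(
        dt=float(dts[0]) if len(dts) else 1.0,
        signal=tdf["value"].to_numpy(dtype=float),
        events=events,
    )
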