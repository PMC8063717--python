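"""Logistic choice and performance models with trial-history terms.

The lagged model regresses, on each trial n, either the metacognitive
choice (internal = 1) or the perceptual outcome on:

* the current internal evidence ``x_int(n)`` (the coherence ladder
  linearized from its roughly geometric spacing),
* the current external probability ``x_ext(n)``,
* and, for each of the past three *encounters* of each task type, the
  outcome ``o(n-k)``, the offered probability ``x(n-k)``, and their
  product.

An "encounter" of a task type is a past trial on which that type was
actually chosen, so the k-th lag refers to the k-th most recent such
trial, not to a fixed trial offset.  Histories never cross session
boundaries.  All predictors are z-scored within session after row
selection.

The decision-variable (DV) model is the single-predictor logistic of the
choice on the difference between the follow-up-implied internal reward
probability and the offered external probability.

Fitting is maximum likelihood via iteratively reweighted least squares
(IRLS), with explicit detection of perfect separation and degenerate
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .task_core import FollowUpTable, SessionLog

__all__ = [
    "LaggedDesign",
    "FitResult",
    "SeparationError",
    "DegenerateDesignError",
    "coherence_transform",
    "build_lagged_design",
    "fit_logistic",
    "fit_dv_model",
    "fit_lagged_model",
]

N_LAGS = 3


class SeparationError(RuntimeError):
    """The likelihood is unbounded: some direction separates the classes."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "perfect (quasi-)separation detected; diverging columns: "
            + ", ".join(self.columns)
        )


class DegenerateDesignError(ValueError):
    """The design matrix is rank deficient or contains constant columns."""


@dataclass
class LaggedDesign:
    """Design matrix, response, and bookkeeping for one session."""

    y: np.ndarray
    X: pd.DataFrame  # z-scored predictors, no intercept column
    n_dropped: int
    degenerate_columns: list[str] = field(default_factory=list)


@dataclass
class FitResult:
    """Converged maximum-likelihood logistic fit."""

    params: pd.Series  # includes "intercept"
    bse: pd.Series
    converged: bool
    n_rows_used: int
    log_likelihood: float
    n_iterations: int


def coherence_transform(
    coherence,
    levels: Sequence[float],
    method: Literal["rank", "log"] = "rank",
):
    """Linearize the roughly geometric coherence ladder.

    ``rank`` (default) maps each level to its index in the sorted ladder,
    rescaled to [0, 1].  ``log`` maps to log-coherence (zero coherence is
    assigned half the smallest nonzero level) rescaled to [0, 1].  Both
    are affinely equivalent after within-session z-scoring only when the
    ladder really is geometric; they are exposed as alternatives.
    """
    lv = sorted(levels)
    c_arr = np.atleast_1d(np.asarray(coherence, dtype=float))
    if method == "rank":
        out = np.empty_like(c_arr)
        for i, c in enumerate(c_arr):
            idx = int(np.argmin(np.abs(np.array(lv) - c)))
            if abs(lv[idx] - c) > 1e-9:
                raise ValueError(f"coherence {c} not on the ladder")
            out[i] = idx / (len(lv) - 1)
    elif method == "log":
        nonzero = [x for x in lv if x > 0]
        floor = min(nonzero) / 2.0
        logs = np.log([max(x, floor) for x in lv])
        lo, hi = logs.min(), logs.max()
        out = (np.log(np.maximum(c_arr, floor)) - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown transform {method!r}")
    return float(out[0]) if np.isscalar(coherence) else out


def _zscore(col: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = col.std()
    if sd == 0:
        return col - col.mean(), True
    return (col - col.mean()) / sd, False


def build_lagged_design(
    log: SessionLog,
    dependent: Literal["choice", "performance"] = "choice",
    *,
    n_lags: int = N_LAGS,
    transform: Literal["rank", "log"] = "rank",
) -> LaggedDesign:
    """Construct the lagged design matrix for one session.

    Rows whose history is incomplete (fewer than ``n_lags`` prior
    encounters of either task type) are dropped and counted.  For the
    performance model the response is the perceptual outcome on
    internal-option trials only.
    """
    if dependent not in ("choice", "performance"):
        raise ValueError(f"unknown dependent {dependent!r}")
    trials = log.trials
    levels = log.config.coherence_levels
    x_int_all = [coherence_transform(t.coherence, levels, transform) for t in trials]

    rows: list[dict] = []
    ys: list[int] = []
    n_dropped = 0
    int_hist: list[tuple[float, int]] = []  # (x_int, outcome) per internal encounter
    ext_hist: list[tuple[float, int]] = []
    for i, t in enumerate(trials):
        eligible = len(int_hist) >= n_lags and len(ext_hist) >= n_lags
        in_scope = dependent == "choice" or t.chose_internal
        if in_scope:
            if not eligible:
                n_dropped += 1
            else:
                row = {"x_int": x_int_all[i], "x_ext": t.p_external}
                for k in range(1, n_lags + 1):
                    xi, oi = int_hist[-k]
                    xe, oe = ext_hist[-k]
                    row[f"o_int_{k}"] = oi
                    row[f"o_ext_{k}"] = oe
                    row[f"x_int_{k}"] = xi
                    row[f"x_ext_{k}"] = xe
                    row[f"ox_int_{k}"] = oi * xi
                    row[f"ox_ext_{k}"] = oe * xe
                rows.append(row)
                ys.append(
                    int(t.chose_internal)
                    if dependent == "choice"
                    else int(t.perceptual_correct)
                )
        # update encounter histories with the trial just seen
        outcome = int(t.rewarded)
        if t.chose_internal:
            int_hist.append((x_int_all[i], outcome))
        else:
            ext_hist.append((t.p_external, outcome))

    if dependent == "performance" and not any(t.chose_internal for t in trials):
        raise ValueError("performance model needs at least one internal-option trial")
    if not rows:
        raise ValueError(
            f"no usable rows: every trial lacks {n_lags} encounters of each type"
        )
    X = pd.DataFrame(rows)
    degenerate: list[str] = []
    for col in X.columns:
        z, is_const = _zscore(X[col].to_numpy(dtype=float))
        X[col] = z
        if is_const:
            degenerate.append(col)
    return LaggedDesign(
        y=np.array(ys, dtype=float), X=X, n_dropped=n_dropped,
        degenerate_columns=degenerate,
    )


def build_pooled_design(
    logs: Sequence[SessionLog],
    dependent: Literal["choice", "performance"] = "choice",
    **design_kwargs,
) -> LaggedDesign:
    """Concatenate per-session designs for one pooled fit.

    Predictors are z-scored within each session before concatenation, so
    a single fit over several sessions of one participant leaves each
    session's normalization intact.  Lag histories never cross session
    boundaries because each design is built per session.  Degeneracy is
    re-assessed on the pooled matrix (a column constant within one
    session may still vary across sessions).
    """
    designs = [build_lagged_design(log, dependent, **design_kwargs) for log in logs]
    X = pd.concat([d.X for d in designs], ignore_index=True)
    y = np.concatenate([d.y for d in designs])
    degenerate = [c for c in X.columns if X[c].std(ddof=0) == 0]
    return LaggedDesign(
        y=y,
        X=X,
        n_dropped=sum(d.n_dropped for d in designs),
        degenerate_columns=degenerate,
    )


def fit_logistic(
    design: LaggedDesign | tuple[np.ndarray, pd.DataFrame],
    *,
    max_iter: int = 200,
    tol: float = 1e-8,
    separation_threshold: float = 30.0,
) -> FitResult:
    """Maximum-likelihood logistic regression via IRLS.

    Convergence is declared when the largest coefficient change falls
    below ``tol``; the log-likelihood is monotone non-decreasing across
    iterations by construction (step halving on any decrease).  Perfect
    or quasi-perfect separation is reported explicitly, naming the
    columns whose coefficients diverge.
    """
    if isinstance(design, LaggedDesign):
        if design.degenerate_columns:
            raise DegenerateDesignError(
                f"constant predictor columns: {design.degenerate_columns}"
            )
        y, Xdf = design.y, design.X
    else:
        y, Xdf = design
        y = np.asarray(y, dtype=float)
    names = ["intercept", *Xdf.columns]
    X = np.column_stack([np.ones(len(y)), Xdf.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("design matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    ll_old = _loglik(y, X, beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        w = np.maximum(w, 1e-10)
        z = eta + (y - p) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as err:
            raise DegenerateDesignError(f"normal equations singular: {err}") from err
        # step-halve if the likelihood would decrease (keeps IRLS monotone)
        step = beta_new - beta
        ll_new = _loglik(y, X, beta + step)
        halvings = 0
        while ll_new < ll_old - 1e-12 and halvings < 30:
            step /= 2.0
            ll_new = _loglik(y, X, beta + step)
            halvings += 1
        beta = beta + step
        if np.max(np.abs(beta)) > separation_threshold:
            order = np.argsort(-np.abs(beta))
            culprits = [names[j] for j in order if abs(beta[j]) > separation_threshold]
            raise SeparationError(culprits or [names[order[0]]])
        if np.max(np.abs(step)) < tol:
            ll_old = ll_new
            break
        ll_old = ll_new
    converged = np.max(np.abs(step)) < tol

    p = expit(X @ beta)
    w = np.maximum(p * (1.0 - p), 1e-10)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    return FitResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        converged=bool(converged),
        n_rows_used=len(y),
        log_likelihood=float(ll_old),
        n_iterations=n_iter,
    )


def _loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_lagged_model(
    log: SessionLog,
    dependent: Literal["choice", "performance"] = "choice",
    **design_kwargs,
) -> FitResult:
    """Convenience wrapper: build the lagged design and fit it."""
    return fit_logistic(build_lagged_design(log, dependent, **design_kwargs))


def fit_dv_model(log: SessionLog, followup: FollowUpTable) -> FitResult:
    """Logistic fit of the choice on the decision variable.

    DV(n) = follow-up internal reward probability at the trial's coherence
    minus the offered external probability.
    """
    dv = np.array(
        [followup.p_correct(t.coherence) * 1.0 - t.p_external for t in log.trials]
    )
    y = np.array([int(t.chose_internal) for t in log.trials], dtype=float)
    X = pd.DataFrame({"dv": dv})
    return fit_logistic((y, X))
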