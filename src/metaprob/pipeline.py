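"""End-to-end harness: simulate, analyze, and parameter-recovery studies.

`run_pipeline` chains the full analysis path on one simulated study —
trial logs, follow-up baseline, signal-detection indices, lagged and
decision-variable regressions, probability-weighting fits, and the
challenge/inevitable contrast — writing one JSON artifact per stage plus
a manifest (configuration, package version, seed), so a rerun with the
same manifest is byte-identical.

`recover` runs the simulate-and-refit studies that validate the whole
chain: distortion-exponent (gamma) recovery, lagged-logistic coefficient
recovery, and the monotone degradation of type II A_ROC under increasing
metacognitive readout noise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from . import __version__
from .agent_sim import AgentParams, SimulationSpec, simulate_study
from .challenge_analysis import challenge_contrast, classify_challenge
from .choice_models import build_pooled_design, fit_dv_model, fit_logistic
from .sdt_metrics import sdt_summary
from .task_core import (
    SessionLog,
    followup_table,
    write_followup_table,
    write_session_log,
)
from .utility_fit import empirical_choice_curve, fit_gamma, prospect_weight, risk_metrics

__all__ = ["RunConfig", "RecoverySpec", "run_pipeline", "recover", "pooled_followup"]

logger = logging.getLogger("metaprob")


class StageError(RuntimeError):
    """An analysis stage failed; the stage name is part of the message."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    out_dir: Path
    seed: int = 0
    spec: SimulationSpec = field(default_factory=SimulationSpec)
    verbosity: int = 1


@dataclass
class RecoverySpec:
    """Generating parameters and replicate counts for recovery studies."""

    gammas: tuple[float, ...] = (0.4, 0.7, 1.0, 1.5)
    beta_internal: float = 2.9
    beta_external: float = -3.0
    tms_factors: tuple[float, ...] = (1.0, 2.0, 3.0)
    replicates: int = 5
    sessions_per_replicate: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicate count must be at least 2")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def pooled_followup(followup_logs: list[SessionLog]):
    """Follow-up table pooled over all follow-up sessions."""
    trials = [t for log in followup_logs for t in log.trials]
    return followup_table(trials)


def _fit_to_dict(fit) -> dict:
    return {
        "params": {k: float(v) for k, v in fit.params.items()},
        "bse": {k: float(v) for k, v in fit.bse.items()},
        "converged": fit.converged,
        "n_rows_used": fit.n_rows_used,
        "log_likelihood": fit.log_likelihood,
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Simulate one study and run every analysis stage in order.

    Returns a mapping from stage name to the JSON artifact written for
    it.  A failing stage raises :class:`StageError` naming the stage;
    artifacts of earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "spec": config.spec.to_dict(),
    }
    write_json(manifest, out / "manifest.json")
    artifacts["manifest"] = out / "manifest.json"

    stage = "simulate"
    try:
        sessions = simulate_study(config.spec, config.seed)
        main_trials = [t for main, _ in sessions for t in main.trials]
        for i, (main, fup) in enumerate(sessions):
            write_session_log(main, out / f"session_{i:02d}.tsv")
            if fup is not None:
                write_session_log(fup, out / f"followup_{i:02d}.tsv")
        fup_logs = [f for _, f in sessions if f is not None]
        logger.info("simulated %d sessions (%d trials)", len(sessions), len(main_trials))

        stage = "sdt"
        if not fup_logs:
            raise ValueError(
                "precondition: a follow-up baseline is required "
                "(include_followup=True)"
            )
        followup = pooled_followup(fup_logs)
        write_followup_table(followup, out / "followup_table.tsv")
        sdt = sdt_summary(main_trials, followup)
        write_json(sdt, out / "sdt.json")
        artifacts["sdt"] = out / "sdt.json"

        stage = "regressions"
        reg: dict = {}
        main_logs = [main for main, _ in sessions]
        for dependent in ("choice", "performance"):
            # one fit per participant over all sessions, predictors
            # normalized within session
            fit = fit_logistic(build_pooled_design(main_logs, dependent))
            reg[dependent] = _fit_to_dict(fit)
        dv_fits = [_fit_to_dict(fit_dv_model(main, followup)) for main, _ in sessions]
        reg["dv"] = {
            "per_session": dv_fits,
            "mean_params": {
                k: float(np.mean([f["params"][k] for f in dv_fits]))
                for k in dv_fits[0]["params"]
            },
        }
        write_json(reg, out / "regressions.json")
        artifacts["regressions"] = out / "regressions.json"

        stage = "utility"
        util = {}
        for side in ("internal", "external"):
            curve = empirical_choice_curve(main_trials, followup, side)
            fit = fit_gamma([(p, w) for _, p, w, _ in curve])
            rate, var = risk_metrics(main_trials, side)
            util[side] = {
                "gamma": fit.gamma,
                "log_gamma": fit.log_gamma,
                "sse": fit.sse,
                "curve": curve,
                "reward_rate": rate,
                "outcome_variance": var,
            }
        write_json(util, out / "utility.json")
        artifacts["utility"] = out / "utility.json"

        stage = "challenge"
        labels = classify_challenge(main_trials, followup)
        contrast = challenge_contrast(main_trials, labels)
        write_json(contrast, out / "challenge.json")
        artifacts["challenge"] = out / "challenge.json"
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, err) from err
    return artifacts


# ---------------------------------------------------------------------------
# Recovery studies


def gamma_recovery(spec: RecoverySpec, n_sessions: int = 20) -> dict:
    """Simulate-and-refit recovery of the weighting exponent gamma.

    Choice proportions are drawn binomially from the weighting function
    ``w(p; gamma)`` itself, at the objective-probability placements and
    bin sizes of a simulated study — the direct parameter-recovery study
    for the descriptive weighting model.  (The structural observer's
    generative distortion exponent is only expected to map monotonically
    onto the descriptive fit; see :func:`gamma_sweep_structural`.)
    """
    sim = SimulationSpec(n_sessions=n_sessions)
    sessions = simulate_study(sim, spec.seed)
    trials = [t for main, _ in sessions for t in main.trials]
    followup = pooled_followup([f for _, f in sessions])
    # objective-probability placements and bin sizes from both option
    # sides, so the refit sees the full span the task design produces
    base_curve = [
        (level, p, w, n)
        for side in ("internal", "external")
        for level, p, w, n in empirical_choice_curve(trials, followup, side)
    ]
    rng = np.random.default_rng(spec.seed + 2)
    rows = []
    for gamma in spec.gammas:
        estimates = []
        for _rep in range(spec.replicates):
            pairs = []
            for _level, p, _w, n in base_curve:
                w_true = prospect_weight(p, gamma)
                pairs.append((p, rng.binomial(n, w_true) / n))
            estimates.append(fit_gamma(pairs).gamma)
        rows.append(
            {
                "gamma_generating": gamma,
                "gamma_recovered_mean": float(np.mean(estimates)),
                "gamma_recovered_sd": float(np.std(estimates)),
                "abs_error": float(abs(np.mean(estimates) - gamma)),
                "estimates": estimates,
            }
        )
    return {
        "per_gamma": rows,
        "mean_abs_error": float(np.mean([r["abs_error"] for r in rows])),
    }


def gamma_sweep_structural(spec: RecoverySpec) -> dict:
    """Descriptive gamma fitted to full simulated behavior, per generative gamma.

    The observer's generative distortion reaches the choice curve only
    through the soft part of the value comparison, and evidence noise
    adds an inverse-S attenuation of its own, so the fitted exponent is
    an attenuated, biased readout of the generative one.  The meaningful
    check is monotonicity of the mapping, not unbiasedness.
    """
    rows = []
    for gi, gamma in enumerate(spec.gammas):
        estimates = []
        for rep in range(spec.replicates):
            agent = AgentParams(gamma_internal=gamma, gamma_external=gamma)
            sim = SimulationSpec(agent=agent, n_sessions=spec.sessions_per_replicate)
            seed = (spec.seed + 7919 * gi + 104729 * rep) % (2**31 - 1)
            sessions = simulate_study(sim, seed)
            trials = [t for main, _ in sessions for t in main.trials]
            followup = pooled_followup([f for _, f in sessions])
            curve = empirical_choice_curve(trials, followup, "internal")
            estimates.append(fit_gamma([(p, w) for _, p, w, _ in curve]).gamma)
        rows.append(
            {"gamma_generating": gamma, "gamma_fitted_mean": float(np.mean(estimates))}
        )
    return {"per_gamma": rows}


def lagged_beta_recovery(
    spec: RecoverySpec, n_sessions: int = 20, alpha: float = 0.0
) -> dict:
    """Conditional simulate-and-refit of the lagged choice model.

    Designs come from simulated sessions (predictors z-scored within
    session); responses are regenerated from known coefficients on the
    current-trial predictors (all history terms zero), then refit with
    one pooled fit over all sessions.
    """
    sim = SimulationSpec(n_sessions=n_sessions)
    sessions = simulate_study(sim, spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    design = build_pooled_design([m for m, _ in sessions], "choice")
    eta = (
        alpha
        + spec.beta_internal * design.X["x_int"].to_numpy()
        + spec.beta_external * design.X["x_ext"].to_numpy()
    )
    y = (rng.random(len(eta)) < expit(eta)).astype(float)
    fit = fit_logistic((y, design.X))
    mean_int = float(fit.params["x_int"])
    mean_ext = float(fit.params["x_ext"])
    return {
        "beta_internal_generating": spec.beta_internal,
        "beta_external_generating": spec.beta_external,
        "beta_internal_recovered": mean_int,
        "beta_external_recovered": mean_ext,
        "relative_bias_internal": (mean_int - spec.beta_internal) / spec.beta_internal,
        "relative_bias_external": (mean_ext - spec.beta_external) / spec.beta_external,
        "n_sessions": n_sessions,
    }


def tms_sweep(spec: RecoverySpec) -> dict:
    """Type II / type I areas across increasing metacognitive noise."""
    rows = []
    for fi, factor in enumerate(spec.tms_factors):
        t2s, t1s = [], []
        for rep in range(spec.replicates):
            sim = SimulationSpec(
                n_sessions=spec.sessions_per_replicate,
                tms_condition="alpfc",
                tms_factor=factor,
            )
            seed = (spec.seed + 31337 * fi + 271 * rep) % (2**31 - 1)
            sessions = simulate_study(sim, seed)
            trials = [t for main, _ in sessions for t in main.trials]
            followup = pooled_followup([f for _, f in sessions])
            res = sdt_summary(trials, followup)
            t2s.append(res.type_two.area)
            t1s.append(res.type_one.area)
        rows.append(
            {
                "tms_factor": factor,
                "type_two_aroc": float(np.mean(t2s)),
                "type_one_aroc": float(np.mean(t1s)),
            }
        )
    return {"per_factor": rows}


def recover(spec: RecoverySpec) -> dict:
    """Full recovery report: gamma, lagged betas, and the noise sweep."""
    return {
        "gamma": gamma_recovery(spec),
        "gamma_structural": gamma_sweep_structural(spec),
        "lagged_betas": lagged_beta_recovery(spec),
        "tms": tms_sweep(spec),
        "spec": dataclasses.asdict(spec),
    }
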