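import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from metaprob.agent_sim import AgentParams, SimulationSpec, simulate_study
from metaprob.choice_models import (
    DegenerateDesignError,
    SeparationError,
    build_lagged_design,
    build_pooled_design,
    coherence_transform,
    fit_dv_model,
    fit_logistic,
)
from metaprob.task_core import FollowUpTable, SessionLog, TaskConfig

from conftest import make_trial

LEVELS = TaskConfig().coherence_levels


def _log(trials):
    return SessionLog(config=TaskConfig(), trials=trials)


def _alternating_log(n=40):
    """Deterministic log alternating internal/external with known outcomes."""
    trials = []
    for i in range(1, n + 1):
        internal = i % 2 == 1
        correct = (i % 3) != 0
        trials.append(
            make_trial(
                coherence=LEVELS[i % len(LEVELS)],
                p_external=(0.1, 0.3, 0.5, 0.7, 0.9)[i % 5],
                chose_internal=internal,
                correct=correct,
                rewarded=correct if internal else (correct and i % 4 == 0),
                trial_index=i,
            )
        )
    return _log(trials)


class TestCoherenceTransform:
    def test_rank_maps_ladder_to_unit_interval(self):
        assert coherence_transform(0.0, LEVELS) == 0.0
        assert coherence_transform(0.75, LEVELS) == 1.0
        assert coherence_transform(0.12, LEVELS) == pytest.approx(3 / 7)

    def test_log_transform_monotone(self):
        vals = [coherence_transform(c, LEVELS, "log") for c in sorted(LEVELS)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_off_ladder_coherence_rejected(self):
        with pytest.raises(ValueError, match="ladder"):
            coherence_transform(0.5001, LEVELS)


class TestLaggedDesign:
    def test_rows_without_full_history_dropped(self):
        # first usable row needs 3 prior encounters of EACH type
        log = _alternating_log(40)
        design = build_lagged_design(log, "choice")
        # encounters alternate, so trial 7 is the first with 3 of each
        assert design.n_dropped == 6
        assert len(design.y) == 40 - 6

    def test_lag_one_outcome_is_most_recent_encounter(self):
        log = _alternating_log(40)
        raw_rows = []
        int_hist, ext_hist = [], []
        for t in log.trials:
            if len(int_hist) >= 3 and len(ext_hist) >= 3:
                raw_rows.append((int_hist[-1], ext_hist[-1]))
            (int_hist if t.chose_internal else ext_hist).append(int(t.rewarded))
        design = build_lagged_design(log, "choice")
        # recover the pre-z-scored lag-1 outcomes from column structure:
        # z-scoring is monotone, so order statistics must agree
        o1 = design.X["o_int_1"].to_numpy()
        expected = np.array([a for a, _ in raw_rows], dtype=float)
        assert len(o1) == len(expected)
        assert np.array_equal(o1 > o1.mean(), expected > expected.mean())

    def test_histories_do_not_cross_sessions(self):
        log1 = _alternating_log(40)
        design1 = build_lagged_design(log1, "choice")
        # an identical second session must produce the identical design,
        # regardless of what preceded it in another session object
        design2 = build_lagged_design(_alternating_log(40), "choice")
        pd.testing.assert_frame_equal(design1.X, design2.X)

    def test_constant_predictor_flagged_degenerate(self):
        trials = []
        for i in range(1, 41):
            trials.append(
                make_trial(
                    coherence=0.12,  # constant -> degenerate x_int
                    p_external=(0.1, 0.9)[i % 2],
                    chose_internal=i % 2 == 1,
                    correct=i % 3 != 0,
                    rewarded=(i % 3 != 0) if i % 2 == 1 else (i % 4 == 0),
                    trial_index=i,
                )
            )
        design = build_lagged_design(_log(trials), "choice")
        assert "x_int" in design.degenerate_columns
        with pytest.raises(DegenerateDesignError):
            fit_logistic(design)

    def test_performance_model_requires_internal_trials(self):
        trials = [
            make_trial(chose_internal=False, trial_index=i, rewarded=False)
            for i in range(1, 10)
        ]
        with pytest.raises(ValueError, match="internal"):
            build_lagged_design(_log(trials), "performance")

    def test_predictors_are_z_scored(self):
        design = build_lagged_design(_alternating_log(60), "choice")
        for col in design.X.columns:
            if col in design.degenerate_columns:
                continue
            assert design.X[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert design.X[col].std(ddof=0) == pytest.approx(1.0)


class TestFitLogistic:
    def test_null_data_gives_null_slopes(self, rng):
        n = 10000
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        y = (rng.random(n) < 0.5).astype(float)
        fit = fit_logistic((y, X))
        assert fit.converged
        for col in "abc":
            assert abs(fit.params[col]) < 3 * fit.bse[col]

    def test_agrees_with_statsmodels_reference(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 600
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        eta = 0.3 + 1.2 * X["a"] - 0.8 * X["c"]
        y = (rng.random(n) < expit(eta)).astype(float)
        fit = fit_logistic((y, X))
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            fit.params.to_numpy(), ref.params.to_numpy(), atol=1e-6
        )
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse.to_numpy(), atol=1e-6)

    def test_known_coefficients_recovered_with_paper_sign_pattern(self, rng):
        """Simulate from beta_int=+2.9, beta_ext=-3.0 and refit."""
        spec = SimulationSpec(n_sessions=8, include_followup=False)
        sessions = simulate_study(spec, 31)
        design = build_pooled_design([m for m, _ in sessions], "choice")
        eta = 2.9 * design.X["x_int"] - 3.0 * design.X["x_ext"]
        y = (rng.random(len(eta)) < expit(eta)).astype(float)
        fit = fit_logistic((y, design.X))
        b_int, b_ext = fit.params["x_int"], fit.params["x_ext"]
        assert b_int > 0 > b_ext
        assert abs(b_int - 2.9) / 2.9 < 0.15
        assert abs(b_ext + 3.0) / 3.0 < 0.15

    def test_perfect_separation_detected_with_culprit(self, rng):
        n = 200
        X = pd.DataFrame({"sep": rng.standard_normal(n)})
        y = (X["sep"] > 0).astype(float)
        with pytest.raises(SeparationError, match="sep"):
            fit_logistic((y.to_numpy(), X))

    def test_performance_model_shows_selection_effect(self):
        """External probability predicts internal-task accuracy (positive).

        On trials where a high external offer was rejected, the agent
        must have held strong internal evidence, so performance is
        better: the selection effect of prospective metacognition.
        """
        spec = SimulationSpec(
            agent=AgentParams(meta_noise=0.5),
            n_sessions=30,
            include_followup=False,
        )
        logs = [m for m, _ in simulate_study(spec, 17)]
        fit = fit_logistic(build_pooled_design(logs, "performance"))
        assert fit.params["x_ext"] > 0
        assert fit.params["x_int"] > 0


class TestDvModel:
    @pytest.fixture
    def followup(self):
        return FollowUpTable(
            {c: (100, int(100 * p)) for c, p in
             zip(LEVELS, (0.5, 0.55, 0.7, 0.8, 0.95, 0.98, 0.99, 1.0))}
        )

    def test_constant_zero_dv_is_degenerate(self, rng):
        # every offer sits exactly on the indifference line, so the DV
        # column is identically zero and the slope is unidentifiable
        table = FollowUpTable({0.12: (100, 70)})
        trials = [
            make_trial(
                coherence=0.12,
                p_external=0.7,
                chose_internal=bool(rng.random() < 0.5),
                trial_index=i,
            )
            for i in range(1, 301)
        ]
        with pytest.raises(DegenerateDesignError):
            fit_dv_model(_log(trials), table)

    def test_uninformative_dv_gives_null_slope(self, rng):
        # DV varies but choices ignore it: slope within 3 SE of zero
        table = FollowUpTable({0.06: (100, 60), 0.25: (100, 90)})
        trials = [
            make_trial(
                coherence=(0.06, 0.25)[i % 2],
                p_external=(0.1, 0.5, 0.9)[i % 3],
                chose_internal=bool(rng.random() < 0.5),
                trial_index=i,
            )
            for i in range(1, 2001)
        ]
        fit = fit_dv_model(_log(trials), table)
        assert abs(fit.params["dv"]) < 3 * fit.bse["dv"]

    def test_deterministic_chooser_separates(self, followup, rng):
        trials = []
        i = 1
        for c in LEVELS:
            for p_ext in (0.1, 0.3, 0.5, 0.7, 0.9):
                dv = followup.p_correct(c) - p_ext
                if dv == 0:
                    continue
                for _ in range(3):
                    trials.append(
                        make_trial(
                            coherence=c,
                            p_external=p_ext,
                            chose_internal=dv > 0,
                            trial_index=i,
                        )
                    )
                    i += 1
        with pytest.raises((SeparationError, DegenerateDesignError)):
            fit_dv_model(_log(trials), followup)

    def test_slope_increases_with_choice_determinism(self, followup):
        slopes = []
        for beta in (2.0, 6.0, 18.0):
            spec = SimulationSpec(
                agent=AgentParams(choice_beta=beta, meta_noise=0.5),
                n_sessions=2,
            )
            sessions = simulate_study(spec, 13)
            from metaprob.pipeline import pooled_followup

            table = pooled_followup([f for _, f in sessions])
            fits = [fit_dv_model(m, table).params["dv"] for m, _ in sessions]
            slopes.append(np.mean(fits))
        assert slopes[0] < slopes[1] < slopes[2]
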