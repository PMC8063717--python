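import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from metaprob.sdt_metrics import (
    DegenerateRocError,
    classify_optimality,
    m_ratio,
    roc_area,
    sdt_summary,
    type_one_aroc,
    type_two_aroc,
)
from metaprob.task_core import FollowUpTable

from conftest import make_trial


@pytest.fixture
def followup():
    # accuracies 0.55 / 0.70 / 0.80 / 0.95 at the four eligible coherences
    return FollowUpTable(
        {0.03: (100, 55), 0.06: (100, 70), 0.12: (100, 80), 0.25: (100, 95)}
    )


def brute_force_trapezoid(points):
    """Independent oracle: sort, anchor, and sum trapezoid strips."""
    pts = sorted(set(points) | {(0.0, 0.0), (1.0, 1.0)})
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += 0.5 * (y0 + y1) * (x1 - x0)
    return area


class TestClassifyOptimality:
    def test_external_optimal_when_p_ext_exceeds_baseline(self, followup):
        trials = [make_trial(coherence=0.12, p_external=0.9)]
        (label,) = classify_optimality(trials, followup)
        assert label.internal_optimal is False

    def test_internal_optimal_when_baseline_exceeds_p_ext(self, followup):
        trials = [make_trial(coherence=0.25, p_external=0.5)]
        (label,) = classify_optimality(trials, followup)
        assert label.internal_optimal is True

    def test_tie_favors_internal(self, followup):
        trials = [make_trial(coherence=0.06, p_external=0.7)]
        (label,) = classify_optimality(trials, followup)
        assert label.internal_optimal is True

    def test_ineligible_coherences_excluded(self, followup):
        trials = [make_trial(coherence=0.75), make_trial(coherence=0.0)]
        assert classify_optimality(trials, followup) == [None, None]

    def test_missing_followup_entry_names_coherence(self):
        table = FollowUpTable({0.03: (10, 6)})
        with pytest.raises(ValueError, match="0.06"):
            classify_optimality([make_trial()], table)


class TestTypeTwoAroc:
    def _trials_labels(self, followup, choose_fn):
        trials, labels = [], None
        for c in (0.03, 0.06, 0.12, 0.25):
            for p_ext in (0.1, 0.5, 0.9):
                for rep in range(5):
                    opt = followup.p_correct(c) >= p_ext
                    trials.append(
                        make_trial(
                            coherence=c,
                            p_external=p_ext,
                            chose_internal=choose_fn(opt, c, p_ext),
                        )
                    )
        return trials, classify_optimality(trials, followup)

    def test_always_internal_chooser_is_chance(self, followup):
        trials, labels = self._trials_labels(followup, lambda opt, c, p: True)
        res = type_two_aroc(trials, labels)
        assert res.area == pytest.approx(0.5)

    def test_perfect_selector_area_one(self, followup):
        trials, labels = self._trials_labels(followup, lambda opt, c, p: opt)
        res = type_two_aroc(trials, labels)
        assert res.area == pytest.approx(1.0)

    def test_hand_computed_point_set(self):
        # (fa, hit) per level: (0.1,0.6),(0.3,0.8),(0.6,0.9),(0.9,1.0)
        # with anchors (0,0),(1,1): strips 0.03+0.14+0.255+0.285+0.1 = 0.81
        points = [(0.1, 0.6), (0.3, 0.8), (0.6, 0.9), (0.9, 1.0)]
        assert roc_area(points) == pytest.approx(0.81, abs=1e-12)
        assert roc_area(points) == pytest.approx(brute_force_trapezoid(points))

    def test_all_one_class_raises_not_half(self, followup):
        trials = [make_trial(coherence=0.25, p_external=0.1) for _ in range(10)]
        labels = classify_optimality(trials, followup)
        with pytest.raises(DegenerateRocError):
            type_two_aroc(trials, labels)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_brute_force_oracle_on_random_point_sets(self, points):
        assert roc_area(points) == pytest.approx(
            brute_force_trapezoid(points), abs=1e-12
        )


class TestTypeOneAroc:
    def _directional_trials(self, n_left, k_left_resp_left, n_right, k_right_resp_left):
        trials = []
        for i in range(n_left):
            trials.append(
                make_trial(true_direction="left", correct=i < k_left_resp_left)
            )
        for i in range(n_right):
            trials.append(
                make_trial(true_direction="right", correct=i >= k_right_resp_left)
            )
        return trials

    def test_equal_rates_give_chance(self):
        trials = self._directional_trials(40, 20, 40, 20)
        res = type_one_aroc(trials, edge_correction=False)
        assert res.area == pytest.approx(0.5)
        assert res.d_prime == pytest.approx(0.0)

    def test_gaussian_formula_oracle(self):
        # hit=0.9, fa=0.1: A = Phi((Z(.9)-Z(.1))/sqrt 2) = Phi(1.8124) = 0.9650
        trials = self._directional_trials(100, 90, 100, 10)
        res = type_one_aroc(trials, edge_correction=False)
        expected = norm.cdf((norm.ppf(0.9) - norm.ppf(0.1)) / np.sqrt(2))
        assert res.area == pytest.approx(expected)
        assert res.area == pytest.approx(0.9650, abs=5e-5)

    def test_edge_correction_keeps_area_interior(self):
        trials = self._directional_trials(20, 20, 20, 0)
        res = type_one_aroc(trials)
        assert 0.5 < res.area < 1.0
        assert np.isfinite(res.d_prime)

    def test_single_direction_raises(self):
        trials = self._directional_trials(20, 15, 0, 0)
        with pytest.raises(ValueError, match="both directions"):
            type_one_aroc(trials)

    def test_zero_coherence_excluded_by_default(self):
        trials = self._directional_trials(30, 25, 30, 5)
        ambiguous = [
            make_trial(coherence=0.0, true_direction="left", correct=True)
            for _ in range(50)
        ]
        res_excl = type_one_aroc(trials + ambiguous)
        res_only = type_one_aroc(trials)
        assert res_excl.area == res_only.area
        assert type_one_aroc(trials + ambiguous, exclude_zero_coherence=False).n_signal == 80


class TestMRatio:
    def test_equal_areas_give_unity(self):
        for a in (0.55, 0.7, 0.84, 0.95):
            assert m_ratio(a, a) == pytest.approx(1.0)

    def test_chance_type_two_gives_zero(self):
        assert m_ratio(0.5, 0.84) == pytest.approx(0.0)

    def test_representative_group_means(self):
        # Z(0.72)/Z(0.84) = 0.5828/0.9945
        assert m_ratio(0.72, 0.84) == pytest.approx(0.586, abs=5e-4)

    def test_chance_type_one_undefined(self):
        with pytest.raises(ValueError):
            m_ratio(0.7, 0.5)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.2])
    def test_areas_outside_open_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            m_ratio(bad, 0.8)


class TestChanceLevels:
    def test_random_chooser_type_two_near_half(self, followup, rng):
        trials = []
        for i in range(2000):
            c = rng.choice((0.03, 0.06, 0.12, 0.25))
            p_ext = rng.choice((0.1, 0.3, 0.5, 0.7, 0.9))
            trials.append(
                make_trial(
                    coherence=float(c),
                    p_external=float(p_ext),
                    chose_internal=bool(rng.random() < 0.5),
                )
            )
        labels = classify_optimality(trials, followup)
        res = type_two_aroc(trials, labels)
        assert abs(res.area - 0.5) < 0.05

    def test_random_responder_type_one_near_half(self, rng):
        trials = [
            make_trial(
                true_direction=str(rng.choice(["left", "right"])),
                correct=bool(rng.random() < 0.5),
            )
            for _ in range(2000)
        ]
        res = type_one_aroc(trials)
        assert abs(res.area - 0.5) < 0.05


def test_sdt_summary_internal_consistency(small_study):
    res = sdt_summary(small_study["trials"], small_study["followup"])
    assert 0.5 < res.type_two.area < 1.0
    assert 0.5 < res.type_one.area < 1.0
    # the Z identities tie areas, sensitivities, and M-ratio together
    assert res.d_prime == pytest.approx(np.sqrt(2) * norm.ppf(res.type_one.area))
    assert res.m_ratio == pytest.approx(res.meta_d_prime / res.d_prime)
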