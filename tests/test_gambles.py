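import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rrss_choice as rc
from rrss_choice.gambles import classify_domain_from_gambles


@st.composite
def gambles(draw, min_outcomes=1, max_outcomes=4):
    n = draw(st.integers(min_outcomes, max_outcomes))
    xs = draw(
        st.lists(
            st.floats(-100, 100, allow_nan=False, width=32), min_size=n, max_size=n
        )
    )
    raw = draw(st.lists(st.integers(1, 20), min_size=n, max_size=n))
    total = sum(raw)
    ps = [r / total for r in raw]
    ps[-1] = 1.0 - sum(ps[:-1])
    return rc.Gamble(list(zip(xs, ps)))


class TestGamble:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            rc.Gamble([(1, 0.5), (2, 0.4)])
        with pytest.raises(ValueError):
            rc.Gamble([])

    def test_safe_option_is_one_certain_outcome(self):
        g = rc.Gamble([(3, 1.0)])
        assert g.is_safe and len(g) == 1

    @pytest.mark.parametrize(
        "outcomes,ev",
        [([(4, 0.8), (0, 0.2)], 3.2), ([(3, 1.0)], 3.0), ([(-4, 0.8), (0, 0.2)], -3.2)],
    )
    def test_expected_value(self, outcomes, ev):
        assert rc.expected_value(rc.Gamble(outcomes)) == pytest.approx(ev)

    @settings(deadline=None, derandomize=True)
    @given(gambles(), st.floats(-5, 5, allow_nan=False))
    def test_expected_value_is_linear_in_payoff_scale(self, g, k):
        scaled = rc.Gamble([(k * x, p) for x, p in g.outcomes])
        assert rc.expected_value(scaled) == pytest.approx(
            k * rc.expected_value(g), abs=1e-8
        )

    @pytest.mark.parametrize(
        "outcomes,cv",
        [
            ([(4, 0.8), (0, 0.2)], 0.5),  # SD = 1.6, EV = 3.2
            ([(3, 1.0)], 0.0),
            ([(1, 0.5), (-1, 0.5)], None),  # EV = 0: undefined
        ],
    )
    def test_coefficient_of_variation(self, outcomes, cv):
        got = rc.coefficient_of_variation(rc.Gamble(outcomes))
        if cv is None:
            assert got is None
        else:
            assert got == pytest.approx(cv)

    @settings(deadline=None, derandomize=True)
    @given(gambles(min_outcomes=2), st.floats(0.1, 10, allow_nan=False))
    def test_cv_scale_invariant_and_sign_symmetric(self, g, k):
        cv = rc.coefficient_of_variation(g)
        if cv is None:
            return
        up = rc.Gamble([(k * x, p) for x, p in g.outcomes])
        flip = rc.Gamble([(-x, p) for x, p in g.outcomes])
        assert rc.coefficient_of_variation(up) == pytest.approx(cv, rel=1e-6, abs=1e-9)
        assert rc.coefficient_of_variation(flip) == pytest.approx(cv, rel=1e-6, abs=1e-9)


class TestProblems:
    def test_domain_classification(self, p1, p2):
        assert rc.classify_domain(p1) is rc.Domain.GAIN
        assert rc.classify_domain(p2) is rc.Domain.LOSS
        mixed = rc.ChoiceProblem(
            "m", rc.Gamble([(5, 0.5), (-5, 0.5)]), rc.Gamble([(1, 1.0)])
        )
        assert rc.classify_domain(mixed) is rc.Domain.MIXED

    def test_all_zero_outcomes_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            classify_domain_from_gambles(
                rc.Gamble([(0, 1.0)]), rc.Gamble([(0, 0.5), (0, 0.5)])
            )

    def test_declared_domain_validated(self):
        with pytest.raises(ValueError, match="inconsistent"):
            rc.ChoiceProblem(
                "x", rc.Gamble([(4, 0.8), (0, 0.2)]), rc.Gamble([(3, 1.0)]), rc.Domain.LOSS
            )

    def test_identical_options_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            rc.ChoiceProblem("x", rc.Gamble([(3, 1.0)]), rc.Gamble([(3, 1.0)]))


class TestBehavioralMetrics:
    def test_decision_quality(self, p1):
        # A has EV 3.2 > B's 3.0
        assert rc.decision_quality(p1, "A") == 1
        assert rc.decision_quality(p1, "B") == 0

    def test_decision_quality_undefined_on_ev_tie(self):
        tied = rc.ChoiceProblem(
            "t", rc.Gamble([(4, 0.5), (2, 0.5)]), rc.Gamble([(3, 1.0)])
        )
        assert rc.decision_quality(tied, "A") is None

    def test_risk_aversion_indicator(self, p1):
        # B is safe (CV 0) vs A risky (CV 0.5)
        assert rc.risk_aversion_indicator(p1, "B") == 1
        assert rc.risk_aversion_indicator(p1, "A") == 0

    def test_risk_aversion_undefined_when_cv_tied_or_missing(self):
        both_safe = rc.ChoiceProblem("s", rc.Gamble([(3, 1.0)]), rc.Gamble([(2, 1.0)]))
        assert rc.risk_aversion_indicator(both_safe, "A") is None

    def test_indicators_complementary_over_choices(self, problem_set):
        for p in problem_set:
            q_a, q_b = rc.decision_quality(p, "A"), rc.decision_quality(p, "B")
            if q_a is not None:
                assert q_a + q_b == 1
            r_a, r_b = rc.risk_aversion_indicator(p, "A"), rc.risk_aversion_indicator(p, "B")
            if r_a is not None:
                assert r_a + r_b == 1


class TestChoiceDataset:
    def _records(self):
        return pd.DataFrame(
            {
                "participant_id": ["p1", "p1", "p2"],
                "age_group": ["younger", "younger", "older"],
                "problem_id": ["a", "b", "a"],
                "choice": ["A", "B", "A"],
            }
        )

    def test_valid_roundtrip(self, tmp_path):
        ds = rc.ChoiceDataset(self._records())
        rc.io.write_choices(ds, tmp_path / "choices.csv")
        back = rc.io.read_choices(tmp_path / "choices.csv")
        assert back == ds

    def test_duplicate_records_rejected(self):
        df = self._records()
        df.loc[1, "problem_id"] = "a"
        with pytest.raises(ValueError, match="duplicate"):
            rc.ChoiceDataset(df)

    def test_invalid_choice_rejected(self):
        df = self._records()
        df.loc[0, "choice"] = "C"
        with pytest.raises(ValueError, match="choice"):
            rc.ChoiceDataset(df)


class TestProblemIO:
    def test_roundtrip_preserves_problems(self, tmp_path, problem_set):
        path = tmp_path / "problems.csv"
        rc.io.write_problems(problem_set, path)
        back = rc.io.read_problems(path)
        assert len(back) == len(problem_set)
        for a, b in zip(problem_set, back):
            assert a.id == b.id and a.domain == b.domain
            assert a.option_a.outcomes == b.option_a.outcomes
            assert a.option_b.outcomes == b.option_b.outcomes

    def test_safe_options_written_as_missing_trailing_pairs(self, tmp_path, p1, two_by_two):
        path = tmp_path / "p.csv"
        rc.io.write_problems([p1, two_by_two], path)
        df = pd.read_csv(path)
        assert math.isnan(df.loc[0, "o_b2"]) and math.isnan(df.loc[0, "p_b2"])
        assert df.loc[1, "o_b2"] == 1.0
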