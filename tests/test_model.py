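import math

import numpy as np
import pandas as pd
import pytest

import rrss_choice as rc
from rrss_choice.strategies import StrategyId

from oracles import enumerate_grid_ll


def rng(seed=0):
    return np.random.default_rng(seed)


def hand_stats():
    """Worked payoff/cost table: MINI r=3.0 c=8, WADD r=3.2 c=16."""
    df = pd.DataFrame(
        [
            {"strategy": "MINI", "problem_id": "px", "r": 3.0, "c": 8.0},
            {"strategy": "WADD", "problem_id": "px", "r": 3.2, "c": 16.0},
        ]
    )
    return rc.StrategyStats(df, reps=1)


def make_data(pairs, participant="p", group="unspecified"):
    return pd.DataFrame(
        {
            "participant_id": participant,
            "age_group": group,
            "problem_id": [pid for pid, _ in pairs],
            "choice": [c for _, c in pairs],
        }
    )


class TestSelectStrategy:
    def test_delta_zero_maximizes_payoff(self):
        s = rc.select_strategy(["MINI", "WADD"], 0.0, hand_stats(), "px", rng())
        assert s is StrategyId.WADD

    def test_high_delta_prefers_cheap_strategy(self):
        # 3.2 - 0.1*16 = 1.6 < 3.0 - 0.1*8 = 2.2
        s = rc.select_strategy(["MINI", "WADD"], 0.1, hand_stats(), "px", rng())
        assert s is StrategyId.MINI

    def test_score_tie_resolved_uniformly(self):
        # delta = 0.025: both score 2.8
        picks = [
            rc.select_strategy(["MINI", "WADD"], 0.025, hand_stats(), "px", rng(s))
            for s in range(200)
        ]
        frac = np.mean([p is StrategyId.MINI for p in picks])
        assert 0.35 < frac < 0.65

    def test_missing_stats_is_error(self):
        with pytest.raises(KeyError):
            rc.select_strategy(["MINI"], 0.0, hand_stats(), "unknown", rng())

    def test_delta_limits(self, problem_set, stats_small):
        for p in problem_set:
            lo = rc.select_strategy(list(StrategyId), 0.0, stats_small, p.id, rng(1))
            hi = rc.select_strategy(list(StrategyId), 1e6, stats_small, p.id, rng(1))
            rs = {s: stats_small.r(s, p.id) for s in StrategyId}
            cs = {s: stats_small.c(s, p.id) for s in StrategyId}
            assert rs[lo] == pytest.approx(max(rs.values()))
            assert cs[hi] == pytest.approx(min(cs.values()))

    def test_selected_cost_nonincreasing_in_delta(self, stats_small, problem_set):
        """Linear scalarization: a larger cost weight never selects a
        costlier strategy."""
        g = rng(8)
        deltas = rc.GridSpec.desk().deltas
        all_s = list(StrategyId)
        for _ in range(20):
            size = int(g.integers(1, 5))
            toolbox = [all_s[i] for i in g.choice(len(all_s), size=size, replace=False)]
            for p in problem_set:
                prev = None
                for d in deltas:
                    s = rc.select_strategy(toolbox, d, stats_small, p.id, g)
                    c = stats_small.c(s, p.id)
                    if prev is not None:
                        assert c <= prev + 1e-9
                    prev = c


class TestChoiceProbability:
    def test_deterministic_strategy_with_trembling_hand(self, p1):
        stats = rc.compute_strategy_stats([StrategyId.WADD], [p1], reps=5, seed=0)
        params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, 0.1)
        assert rc.choice_probability(p1, params, stats, reps=20, seed=0) == pytest.approx(0.9)

    def test_epsilon_half_always_half(self, p1):
        stats = rc.compute_strategy_stats([StrategyId.WADD], [p1], reps=5, seed=0)
        params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, 0.5)
        assert rc.choice_probability(p1, params, stats, reps=20, seed=0) == 0.5

    def test_probabilities_sum_to_one_under_option_swap(self, p1):
        swapped = rc.ChoiceProblem("P1", p1.option_b, p1.option_a)
        for eps in (0.0, 0.1, 0.3):
            params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, eps)
            stats_a = rc.compute_strategy_stats([StrategyId.WADD], [p1], reps=5, seed=0)
            stats_b = rc.compute_strategy_stats([StrategyId.WADD], [swapped], reps=5, seed=0)
            pa = rc.choice_probability(p1, params, stats_a, reps=10, seed=1)
            pb = rc.choice_probability(swapped, params, stats_b, reps=10, seed=1)
            assert pa + pb == pytest.approx(1.0)

    def test_bounded_by_epsilon(self, problem_set, stats_small):
        g = rng(3)
        all_s = list(StrategyId)
        for _ in range(20):
            toolbox = frozenset(all_s[i] for i in g.choice(len(all_s), size=2, replace=False))
            eps = float(g.uniform(0.05, 0.45))
            params = rc.AgentParams(toolbox, float(g.uniform(0, 3)), eps)
            p = problem_set[int(g.integers(len(problem_set)))]
            prob = rc.choice_probability(p, params, stats_small, reps=10, seed=int(g.integers(100)))
            assert eps - 1e-12 <= prob <= 1 - eps + 1e-12


class TestLogLikelihood:
    def test_single_matching_trial(self, p1):
        stats = rc.compute_strategy_stats([StrategyId.WADD], [p1], reps=3, seed=0)
        params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, 0.2)
        data = make_data([("P1", "A")])  # WADD deterministically picks A
        ll = rc.log_likelihood(data, params, [p1], stats, reps=10, seed=0)
        assert ll == pytest.approx(math.log(0.8))

    def test_single_mismatching_trial(self, p1):
        stats = rc.compute_strategy_stats([StrategyId.WADD], [p1], reps=3, seed=0)
        params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, 0.2)
        data = make_data([("P1", "B")])
        ll = rc.log_likelihood(data, params, [p1], stats, reps=10, seed=0)
        assert ll == pytest.approx(math.log(0.2))

    def test_ten_matched_trials(self, full_problem_set):
        problems = full_problem_set[:10]
        stats = rc.compute_strategy_stats([StrategyId.WADD], problems, reps=3, seed=0)
        choices = [
            (p.id, "A" if rc.expected_value(p.option_a) > rc.expected_value(p.option_b) else "B")
            for p in problems
        ]
        params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, 0.26)
        ll = rc.log_likelihood(make_data(choices), params, problems, stats, reps=5, seed=0)
        assert ll == pytest.approx(10 * math.log(0.74))

    def test_epsilon_zero_mismatch_raises(self, p1):
        stats = rc.compute_strategy_stats([StrategyId.WADD], [p1], reps=3, seed=0)
        params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, 0.0)
        with pytest.raises(ValueError, match="zero-probability"):
            rc.log_likelihood(make_data([("P1", "B")]), params, [p1], stats, reps=5, seed=0)


class TestSimulateChoices:
    def test_noiseless_wadd_maximizes_ev(self, problem_set):
        params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, 0.0)
        ds = rc.simulate_choices(params, problem_set, n_reps=1, seed=0)
        for rec in ds.records.itertuples():
            p = next(q for q in problem_set if q.id == rec.problem_id)
            assert rc.decision_quality(p, rec.choice) == 1

    def test_fixed_seed_bitwise_identical(self, problem_set):
        params = rc.AgentParams(frozenset({StrategyId.MINI, StrategyId.WADD}), 0.5, 0.2)
        a = rc.simulate_choices(params, problem_set, n_reps=3, seed=42)
        b = rc.simulate_choices(params, problem_set, n_reps=3, seed=42)
        assert a == b

    def test_epsilon_half_is_coin_flip(self, p1):
        params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, 0.5)
        ds = rc.simulate_choices(params, [p1], n_reps=400, seed=7)
        frac_a = (ds.records["choice"] == "A").mean()
        assert frac_a == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(400))


class TestFitParticipant:
    CANDIDATES = (StrategyId.MINI, StrategyId.EQW, StrategyId.WADD)

    def micro_setup(self, seed):
        g = rng(seed)
        cfg = rc.ProblemSetConfig(n_gain=4, n_loss=2, n_mixed=2, n_with_safe=0, seed=seed)
        problems = [
            p
            for p in rc.generate_problem_set(cfg)
            if all(not rc.apply_strategy(s, p, g).tie for s in self.CANDIDATES)
        ][:6]
        grid = rc.GridSpec(
            name="micro",
            toolbox_sizes=(1, 2),
            deltas=(0.0, 0.31, 1.7),
            epsilons=(0.1, 0.3),
            reps=4,
            candidates=self.CANDIDATES,
        )
        stats = rc.compute_strategy_stats(self.CANDIDATES, problems, reps=10, seed=seed)
        choices = ["A" if g.random() < 0.5 else "B" for _ in problems]
        data = make_data(list(zip([p.id for p in problems], choices)))
        return problems, grid, stats, data

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_fit_matches_exhaustive_enumeration(self, seed):
        problems, grid, stats, data = self.micro_setup(seed)
        fit = rc.fit_participant(data, problems, stats=stats, grid=grid, seed=seed)
        oracle = enumerate_grid_ll(data, problems, stats, grid)
        best = max(oracle.values())
        assert fit.log_likelihood == pytest.approx(best, abs=1e-9)
        argmax = [k for k, v in oracle.items() if v > best - 1e-9]
        min_size = min(len(k[0]) for k in argmax)
        finalists = {
            (frozenset(k[0]), k[1], k[2]) for k in argmax if len(k[0]) == min_size
        }
        assert (fit.params.toolbox, fit.params.delta, fit.params.epsilon) in finalists

    def test_smaller_toolbox_preferred_on_ll_tie(self, problem_set):
        # data generated noiselessly by WADD: {WADD} and {WADD, X} at
        # delta=0 tie in likelihood; the singleton must win
        params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, 0.0)
        ds = rc.simulate_choices(params, problem_set, n_reps=1, seed=4, participant_prefix="p")
        grid = rc.GridSpec(
            name="micro",
            toolbox_sizes=(1, 2),
            deltas=(0.0,),
            epsilons=(0.05,),
            reps=4,
            candidates=self.CANDIDATES,
        )
        fit = rc.fit_participant(ds.records, problem_set, grid=grid, seed=0)
        assert fit.params.toolbox == frozenset({StrategyId.WADD})
        assert fit.n_ties_at_max >= 2

    def test_fit_deterministic_for_fixed_seed(self):
        problems, grid, stats, data = self.micro_setup(5)
        f1 = rc.fit_participant(data, problems, stats=stats, grid=grid, seed=11)
        f2 = rc.fit_participant(data, problems, stats=stats, grid=grid, seed=11)
        assert f1.params == f2.params and f1.log_likelihood == f2.log_likelihood

    def test_empty_data_rejected(self, problem_set):
        with pytest.raises(ValueError):
            rc.fit_participant(make_data([]), problem_set, seed=0)


class TestPosteriorPredictive:
    def test_matches_generating_model_at_low_noise(self, problem_set):
        params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, 0.01)
        ds = rc.simulate_choices(params, problem_set, n_reps=1, seed=2, participant_prefix="p")
        fit = rc.FitResult("p", params, 0.0, 1, {})
        ppc = rc.posterior_predictive(fit, problem_set, ds.records, reps=50, seed=3)
        assert ppc["match_proportion"] >= 0.9

    def test_epsilon_half_matches_at_chance(self, problem_set):
        params = rc.AgentParams(frozenset({StrategyId.WADD}), 0.0, 0.5)
        ds = rc.simulate_choices(params, problem_set, n_reps=1, seed=5, participant_prefix="p")
        fit = rc.FitResult("p", params, 0.0, 1, {})
        ppc = rc.posterior_predictive(fit, problem_set, ds.records, reps=100, seed=6)
        assert ppc["match_proportion"] == pytest.approx(0.5, abs=0.05)

    def test_normalized_strategy_counts_sum_to_trials(self, problem_set, stats_small):
        params = rc.AgentParams(frozenset({StrategyId.MINI, StrategyId.WADD}), 0.5, 0.2)
        ds = rc.simulate_choices(params, problem_set, n_reps=1, seed=9, participant_prefix="p")
        fit = rc.FitResult("p", params, 0.0, 1, {})
        ppc = rc.posterior_predictive(
            fit, problem_set, ds.records, reps=40, seed=1, stats=stats_small
        )
        assert sum(ppc["strategy_counts"].values()) == pytest.approx(len(problem_set))
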