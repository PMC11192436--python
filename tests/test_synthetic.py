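import numpy as np
import pandas as pd
import pytest

import rrss_choice as rc
from rrss_choice.strategies import StrategyId


class TestProblemGeneration:
    def test_default_design_counts(self, full_problem_set):
        problems = full_problem_set
        assert len(problems) == 105
        domains = [p.domain.value for p in problems]
        assert domains.count("gain") == 41
        assert domains.count("loss") == 31
        assert domains.count("mixed") == 33
        assert sum(p.has_safe_option for p in problems) == 9

    def test_same_seed_identical_sets(self):
        cfg = rc.ProblemSetConfig(seed=7)
        a = rc.generate_problem_set(cfg)
        b = rc.generate_problem_set(cfg)
        assert [(p.id, p.option_a.outcomes, p.option_b.outcomes) for p in a] == [
            (p.id, p.option_a.outcomes, p.option_b.outcomes) for p in b
        ]

    def test_single_gain_problem(self):
        cfg = rc.ProblemSetConfig(n_gain=1, n_loss=0, n_mixed=0, n_with_safe=0, seed=0)
        (p,) = rc.generate_problem_set(cfg)
        assert p.domain is rc.Domain.GAIN
        assert all(x >= 0 for x in p.option_a.payoffs) and all(x >= 0 for x in p.option_b.payoffs)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            rc.ProblemSetConfig(n_gain=1, n_loss=0, n_mixed=0, n_with_safe=5)

    def test_no_ev_or_cv_ties_by_default(self, full_problem_set):
        for p in full_problem_set:
            assert rc.expected_value(p.option_a) != rc.expected_value(p.option_b)
            cva = rc.coefficient_of_variation(p.option_a)
            cvb = rc.coefficient_of_variation(p.option_b)
            assert cva is not None and cvb is not None and cva != cvb

    def test_roundtrip_through_csv(self, tmp_path, full_problem_set):
        rc.io.write_problems(full_problem_set, tmp_path / "p.csv")
        back = rc.io.read_problems(tmp_path / "p.csv")
        assert [(p.id, p.option_a.outcomes) for p in back] == [
            (p.id, p.option_a.outcomes) for p in full_problem_set
        ]

    def test_safe_vs_risky_gain_set(self):
        problems = rc.generate_safe_risky_gain(20, seed=1)
        for p in problems:
            assert p.domain is rc.Domain.GAIN
            assert p.option_b.is_safe and not p.option_a.is_safe
            lo, hi = p.option_a.payoffs.min(), p.option_a.payoffs.max()
            assert lo < p.option_b.payoffs[0] < hi


class TestPopulation:
    def test_noiseless_wadd_agents_maximize_ev(self, problem_set):
        pop = rc.PopulationConfig(
            groups={
                "unspecified": rc.GroupConfig(
                    n_agents=3,
                    toolbox_sizes=(1,),
                    strategy_weights={StrategyId.WADD: 1.0},
                    delta_range=(0.0, 0.0),
                    epsilon_range=(0.0, 0.0),
                )
            },
            seed=3,
        )
        ds, truth = rc.generate_population(pop, problem_set, stats_reps=10)
        assert (truth["toolbox"] == "WADD").all()
        summary = ds.behavioral_summary(problem_set)
        assert np.allclose(summary["decision_quality"], 1.0)

    def test_epsilon_half_agents_match_ev_at_chance(self, problem_set):
        pop = rc.PopulationConfig(
            groups={
                "unspecified": rc.GroupConfig(
                    n_agents=10,
                    toolbox_sizes=(1,),
                    strategy_weights={StrategyId.WADD: 1.0},
                    delta_range=(0.0, 0.0),
                    epsilon_range=(0.5, 0.5),
                )
            },
            seed=4,
        )
        ds, _ = rc.generate_population(pop, problem_set, stats_reps=5)
        summary = ds.behavioral_summary(problem_set)
        n = 10 * len(problem_set)
        assert summary["decision_quality"].mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_truth_table_matches_dataset(self, problem_set):
        pop = rc.PopulationConfig(
            groups={
                "younger": rc.GroupConfig(n_agents=2),
                "older": rc.GroupConfig(n_agents=3),
            },
            seed=5,
        )
        ds, truth = rc.generate_population(pop, problem_set, stats_reps=5)
        assert len(truth) == 5
        assert set(truth["participant_id"]) == set(ds.participants)
        assert ds.records.groupby("participant_id").size().eq(len(problem_set)).all()

    def test_group_toolbox_mixes_shape_strategy_usage(self, problem_set):
        """Two groups drawing from disjoint strategy pools must produce
        different toolbox compositions."""
        pop = rc.PopulationConfig(
            groups={
                "younger": rc.GroupConfig(
                    n_agents=5, strategy_weights={StrategyId.MINI: 1, StrategyId.LL: 1}, toolbox_sizes=(2,)
                ),
                "older": rc.GroupConfig(
                    n_agents=5, strategy_weights={StrategyId.MAXI: 1, StrategyId.EQW: 1}, toolbox_sizes=(2,)
                ),
            },
            seed=6,
        )
        _, truth = rc.generate_population(pop, problem_set, stats_reps=5)
        young = set(truth.loc[truth.age_group == "younger", "toolbox"])
        old = set(truth.loc[truth.age_group == "older", "toolbox"])
        assert young == {"LL|MINI"} and old == {"EQW|MAXI"}


class TestScoreRecovery:
    def _truth(self):
        return pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "age_group": ["younger", "older"],
                "toolbox": ["MINI|WADD", "EQW"],
                "toolbox_size": [2, 1],
                "delta": [1.0, 2.0],
                "epsilon": [0.1, 0.3],
            }
        )

    def test_perfect_fits_score_perfectly(self):
        truth = self._truth()
        fits = truth.copy()
        score = rc.score_recovery(truth, fits)
        assert score["jaccard_mean"] == 1.0
        assert score["delta_mae"] == 0.0 and score["epsilon_mae"] == 0.0
        assert score["epsilon_within_0.1"] == 1.0

    def test_id_mismatch_rejected(self):
        truth = self._truth()
        fits = truth.copy()
        fits.loc[0, "participant_id"] = "zzz"
        with pytest.raises(ValueError, match="ids"):
            rc.score_recovery(truth, fits)

    def test_random_jaccard_baseline_is_modest(self):
        base = rc.random_jaccard_baseline([2, 3], [2, 3], n_draws=500, seed=0)
        assert 0.05 < base < 0.4
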