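import numpy as np
import pytest

import rrss_choice as rc


@pytest.fixture(scope="session")
def p1():
    """Gain problem: risky A = (4, .8; 0, .2) vs safe B = (3, 1.0)."""
    return rc.ChoiceProblem("P1", rc.Gamble([(4, 0.8), (0, 0.2)]), rc.Gamble([(3, 1.0)]))


@pytest.fixture(scope="session")
def p2():
    """Loss mirror of P1: A = (-4, .8; 0, .2) vs B = (-3, 1.0)."""
    return rc.ChoiceProblem("P2", rc.Gamble([(-4, 0.8), (0, 0.2)]), rc.Gamble([(-3, 1.0)]))


@pytest.fixture(scope="session")
def two_by_two():
    """Gain problem with two two-outcome options (the canonical shape)."""
    return rc.ChoiceProblem(
        "T1", rc.Gamble([(4, 0.8), (0, 0.2)]), rc.Gamble([(3, 0.6), (1, 0.4)])
    )


@pytest.fixture(scope="session")
def problem_set():
    """A small generated problem set covering all three domains."""
    cfg = rc.ProblemSetConfig(n_gain=8, n_loss=6, n_mixed=6, n_with_safe=3, seed=11)
    return rc.generate_problem_set(cfg)


@pytest.fixture(scope="session")
def full_problem_set():
    """The study-sized problem set: 105 problems, 41/31/33, 9 safe."""
    return rc.generate_problem_set(rc.ProblemSetConfig(seed=42))


@pytest.fixture(scope="session")
def stats_small(problem_set):
    return rc.compute_strategy_stats(list(rc.StrategyId), problem_set, reps=30, seed=5)


def rng(seed=0):
    return np.random.default_rng(seed)
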