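"""Synthetic study generator: choice problems and simulated participants.

The generator emulates the design of the behavioral study the analysis is
built for: 105 two-option problems (41 gain, 31 loss, 33 mixed; mostly two
two-outcome gambles, 9 problems including a safe option) and participants
characterized by a strategy toolbox, a cost weight δ, and a trembling-hand
error ε.  The original problems' payoffs and probabilities are not
published, so magnitudes come from the config: integer outcomes up to 100
money units and probabilities on a 0.05 grid by default.

Problems are rejection-sampled so that the behavioral metrics are defined
everywhere: option EVs differ (decision quality defined) and CVs are
defined and differ (risk aversion defined), unless ties are explicitly
requested for edge-case testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .costs import StrategyStats, compute_strategy_stats
from .gambles import (
    ChoiceDataset,
    ChoiceProblem,
    Domain,
    Gamble,
    coefficient_of_variation,
    expected_value,
)
from .model import AgentParams, FitResult, simulate_choices
from .strategies import StrategyId

__all__ = [
    "ProblemSetConfig",
    "GroupConfig",
    "PopulationConfig",
    "generate_problem_set",
    "generate_safe_risky_gain",
    "generate_population",
    "score_recovery",
    "random_jaccard_baseline",
    "fits_to_frame",
]

_DEFAULT_PROB_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 10))


@dataclass(frozen=True)
class ProblemSetConfig:
    """Design of a generated problem set (defaults mirror the study design)."""

    n_gain: int = 41
    n_loss: int = 31
    n_mixed: int = 33
    n_with_safe: int = 9
    outcome_max: int = 100
    prob_grid: tuple[float, ...] = _DEFAULT_PROB_GRID
    allow_ties: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.n_gain, self.n_loss, self.n_mixed, self.n_with_safe) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_with_safe > self.n_gain + self.n_loss + self.n_mixed:
            raise ValueError("more safe-option problems than problems")
        if self.outcome_max < 2:
            raise ValueError("outcome_max must be at least 2")

    @property
    def n_total(self) -> int:
        return self.n_gain + self.n_loss + self.n_mixed


def _safe_allocation(cfg: ProblemSetConfig) -> dict[Domain, int]:
    """Spread the safe-option problems over domains, proportional to size."""
    counts = {Domain.GAIN: cfg.n_gain, Domain.LOSS: cfg.n_loss, Domain.MIXED: cfg.n_mixed}
    total = cfg.n_total
    if total == 0:
        return {d: 0 for d in counts}
    raw = {d: cfg.n_with_safe * c / total for d, c in counts.items()}
    alloc = {d: min(int(np.floor(v)), counts[d]) for d, v in raw.items()}
    remainders = sorted(raw, key=lambda d: raw[d] - np.floor(raw[d]), reverse=True)
    i = 0
    while sum(alloc.values()) < cfg.n_with_safe:
        d = remainders[i % len(remainders)]
        if alloc[d] < counts[d]:
            alloc[d] += 1
        i += 1
    return alloc


def _draw_risky(rng, domain: Domain, cfg: ProblemSetConfig) -> Gamble:
    lo, hi = 1, cfg.outcome_max
    p = float(rng.choice(cfg.prob_grid))
    if domain is Domain.GAIN:
        x1, x2 = rng.choice(np.arange(0, hi + 1), size=2, replace=False)
    elif domain is Domain.LOSS:
        x1, x2 = -rng.choice(np.arange(0, hi + 1), size=2, replace=False)
    else:  # mixed: one gain, one loss
        x1 = int(rng.integers(lo, hi + 1))
        x2 = -int(rng.integers(lo, hi + 1))
    return Gamble([(float(x1), p), (float(x2), round(1.0 - p, 10))])


def _draw_safe(rng, domain: Domain, cfg: ProblemSetConfig) -> Gamble:
    hi = cfg.outcome_max
    if domain is Domain.LOSS:
        value = -int(rng.integers(1, hi + 1))
    else:  # a safe gain also works inside a mixed problem
        value = int(rng.integers(1, hi + 1))
    return Gamble([(float(value), 1.0)])


def _valid_problem(a: Gamble, b: Gamble, domain: Domain, allow_ties: bool) -> bool:
    try:
        p = ChoiceProblem(id="tmp", option_a=a, option_b=b)
    except ValueError:
        return False
    if p.domain is not domain:
        return False
    if allow_ties:
        return True
    if expected_value(a) == expected_value(b):
        return False
    cva, cvb = coefficient_of_variation(a), coefficient_of_variation(b)
    if cva is None or cvb is None or cva == cvb:
        return False
    return True


def generate_problem_set(config: ProblemSetConfig) -> list[ChoiceProblem]:
    """Generate a problem set matching the configured design exactly.

    Reproducible for a fixed seed; domain counts and the number of
    safe-option problems are exact.
    """
    rng = np.random.default_rng(config.seed)
    safe_alloc = _safe_allocation(config)
    problems: list[ChoiceProblem] = []
    prefix = {Domain.GAIN: "g", Domain.LOSS: "l", Domain.MIXED: "m"}
    for domain, n in (
        (Domain.GAIN, config.n_gain),
        (Domain.LOSS, config.n_loss),
        (Domain.MIXED, config.n_mixed),
    ):
        n_safe = safe_alloc[domain]
        for i in range(n):
            with_safe = i < n_safe
            for _ in range(10_000):
                a = _draw_risky(rng, domain, config)
                b = (
                    _draw_safe(rng, domain, config)
                    if with_safe
                    else _draw_risky(rng, domain, config)
                )
                if _valid_problem(a, b, domain, config.allow_ties):
                    break
            else:  # pragma: no cover - config would have to be pathological
                raise RuntimeError(f"could not generate a valid {domain.value} problem")
            problems.append(
                ChoiceProblem(
                    id=f"{prefix[domain]}{i + 1:02d}", option_a=a, option_b=b, domain=domain
                )
            )
    return problems


def generate_safe_risky_gain(
    n: int, seed: int = 0, outcome_max: int = 100
) -> list[ChoiceProblem]:
    """Gain-domain problems pairing a risky two-outcome gamble against a
    safe option whose value lies strictly between the risky outcomes (so
    neither option dominates).  Useful for probing strategy risk profiles:
    the safe option always has the lower coefficient of variation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    problems = []
    i = 0
    while len(problems) < n:
        i += 1
        lo, hi = sorted(rng.choice(np.arange(0, outcome_max + 1), size=2, replace=False))
        if hi - lo < 2:
            continue
        p_hi = float(rng.choice(_DEFAULT_PROB_GRID))
        risky = Gamble([(float(hi), p_hi), (float(lo), round(1.0 - p_hi, 10))])
        safe = Gamble([(float(rng.integers(lo + 1, hi)), 1.0)])
        if not _valid_problem(risky, safe, Domain.GAIN, allow_ties=False):
            continue
        problems.append(
            ChoiceProblem(id=f"sr{len(problems) + 1:02d}", option_a=risky, option_b=safe)
        )
    return problems


@dataclass(frozen=True)
class GroupConfig:
    """Sampling distribution of agent parameters within one group."""

    n_agents: int
    toolbox_sizes: tuple[int, ...] = (1, 2, 3)
    strategy_weights: Optional[Mapping[StrategyId, float]] = None
    delta_range: tuple[float, float] = (0.0, 5.0)
    epsilon_range: tuple[float, float] = (0.05, 0.3)

    def __post_init__(self):
        if self.n_agents < 0:
            raise ValueError("n_agents must be nonnegative")
        if min(self.toolbox_sizes) < 1 or max(self.toolbox_sizes) > 7:
            raise ValueError("toolbox sizes must lie in 1–7")
        if self.delta_range[0] < 0:
            raise ValueError("delta must be nonnegative")
        if not (0.0 <= self.epsilon_range[0] <= self.epsilon_range[1] <= 0.5):
            raise ValueError("epsilon range must lie in [0, 0.5]")


@dataclass(frozen=True)
class PopulationConfig:
    """Groups of simulated agents (e.g., two age groups with different
    toolbox mixes)."""

    groups: Mapping[str, GroupConfig]
    seed: int = 0


def _sample_agent(rng, gc: GroupConfig) -> AgentParams:
    size = int(rng.choice(gc.toolbox_sizes))
    all_s = sorted(StrategyId, key=lambda s: s.value)
    if gc.strategy_weights:
        w = np.array([gc.strategy_weights.get(s, 0.0) for s in all_s], dtype=float)
    else:
        w = np.ones(len(all_s))
    w = w / w.sum()
    idx = rng.choice(len(all_s), size=size, replace=False, p=w)
    return AgentParams(
        toolbox=frozenset(all_s[i] for i in idx),
        delta=float(rng.uniform(*gc.delta_range)),
        epsilon=float(rng.uniform(*gc.epsilon_range)),
    )


def toolbox_to_str(toolbox) -> str:
    return "|".join(sorted(StrategyId(s).value for s in toolbox))


def str_to_toolbox(s: str) -> frozenset:
    return frozenset(StrategyId(x) for x in s.split("|"))


def generate_population(
    pop_config: PopulationConfig,
    problems: Sequence[ChoiceProblem],
    stats: Optional[StrategyStats] = None,
    stats_reps: int = 100,
) -> tuple[ChoiceDataset, pd.DataFrame]:
    """Simulate a population of agents with known (ground-truth) parameters.

    Every agent's choices are produced by the forward model with its true
    parameters; the truth table (one row per agent) is returned alongside
    for recovery scoring.
    """
    ss = np.random.SeedSequence(pop_config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    if stats is None:
        stats = compute_strategy_stats(
            list(StrategyId), problems, reps=stats_reps, seed=int(rng.integers(2**31))
        )
    frames = []
    truth_rows = []
    counter = 0
    for group, gc in pop_config.groups.items():
        for _ in range(gc.n_agents):
            counter += 1
            pid = f"agent{counter:03d}"
            params = _sample_agent(rng, gc)
            ds = simulate_choices(
                params,
                problems,
                n_reps=1,
                seed=rng,
                stats=stats,
                age_group=group,
                participant_prefix=pid,
            )
            frames.append(ds.records)
            truth_rows.append(
                {
                    "participant_id": pid,
                    "age_group": group,
                    "toolbox": toolbox_to_str(params.toolbox),
                    "toolbox_size": len(params.toolbox),
                    "delta": params.delta,
                    "epsilon": params.epsilon,
                }
            )
    dataset = ChoiceDataset(pd.concat(frames, ignore_index=True))
    return dataset, pd.DataFrame(truth_rows)


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Tidy per-participant table of fitted RRSS parameters."""
    return pd.DataFrame(
        {
            "participant_id": f.participant_id,
            "toolbox": toolbox_to_str(f.params.toolbox),
            "toolbox_size": len(f.params.toolbox),
            "delta": f.params.delta,
            "epsilon": f.params.epsilon,
            "log_likelihood": f.log_likelihood,
            "n_ties_at_max": f.n_ties_at_max,
        }
        for f in fits
    )


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def score_recovery(truth: pd.DataFrame, fits) -> dict:
    """Compare fitted parameters against the generating truth.

    Reports the mean toolbox Jaccard overlap, absolute errors for δ and ε,
    the fraction of agents with ε recovered within ±0.1, and true-vs-fitted
    Pearson correlations.
    """
    if not isinstance(fits, pd.DataFrame):
        fits = fits_to_frame(fits)
    t = truth.set_index("participant_id")
    f = fits.set_index("participant_id")
    if set(t.index) != set(f.index):
        raise ValueError("participant ids of truth table and fits do not match")
    f = f.loc[t.index]
    jac = np.array(
        [
            _jaccard(str_to_toolbox(t.loc[i, "toolbox"]), str_to_toolbox(f.loc[i, "toolbox"]))
            for i in t.index
        ]
    )
    d_err = np.abs(t["delta"].to_numpy() - f["delta"].to_numpy())
    e_err = np.abs(t["epsilon"].to_numpy() - f["epsilon"].to_numpy())
    out = {
        "n_agents": len(t),
        "jaccard_mean": float(jac.mean()),
        "jaccard_per_agent": jac.tolist(),
        "delta_mae": float(d_err.mean()),
        "epsilon_mae": float(e_err.mean()),
        "epsilon_within_0.1": float((e_err <= 0.1).mean()),
    }
    for name in ("delta", "epsilon", "toolbox_size"):
        x, y = t[name].to_numpy(dtype=float), f[name].to_numpy(dtype=float)
        if np.std(x) > 0 and np.std(y) > 0:
            out[f"{name}_correlation"] = float(sp_stats.pearsonr(x, y)[0])
        else:
            out[f"{name}_correlation"] = float("nan")
    return out


def random_jaccard_baseline(
    true_sizes: Sequence[int],
    fitted_sizes: Sequence[int],
    n_strategies: int = 11,
    n_draws: int = 2000,
    seed: int = 0,
) -> float:
    """Expected Jaccard overlap of random toolboxes with the given sizes.

    Monte-Carlo baseline: what overlap would a fitter achieve by guessing
    uniformly random subsets of the observed sizes?
    """
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_draws):
        s_true = int(rng.choice(true_sizes))
        s_fit = int(rng.choice(fitted_sizes))
        a = frozenset(rng.choice(n_strategies, size=s_true, replace=False).tolist())
        b = frozenset(rng.choice(n_strategies, size=s_fit, replace=False).tolist())
        total += len(a & b) / len(a | b)
    return total / n_draws
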