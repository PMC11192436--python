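"""The resource-rational strategy-selection (RRSS) model.

A decision maker carries a toolbox S of candidate strategies.  On each
choice problem p they select the strategy that maximizes the payoff–cost
trade-off

    s* = argmax_{s in S} ( r_{s,p} − δ · c_{s,p} )

where r is the strategy's expected payoff, c its expected EIP cost, and
δ ≥ 0 the cost weight.  The selected strategy's choice is then executed
with a trembling-hand error ε:

    P(A) = P(A | δ, S) · (1 − ε) + P(B | δ, S) · ε.

Fitting is a grid search over toolbox compositions, δ, and ε.  Because
tie-breaking (in both selection and strategy execution) is random, the
model is simulated repeatedly: each simulation run yields a
deterministic-or-indifferent prediction, i.e. P(A | δ, S) ∈ {0, ½, 1} for
that run, and the per-run log-likelihoods are averaged across runs — the
averaging happens on the log scale, not on the probabilities.  Among
equal-likelihood grid points, smaller toolboxes are preferred and any
remaining tie is resolved at random.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .costs import StrategyStats, compute_strategy_stats
from .gambles import ChoiceDataset, ChoiceProblem
from .strategies import StrategyId, apply_strategy

__all__ = [
    "AgentParams",
    "GridSpec",
    "FitResult",
    "select_strategy",
    "choice_probability",
    "simulate_choices",
    "log_likelihood",
    "fit_participant",
    "posterior_predictive",
    "SimulationTable",
]

_LL_TIE_TOL = 1e-9
_SCORE_RTOL = 1e-9
_SCORE_ATOL = 1e-12

ALL_STRATEGIES = tuple(StrategyId)


@dataclass(frozen=True)
class AgentParams:
    """RRSS parameter vector: toolbox S, cost weight δ, trembling hand ε."""

    toolbox: frozenset
    delta: float
    epsilon: float

    def __post_init__(self):
        tb = frozenset(StrategyId(s) for s in self.toolbox)
        if not tb:
            raise ValueError("toolbox must be nonempty")
        object.__setattr__(self, "toolbox", tb)
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError("epsilon must lie in [0, 0.5]")

    @property
    def toolbox_sorted(self) -> tuple[StrategyId, ...]:
        return tuple(sorted(self.toolbox, key=lambda s: s.value))


@dataclass(frozen=True)
class GridSpec:
    """Search grid for fitting: toolbox sizes, δ and ε values, rep count.

    ``full`` is the original estimation grid (toolboxes of 1–7 strategies,
    δ from 0 to 20 in steps of 0.1, ε from 0.01 to 0.5 in steps of 0.01,
    100 simulation runs).  ``desk`` is a reduced default for routine use:
    toolbox sizes 1–4, δ step 0.5, ε step 0.05, 20 runs.
    """

    name: str
    toolbox_sizes: tuple[int, ...]
    deltas: tuple[float, ...]
    epsilons: tuple[float, ...]
    reps: int
    candidates: tuple[StrategyId, ...] = ALL_STRATEGIES

    def __post_init__(self):
        if not self.candidates:
            raise ValueError("candidate strategy set must be nonempty")
        if min(self.toolbox_sizes) < 1:
            raise ValueError("toolbox sizes must be >= 1")
        if any(e < 0 or e > 0.5 for e in self.epsilons):
            raise ValueError("epsilon grid must lie in [0, 0.5]")

    @classmethod
    def full(cls, candidates: Sequence[StrategyId] = ALL_STRATEGIES) -> "GridSpec":
        return cls(
            name="full",
            toolbox_sizes=tuple(range(1, 8)),
            deltas=tuple(np.round(np.arange(0.0, 20.0 + 1e-9, 0.1), 10)),
            epsilons=tuple(np.round(np.arange(0.01, 0.5 + 1e-9, 0.01), 10)),
            reps=100,
            candidates=tuple(StrategyId(s) for s in candidates),
        )

    @classmethod
    def desk(cls, candidates: Sequence[StrategyId] = ALL_STRATEGIES) -> "GridSpec":
        return cls(
            name="desk",
            toolbox_sizes=tuple(range(1, 5)),
            deltas=tuple(np.round(np.arange(0.0, 20.0 + 1e-9, 0.5), 10)),
            epsilons=tuple(np.round(np.arange(0.05, 0.5 + 1e-9, 0.05), 10)),
            reps=20,
            candidates=tuple(StrategyId(s) for s in candidates),
        )

    def describe(self) -> dict:
        return {
            "name": self.name,
            "toolbox_sizes": list(self.toolbox_sizes),
            "delta_range": [min(self.deltas), max(self.deltas), len(self.deltas)],
            "epsilon_range": [min(self.epsilons), max(self.epsilons), len(self.epsilons)],
            "reps": self.reps,
            "candidates": [s.value for s in self.candidates],
        }


@dataclass
class FitResult:
    """Best-fitting parameters for one participant plus diagnostics."""

    participant_id: str
    params: AgentParams
    log_likelihood: float
    n_ties_at_max: int
    grid_spec: dict


def select_strategy(
    toolbox: Sequence[StrategyId],
    delta: float,
    stats: StrategyStats,
    problem_id: str,
    rng: np.random.Generator,
) -> StrategyId:
    """Resource-rational selection: argmax of r − δ·c over the toolbox.

    Exact score ties (within floating-point tolerance) are resolved
    uniformly at random.
    """
    members = sorted((StrategyId(s) for s in toolbox), key=lambda s: s.value)
    if not members:
        raise ValueError("toolbox must be nonempty")
    for s in members:
        if not stats.has(s, problem_id):
            raise KeyError(f"no stats for strategy {s.value} on problem {problem_id}")
    scores = np.array(
        [stats.r(s, problem_id) - delta * stats.c(s, problem_id) for s in members]
    )
    best = scores.max()
    tied = np.flatnonzero(np.isclose(scores, best, rtol=_SCORE_RTOL, atol=_SCORE_ATOL))
    if len(tied) == 1:
        return members[tied[0]]
    return members[tied[int(rng.integers(len(tied)))]]


def _run_choice_prob(p: ChoiceProblem, s: StrategyId, rng) -> float:
    """P(A | δ, S) contributed by one simulation run: 0, ½, or 1."""
    dec = apply_strategy(s, p, rng)
    if dec.tie:
        return 0.5
    return 1.0 if dec.choice == "A" else 0.0


def choice_probability(
    p: ChoiceProblem,
    params: AgentParams,
    stats: StrategyStats,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo probability of choosing A under the trembling-hand model.

    Estimates P(A | δ, S) by repeatedly selecting and executing a strategy,
    then mixes with ε; the result is bounded in [ε, 1 − ε] and equals ½
    exactly when ε = ½.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = 0.0
    for _ in range(reps):
        s = select_strategy(params.toolbox, params.delta, stats, p.id, rng)
        total += _run_choice_prob(p, s, rng)
    p_a = total / reps
    return p_a * (1.0 - params.epsilon) + (1.0 - p_a) * params.epsilon


def simulate_choices(
    params: AgentParams,
    problems: Sequence[ChoiceProblem],
    n_reps: int = 1,
    seed: int | np.random.Generator = 0,
    stats: Optional[StrategyStats] = None,
    age_group: str = "unspecified",
    participant_prefix: str = "sim",
    stats_reps: int = 100,
) -> ChoiceDataset:
    """Forward-simulate the model; each rep becomes one synthetic participant.

    Per problem: select a strategy (Eq-1 ties random), execute it (rule
    ties random), then flip the choice with probability ε.  Fixed seeds
    give bitwise-identical datasets.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if stats is None:
        stats = compute_strategy_stats(
            sorted(params.toolbox, key=lambda s: s.value),
            problems,
            reps=stats_reps,
            seed=int(rng.integers(2**31)),
        )
    rows = []
    for rep in range(n_reps):
        pid = f"{participant_prefix}{rep:03d}" if n_reps > 1 else participant_prefix
        for p in problems:
            s = select_strategy(params.toolbox, params.delta, stats, p.id, rng)
            choice = apply_strategy(s, p, rng).choice
            if rng.random() < params.epsilon:
                choice = "B" if choice == "A" else "A"
            rows.append(
                {
                    "participant_id": pid,
                    "age_group": age_group,
                    "problem_id": p.id,
                    "choice": choice,
                }
            )
    return ChoiceDataset(pd.DataFrame(rows))


class SimulationTable:
    """Pre-simulated per-run strategy predictions, shared across the grid.

    ``pchoice[run, strategy, problem]`` holds the run's P(A | strategy) in
    {0, ½, 1}.  Strategy execution does not depend on δ or ε, so the same
    table serves every grid point; δ only reorders the selection scores
    and ε only mixes the final probability.
    """

    def __init__(
        self,
        problems: Sequence[ChoiceProblem],
        strategies: Sequence[StrategyId],
        reps: int,
        seed: int | np.random.Generator,
    ):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.problems = list(problems)
        self.strategies = tuple(StrategyId(s) for s in strategies)
        self.reps = int(reps)
        self.problem_index = {p.id: i for i, p in enumerate(self.problems)}
        self.strategy_index = {s: i for i, s in enumerate(self.strategies)}
        self.pchoice = np.empty((reps, len(self.strategies), len(self.problems)))
        for rep in range(reps):
            for si, s in enumerate(self.strategies):
                for pi, p in enumerate(self.problems):
                    self.pchoice[rep, si, pi] = _run_choice_prob(p, s, rng)


def _per_run_pA(
    table: SimulationTable,
    members_idx: np.ndarray,
    scores: np.ndarray,
    tie_rng: np.random.Generator,
) -> np.ndarray:
    """(reps, n_problems) per-run P(A) for one toolbox at one δ.

    ``scores`` has shape (n_members, n_problems); Eq-1 ties are resolved
    uniformly at random, independently per run.
    """
    best = scores.max(axis=0)
    tied = np.isclose(scores, best[None, :], rtol=_SCORE_RTOL, atol=_SCORE_ATOL)
    sel = scores.argmax(axis=0)
    n_tied = tied.sum(axis=0)
    reps = table.reps
    run_idx = np.arange(reps)
    out = table.pchoice[:, members_idx[sel], np.arange(scores.shape[1])]
    for pi in np.flatnonzero(n_tied > 1):
        cands = members_idx[np.flatnonzero(tied[:, pi])]
        picks = cands[tie_rng.integers(len(cands), size=reps)]
        out[:, pi] = table.pchoice[run_idx, picks, pi]
    return out


def _ll_over_epsilons(
    p_obs: np.ndarray, epsilons: np.ndarray
) -> np.ndarray:
    """Run-averaged log-likelihood for every ε.

    ``p_obs[run, trial]`` is the run's probability of the observed choice
    before the trembling hand; the Eq-2 mixture gives
    q = ε + p_obs · (1 − 2ε), and the per-run trial log-probabilities are
    summed then averaged across runs on the log scale.
    """
    q = epsilons[None, None, :] + p_obs[:, :, None] * (1.0 - 2.0 * epsilons)[None, None, :]
    with np.errstate(divide="ignore"):
        ll_runs = np.log(q).sum(axis=1)  # (reps, n_eps)
    return ll_runs.mean(axis=0)


def log_likelihood(
    data: pd.DataFrame,
    params: AgentParams,
    problems: Sequence[ChoiceProblem],
    stats: StrategyStats,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Run-averaged log-likelihood of one participant's choices.

    Each of ``reps`` simulation runs yields per-trial probabilities in
    {ε, ½, 1 − ε}; trial log-probabilities are summed per run and the sum
    is averaged across runs.  With ε = 0 a run can assign probability 0 to
    an observed choice, which is reported as an explicit error rather than
    −inf.
    """
    if len(data) == 0:
        raise ValueError("no choice records")
    by_id = {p.id: p for p in problems}
    trials = [(by_id[rec.problem_id], rec.choice) for rec in data.itertuples()]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = params.epsilon
    ll_runs = np.zeros(reps)
    for rep in range(reps):
        total = 0.0
        for p, choice in trials:
            s = select_strategy(params.toolbox, params.delta, stats, p.id, rng)
            p_a = _run_choice_prob(p, s, rng)
            p_run = p_a if choice == "A" else 1.0 - p_a
            q = eps + p_run * (1.0 - 2.0 * eps)
            if q <= 0.0:
                raise ValueError(
                    "zero-probability observation: epsilon = 0 with a "
                    "deterministic prediction opposite to the data"
                )
            total += math.log(q)
        ll_runs[rep] = total
    return float(ll_runs.mean())


def _toolboxes(grid: GridSpec):
    for size in grid.toolbox_sizes:
        if size > len(grid.candidates):
            continue
        yield from itertools.combinations(range(len(grid.candidates)), size)


def fit_participant(
    data: pd.DataFrame,
    problems: Sequence[ChoiceProblem],
    stats: Optional[StrategyStats] = None,
    grid: Optional[GridSpec] = None,
    seed: int = 0,
    table: Optional[SimulationTable] = None,
    participant_id: Optional[str] = None,
) -> FitResult:
    """Grid-search maximum likelihood fit of the RRSS model for one participant.

    Searches every toolbox composition of the allowed sizes crossed with
    the δ and ε grids, maximizing the run-averaged log-likelihood.  Among
    grid points tied at the maximum, smaller toolboxes are preferred and a
    remaining tie is resolved at random (the number of tied points is
    reported as ``n_ties_at_max``).

    Within a toolbox, δ only permutes the selection scores, so the per-run
    strategy predictions are simulated once and reused across the whole
    (δ, ε) grid; identical selection patterns are likelihood-evaluated
    only once.
    """
    if len(data) == 0:
        raise ValueError("no choice records to fit")
    grid = grid or GridSpec.desk()
    ss = np.random.SeedSequence(seed)
    sim_rng, stats_rng, tie_rng, pick_rng = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    if participant_id is None:
        participant_id = str(data["participant_id"].iloc[0]) if "participant_id" in data else "?"

    problem_ids = [str(r) for r in data["problem_id"]]
    used_ids = sorted(set(problem_ids))
    by_id = {p.id: p for p in problems}
    used_problems = [by_id[i] for i in used_ids]

    if stats is None:
        stats = compute_strategy_stats(
            grid.candidates, used_problems, reps=grid.reps, seed=stats_rng
        )
    if table is None:
        table = SimulationTable(used_problems, grid.candidates, grid.reps, sim_rng)

    r_mat, c_mat = stats.matrices(grid.candidates, [p.id for p in table.problems])
    pidx = np.array([table.problem_index[i] for i in problem_ids])
    obs_a = np.array([c == "A" for c in data["choice"]])
    deltas = np.asarray(grid.deltas)
    epsilons = np.asarray(grid.epsilons)

    best_ll = -np.inf
    maxima: list[tuple[int, float, float, float]] = []  # (size, delta, eps, ll)
    memo: dict[bytes, np.ndarray] = {}

    for combo in _toolboxes(grid):
        members_idx = np.array(combo)
        r_sub, c_sub = r_mat[members_idx], c_mat[members_idx]
        # (n_deltas, n_members, n_problems) selection scores
        scores_all = r_sub[None, :, :] - deltas[:, None, None] * c_sub[None, :, :]
        best_sc = scores_all.max(axis=1)
        tied_all = np.isclose(
            scores_all, best_sc[:, None, :], rtol=_SCORE_RTOL, atol=_SCORE_ATOL
        )
        argm = scores_all.argmax(axis=1)  # (n_deltas, n_problems)
        # group deltas by identical selection pattern (including tie sets)
        keys: dict[bytes, list[int]] = {}
        for di in range(len(deltas)):
            key = argm[di].tobytes() + tied_all[di].tobytes()
            keys.setdefault(key, []).append(di)
        for key, delta_idxs in keys.items():
            di0 = delta_idxs[0]
            has_tie = tied_all[di0].sum(axis=0).max() > 1
            cache_key = members_idx.tobytes() + key
            if not has_tie and cache_key in memo:
                ll_eps = memo[cache_key]
            else:
                pA = _per_run_pA(table, members_idx, scores_all[di0], tie_rng)
                p_obs = np.where(obs_a[None, :], pA[:, pidx], 1.0 - pA[:, pidx])
                ll_eps = _ll_over_epsilons(p_obs, epsilons)
                if not has_tie:
                    memo[cache_key] = ll_eps
            size = len(combo)
            for ei, ll in enumerate(ll_eps):
                if ll > best_ll + _LL_TIE_TOL:
                    best_ll = ll
                    maxima = []
                if ll > best_ll - _LL_TIE_TOL:
                    for di in delta_idxs:
                        maxima.append((size, float(deltas[di]), float(epsilons[ei]), combo))

    n_ties = len(maxima)
    min_size = min(m[0] for m in maxima)
    finalists = [m for m in maxima if m[0] == min_size]
    pick = finalists[int(pick_rng.integers(len(finalists)))]
    _, delta, eps, combo = pick
    params = AgentParams(
        toolbox=frozenset(grid.candidates[i] for i in combo), delta=delta, epsilon=eps
    )
    return FitResult(
        participant_id=participant_id,
        params=params,
        log_likelihood=float(best_ll),
        n_ties_at_max=n_ties,
        grid_spec=grid.describe() | {"seed": seed},
    )


def posterior_predictive(
    fit: FitResult,
    problems: Sequence[ChoiceProblem],
    data: pd.DataFrame,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
    stats: Optional[StrategyStats] = None,
) -> dict:
    """Posterior predictive checks for one fitted participant.

    Simulates the fitted model ``reps`` times on the participant's
    problems and reports the proportion of simulated choices matching the
    observed ones, simulated decision quality and risk aversion overall
    and per domain, and strategy-selection counts normalized by the number
    of runs (so the normalized counts sum to the number of trials).
    """
    from .gambles import Domain, decision_quality, risk_aversion_indicator

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_id = {p.id: p for p in problems}
    trials = [(by_id[str(r.problem_id)], r.choice) for r in data.itertuples()]
    params = fit.params
    if stats is None:
        stats = compute_strategy_stats(
            sorted(params.toolbox, key=lambda s: s.value),
            [t[0] for t in trials],
            reps=reps,
            seed=int(rng.integers(2**31)),
        )
    matches = 0
    cost_total = 0.0
    counts = {s.value: 0 for s in sorted(params.toolbox, key=lambda s: s.value)}
    dq: dict[str, list] = {d.value: [] for d in Domain}
    ra: dict[str, list] = {d.value: [] for d in Domain}
    for _ in range(reps):
        for p, observed in trials:
            s = select_strategy(params.toolbox, params.delta, stats, p.id, rng)
            counts[s.value] += 1
            cost_total += stats.c(s, p.id)
            choice = apply_strategy(s, p, rng).choice
            if rng.random() < params.epsilon:
                choice = "B" if choice == "A" else "A"
            matches += choice == observed
            q = decision_quality(p, choice)
            if q is not None:
                dq[p.domain.value].append(q)
            r = risk_aversion_indicator(p, choice)
            if r is not None:
                ra[p.domain.value].append(r)
    n = reps * len(trials)
    pooled_dq = sum(dq.values(), [])
    pooled_ra = sum(ra.values(), [])
    result = {
        "participant_id": fit.participant_id,
        "match_proportion": matches / n,
        "mean_selected_cost": cost_total / n,
        "decision_quality": {
            "overall": float(np.mean(pooled_dq)) if pooled_dq else float("nan"),
            **{
                d: (float(np.mean(v)) if v else float("nan"))
                for d, v in dq.items()
            },
        },
        "risk_aversion": {
            "overall": float(np.mean(pooled_ra)) if pooled_ra else float("nan"),
            **{
                d: (float(np.mean(v)) if v else float("nan"))
                for d, v in ra.items()
            },
        },
        "strategy_counts": {k: v / reps for k, v in counts.items()},
    }
    return result
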