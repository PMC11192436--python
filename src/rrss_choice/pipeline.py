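"""End-to-end synthetic study: generate, fit, check, summarize.

One call runs the whole analysis on a self-generated dataset: build the
problem set, simulate a population of agents with known parameters, fit
the strategy-selection model to every simulated participant, run
posterior predictive checks, aggregate group summaries, and score
parameter recovery against the ground truth.  Every stage derives its
randomness from the study seed, so a rerun with the same configuration
is bitwise-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .costs import StrategyStats, compute_strategy_stats
from .gambles import ChoiceDataset, ChoiceProblem
from .model import (
    ALL_STRATEGIES,
    FitResult,
    GridSpec,
    SimulationTable,
    fit_participant,
    posterior_predictive,
)
from .report import GroupSummary, summarize_groups
from .synthetic import (
    PopulationConfig,
    ProblemSetConfig,
    fits_to_frame,
    generate_population,
    generate_problem_set,
    score_recovery,
)

__all__ = ["StudyConfig", "StudyResult", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a full synthetic study."""

    problems: ProblemSetConfig
    population: PopulationConfig
    grid: GridSpec = field(default_factory=GridSpec.desk)
    stats_reps: int = 100
    ppc_reps: int = 100
    seed: int = 0


@dataclass
class StudyResult:
    problems: list
    dataset: ChoiceDataset
    truth: pd.DataFrame
    stats: StrategyStats
    fits: list
    fit_frame: pd.DataFrame
    ppcs: list
    summary: GroupSummary
    recovery: dict


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full pipeline on a synthetic study; deterministic per config."""
    ss = np.random.SeedSequence(config.seed)
    stats_seed, table_seed, fit_root, ppc_root = ss.spawn(4)
    problems = generate_problem_set(config.problems)
    stats = compute_strategy_stats(
        list(ALL_STRATEGIES),
        problems,
        reps=config.stats_reps,
        seed=np.random.default_rng(stats_seed),
    )
    dataset, truth = generate_population(config.population, problems, stats=stats)
    table = SimulationTable(
        problems,
        config.grid.candidates,
        config.grid.reps,
        np.random.default_rng(table_seed),
    )
    fits: list[FitResult] = []
    ppcs: list[dict] = []
    fit_seeds = fit_root.generate_state(len(dataset.participants)) % (2**31)
    ppc_seeds = ppc_root.generate_state(len(dataset.participants))
    for i, pid in enumerate(dataset.participants):
        records = dataset.for_participant(pid)
        fit = fit_participant(
            records,
            problems,
            stats=stats,
            grid=config.grid,
            seed=int(fit_seeds[i]),
            table=table,
            participant_id=pid,
        )
        fits.append(fit)
        ppcs.append(
            posterior_predictive(
                fit,
                problems,
                records,
                reps=config.ppc_reps,
                seed=np.random.default_rng(ppc_seeds[i]),
                stats=stats,
            )
        )
    summary = summarize_groups(fits, ppcs, dataset, problems)
    recovery = score_recovery(truth, fits)
    return StudyResult(
        problems=problems,
        dataset=dataset,
        truth=truth,
        stats=stats,
        fits=fits,
        fit_frame=fits_to_frame(fits),
        ppcs=ppcs,
        summary=summary,
        recovery=recovery,
    )
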