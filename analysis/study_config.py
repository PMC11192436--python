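"""Shared configuration for the numbered analysis scripts.

The synthetic study emulates the design the pipeline targets: 105 choice
problems (41 gain / 31 loss / 33 mixed, 9 with a safe option) and two age
groups of simulated agents whose strategy pools differ — a younger pool
leaning on probability-sensitive, risk-averse heuristics and an older
pool leaning on outcome-only, risk-seeking heuristics — with toolboxes of
2-4 strategies and trembling-hand errors around 0.26.
"""

from pathlib import Path

import numpy as np

import rrss_choice as rc
from rrss_choice.strategies import StrategyId

RESULTS = Path(__file__).resolve().parent.parent / "results"

N_AGENTS_PER_GROUP = 6
STATS_REPS = 100
PPC_REPS = 100
GRID = rc.GridSpec.desk()

YOUNG_POOL = {StrategyId.MINI: 2, StrategyId.LL: 2, StrategyId.PH: 2,
              StrategyId.ML: 1, StrategyId.LEX: 1, StrategyId.WADD: 1}
OLD_POOL = {StrategyId.EQW: 2, StrategyId.MAXI: 2, StrategyId.BTA: 1,
            StrategyId.TALLY: 1, StrategyId.PROB: 1, StrategyId.WADD: 1}


def seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def population_config(seed: int) -> rc.PopulationConfig:
    return rc.PopulationConfig(
        groups={
            "younger": rc.GroupConfig(
                n_agents=N_AGENTS_PER_GROUP, toolbox_sizes=(2, 3, 4),
                strategy_weights=YOUNG_POOL, delta_range=(0.0, 5.0),
                epsilon_range=(0.2, 0.32),
            ),
            "older": rc.GroupConfig(
                n_agents=N_AGENTS_PER_GROUP, toolbox_sizes=(2, 3, 4),
                strategy_weights=OLD_POOL, delta_range=(0.0, 5.0),
                epsilon_range=(0.2, 0.32),
            ),
        },
        seed=seed,
    )
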