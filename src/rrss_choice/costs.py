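"""Strategy payoff and cost accounting.

For every strategy × problem pair the model needs two quantities:

``r``  the expected payoff — the (objective) expected value of the gamble
       the strategy selects, averaged over repeated simulations so that
       random tie-breaking is integrated out;

``c``  the expected cost — the number of elementary information processes
       (EIPs) the execution performs, likewise simulation-averaged.  Early
       stopping (the priority heuristic) makes counts path-dependent, so
       averaging matters there too.

The default cost scheme is defined operationally by the traces the
strategy implementations emit (documented in ``docs/methods.md``); an
alternative scheme can be supplied as a YAML/JSON mapping from strategy
abbreviation to a fixed per-problem count, which then overrides the traced
cost for that strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .eip import Eip
from .gambles import ChoiceProblem, expected_value
from .strategies import StrategyId, apply_strategy

__all__ = [
    "Eip",
    "CostScheme",
    "count_eips",
    "compute_strategy_stats",
    "StrategyStats",
]


@dataclass(frozen=True)
class CostScheme:
    """Optional per-strategy overrides of the traced EIP count."""

    overrides: Mapping[StrategyId, float] = None  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(
            self,
            "overrides",
            {StrategyId(k): float(v) for k, v in (self.overrides or {}).items()},
        )

    @classmethod
    def from_file(cls, path) -> "CostScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(overrides=raw)

    def cost(self, s: StrategyId, traced_count: int) -> float:
        return self.overrides.get(StrategyId(s), float(traced_count))


def count_eips(
    s: StrategyId, p: ChoiceProblem, rng: np.random.Generator
) -> int:
    """EIP count of a single strategy execution (length of its trace)."""
    n = len(apply_strategy(s, p, rng).eip_trace)
    assert n > 0
    return n


class StrategyStats:
    """Simulation-averaged payoff ``r`` and cost ``c`` per strategy × problem.

    Backed by a tidy DataFrame with columns
    ``strategy, problem_id, r, c`` and the rep count used for averaging.
    """

    def __init__(self, table: pd.DataFrame, reps: int):
        self.table = table.reset_index(drop=True)
        self.reps = int(reps)
        self._r = {
            (row.strategy, row.problem_id): row.r for row in table.itertuples()
        }
        self._c = {
            (row.strategy, row.problem_id): row.c for row in table.itertuples()
        }

    def r(self, s: StrategyId, problem_id: str) -> float:
        return self._r[(StrategyId(s).value, problem_id)]

    def c(self, s: StrategyId, problem_id: str) -> float:
        return self._c[(StrategyId(s).value, problem_id)]

    def has(self, s: StrategyId, problem_id: str) -> bool:
        return (StrategyId(s).value, problem_id) in self._r

    def matrices(
        self, strategies: Sequence[StrategyId], problem_ids: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """(r, c) arrays of shape (n_strategies, n_problems)."""
        r = np.array([[self.r(s, pid) for pid in problem_ids] for s in strategies])
        c = np.array([[self.c(s, pid) for pid in problem_ids] for s in strategies])
        return r, c

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, reps: int) -> "StrategyStats":
        return cls(pd.read_csv(path, dtype={"problem_id": str}), reps)


def compute_strategy_stats(
    strategies: Sequence[StrategyId],
    problems: Sequence[ChoiceProblem],
    reps: int = 100,
    seed: int = 0,
    cost_scheme: Optional[CostScheme] = None,
) -> StrategyStats:
    """Simulate every strategy on every problem ``reps`` times and average.

    ``r`` is the mean expected value of the selected gambles (objective
    EVs, not realized draws); ``c`` is the mean trace length, unless a
    cost-scheme override fixes it.  Deterministic for a fixed seed.
    """
    if not strategies:
        raise ValueError("no strategies given")
    if not problems:
        raise ValueError("no problems given")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    scheme = cost_scheme or CostScheme()
    rng = np.random.default_rng(seed)
    evs = {p.id: (expected_value(p.option_a), expected_value(p.option_b)) for p in problems}
    rows = []
    for s in strategies:
        s = StrategyId(s)
        for p in problems:
            r_sum = 0.0
            c_sum = 0.0
            for _ in range(reps):
                dec = apply_strategy(s, p, rng)
                r_sum += evs[p.id][0] if dec.choice == "A" else evs[p.id][1]
                c_sum += len(dec.eip_trace)
            rows.append(
                {
                    "strategy": s.value,
                    "problem_id": p.id,
                    "r": r_sum / reps,
                    "c": scheme.cost(s, c_sum / reps),
                }
            )
    return StrategyStats(pd.DataFrame(rows), reps)
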