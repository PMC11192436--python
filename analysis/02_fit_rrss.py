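"""Fit the resource-rational strategy-selection model to every participant.

Reads results/problems.csv and results/choices.csv, runs the grid search
(reduced "desk" grid: toolbox sizes 1-4, delta 0-20 step 0.5, epsilon
0.05-0.5 step 0.05, 20 simulation runs) and writes results/fits.csv.
"""

import argparse
import time

import numpy as np

import rrss_choice as rc
from study_config import GRID, RESULTS, STATS_REPS, seeds


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    _, _, s_stats, s_table, s_fit = seeds(args.seed, 5)

    problems = rc.io.read_problems(RESULTS / "problems.csv")
    dataset = rc.io.read_choices(RESULTS / "choices.csv")
    stats = rc.compute_strategy_stats(
        list(rc.StrategyId), problems, reps=STATS_REPS, seed=s_stats
    )
    stats.to_csv(RESULTS / "strategy_stats.csv")
    table = rc.SimulationTable(problems, GRID.candidates, GRID.reps, np.random.default_rng(s_table))

    import math

    n_toolboxes = sum(math.comb(len(GRID.candidates), k) for k in GRID.toolbox_sizes)
    n_grid = n_toolboxes * len(GRID.deltas) * len(GRID.epsilons)
    print(f"Grid: {n_grid:,} parameter combinations per participant "
          f"({GRID.reps} simulation runs each, shared across epsilon).")

    fits = []
    t0 = time.time()
    for i, pid in enumerate(dataset.participants):
        fit = rc.fit_participant(
            dataset.for_participant(pid), problems, stats=stats, grid=GRID,
            seed=s_fit + i, table=table, participant_id=pid,
        )
        fits.append(fit)
        print(f"  {pid}: toolbox {{{ '|'.join(s.value for s in fit.params.toolbox_sorted) }}}, "
              f"delta={fit.params.delta:.1f}, epsilon={fit.params.epsilon:.2f}, "
              f"LL={fit.log_likelihood:.1f}, ties at max={fit.n_ties_at_max}")
    frame = rc.fits_to_frame(fits)
    frame.to_csv(RESULTS / "fits.csv", index=False)
    print(f"Fitted {len(fits)} participants in {time.time() - t0:.0f}s; "
          f"mean epsilon {frame.epsilon.mean():.2f}, mean toolbox size "
          f"{frame.toolbox_size.mean():.2f}. Wrote fits.csv.")


if __name__ == "__main__":
    main()
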