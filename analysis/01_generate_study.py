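"""Generate the synthetic study: choice problems and simulated participants.

Writes results/problems.csv, results/choices.csv and results/truth.csv
(the ground-truth agent parameters used later for recovery scoring).
"""

import argparse

import rrss_choice as rc
from study_config import RESULTS, STATS_REPS, population_config, seeds


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    s_problems, s_pop = seeds(args.seed, 2)

    problems = rc.generate_problem_set(rc.ProblemSetConfig(seed=s_problems))
    dataset, truth = rc.generate_population(
        population_config(s_pop), problems, stats_reps=STATS_REPS
    )
    rc.io.write_problems(problems, RESULTS / "problems.csv")
    rc.io.write_choices(dataset, RESULTS / "choices.csv")
    truth.to_csv(RESULTS / "truth.csv", index=False)

    n_safe = sum(p.has_safe_option for p in problems)
    domains = [p.domain.value for p in problems]
    print(
        f"Generated {len(problems)} problems "
        f"({domains.count('gain')} gain / {domains.count('loss')} loss / "
        f"{domains.count('mixed')} mixed, {n_safe} with a safe option) "
        f"and {len(truth)} simulated participants "
        f"({(truth.age_group == 'younger').sum()} younger, "
        f"{(truth.age_group == 'older').sum()} older)."
    )
    print(f"True epsilon range: {truth.epsilon.min():.2f}-{truth.epsilon.max():.2f}; "
          f"mean toolbox size {truth.toolbox_size.mean():.2f}.")
    print(f"Wrote problems.csv, choices.csv, truth.csv to {RESULTS}/")


if __name__ == "__main__":
    main()
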