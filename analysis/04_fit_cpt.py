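"""Fit the cumulative prospect theory baseline and compare model fits.

Fits the six-parameter CPT model to every participant (coarse grid plus
L-BFGS-B refinement) and writes results/cpt_fits.csv and a model
comparison table of summed log-likelihoods per age group,
results/model_comparison.csv.
"""

import argparse

import pandas as pd

import rrss_choice as rc
from study_config import RESULTS

GRID_STEPS = 7
N_STARTS = 15


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)  # CPT fitting is deterministic
    ap.parse_args()

    problems = rc.io.read_problems(RESULTS / "problems.csv")
    dataset = rc.io.read_choices(RESULTS / "choices.csv")
    rrss_fits = pd.read_csv(RESULTS / "fits.csv")

    rows = []
    for pid in dataset.participants:
        records = dataset.for_participant(pid)
        params, ll, diag = rc.fit_cpt(records, problems, grid_steps=GRID_STEPS, n_starts=N_STARTS)
        rows.append(
            {"participant_id": pid, "age_group": dataset.age_group_of(pid)}
            | params.as_dict()
            | {"log_likelihood": ll, "n_successful_starts": diag["n_successful"]}
        )
    cpt = pd.DataFrame(rows)
    cpt.to_csv(RESULTS / "cpt_fits.csv", index=False)

    rrss_fits = rrss_fits.merge(
        cpt[["participant_id", "age_group"]], on="participant_id"
    )
    comparison = []
    for model, frame in (("rrss", rrss_fits), ("cpt", cpt)):
        row = {"model": model, "full_sample": frame.log_likelihood.sum()}
        for grp, sub in frame.groupby("age_group"):
            row[grp] = sub.log_likelihood.sum()
        comparison.append(row)
    comp = pd.DataFrame(comparison)
    comp.to_csv(RESULTS / "model_comparison.csv", index=False)
    print("Summed log-likelihoods (higher = better fit):")
    print(comp.to_string(index=False))
    print("Wrote cpt_fits.csv and model_comparison.csv.")


if __name__ == "__main__":
    main()
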