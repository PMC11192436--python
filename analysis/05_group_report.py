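"""Aggregate everything into group summaries and score parameter recovery.

Reads the fits, posterior predictive checks and ground truth, writes the
group report (CSV tables plus report.md) under results/report/ and the
recovery scores to results/recovery.csv.
"""

import argparse

import pandas as pd

import rrss_choice as rc
from rrss_choice.synthetic import str_to_toolbox
from study_config import RESULTS


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--figures", action="store_true", help="also write bar charts")
    args = ap.parse_args()

    problems = rc.io.read_problems(RESULTS / "problems.csv")
    dataset = rc.io.read_choices(RESULTS / "choices.csv")
    fits_frame = pd.read_csv(RESULTS / "fits.csv")
    ppc_frame = pd.read_csv(RESULTS / "ppc.csv")
    truth = pd.read_csv(RESULTS / "truth.csv")

    fits, ppcs = [], []
    for _, row in fits_frame.iterrows():
        fits.append(
            rc.FitResult(
                participant_id=row.participant_id,
                params=rc.AgentParams(str_to_toolbox(row.toolbox), row.delta, row.epsilon),
                log_likelihood=row.log_likelihood,
                n_ties_at_max=int(row.n_ties_at_max),
                grid_spec={},
            )
        )
        p = ppc_frame[ppc_frame.participant_id == row.participant_id].iloc[0]
        ppcs.append(
            {
                "participant_id": row.participant_id,
                "match_proportion": p.match_proportion,
                "mean_selected_cost": p.mean_selected_cost,
                "decision_quality": {
                    d: p[f"decision_quality_{d}"] for d in ("overall", "gain", "loss", "mixed")
                },
                "risk_aversion": {
                    d: p[f"risk_aversion_{d}"] for d in ("overall", "gain", "loss", "mixed")
                },
                "strategy_counts": {
                    c.removeprefix("count_"): p[c]
                    for c in ppc_frame.columns
                    if c.startswith("count_") and pd.notna(p[c])
                },
            }
        )
    summary = rc.summarize_groups(fits, ppcs, dataset, problems)
    rc.write_report(summary, RESULTS / "report", figures=args.figures)

    recovery = rc.score_recovery(truth, fits_frame)
    pd.DataFrame([{k: v for k, v in recovery.items() if not isinstance(v, list)}]).to_csv(
        RESULTS / "recovery.csv", index=False
    )

    gp = summary.group_params.set_index("age_group")
    for grp in gp.index:
        print(
            f"{grp}: toolbox size {gp.loc[grp, 'toolbox_size_mean']:.2f} "
            f"(SD {gp.loc[grp, 'toolbox_size_sd']:.2f}), "
            f"selected cost {gp.loc[grp, 'selected_cost_mean']:.2f}, "
            f"delta {gp.loc[grp, 'delta_mean']:.2f}, "
            f"epsilon {gp.loc[grp, 'epsilon_mean']:.2f}, "
            f"PPC match {gp.loc[grp, 'match_proportion_mean']:.2f}"
        )
    print(
        f"Recovery vs ground truth: toolbox Jaccard {recovery['jaccard_mean']:.2f}, "
        f"epsilon MAE {recovery['epsilon_mae']:.3f} "
        f"(within 0.1 for {recovery['epsilon_within_0.1']:.0%} of agents)."
    )
    print(f"Wrote report tables to {RESULTS}/report and recovery.csv.")


if __name__ == "__main__":
    main()
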