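"""Group-level summaries and report writing.

Aggregates per-participant fits and posterior predictive checks into the
descriptive quantities the analysis reports per group: mean/SD of the
selected-strategy cost, toolbox size, cost weight δ and trembling-hand
error ε; normalized strategy-frequency tables; and decision quality and
risk aversion by domain, observed and simulated.  Closed-form effect
sizes (Cohen's d, Cramér's V) are provided as the descriptive inputs a
downstream inferential analysis would consume; no Bayes-factor or
mixed-model machinery is reimplemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .gambles import ChoiceDataset, ChoiceProblem, Domain
from .model import FitResult
from .strategies import StrategyId

__all__ = [
    "GroupSummary",
    "summarize_groups",
    "write_report",
    "read_summary",
    "cohens_d",
    "cramers_v",
]


@dataclass
class GroupSummary:
    """Three tidy tables: per-group parameters, strategy frequencies, and
    behavioral metrics by domain (observed vs simulated)."""

    group_params: pd.DataFrame
    strategy_freq: pd.DataFrame
    behavior: pd.DataFrame

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GroupSummary)
            and self.group_params.equals(other.group_params)
            and self.strategy_freq.equals(other.strategy_freq)
            and self.behavior.equals(other.behavior)
        )


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardized mean difference with a pooled-variance denominator."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        return float("nan")
    pooled = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled))


def cramers_v(table: np.ndarray) -> float:
    """Association strength for a contingency table: sqrt(chi2 / (n*(k-1)))."""
    table = np.asarray(table, float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    n = table.sum()
    k = min(table.shape) - 1 if table.ndim == 2 and min(table.shape) else 0
    if n == 0 or k < 1:
        return float("nan")
    chi2 = sp_stats.chi2_contingency(table, correction=False)[0]
    return float(np.sqrt(chi2 / (n * k)))


def summarize_groups(
    fits: Sequence[FitResult],
    ppcs: Sequence[dict],
    dataset: ChoiceDataset,
    problems: Sequence[ChoiceProblem],
) -> GroupSummary:
    """Aggregate per-participant results into per-group descriptives.

    ``ppcs`` are the per-participant posterior predictive records (in the
    same order or keyed by participant id); observed behavior comes from
    the dataset itself.
    """
    if not fits:
        raise ValueError("no fits to summarize")
    ppc_by_id = {p["participant_id"]: p for p in ppcs}
    fit_rows = []
    for f in fits:
        group = dataset.age_group_of(f.participant_id)
        ppc = ppc_by_id.get(f.participant_id)
        if ppc is None:
            raise ValueError(f"no posterior predictive record for {f.participant_id}")
        fit_rows.append(
            {
                "participant_id": f.participant_id,
                "age_group": group,
                "toolbox_size": len(f.params.toolbox),
                "delta": f.params.delta,
                "epsilon": f.params.epsilon,
                "selected_cost": ppc["mean_selected_cost"],
                "match_proportion": ppc["match_proportion"],
            }
        )
    per_part = pd.DataFrame(fit_rows)

    rows = []
    for group, sub in per_part.groupby("age_group", sort=True):
        if sub.empty:
            raise ValueError(f"empty group {group!r}")
        row = {"age_group": group, "n_participants": len(sub)}
        for col in ("selected_cost", "toolbox_size", "delta", "epsilon", "match_proportion"):
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(row)
    group_params = pd.DataFrame(rows)

    freq_rows = []
    for f in fits:
        group = dataset.age_group_of(f.participant_id)
        for s, cnt in ppc_by_id[f.participant_id]["strategy_counts"].items():
            freq_rows.append({"age_group": group, "strategy": s, "count": cnt})
    strategy_freq = (
        pd.DataFrame(freq_rows)
        .groupby(["age_group", "strategy"], sort=True, as_index=False)["count"]
        .sum()
    )
    # include zero rows so every group covers all 11 strategies
    groups = sorted(strategy_freq["age_group"].unique())
    full = pd.MultiIndex.from_product(
        [groups, [s.value for s in StrategyId]], names=["age_group", "strategy"]
    )
    strategy_freq = (
        strategy_freq.set_index(["age_group", "strategy"])
        .reindex(full, fill_value=0.0)
        .reset_index()
        .sort_values(["age_group", "strategy"], ignore_index=True)
    )

    observed = dataset.behavioral_summary(problems)
    obs_by_id = observed.set_index("participant_id")
    beh_rows = []
    for group, sub in per_part.groupby("age_group", sort=True):
        ids = sub["participant_id"]
        for domain in ["overall"] + [d.value for d in Domain]:
            obs_dq_col = "decision_quality" if domain == "overall" else f"decision_quality_{domain}"
            obs_ra_col = "risk_aversion" if domain == "overall" else f"risk_aversion_{domain}"
            sim_dq = [ppc_by_id[i]["decision_quality"][domain] for i in ids]
            sim_ra = [ppc_by_id[i]["risk_aversion"][domain] for i in ids]
            beh_rows.append(
                {
                    "age_group": group,
                    "domain": domain,
                    "observed_decision_quality": float(np.nanmean(obs_by_id.loc[ids, obs_dq_col])),
                    "observed_risk_aversion": float(np.nanmean(obs_by_id.loc[ids, obs_ra_col])),
                    "simulated_decision_quality": float(np.nanmean(sim_dq)),
                    "simulated_risk_aversion": float(np.nanmean(sim_ra)),
                }
            )
    behavior = pd.DataFrame(beh_rows)
    return GroupSummary(group_params=group_params, strategy_freq=strategy_freq, behavior=behavior)


_FILES = {
    "group_params": "group_parameters.csv",
    "strategy_freq": "strategy_frequencies.csv",
    "behavior": "behavior_by_domain.csv",
}


def write_report(summary: GroupSummary, path, figures: bool = False) -> None:
    """Write the summary tables as CSVs plus a short markdown report.

    With ``figures=True`` bar charts of the group parameters and strategy
    frequencies are also written (matplotlib is only imported in that
    case).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for attr, fname in _FILES.items():
        getattr(summary, attr).to_csv(path / fname, index=False)
    lines = ["# Group summary", "", "## Parameters", ""]
    lines.append(summary.group_params.to_string(index=False))
    lines += ["", "## Strategy frequencies (normalized counts)", ""]
    pivot = summary.strategy_freq.pivot(index="strategy", columns="age_group", values="count")
    lines.append(pivot.to_string())
    lines += ["", "## Behavior by domain", ""]
    lines.append(summary.behavior.to_string(index=False))
    groups = list(summary.group_params["age_group"])
    if len(groups) == 2:
        tab = pivot.to_numpy().T
        lines += ["", f"Strategy-distribution Cramér's V: {cramers_v(tab):.3f}"]
    (path / "report.md").write_text("\n".join(lines) + "\n")
    if figures:
        _write_figures(summary, path)


def read_summary(path) -> GroupSummary:
    path = Path(path)
    return GroupSummary(
        **{attr: pd.read_csv(path / fname) for attr, fname in _FILES.items()}
    )


def _write_figures(summary: GroupSummary, path: Path) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    panels = [
        ("selected_cost", "Average strategy cost"),
        ("toolbox_size", "Toolbox size"),
        ("delta", "Cost weight delta"),
        ("epsilon", "Trembling-hand error"),
    ]
    gp = summary.group_params
    for ax, (col, title) in zip(axes.ravel(), panels):
        ax.bar(gp["age_group"], gp[f"{col}_mean"], yerr=gp[f"{col}_sd"], capsize=4)
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path / "group_parameters.png", dpi=150)
    plt.close(fig)

    pivot = summary.strategy_freq.pivot(
        index="strategy", columns="age_group", values="count"
    )
    ax = pivot.plot.bar(figsize=(9, 4))
    ax.set_ylabel("normalized strategy count")
    ax.figure.tight_layout()
    ax.figure.savefig(path / "strategy_frequencies.png", dpi=150)
    plt.close(ax.figure)
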