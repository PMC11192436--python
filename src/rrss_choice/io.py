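"""CSV schemas for choice problems, choice data, and fitted parameters.

Problem files are wide tables: ``id``, optional ``domain``, then up to N
outcome/probability column pairs per option (``o_a1, p_a1, o_a2, p_a2, ...``
and likewise ``o_b*``, ``p_b*``).  Trailing empty pairs encode safe options.
Choice files are long tables with ``participant_id, age_group, problem_id,
choice``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gambles import ChoiceDataset, ChoiceProblem, Domain, Gamble

__all__ = [
    "read_problems",
    "write_problems",
    "read_choices",
    "write_choices",
]


def _gamble_from_row(row: pd.Series, side: str) -> Gamble:
    pat = re.compile(rf"^o_{side}(\d+)$")
    idxs = sorted(int(m.group(1)) for c in row.index if (m := pat.match(c)))
    outcomes = []
    for i in idxs:
        x, p = row.get(f"o_{side}{i}"), row.get(f"p_{side}{i}")
        if pd.isna(x) and pd.isna(p):
            continue
        if pd.isna(x) or pd.isna(p):
            raise ValueError(f"outcome/probability pair o_{side}{i}/p_{side}{i} incomplete")
        outcomes.append((float(x), float(p)))
    return Gamble(outcomes)


def read_problems(path) -> list[ChoiceProblem]:
    """Load and validate a problem CSV; declared domains are checked."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("problem file needs an 'id' column")
    problems = []
    for _, row in df.iterrows():
        domain = None
        if "domain" in df.columns and not pd.isna(row["domain"]):
            domain = Domain(row["domain"])
        problems.append(
            ChoiceProblem(
                id=str(row["id"]),
                option_a=_gamble_from_row(row, "a"),
                option_b=_gamble_from_row(row, "b"),
                domain=domain,
            )
        )
    ids = [p.id for p in problems]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate problem ids")
    return problems


def write_problems(problems: Sequence[ChoiceProblem], path) -> None:
    n_a = max(len(p.option_a) for p in problems)
    n_b = max(len(p.option_b) for p in problems)
    rows = []
    for p in problems:
        row: dict = {"id": p.id, "domain": p.domain.value}
        for side, g, n in (("a", p.option_a, n_a), ("b", p.option_b, n_b)):
            for i in range(n):
                if i < len(g):
                    x, pr = g.outcomes[i]
                    row[f"o_{side}{i + 1}"] = x
                    row[f"p_{side}{i + 1}"] = pr
                else:
                    row[f"o_{side}{i + 1}"] = np.nan
                    row[f"p_{side}{i + 1}"] = np.nan
        rows.append(row)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_choices(path) -> ChoiceDataset:
    df = pd.read_csv(path, dtype={"participant_id": str, "problem_id": str})
    return ChoiceDataset(df)


def write_choices(dataset: ChoiceDataset, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.records.to_csv(path, index=False)
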