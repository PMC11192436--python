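"""Gambles, choice problems, and the behavioral metrics built on them.

A *gamble* is a probability distribution over monetary outcomes; a *safe
option* is the degenerate one-outcome gamble.  A *choice problem* pairs two
gambles and is classified as gain, loss, or mixed by the signs of its
payoffs.  Two behavioral summaries are used throughout the analysis:

decision quality
    indicator that the chosen option has the strictly higher expected value
    (a proxy for long-run payoff maximization);

risk aversion
    indicator that the chosen option has the strictly lower coefficient of
    variation, CV = SD / |EV|, a standard dispersion-per-magnitude measure
    of an option's riskiness.

Ties and undefined cases (equal EVs, equal CVs, CV of a zero-EV gamble)
yield ``None`` and are excluded from averages rather than given half
credit.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Domain",
    "Gamble",
    "ChoiceProblem",
    "ChoiceDataset",
    "expected_value",
    "coefficient_of_variation",
    "classify_domain",
    "decision_quality",
    "risk_aversion_indicator",
]

_PROB_TOL = 1e-9


class Domain(str, enum.Enum):
    """Sign-based classification of a choice problem's payoffs."""

    GAIN = "gain"
    LOSS = "loss"
    MIXED = "mixed"


@dataclass(frozen=True)
class Gamble:
    """A finite lottery: outcome payoffs with their probabilities.

    Parameters
    ----------
    outcomes
        Sequence of ``(payoff, probability)`` pairs.  Probabilities must be
        in [0, 1] and sum to 1 (tolerance 1e-9).  A safe option is a single
        outcome with probability 1.
    """

    outcomes: tuple[tuple[float, float], ...]

    def __init__(self, outcomes: Iterable[tuple[float, float]]):
        outs = tuple((float(x), float(p)) for x, p in outcomes)
        if not outs:
            raise ValueError("a gamble needs at least one outcome")
        probs = [p for _, p in outs]
        if any(p < -_PROB_TOL or p > 1 + _PROB_TOL for p in probs):
            raise ValueError(f"probabilities must lie in [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)}")
        object.__setattr__(self, "outcomes", outs)

    @property
    def payoffs(self) -> np.ndarray:
        return np.array([x for x, _ in self.outcomes])

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p for _, p in self.outcomes])

    @property
    def is_safe(self) -> bool:
        return len(self.outcomes) == 1

    def __len__(self) -> int:
        return len(self.outcomes)


def expected_value(g: Gamble) -> float:
    """Probability-weighted mean payoff of a gamble."""
    return float(np.dot(g.payoffs, g.probabilities))


def coefficient_of_variation(g: Gamble) -> Optional[float]:
    """SD of the payoff distribution divided by |EV|.

    Returns ``None`` (undefined) when EV = 0; |EV| in the denominator keeps
    the ratio nonnegative for loss gambles.
    """
    ev = expected_value(g)
    if ev == 0.0:
        return None
    var = float(np.dot(g.probabilities, (g.payoffs - ev) ** 2))
    return math.sqrt(max(var, 0.0)) / abs(ev)


@dataclass(frozen=True)
class ChoiceProblem:
    """A pair of gambles to choose between, with a sign-domain label."""

    id: str
    option_a: Gamble
    option_b: Gamble
    domain: Domain = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        inferred = classify_domain_from_gambles(self.option_a, self.option_b)
        if self.domain is None:
            object.__setattr__(self, "domain", inferred)
        else:
            dom = Domain(self.domain)
            if dom is not inferred:
                raise ValueError(
                    f"problem {self.id}: declared domain {dom.value!r} "
                    f"inconsistent with payoffs ({inferred.value!r})"
                )
            object.__setattr__(self, "domain", dom)
        if self.option_a.outcomes == self.option_b.outcomes:
            raise ValueError(f"problem {self.id}: options are identical")

    def option(self, which: str) -> Gamble:
        if which == "A":
            return self.option_a
        if which == "B":
            return self.option_b
        raise ValueError(f"choice must be 'A' or 'B', got {which!r}")

    @property
    def options(self) -> tuple[Gamble, Gamble]:
        return (self.option_a, self.option_b)

    @property
    def has_safe_option(self) -> bool:
        return self.option_a.is_safe or self.option_b.is_safe


def classify_domain_from_gambles(a: Gamble, b: Gamble) -> Domain:
    payoffs = np.concatenate([a.payoffs, b.payoffs])
    if np.all(payoffs == 0):
        raise ValueError("degenerate problem: every payoff is zero")
    if np.all(payoffs >= 0):
        return Domain.GAIN
    if np.all(payoffs <= 0):
        return Domain.LOSS
    return Domain.MIXED


def classify_domain(p: ChoiceProblem) -> Domain:
    """Gain iff all payoffs >= 0 (not all zero), loss iff all <= 0, else mixed."""
    return classify_domain_from_gambles(p.option_a, p.option_b)


def decision_quality(p: ChoiceProblem, choice: str) -> Optional[int]:
    """1 if the chosen option has the strictly higher EV, 0 if lower.

    ``None`` when the EVs tie (the problem carries no signal about
    EV maximization and is excluded from averages).
    """
    ev_chosen = expected_value(p.option(choice))
    ev_other = expected_value(p.option("B" if choice == "A" else "A"))
    if ev_chosen == ev_other:
        return None
    return int(ev_chosen > ev_other)


def risk_aversion_indicator(p: ChoiceProblem, choice: str) -> Optional[int]:
    """1 if the chosen option has the strictly lower CV, 0 if higher.

    ``None`` when either CV is undefined (zero EV) or the CVs tie.
    """
    cv_chosen = coefficient_of_variation(p.option(choice))
    cv_other = coefficient_of_variation(p.option("B" if choice == "A" else "A"))
    if cv_chosen is None or cv_other is None or cv_chosen == cv_other:
        return None
    return int(cv_chosen < cv_other)


class ChoiceDataset:
    """Long-format table of observed (or simulated) choices.

    Columns: ``participant_id``, ``age_group`` (younger / older /
    unspecified), ``problem_id``, ``choice`` (A or B).  Each
    (participant, problem) pair appears at most once.
    """

    AGE_GROUPS = ("younger", "older", "unspecified")

    def __init__(self, records: pd.DataFrame):
        required = ["participant_id", "age_group", "problem_id", "choice"]
        missing = [c for c in required if c not in records.columns]
        if missing:
            raise ValueError(f"choice table missing columns: {missing}")
        df = records[required].copy().reset_index(drop=True)
        bad_choice = ~df["choice"].isin(["A", "B"])
        if bad_choice.any():
            raise ValueError(
                f"invalid choice values: {sorted(df.loc[bad_choice, 'choice'].unique())}"
            )
        bad_group = ~df["age_group"].isin(self.AGE_GROUPS)
        if bad_group.any():
            raise ValueError(
                f"invalid age groups: {sorted(df.loc[bad_group, 'age_group'].unique())}"
            )
        if df.duplicated(subset=["participant_id", "problem_id"]).any():
            raise ValueError("duplicate (participant, problem) records")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChoiceDataset) and self.records.equals(other.records)

    @property
    def participants(self) -> list:
        return list(self.records["participant_id"].unique())

    def for_participant(self, participant_id) -> pd.DataFrame:
        return self.records[self.records["participant_id"] == participant_id]

    def age_group_of(self, participant_id) -> str:
        sub = self.for_participant(participant_id)
        if sub.empty:
            raise KeyError(f"no records for participant {participant_id!r}")
        return sub["age_group"].iloc[0]

    def behavioral_summary(
        self, problems: Sequence[ChoiceProblem]
    ) -> pd.DataFrame:
        """Per-participant decision quality and risk aversion, overall and by domain."""
        by_id = {p.id: p for p in problems}
        rows = []
        for pid, sub in self.records.groupby("participant_id", sort=False):
            dq: dict[str, list] = {d.value: [] for d in Domain}
            ra: dict[str, list] = {d.value: [] for d in Domain}
            for rec in sub.itertuples():
                prob = by_id[rec.problem_id]
                q = decision_quality(prob, rec.choice)
                r = risk_aversion_indicator(prob, rec.choice)
                if q is not None:
                    dq[prob.domain.value].append(q)
                if r is not None:
                    ra[prob.domain.value].append(r)
            row = {
                "participant_id": pid,
                "age_group": sub["age_group"].iloc[0],
                "decision_quality": _mean_or_nan(sum(dq.values(), [])),
                "risk_aversion": _mean_or_nan(sum(ra.values(), [])),
            }
            for d in Domain:
                row[f"decision_quality_{d.value}"] = _mean_or_nan(dq[d.value])
                row[f"risk_aversion_{d.value}"] = _mean_or_nan(ra[d.value])
            rows.append(row)
        return pd.DataFrame(rows)


def _mean_or_nan(values: list) -> float:
    return float(np.mean(values)) if values else float("nan")
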