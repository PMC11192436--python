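"""Eleven heuristic strategies for binary risky choice.

Each strategy is a deterministic decision rule up to tie-breaking: when a
rule is indifferent between the two options, the choice is made uniformly
at random with the supplied generator and flagged as a tie.  Every
execution emits a trace of elementary information processes (EIPs) whose
length serves as the strategy's cognitive cost.

Domain handling.  All rules operate on signed payoffs, so "higher" always
means "better": in the loss domain, maximax picks the least-bad maximum and
minimax avoids the worst loss, exactly as in gains.  Tallying's loss-domain
formulation (swap gain/loss and higher/lower) reduces to the same four
signed-payoff comparisons as its gain formulation, so a single
implementation covers both.  The priority heuristic is mirrored for loss
problems: attributes become minimum loss, probability of minimum loss, and
maximum loss, with the aspiration level set to 1/10 of the absolute maximum
loss; mixed problems use the gain form on signed payoffs (the worst outcome
plays the role of the minimum gain).

Internal indifference (e.g., which outcome is "most likely" in a 50/50
gamble) is resolved randomly as well, but only indifference between the
*options* sets the tie flag.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .eip import Eip
from .gambles import (
    ChoiceProblem,
    Domain,
    Gamble,
    risk_aversion_indicator,
)

__all__ = [
    "StrategyId",
    "Decision",
    "apply_strategy",
    "decision_profile",
    "risk_profile",
    "STRATEGY_LABELS",
]

_TOL = 1e-9


class StrategyId(str, enum.Enum):
    """The eleven candidate strategies, by their standard abbreviations."""

    MINI = "MINI"  # minimax
    MAXI = "MAXI"  # maximax
    LL = "LL"  # least-likely
    ML = "ML"  # most-likely
    BTA = "BTA"  # better-than-average
    EQW = "EQW"  # equal-weight
    TALLY = "TALLY"  # tallying
    PROB = "PROB"  # probable
    LEX = "LEX"  # lexicographic
    PH = "PH"  # priority heuristic
    WADD = "WADD"  # weighted-additive


STRATEGY_LABELS = {
    StrategyId.MINI: "minimax",
    StrategyId.MAXI: "maximax",
    StrategyId.LL: "least-likely",
    StrategyId.ML: "most-likely",
    StrategyId.BTA: "better-than-average",
    StrategyId.EQW: "equal-weight",
    StrategyId.TALLY: "tallying",
    StrategyId.PROB: "probable",
    StrategyId.LEX: "lexicographic",
    StrategyId.PH: "priority heuristic",
    StrategyId.WADD: "weighted-additive",
}


@dataclass(frozen=True)
class Decision:
    """Outcome of one strategy execution.

    ``tie`` is True when the rule was indifferent between the options and
    the recorded ``choice`` was drawn at random.  ``eip_trace`` is the
    ordered list of elementary operations the execution performed.
    """

    choice: str  # "A" or "B"
    tie: bool
    eip_trace: tuple[Eip, ...]


def _argbest(values: Sequence[float], *, largest: bool) -> Optional[int]:
    """Index of the better of two values; None on an (exact) tie."""
    a, b = values
    if a == b:
        return None
    if largest:
        return 0 if a > b else 1
    return 0 if a < b else 1


def _read_payoffs(g: Gamble, trace: list) -> np.ndarray:
    trace.extend([Eip.READ] * len(g))
    return g.payoffs


def _read_probs(g: Gamble, trace: list) -> np.ndarray:
    trace.extend([Eip.READ] * len(g))
    return g.probabilities


def _scan_extreme(g: Gamble, trace: list, *, largest: bool) -> float:
    """Read the payoffs of one option and locate its min or max."""
    xs = _read_payoffs(g, trace)
    trace.extend([Eip.COMPARE] * (len(g) - 1))
    return float(xs.max() if largest else xs.min())


def _prob_of_extreme(g: Gamble, trace: list, *, largest: bool) -> float:
    """Total probability of the option's best/worst payoff (one READ per
    contributing outcome, ADDs if several outcomes share the extreme)."""
    xs = g.payoffs
    target = xs.max() if largest else xs.min()
    mask = xs == target
    k = int(mask.sum())
    trace.extend([Eip.READ] * k)
    trace.extend([Eip.ADD] * (k - 1))
    return float(g.probabilities[mask].sum())


def _likelihood_order(g: Gamble, rng: np.random.Generator, trace: list) -> list[int]:
    """Outcome indices ordered from most to least likely; equal
    probabilities are ordered randomly."""
    ps = _read_probs(g, trace)
    trace.extend([Eip.COMPARE] * (len(g) - 1))
    jitter = rng.random(len(ps))
    return sorted(range(len(ps)), key=lambda i: (-ps[i], jitter[i]))


# --- individual rules: each returns (winner index or None, trace grown in place)


def _minimax(p: ChoiceProblem, rng, trace) -> Optional[int]:
    mins = [_scan_extreme(g, trace, largest=False) for g in p.options]
    trace.append(Eip.COMPARE)
    return _argbest(mins, largest=True)


def _maximax(p: ChoiceProblem, rng, trace) -> Optional[int]:
    maxs = [_scan_extreme(g, trace, largest=True) for g in p.options]
    trace.append(Eip.COMPARE)
    return _argbest(maxs, largest=True)


def _least_likely(p: ChoiceProblem, rng, trace) -> Optional[int]:
    probs = []
    for g in p.options:
        _scan_extreme(g, trace, largest=False)  # identify the worst outcome
        probs.append(_prob_of_extreme(g, trace, largest=False))
    trace.append(Eip.COMPARE)
    return _argbest(probs, largest=False)


def _most_likely(p: ChoiceProblem, rng, trace) -> Optional[int]:
    payoffs = []
    for g in p.options:
        order = _likelihood_order(g, rng, trace)
        trace.append(Eip.READ)
        payoffs.append(float(g.payoffs[order[0]]))
    trace.append(Eip.COMPARE)
    return _argbest(payoffs, largest=True)


def _better_than_average(p: ChoiceProblem, rng, trace) -> Optional[int]:
    all_payoffs = np.concatenate([_read_payoffs(g, trace) for g in p.options])
    trace.extend([Eip.ADD] * (len(all_payoffs) - 1))
    trace.append(Eip.PRODUCT)  # division by the number of outcomes
    grand_avg = float(all_payoffs.mean())
    counts = []
    for g in p.options:
        trace.extend([Eip.COMPARE] * len(g))
        counts.append(int((g.payoffs >= grand_avg).sum()))
    trace.append(Eip.COMPARE)
    return _argbest(counts, largest=True)


def _equal_weight(p: ChoiceProblem, rng, trace) -> Optional[int]:
    sums = []
    for g in p.options:
        xs = _read_payoffs(g, trace)
        trace.extend([Eip.ADD] * (len(g) - 1))
        sums.append(float(xs.sum()))
    trace.append(Eip.COMPARE)
    return _argbest(sums, largest=True)


def _tally(p: ChoiceProblem, rng, trace) -> Optional[int]:
    # On signed payoffs the gain and loss formulations coincide: award a
    # mark for the higher minimum, the higher maximum, the lower
    # probability of the minimum, and the higher probability of the maximum.
    feats = []
    for g in p.options:
        xs = _read_payoffs(g, trace)
        trace.extend([Eip.COMPARE] * (len(g) - 1))
        lo, hi = float(xs.min()), float(xs.max())
        p_lo = _prob_of_extreme(g, trace, largest=False)
        p_hi = _prob_of_extreme(g, trace, largest=True)
        feats.append((lo, hi, p_lo, p_hi))
    tallies = [0, 0]
    criteria = [
        ([f[0] for f in feats], True),  # higher minimum
        ([f[1] for f in feats], True),  # higher maximum
        ([f[2] for f in feats], False),  # lower probability of minimum
        ([f[3] for f in feats], True),  # higher probability of maximum
    ]
    for values, largest in criteria:
        trace.append(Eip.COMPARE)
        w = _argbest(values, largest=largest)
        if w is not None:
            trace.append(Eip.ADD)
            tallies[w] += 1
    trace.append(Eip.COMPARE)
    return _argbest(tallies, largest=True)


def _probable(p: ChoiceProblem, rng, trace) -> Optional[int]:
    means = []
    for g in p.options:
        ps = _read_probs(g, trace)
        trace.extend([Eip.COMPARE] * len(g))  # categorize each as (im)probable
        probable = ps >= 0.5
        trace.extend([Eip.ELIMINATE] * int((~probable).sum()))
        k = int(probable.sum())
        if k == 0:
            # every outcome cancelled: nothing to average, value defaults to 0
            means.append(0.0)
            continue
        trace.extend([Eip.READ] * k)
        trace.extend([Eip.ADD] * (k - 1))
        if k > 1:
            trace.append(Eip.PRODUCT)
        means.append(float(g.payoffs[probable].mean()))
    trace.append(Eip.COMPARE)
    return _argbest(means, largest=True)


def _lexicographic(p: ChoiceProblem, rng, trace) -> Optional[int]:
    orders = [_likelihood_order(g, rng, trace) for g in p.options]
    for rank in range(2):  # most likely, then second most likely
        payoffs = []
        for g, order in zip(p.options, orders):
            idx = order[rank] if rank < len(order) else order[-1]
            trace.append(Eip.READ)
            payoffs.append(float(g.payoffs[idx]))
        trace.append(Eip.COMPARE)
        w = _argbest(payoffs, largest=True)
        if w is not None:
            return w
    return None  # still indifferent: random


def _priority_heuristic(p: ChoiceProblem, rng, trace) -> Optional[int]:
    mins = [_scan_extreme(g, trace, largest=False) for g in p.options]
    all_payoffs = np.concatenate([g.payoffs for g in p.options])
    if p.domain is Domain.LOSS:
        aspiration_base = abs(float(all_payoffs.min()))  # absolute maximum loss
    else:
        aspiration_base = float(all_payoffs.max())  # problem-wide maximum gain
    trace.append(Eip.COMPARE)  # locate the extreme payoff
    trace.append(Eip.PRODUCT)  # scale by 1/10
    aspiration = 0.1 * aspiration_base

    trace.append(Eip.DIFFERENCE)
    trace.append(Eip.COMPARE)
    if abs(mins[0] - mins[1]) >= aspiration - _TOL:
        return _argbest(mins, largest=True)

    p_mins = [_prob_of_extreme(g, trace, largest=False) for g in p.options]
    trace.append(Eip.DIFFERENCE)
    trace.append(Eip.COMPARE)
    if abs(p_mins[0] - p_mins[1]) >= 0.1 - _TOL:
        return _argbest(p_mins, largest=False)

    maxs = []
    for g in p.options:
        trace.extend([Eip.COMPARE] * (len(g) - 1))  # payoffs already read
        maxs.append(float(g.payoffs.max()))
    trace.append(Eip.COMPARE)
    return _argbest(maxs, largest=True)


def _weighted_additive(p: ChoiceProblem, rng, trace) -> Optional[int]:
    sums = []
    for g in p.options:
        trace.extend([Eip.READ] * (2 * len(g)))
        trace.extend([Eip.PRODUCT] * len(g))
        trace.extend([Eip.ADD] * (len(g) - 1))
        sums.append(float(np.dot(g.payoffs, g.probabilities)))
    trace.append(Eip.COMPARE)
    return _argbest(sums, largest=True)


_RULES: dict[StrategyId, Callable] = {
    StrategyId.MINI: _minimax,
    StrategyId.MAXI: _maximax,
    StrategyId.LL: _least_likely,
    StrategyId.ML: _most_likely,
    StrategyId.BTA: _better_than_average,
    StrategyId.EQW: _equal_weight,
    StrategyId.TALLY: _tally,
    StrategyId.PROB: _probable,
    StrategyId.LEX: _lexicographic,
    StrategyId.PH: _priority_heuristic,
    StrategyId.WADD: _weighted_additive,
}


def apply_strategy(
    s: StrategyId, p: ChoiceProblem, rng: np.random.Generator
) -> Decision:
    """Execute one strategy on one problem.

    Returns the decision, a tie flag (True when the rule was indifferent
    between the options and the choice was randomized), and the EIP trace
    of the execution.  Identical generator states yield identical
    decisions.
    """
    s = StrategyId(s)
    trace: list[Eip] = []
    winner = _RULES[s](p, rng, trace)
    tie = winner is None
    if tie:
        winner = int(rng.integers(2))
    trace.append(Eip.CHOOSE)
    return Decision(choice="AB"[winner], tie=tie, eip_trace=tuple(trace))


def decision_profile(
    s: StrategyId,
    problems: Sequence[ChoiceProblem],
    reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Monte-Carlo frequency of choosing option A, per problem.

    Strategies without ties yield exactly 0 or 1; tie-prone strategies
    yield sampling frequencies around the tie-break probability.
    """
    if not problems:
        raise ValueError("decision_profile needs at least one problem")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freq = np.zeros(len(problems))
    for _ in range(reps):
        for i, p in enumerate(problems):
            if apply_strategy(s, p, rng).choice == "A":
                freq[i] += 1
    return freq / reps


def risk_profile(
    s: StrategyId,
    problems: Sequence[ChoiceProblem],
    reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Proportion of lower-CV choices made by a strategy, overall and per domain.

    Problems with an undefined risk-aversion indicator (CV tie or zero-EV
    option) are excluded; it is an error if no problem is informative.
    """
    if not problems:
        raise ValueError("risk_profile needs at least one problem")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    hits: dict[str, list[int]] = {d.value: [] for d in Domain}
    for _ in range(reps):
        for p in problems:
            dec = apply_strategy(s, p, rng)
            ind = risk_aversion_indicator(p, dec.choice)
            if ind is not None:
                hits[p.domain.value].append(ind)
    pooled = sum(hits.values(), [])
    if not pooled:
        raise ValueError("risk profile undefined: no problem has distinct CVs")
    out = {"overall": float(np.mean(pooled))}
    for d in Domain:
        out[d.value] = float(np.mean(hits[d.value])) if hits[d.value] else float("nan")
    return out
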