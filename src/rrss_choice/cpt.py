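"""Cumulative prospect theory (CPT) baseline model.

Subjective value of a gamble is a rank-dependent sum of transformed
outcomes.  The conventions used here are the dominant ones in the risky
choice literature and are configurable assumptions, not the only possible
reading of a "six parameter" CPT:

* power value function, split by sign:
  v(x) = x**alpha_gain for x >= 0, v(x) = -lam * (-x)**alpha_loss for x < 0;
* one-parameter inverse-S probability weighting per sign,
  w(p) = p**g / (p**g + (1-p)**g)**(1/g), applied to cumulative
  probabilities (decision weights telescope so that, per sign, they sum to
  the weight of that sign's total probability);
* softmax (logistic) choice with sensitivity theta on the value
  difference.

Fitting follows a two-stage scheme: coarse grid search over [0, 2]^6, then
bounded L-BFGS-B refinement from the best grid points.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .gambles import ChoiceDataset, ChoiceProblem, Gamble

__all__ = [
    "CptParams",
    "cpt_value",
    "cpt_choice_probability",
    "cpt_log_likelihood",
    "fit_cpt",
    "simulate_cpt_choices",
]

PARAM_NAMES = ("alpha_gain", "alpha_loss", "lam", "gamma_gain", "gamma_loss", "theta")
BOUNDS = (0.0, 2.0)


@dataclass(frozen=True)
class CptParams:
    """CPT parameter vector, all bounded to [0, 2] for fitting."""

    alpha_gain: float = 1.0
    alpha_loss: float = 1.0
    lam: float = 1.0
    gamma_gain: float = 1.0
    gamma_loss: float = 1.0
    theta: float = 1.0

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not BOUNDS[0] <= v <= BOUNDS[1]:
                raise ValueError(f"{name}={v} outside bounds {BOUNDS}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, arr) -> "CptParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))

    def as_dict(self) -> dict:
        return asdict(self)


def _weight(p: np.ndarray, gamma: float) -> np.ndarray:
    """Inverse-S probability weighting, stable for small gamma.

    Computed in log space so that the gamma -> 0 limit degenerates to an
    indicator of certainty instead of overflowing.
    """
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    if gamma <= 1e-12:
        return (p >= 1.0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_num = gamma * np.log(p)
        log_den = np.log(p**gamma + (1.0 - p) ** gamma) / gamma
        w = np.exp(log_num - log_den)
    return np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, w))


def _rank_dependent_parts(g: Gamble) -> tuple[np.ndarray, ...]:
    """Sorted payoffs and cumulative probabilities, split by sign.

    Gains (x >= 0) sorted from best down, with P(X >= x_i) inclusive and
    exclusive; losses sorted from worst up, with P(X <= x_j) inclusive and
    exclusive.  Decision weights are differences of weighted cumulatives.
    """
    xs, ps = g.payoffs, g.probabilities
    gains = xs >= 0
    gx, gp = xs[gains], ps[gains]
    order = np.argsort(-gx, kind="stable")
    gx, gp = gx[order], gp[order]
    g_incl = np.cumsum(gp)
    g_excl = g_incl - gp
    lx, lp = -xs[~gains], ps[~gains]
    order = np.argsort(-lx, kind="stable")
    lx, lp = lx[order], lp[order]
    l_incl = np.cumsum(lp)
    l_excl = l_incl - lp
    return gx, g_incl, g_excl, lx, l_incl, l_excl


def cpt_value(g: Gamble, params: CptParams) -> float:
    """Rank-dependent subjective value of a gamble.

    With all transformation parameters at 1 this reduces exactly to the
    expected value.
    """
    gx, g_incl, g_excl, lx, l_incl, l_excl = _rank_dependent_parts(g)
    wg = _weight(g_incl, params.gamma_gain) - _weight(g_excl, params.gamma_gain)
    wl = _weight(l_incl, params.gamma_loss) - _weight(l_excl, params.gamma_loss)
    v_gain = float(np.dot(wg, gx**params.alpha_gain)) if len(gx) else 0.0
    v_loss = float(np.dot(wl, lx**params.alpha_loss)) if len(lx) else 0.0
    return v_gain - params.lam * v_loss


def cpt_choice_probability(p: ChoiceProblem, params: CptParams) -> float:
    """Softmax probability of choosing option A: logistic of theta * (V_A - V_B)."""
    dv = cpt_value(p.option_a, params) - cpt_value(p.option_b, params)
    return float(expit(params.theta * dv))


class _ProblemTensors:
    """Padded per-problem arrays so values vectorize over all gambles."""

    def __init__(self, problems: Sequence[ChoiceProblem]):
        self.problems = list(problems)
        gambles = [g for p in problems for g in (p.option_a, p.option_b)]
        parts = [_rank_dependent_parts(g) for g in gambles]
        mg = max(len(pt[0]) for pt in parts) or 1
        ml = max((len(pt[3]) for pt in parts), default=1) or 1
        n = len(gambles)
        self.gx = np.zeros((n, mg))
        self.g_incl = np.zeros((n, mg))
        self.g_excl = np.zeros((n, mg))
        self.gmask = np.zeros((n, mg))
        self.lx = np.zeros((n, ml))
        self.l_incl = np.zeros((n, ml))
        self.l_excl = np.zeros((n, ml))
        self.lmask = np.zeros((n, ml))
        for i, (gx, gi, ge, lx, li, le) in enumerate(parts):
            self.gx[i, : len(gx)] = gx
            self.g_incl[i, : len(gx)] = gi
            self.g_excl[i, : len(gx)] = ge
            self.gmask[i, : len(gx)] = 1.0
            self.lx[i, : len(lx)] = lx
            self.l_incl[i, : len(lx)] = li
            self.l_excl[i, : len(lx)] = le
            self.lmask[i, : len(lx)] = 1.0

    def values(self, params: CptParams) -> np.ndarray:
        """Subjective values of all gambles (A then B, interleaved)."""
        wg = (
            _weight(self.g_incl, params.gamma_gain)
            - _weight(self.g_excl, params.gamma_gain)
        ) * self.gmask
        wl = (
            _weight(self.l_incl, params.gamma_loss)
            - _weight(self.l_excl, params.gamma_loss)
        ) * self.lmask
        with np.errstate(invalid="ignore"):
            vx = np.where(self.gmask > 0, self.gx**params.alpha_gain, 0.0)
            lxp = np.where(self.lmask > 0, self.lx**params.alpha_loss, 0.0)
        return (wg * vx).sum(axis=1) - params.lam * (wl * lxp).sum(axis=1)

    def value_diffs(self, params: CptParams) -> np.ndarray:
        v = self.values(params)
        return v[0::2] - v[1::2]


def cpt_log_likelihood(
    data: pd.DataFrame,
    params: CptParams,
    problems: Sequence[ChoiceProblem],
    tensors: Optional[_ProblemTensors] = None,
) -> float:
    """Summed log-probability of one participant's observed choices."""
    if len(data) == 0:
        raise ValueError("no choice records")
    by_id = {p.id: i for i, p in enumerate(problems)}
    tensors = tensors or _ProblemTensors(problems)
    dv = tensors.value_diffs(params)
    idx = np.array([by_id[str(pid)] for pid in data["problem_id"]])
    sign = np.where(np.asarray(data["choice"]) == "A", 1.0, -1.0)
    return float(log_expit(sign * params.theta * dv[idx]).sum())


def fit_cpt(
    data: pd.DataFrame,
    problems: Sequence[ChoiceProblem],
    grid_steps: int = 15,
    n_starts: int = 30,
) -> tuple[CptParams, float, dict]:
    """Maximum-likelihood CPT fit for one participant.

    Stage 1 evaluates the log-likelihood on a ``grid_steps``-per-dimension
    grid over [0, 2]^6 (factorized so the sweep stays tractable); stage 2
    refines the ``n_starts`` best grid points with bounded L-BFGS-B and
    returns the best refined optimum, its log-likelihood, and fitting
    diagnostics.
    """
    if len(data) == 0:
        raise ValueError("no choice records to fit")
    tensors = _ProblemTensors(problems)
    by_id = {p.id: i for i, p in enumerate(problems)}
    idx = np.array([by_id[str(pid)] for pid in data["problem_id"]])
    sign = np.where(np.asarray(data["choice"]) == "A", 1.0, -1.0)

    axis = np.linspace(BOUNDS[0], BOUNDS[1], grid_steps)
    starts = _best_grid_starts(tensors, idx, sign, axis, n_starts)

    def neg_ll(x: np.ndarray) -> float:
        return -cpt_log_likelihood(
            data, CptParams.from_array(np.clip(x, *BOUNDS)), problems, tensors
        )

    best = None
    n_ok = 0
    messages = []
    for x0, grid_ll in starts:
        res = minimize(
            neg_ll, x0, method="L-BFGS-B", bounds=[BOUNDS] * 6
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
        else:
            messages.append(str(res.message))
    if best is None:
        raise RuntimeError(f"all {len(starts)} CPT starts failed: {messages}")
    params = CptParams.from_array(np.clip(best.x, *BOUNDS))
    diagnostics = {
        "n_starts": len(starts),
        "n_successful": n_ok,
        "best_grid_ll": float(max(s[1] for s in starts)),
        "grid_steps": grid_steps,
    }
    return params, float(-best.fun), diagnostics


def _best_grid_starts(
    tensors: _ProblemTensors,
    idx: np.ndarray,
    sign: np.ndarray,
    axis: np.ndarray,
    n_starts: int,
) -> list[tuple[np.ndarray, float]]:
    """Top grid points by log-likelihood, as (parameter vector, LL) pairs."""
    steps = len(axis)
    n = tensors.gx.shape[0]
    G = np.empty((steps, steps, n))
    L = np.empty((steps, steps, n))
    for gi, gamma in enumerate(axis):
        wg = (_weight(tensors.g_incl, gamma) - _weight(tensors.g_excl, gamma)) * tensors.gmask
        wl = (_weight(tensors.l_incl, gamma) - _weight(tensors.l_excl, gamma)) * tensors.lmask
        for ai, alpha in enumerate(axis):
            with np.errstate(invalid="ignore"):
                gx = np.where(tensors.gmask > 0, tensors.gx**alpha, 0.0)
                lx = np.where(tensors.lmask > 0, tensors.lx**alpha, 0.0)
            G[gi, ai] = (wg * gx).sum(axis=1)
            L[gi, ai] = (wl * lx).sum(axis=1)
    # value differences per trial for every (gamma, alpha) pair, by sign part
    dG = (G[:, :, 0::2] - G[:, :, 1::2]).reshape(steps * steps, -1)[:, idx]
    dL = (L[:, :, 0::2] - L[:, :, 1::2]).reshape(steps * steps, -1)[:, idx]

    # running top-k across the (lam, theta, gain-combo, loss-combo) sweep
    top: list[tuple[float, tuple]] = []
    for li, lam in enumerate(axis):
        dv = dG[:, None, :] - lam * dL[None, :, :]  # (gain-combo, loss-combo, trial)
        for ti, theta in enumerate(axis):
            ll = log_expit(sign[None, None, :] * theta * dv).sum(axis=2)
            flat = ll.ravel()
            k = min(n_starts, flat.size)
            best_idx = np.argpartition(-flat, k - 1)[:k]
            for j in best_idx:
                # decode: first axis indexes (gamma+, alpha+), second (gamma-, alpha-)
                gc, lc = divmod(int(j), steps * steps)
                gpi, api = divmod(gc, steps)
                gmi, ami = divmod(lc, steps)
                vec = (
                    float(axis[api]),  # alpha_gain
                    float(axis[ami]),  # alpha_loss
                    float(lam),
                    float(axis[gpi]),  # gamma_gain
                    float(axis[gmi]),  # gamma_loss
                    float(theta),
                )
                item = (float(flat[j]), vec)
                if len(top) < n_starts:
                    heapq.heappush(top, item)
                elif item[0] > top[0][0]:
                    heapq.heapreplace(top, item)
    top.sort(reverse=True)
    return [(np.array(vec), ll) for ll, vec in top]


def simulate_cpt_choices(
    params: CptParams,
    problems: Sequence[ChoiceProblem],
    seed: int | np.random.Generator = 0,
    participant_id: str = "cpt_sim",
    age_group: str = "unspecified",
) -> ChoiceDataset:
    """Draw one synthetic participant's choices from the CPT model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for p in problems:
        pa = cpt_choice_probability(p, params)
        rows.append(
            {
                "participant_id": participant_id,
                "age_group": age_group,
                "problem_id": p.id,
                "choice": "A" if rng.random() < pa else "B",
            }
        )
    return ChoiceDataset(pd.DataFrame(rows))
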