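"""Independent re-implementations of the eleven choice heuristics.

Written directly from the verbal rule descriptions, in plain Python and
without any trace bookkeeping, to serve as an oracle for the main
implementations.  Each oracle returns the *set* of outcomes the rule can
produce: usually a single element ('A', 'B', or 'tie'); where a rule's
intermediate step is itself ambiguous (which outcome counts as "most
likely" in a 50/50 gamble) every resolution is enumerated and the union
of outcomes is returned.

A 1e-9 tolerance is used for the priority heuristic's aspiration
comparisons to guard against float rounding of the 1/10 scaling; all
other comparisons are exact.
"""

from itertools import permutations, product

_TOL = 1e-9


def _xs(g):
    return [x for x, _ in g.outcomes]


def _ps(g):
    return [p for _, p in g.outcomes]


def _cmp(va, vb, higher=True):
    if va == vb:
        return "tie"
    if higher:
        return "A" if va > vb else "B"
    return "A" if va < vb else "B"


def _prob_of(g, value):
    return sum(p for x, p in g.outcomes if x == value)


def _likelihood_orders(g):
    """All orderings of outcome indices by descending probability,
    enumerating permutations of equally likely outcomes."""
    ps = _ps(g)
    idx = sorted(range(len(ps)), key=lambda i: -ps[i])
    groups = []
    for i in idx:
        if groups and ps[groups[-1][0]] == ps[i]:
            groups[-1].append(i)
        else:
            groups.append([i])
    orders = []
    for perm_groups in product(*[list(permutations(gr)) for gr in groups]):
        order = [i for gr in perm_groups for i in gr]
        orders.append(order)
    return orders


def minimax(p):
    return {_cmp(min(_xs(p.option_a)), min(_xs(p.option_b)))}


def maximax(p):
    return {_cmp(max(_xs(p.option_a)), max(_xs(p.option_b)))}


def least_likely(p):
    pa = _prob_of(p.option_a, min(_xs(p.option_a)))
    pb = _prob_of(p.option_b, min(_xs(p.option_b)))
    return {_cmp(pa, pb, higher=False)}


def most_likely(p):
    out = set()
    for oa in _likelihood_orders(p.option_a):
        for ob in _likelihood_orders(p.option_b):
            va = _xs(p.option_a)[oa[0]]
            vb = _xs(p.option_b)[ob[0]]
            out.add(_cmp(va, vb))
    return out


def better_than_average(p):
    allx = _xs(p.option_a) + _xs(p.option_b)
    grand = sum(allx) / len(allx)
    ca = sum(1 for x in _xs(p.option_a) if x >= grand)
    cb = sum(1 for x in _xs(p.option_b) if x >= grand)
    return {_cmp(ca, cb)}


def equal_weight(p):
    return {_cmp(sum(_xs(p.option_a)), sum(_xs(p.option_b)))}


def tallying(p):
    a, b = p.option_a, p.option_b
    if p.domain.value == "loss":
        # work on loss magnitudes: a mark for the lower minimum loss, the
        # lower maximum loss, the higher probability of the minimum loss,
        # and the lower probability of the maximum loss
        la, lb = [-x for x in _xs(a)], [-x for x in _xs(b)]
        marks = [
            _cmp(min(la), min(lb), higher=False),
            _cmp(max(la), max(lb), higher=False),
            _cmp(_prob_of(a, -min(la)), _prob_of(b, -min(lb)), higher=True),
            _cmp(_prob_of(a, -max(la)), _prob_of(b, -max(lb)), higher=False),
        ]
    else:
        marks = [
            _cmp(min(_xs(a)), min(_xs(b)), higher=True),
            _cmp(max(_xs(a)), max(_xs(b)), higher=True),
            _cmp(_prob_of(a, min(_xs(a))), _prob_of(b, min(_xs(b))), higher=False),
            _cmp(_prob_of(a, max(_xs(a))), _prob_of(b, max(_xs(b))), higher=True),
        ]
    ta = sum(1 for m in marks if m == "A")
    tb = sum(1 for m in marks if m == "B")
    return {_cmp(ta, tb)}


def probable(p):
    def mean_probable(g):
        vals = [x for x, pr in g.outcomes if pr >= 0.5]
        return sum(vals) / len(vals) if vals else 0.0

    return {_cmp(mean_probable(p.option_a), mean_probable(p.option_b))}


def lexicographic(p):
    out = set()
    for oa in _likelihood_orders(p.option_a):
        for ob in _likelihood_orders(p.option_b):
            xa, xb = _xs(p.option_a), _xs(p.option_b)
            r = _cmp(xa[oa[0]], xb[ob[0]])
            if r == "tie":
                ia = oa[1] if len(oa) > 1 else oa[-1]
                ib = ob[1] if len(ob) > 1 else ob[-1]
                r = _cmp(xa[ia], xb[ib])
            out.add(r)
    return out


def priority_heuristic(p):
    a, b = p.option_a, p.option_b
    min_a, min_b = min(_xs(a)), min(_xs(b))
    allx = _xs(a) + _xs(b)
    base = -min(allx) if p.domain.value == "loss" else max(allx)
    aspiration = 0.1 * base
    if abs(min_a - min_b) >= aspiration - _TOL:
        return {_cmp(min_a, min_b)}
    pa, pb = _prob_of(a, min_a), _prob_of(b, min_b)
    if abs(pa - pb) >= 0.1 - _TOL:
        return {_cmp(pa, pb, higher=False)}
    return {_cmp(max(_xs(a)), max(_xs(b)))}


def weighted_additive(p):
    wa = sum(x * pr for x, pr in p.option_a.outcomes)
    wb = sum(x * pr for x, pr in p.option_b.outcomes)
    return {_cmp(wa, wb)}


def enumerate_grid_ll(data, problems, stats, grid):
    """Brute-force grid enumeration of the strategy-selection model.

    Independent of the fitting code: nested loops over every toolbox
    combination, delta and epsilon, selecting the argmax-scoring strategy
    per problem and summing trial log-probabilities directly.  Assumes a
    tie-free setting (deterministic strategies, no expected score ties
    that change predictions), which the calling test arranges.

    Returns a dict mapping (toolbox tuple, delta, epsilon) -> log-likelihood.
    """
    import math
    from itertools import combinations

    import numpy as np

    from rrss_choice import apply_strategy

    by_id = {p.id: p for p in problems}
    trials = [(by_id[str(r.problem_id)], r.choice) for r in data.itertuples()]
    rng = np.random.default_rng(0)
    # per strategy, the (deterministic) choice on each problem
    choice = {}
    for s in grid.candidates:
        for p in problems:
            dec = apply_strategy(s, p, rng)
            assert not dec.tie, "oracle requires tie-free strategies"
            choice[(s, p.id)] = dec.choice
    out = {}
    for size in grid.toolbox_sizes:
        for combo in combinations(grid.candidates, size):
            for delta in grid.deltas:
                sel = {}
                for p in problems:
                    scores = [stats.r(s, p.id) - delta * stats.c(s, p.id) for s in combo]
                    sel[p.id] = combo[int(np.argmax(scores))]
                for eps in grid.epsilons:
                    ll = 0.0
                    for p, obs in trials:
                        p_obs = 1.0 if choice[(sel[p.id], p.id)] == obs else 0.0
                        ll += math.log(eps + p_obs * (1.0 - 2.0 * eps))
                    out[(combo, delta, eps)] = ll
    return out


ORACLES = {
    "MINI": minimax,
    "MAXI": maximax,
    "LL": least_likely,
    "ML": most_likely,
    "BTA": better_than_average,
    "EQW": equal_weight,
    "TALLY": tallying,
    "PROB": probable,
    "LEX": lexicographic,
    "PH": priority_heuristic,
    "WADD": weighted_additive,
}
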