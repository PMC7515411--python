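"""Independent brute-force oracles: direct state-sums over the joint table.

These deliberately avoid the library's inclusion-exclusion-over-cached-
entropies route; every quantity is evaluated term by term from the atomic
probabilities, so agreement is a genuine cross-check.
"""

from itertools import combinations, permutations

import numpy as np


def state_sum_entropy(joint, subset):
    """H(S) by explicit summation over the states of the S-marginal."""
    marg = joint.marginal(subset)
    total = 0.0
    for _, p in marg.states():
        if p > 0:
            total -= p * np.log2(p)
    return total


def state_sum_information(joint, subset):
    """I(S) as the single state-sum of the log odd/even marginal ratio."""
    subset = tuple(sorted(subset))
    marginals = {
        T: joint.marginal(T) for size in range(1, len(subset) + 1)
        for T in combinations(subset, size)
    }
    full = marginals[subset]
    axes = {i: full.axis_of(i) for i in subset}
    total = 0.0
    for state, p in full.states():
        if p == 0:
            continue
        log_ratio = 0.0
        for T, marg in marginals.items():
            sub_state = tuple(state[axes[i]] for i in T)
            pT = marg.probs[sub_state]
            sign = 1.0 if len(T) % 2 == 1 else -1.0
            log_ratio += sign * np.log2(pT)
        total -= p * log_ratio
    return total


def conditioned_information(joint, subset, given):
    """B.I(A) as the expectation over B of I(A) under each conditional law."""
    from infosimplex.distributions import JointDistribution

    subset = tuple(sorted(subset))
    given = tuple(sorted(given))
    if not given:
        return state_sum_information(joint, subset)
    both = joint.marginal(subset + given)
    g_axes = tuple(both.axis_of(i) for i in given)
    s_axes = tuple(both.axis_of(i) for i in subset)
    g_marg = both.probs.sum(axis=s_axes) if s_axes else both.probs
    total = 0.0
    it = np.nditer(g_marg, flags=["multi_index"])
    for pg in it:
        pg = float(pg)
        if pg == 0:
            continue
        sl = [slice(None)] * both.probs.ndim
        for ax, val in zip(g_axes, it.multi_index):
            sl[ax] = val
        cond = np.asarray(both.probs[tuple(sl)]) / pg
        sub_vars = tuple(both.variables[a] for a in sorted(s_axes))
        cond_joint = JointDistribution(sub_vars, cond, _validate=False)
        total += pg * state_sum_information(cond_joint, subset)
    return total


def exhaustive_positive_facets(joint, indices, tol=1e-10):
    """Maximal positive-path variable sets by checking all permutations."""
    from infosimplex.infometrics import mutual_information

    maximal = set()
    for k in range(1, len(indices) + 1):
        for order in permutations(indices, k):
            profile = [
                mutual_information(joint, order[: j + 1]) for j in range(k)
            ]
            if any(
                profile[j + 1] >= profile[j] - tol for j in range(k - 1)
            ):
                continue  # not strictly decreasing: not a positive path
            extendable = False
            for x in indices:
                if x in order:
                    continue
                nxt = mutual_information(joint, tuple(order) + (x,))
                if nxt < profile[-1] - tol:
                    extendable = True
                    break
            if not extendable:
                maximal.add(frozenset(order))
    facets = [
        S for S in maximal if not any(S < T for T in maximal)
    ]
    return sorted(tuple(sorted(S)) for S in facets)
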