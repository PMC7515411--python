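"""Scalar information functions in bits, plus the internal/free energy split.

Every function follows the bit convention (base-2 logarithms, equivalently the
multiplicative constant -1/ln 2 on natural logs) and the limit 0*log 0 := 0.
Multivariate mutual information I_k (co-information) is computed by
inclusion-exclusion over cached subset entropies; the direct state-sum remains
available as an independent oracle in the test suite.

Functions taking ``source`` accept either a :class:`JointDistribution` or any
object exposing an ``entropy(subset)`` method over sorted 1-based index tuples
(e.g., a computed :class:`~infosimplex.lattice.SimplicialInfoStructure`), so
lattice-wide computations reuse cached entropies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from .distributions import JointDistribution

#: Absolute tolerance for comparisons against zero on values in bits.
ZERO_TOL = 1e-10

__all__ = [
    "EnergyDecomposition",
    "EnergyTable",
    "entropy",
    "kl_divergence",
    "mutual_information",
    "total_correlation",
    "conditional_entropy",
    "conditional_mutual_information",
    "pseudo_volume",
    "elementary_energies",
    "energy_decomposition",
    "information_rate",
    "subset_entropy",
]


@dataclass(frozen=True)
class EnergyDecomposition:
    """Internal energy U, total free energy G and joint entropy H (bits).

    The decomposition satisfies the isotherm relation ``H = U - G``; G equals
    the total correlation and is therefore non-negative.
    """

    U: float
    G: float
    H: float


@dataclass(frozen=True)
class EnergyTable:
    """Elementary (per-state) energies in bits.

    ``energies[state] = -sum_j log2 p_j(state_j)`` over the single-variable
    marginals.  States with a zero marginal get ``+inf`` and are listed in
    ``flagged``; such states necessarily carry zero joint probability, so the
    0*log 0 convention keeps every expectation finite.
    """

    energies: np.ndarray
    variables: tuple
    flagged: tuple[tuple[int, ...], ...] = ()


# ---------------------------------------------------------------------------
# Entropy and divergence


def _plogp_sum(arr: np.ndarray) -> float:
    p = arr[arr > 0.0]
    return float(-(p * np.log2(p)).sum())


def entropy(joint: JointDistribution) -> float:
    """Shannon joint entropy -sum p log2 p in bits."""
    return _plogp_sum(joint.probs)


def subset_entropy(source, subset: Iterable[int]) -> float:
    """Entropy of the marginal on ``subset``, from a joint or a cached structure."""
    key = tuple(sorted(subset))
    if not key:
        return 0.0
    if isinstance(source, JointDistribution):
        return entropy(source.marginal(key))
    return float(source.entropy(key))


def kl_divergence(p: JointDistribution, q: JointDistribution) -> float:
    """Kullback-Leibler divergence D(p||q) in bits; +inf if q's support misses p's."""
    if p.indices != q.indices:
        raise ValueError("distributions must share the same ordered variable set")
    if p.probs.shape != q.probs.shape:
        raise ValueError("alphabet mismatch")
    pa, qa = p.probs.ravel(), q.probs.ravel()
    mask = pa > 0.0
    if np.any(qa[mask] == 0.0):
        return math.inf
    return float((pa[mask] * np.log2(pa[mask] / qa[mask])).sum())


# ---------------------------------------------------------------------------
# Multivariate informations (inclusion-exclusion)


def mutual_information(source, subset: Iterable[int]) -> float:
    """k-mutual information (co-information) of a variable subset, in bits.

    I_1 = H_1; the empty subset gives 0 (lattice identity).  Computed as the
    alternating inclusion-exclusion sum of subset entropies; may be negative
    for k >= 3 (synergy).
    """
    key = tuple(sorted(subset))
    if not key:
        return 0.0
    total = 0.0
    for size in range(1, len(key) + 1):
        sign = 1.0 if size % 2 == 1 else -1.0
        for T in combinations(key, size):
            total += sign * subset_entropy(source, T)
    return total


def total_correlation(source, subset: Iterable[int]) -> float:
    """Total correlation (multi-information) sum_i H(X_i) - H(joint) >= 0."""
    key = tuple(sorted(subset))
    if len(key) < 2:
        raise ValueError("total correlation needs at least two variables")
    singles = sum(subset_entropy(source, (i,)) for i in key)
    return singles - subset_entropy(source, key)


def conditional_entropy(
    source, target: Iterable[int], given: Iterable[int] = ()
) -> float:
    """H(A | B) = H(A,B) - H(B) in bits; B empty gives H(A)."""
    A = tuple(sorted(target))
    B = tuple(sorted(given))
    if set(A) & set(B):
        raise IndexError("target and conditioning subsets must be disjoint")
    return subset_entropy(source, A + B) - subset_entropy(source, B)


def conditional_mutual_information(
    source, subset: Iterable[int], given: Iterable[int] = ()
) -> float:
    """Conditional co-information B.I(A) in bits.

    Expanded over entropies: I(A|B) = sum_{T subset A, T nonempty}
    (-1)^(|T|-1) H(T,B) - H(B).  Non-negative for |A| = 2; may be negative for
    |A| >= 3 (Matsuda's characterization of information negativity).
    """
    A = tuple(sorted(subset))
    B = tuple(sorted(given))
    if set(A) & set(B):
        raise IndexError("subset and conditioning set must be disjoint")
    if not A:
        return 0.0
    total = 0.0
    for size in range(1, len(A) + 1):
        sign = 1.0 if size % 2 == 1 else -1.0
        for T in combinations(A, size):
            total += sign * subset_entropy(source, tuple(sorted(T + B)))
    return total - subset_entropy(source, B)


def pseudo_volume(source, subset: Iterable[int]) -> float:
    """Pseudo k-volume V_k = H_k - I_k (bits); V_2 is Shannon's pseudo-metric."""
    key = tuple(sorted(subset))
    return subset_entropy(source, key) - mutual_information(source, key)


# ---------------------------------------------------------------------------
# Energies


def elementary_energies(joint: JointDistribution) -> EnergyTable:
    """Per-state extensive energies E(state) = -sum_j log2 p_j(state_j), in bits.

    The unique energy assignment additive over independent coordinates.  The
    expectation of E under the joint equals the internal energy U.
    """
    n = joint.n
    with np.errstate(divide="ignore"):
        logs = []
        for axis in range(n):
            other = tuple(a for a in range(n) if a != axis)
            marg = joint.probs.sum(axis=other) if other else joint.probs
            l = -np.log2(marg)
            shape = [1] * n
            shape[axis] = -1
            logs.append(l.reshape(shape))
    E = np.zeros(joint.probs.shape)
    for l in logs:
        E = E + l
    flagged = tuple(map(tuple, np.argwhere(~np.isfinite(E))))
    return EnergyTable(E, joint.variables, flagged)


def energy_decomposition(source, subset: Iterable[int] | None = None) -> EnergyDecomposition:
    """Split the joint entropy as H = U - G (internal minus total free energy).

    U is the sum of marginal entropies (self-information); G is the
    alternating sum of k-informations for k >= 2, identically equal to the
    total correlation.
    """
    if subset is None:
        if isinstance(source, JointDistribution):
            subset = source.indices
        else:
            subset = source.subset_indices()
    key = tuple(sorted(subset))
    U = sum(subset_entropy(source, (i,)) for i in key)
    H = subset_entropy(source, key)
    return EnergyDecomposition(U=U, G=U - H, H=H)


def information_rate(Hk: float, k: int) -> float:
    """Finite information rate r = H_k / k, bits per variable."""
    if k < 1:
        raise ValueError("degree k must be >= 1")
    return Hk / k
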