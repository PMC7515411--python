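"""Generators of joint distributions and sample matrices with known structure.

Every generator returns an explicit :class:`JointDistribution` whose
information quantities are known in closed form, so estimation, lattice and
path code can be exercised without any external data:

* independent product laws (all co-informations of degree >= 2 vanish),
* fully redundant copies (H_k = I_k = H_1 at every degree),
* the three-bit parity ("Borromean") configuration — pairwise independent
  uniform binary variables bound by an XOR constraint, the canonical
  I_3 = -1 bit synergy example,
* strictly positive Dirichlet-random laws for fuzzing algebraic identities,

plus a tensor-product composer for planting several independent blocks and a
seeded sampler closing the loop data -> plug-in estimate -> measures.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .distributions import DataMatrix, JointDistribution, Variable

__all__ = [
    "gen_independent",
    "gen_redundant",
    "gen_borromean",
    "gen_random_dirichlet",
    "block_product",
    "sample_matrix",
]


def _check_marginal(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("marginal must be a 1-d probability vector")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("marginal entries must be non-negative and sum to 1")
    return p


def gen_independent(
    n: int,
    cardinality: int = 2,
    marginal: Sequence[float] | None = None,
    seed: int | None = None,
) -> JointDistribution:
    """Product law of n iid variables; uniform marginals unless given.

    With ``seed`` set and no explicit marginal, a random marginal is drawn
    once and shared by all variables.
    """
    if marginal is None:
        if seed is None:
            marginal = np.full(cardinality, 1.0 / cardinality)
        else:
            rng = np.random.default_rng(seed)
            marginal = rng.dirichlet(np.ones(cardinality))
    p = _check_marginal(marginal)
    probs = p
    for _ in range(n - 1):
        probs = np.multiply.outer(probs, p)
    variables = tuple(Variable(j + 1, p.size) for j in range(n))
    return JointDistribution(variables, probs.reshape([p.size] * n))


def gen_redundant(n: int, marginal: Sequence[float] | None = None) -> JointDistribution:
    """n fully redundant variables: all equal with probability 1.

    Mass sits on the diagonal states only, so every subset of every degree
    carries the same entropy H_1 and the same information I_k = H_1.
    """
    if marginal is None:
        marginal = (0.5, 0.5)
    p = _check_marginal(marginal)
    card = p.size
    probs = np.zeros([card] * n)
    for x in range(card):
        probs[(x,) * n] = p[x]
    variables = tuple(Variable(j + 1, card) for j in range(n))
    return JointDistribution(variables, probs)


def gen_borromean() -> JointDistribution:
    """Three binary variables, probability 1/4 on {000, 011, 101, 110}.

    Uniform marginals, every pair independent, yet X3 = X1 XOR X2: the
    three-way information is -1 bit while the total correlation is +1 bit.
    """
    probs = np.zeros((2, 2, 2))
    for state in [(0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 0)]:
        probs[state] = 0.25
    variables = tuple(Variable(j + 1, 2) for j in range(3))
    return JointDistribution(variables, probs)


def gen_random_dirichlet(
    n: int,
    cardinality: int = 2,
    concentration: float = 1.0,
    seed: int | None = None,
) -> JointDistribution:
    """Strictly positive random joint law: Dirichlet over all joint states."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    size = cardinality**n
    flat = rng.dirichlet(np.full(size, concentration))
    variables = tuple(Variable(j + 1, cardinality) for j in range(n))
    return JointDistribution(variables, flat.reshape([cardinality] * n))


def block_product(blocks: Iterable[JointDistribution]) -> JointDistribution:
    """Tensor product of independent blocks, variables renumbered 1..total.

    Plants several modules side by side: information within each block is
    preserved and every cross-block information of degree >= 2 is zero.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("need at least one block")
    probs = blocks[0].probs
    variables = list(blocks[0].variables)
    for b in blocks[1:]:
        probs = np.multiply.outer(probs, b.probs)
        variables.extend(b.variables)
    renumbered = tuple(
        Variable(j + 1, v.cardinality, v.name) for j, v in enumerate(variables)
    )
    return JointDistribution(renumbered, probs)


def sample_matrix(joint: JointDistribution, m: int, seed: int | None = None) -> DataMatrix:
    """m iid draws from the joint, as an integer-coded samples x variables matrix."""
    if m < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    flat = joint.probs.ravel()
    draws = rng.choice(flat.size, size=m, p=flat)
    codes = np.column_stack(np.unravel_index(draws, joint.probs.shape))
    return DataMatrix(codes, joint.variables)
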