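"""Hochschild-type coboundary operators on information cochains.

A degree-k cochain of the standard information family evaluates k groups of
variables (each group acting as one joint variable) to their co-information
I_k, with the conditioning action Y.F given by conditional mutual information.
Three coboundary operators act on these cochains, differing in how the first
and last arguments act: the *left* operator conditions on the first argument,
the *trivial* (topological) operator drops the action, and the *symmetric*
operator conditions on both ends.  In low degrees their values reproduce the
information functions themselves — mutual information is a topological
1-coboundary, -I3 a left 2-coboundary, I4 a topological 3-coboundary — and
their cocycle conditions encode the chain rule and statistical independence.

Every cochain value here is a finite linear combination of subset entropies
with integer coefficients.  Evaluation therefore happens in two layers: an
exact layer manipulating the integer coefficient vectors (where the identities
cancel exactly, independent of floating point), and a numeric layer summing
coefficient x entropy for a concrete distribution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Sequence

from .distributions import JointDistribution
from .infometrics import subset_entropy

__all__ = [
    "Cochain",
    "IdentityCheck",
    "mi_coefficients",
    "coboundary_coefficients",
    "coboundary",
    "verify_identities",
]

Group = tuple[int, ...]


def _strip(c: Counter) -> Counter:
    """Drop zero coefficients (Counter's unary + would drop negatives too)."""
    return Counter({k: v for k, v in c.items() if v != 0})


def _as_groups(args: Iterable) -> tuple[Group, ...]:
    groups = tuple(
        tuple(sorted(g)) if isinstance(g, (tuple, list, set, frozenset)) else (int(g),)
        for g in args
    )
    seen: set[int] = set()
    for g in groups:
        if seen & set(g):
            raise ValueError(f"variable groups overlap: {groups}")
        seen |= set(g)
    return groups


def mi_coefficients(groups: Iterable, cond: Iterable[int] = ()) -> Counter:
    """Entropy-coefficient vector of I(G1;...;Gk | cond).

    Inclusion-exclusion over non-empty group subsets:
    I = sum_T (-1)^(|T|-1) H(union T, cond) - H(cond).
    """
    groups = _as_groups(groups)
    cond = tuple(sorted(cond))
    c: Counter = Counter()
    if not groups:
        return c
    k = len(groups)
    for size in range(1, k + 1):
        sign = 1 if size % 2 == 1 else -1
        for T in combinations(groups, size):
            key = tuple(sorted(set().union(*map(set, T)) | set(cond)))
            c[key] += sign
    if cond:
        c[cond] -= 1
    return _strip(c)


def coboundary_coefficients(action: str, args: Iterable) -> Counter:
    """Coefficient vector of the degree-k coboundary applied to the I-cochain.

    ``args`` holds k+1 variable groups.  The operator is the alternating sum
    of the face maps: the first face conditions (left / symmetric) or not
    (trivial); the inner faces join adjacent arguments; the last face
    conditions only under the symmetric action.
    """
    if action not in ("left", "trivial", "symmetric"):
        raise ValueError("action must be 'left', 'trivial' or 'symmetric'")
    args = _as_groups(args)
    if len(args) < 2:
        raise ValueError("coboundary needs at least two arguments")
    k = len(args) - 1
    total: Counter = Counter()

    if action == "trivial":
        first = mi_coefficients(args[1:])
    else:
        first = mi_coefficients(args[1:], cond=args[0])
    total.update(first)

    for i in range(1, k + 1):  # join args[i-1] and args[i] (1-based faces)
        joined = args[: i - 1] + (tuple(sorted(args[i - 1] + args[i])),) + args[i + 1:]
        sign = -1 if i % 2 == 1 else 1
        for key, coef in mi_coefficients(joined).items():
            total[key] += sign * coef

    if action == "symmetric":
        last = mi_coefficients(args[:-1], cond=args[-1])
    else:
        last = mi_coefficients(args[:-1])
    sign = -1 if (k + 1) % 2 == 1 else 1
    for key, coef in last.items():
        total[key] += sign * coef
    return _strip(total)


def _evaluate(coeffs: Counter, joint: JointDistribution) -> float:
    return sum(coef * subset_entropy(joint, key) for key, coef in coeffs.items())


class Cochain:
    """The standard information cochain family over one joint distribution.

    ``F(groups)`` is the co-information of the groups (each group one joint
    variable); ``F(groups, cond=Y)`` applies the conditioning action.  The
    evaluation is symmetric in the groups and vanishes on the empty argument.
    """

    def __init__(self, joint: JointDistribution):
        self.joint = joint

    def __call__(self, groups: Iterable, cond: Iterable[int] = ()) -> float:
        return _evaluate(mi_coefficients(groups, cond), self.joint)

    def coboundary(self, action: str, args: Iterable) -> float:
        return _evaluate(coboundary_coefficients(action, args), self.joint)


def coboundary(
    F: Cochain | JointDistribution, action: str, args: Iterable, joint=None
) -> float:
    """Numeric coboundary of the information cochain on k+1 variable groups."""
    if isinstance(F, JointDistribution):
        F = Cochain(F)
    elif joint is not None and getattr(F, "joint", None) is None:
        F = Cochain(joint)
    return F.coboundary(action, args)


# ---------------------------------------------------------------------------
# Identity verification


@dataclass(frozen=True)
class IdentityCheck:
    """Result of one coboundary identity: numeric residual and exact cancellation."""

    identity: str
    degree: int
    action: str
    max_residual: float
    exact: bool

    @property
    def ok(self) -> bool:
        return self.exact or self.max_residual <= 1e-9

    def to_dict(self) -> dict:
        return {
            "identity": self.identity,
            "degree": self.degree,
            "action": self.action,
            "max_residual": self.max_residual,
            "exact": self.exact,
            "pass": self.ok,
        }


def _expected_coefficients(action: str, degree: int, args: Sequence[Group]) -> Counter:
    """What the degree-k coboundary of the I-cochain must equal.

    Odd degrees: left -> 0, trivial -> +I_{k+1}, symmetric -> -I_{k+1}.
    Even degrees: left -> -I_{k+1}, trivial and symmetric -> 0.
    """
    I_next = mi_coefficients(args)
    zero: Counter = Counter()
    odd = degree % 2 == 1
    if action == "left":
        return zero if odd else Counter({k: -v for k, v in I_next.items()})
    if action == "trivial":
        return I_next if odd else zero
    return Counter({k: -v for k, v in I_next.items()}) if odd else zero


_IDENTITY_NAMES = {
    ("left", True): "d{k}F = 0",
    ("left", False): "d{k}F = -I{k1}",
    ("trivial", True): "dt{k}F = I{k1}",
    ("trivial", False): "dt{k}F = 0",
    ("symmetric", True): "ds{k}F = -I{k1}",
    ("symmetric", False): "ds{k}F = 0",
}


def verify_identities(
    joint: JointDistribution,
    tolerance: float = 1e-9,
    max_degree: int | None = None,
) -> dict:
    """Check the coboundary identities on a concrete distribution.

    Degrees 1..min(n-1, max_degree) are exercised over every ordered choice of
    singleton arguments; for each identity the report carries the maximal
    numeric residual and whether the integer entropy-coefficients cancel
    exactly.  With fewer than four variables only the reachable degrees run
    and the report is flagged partial.
    """
    indices = joint.indices
    n = len(indices)
    top = n - 1 if max_degree is None else min(max_degree, n - 1)
    checks: list[IdentityCheck] = []
    for k in range(1, top + 1):
        odd = k % 2 == 1
        for action in ("left", "trivial", "symmetric"):
            name = _IDENTITY_NAMES[(action, odd)].format(k=k, k1=k + 1)
            worst = 0.0
            exact = True
            for args in permutations(indices, k + 1):
                groups = tuple((i,) for i in args)
                lhs = coboundary_coefficients(action, groups)
                rhs = _expected_coefficients(action, k, groups)
                # numeric: evaluate the two sides independently in floats
                worst = max(worst, abs(_evaluate(lhs, joint) - _evaluate(rhs, joint)))
                diff = Counter(lhs)
                for key, coef in rhs.items():
                    diff[key] -= coef
                if _strip(diff):
                    exact = False
            checks.append(
                IdentityCheck(
                    identity=name,
                    degree=k,
                    action=action,
                    max_residual=worst,
                    exact=exact,
                )
            )
    return {
        "n": n,
        "partial": n < 4,
        "max_degree": top,
        "all_pass": all(
            c.exact or c.max_residual <= tolerance for c in checks
        ),
        "checks": [c.to_dict() for c in checks],
    }
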