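"""Information paths, critical dimensions and the minimum free energy complex.

A path of degree k is an ordering of k variables; its information profile is
the sequence I_1, I_2, ..., I_k of co-informations of the growing prefix, and
the successive differences are minus the conditional informations (the
entropy-kind analogue uses H and plus conditional entropies, and can only
increase — the combinatorial second law).  Paths are in bijection with
permutations, so a k-set carries k! of them.

A positive information path has a strictly decreasing profile; a maximal one
cannot be extended, stopping either at conditional independence (the next
conditional information ties with zero) or at negativity.  The variable sets
of the maximal positive paths, pruned for containment, are the facets of the
minimum free energy complex; its alternating information sum over all faces
is the minimum free energy characteristic H+.

Whether one ordering of a set is a positive path depends only on the chain of
nested subsets it visits (each step compares I of the prefix set before and
after adding one variable), so the search walks subsets depth-first with
memoization; exhaustive permutation enumeration is kept for small n as an
oracle in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np

from .infometrics import mutual_information, subset_entropy
from .lattice import SimplicialInfoStructure

#: Absolute tolerance on bits for positivity / tie decisions.
DEFAULT_TOL = 1e-10

__all__ = [
    "InformationPath",
    "MFEComplex",
    "PathSet",
    "SecondLawReport",
    "enumerate_paths",
    "path_profile",
    "first_critical_dimension",
    "maximal_positive_paths",
    "build_mfe_complex",
    "second_law_audit",
    "plug_in_tolerance",
]


@dataclass(frozen=True)
class InformationPath:
    """An ordered variable sequence with its H- or I-profile along the prefix."""

    order: tuple[int, ...]
    kind: str
    profile: tuple[float, ...]
    derivative: tuple[float, ...]
    first_critical_dimension: int | None = None
    stop_reason: str | None = None


class PathSet(list):
    """A list of paths that remembers whether it was subsampled."""

    def __init__(self, paths: Iterable[InformationPath], sampled: bool, seed=None):
        super().__init__(paths)
        self.sampled = sampled
        self.seed = seed


@dataclass(frozen=True)
class MFEComplex:
    """The simplicial complex generated by the maximal positive information paths.

    ``face_vector[s-1]`` counts faces with s variables (geometric dimension
    s-1).  ``dimension`` follows the variable-count convention (the degree of
    the largest facet, equal to the maximal first critical dimension);
    ``geometric_dimension`` is one less.  ``euler_characteristic`` is the
    alternating face count; ``h_plus`` the alternating information sum over
    all faces (bits), when a structure was supplied.
    """

    facets: tuple[tuple[int, ...], ...]
    faces: tuple[tuple[tuple[int, ...], ...], ...]
    face_vector: tuple[int, ...]
    dimension: int
    geometric_dimension: int
    euler_characteristic: int
    h_plus: float | None = None
    witnesses: dict = field(default_factory=dict, compare=False)
    stop_reasons: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        return {
            "facets": [list(f) for f in self.facets],
            "face_vector": list(self.face_vector),
            "dimension": self.dimension,
            "geometric_dimension": self.geometric_dimension,
            "euler": self.euler_characteristic,
            "h_plus": self.h_plus,
            "stop_reasons": {
                ",".join(map(str, k)): v for k, v in self.stop_reasons.items()
            },
        }


@dataclass(frozen=True)
class SecondLawReport:
    """Audit of entropy-path monotonicity (must hold up to float error)."""

    n_paths: int
    max_violation: float
    ok: bool
    worst_path: tuple[int, ...] | None = None


# ---------------------------------------------------------------------------


def _indices_of(source) -> tuple[int, ...]:
    if hasattr(source, "subset_indices"):
        return tuple(source.subset_indices())
    return tuple(source.indices)


def plug_in_tolerance(m: int) -> float:
    """Data-driven tie tolerance for plug-in estimates: (log2 e) / (2 m) bits.

    The order of the plug-in entropy bias at sample size m; useful when exact
    ties in the true law become small non-zero fluctuations in the estimate.
    """
    return math.log2(math.e) / (2 * m)


def path_profile(source, order: Sequence[int], kind: str = "information") -> InformationPath:
    """Profile of H or I along the growing prefix of ``order``.

    ``source`` is a computed structure (cached entropies) or a joint
    distribution.  The derivative equals +conditional entropy for the entropy
    kind and -conditional information for the information kind.
    """
    order = tuple(int(i) for i in order)
    if len(set(order)) != len(order):
        raise ValueError(f"repeated index in path order {order}")
    if kind not in ("entropy", "information"):
        raise ValueError("kind must be 'entropy' or 'information'")
    profile = []
    for j in range(1, len(order) + 1):
        prefix = order[:j]
        if kind == "entropy":
            profile.append(subset_entropy(source, prefix))
        else:
            profile.append(mutual_information(source, prefix))
    derivative = tuple(
        profile[j + 1] - profile[j] for j in range(len(profile) - 1)
    )
    path = InformationPath(
        order=order, kind=kind, profile=tuple(profile), derivative=derivative
    )
    if kind == "information":
        crit = first_critical_dimension(path)
        if crit is not None:
            path = InformationPath(
                order=order,
                kind=kind,
                profile=tuple(profile),
                derivative=derivative,
                first_critical_dimension=crit,
            )
    return path


def first_critical_dimension(path: InformationPath, tol: float = DEFAULT_TOL) -> int | None:
    """Degree of the first local minimum of an information path, or None.

    The profile must rise strictly (the next conditional information turns
    negative) for a minimum to register; a path that never rises has no
    critical dimension.  The smallest possible value is 3: the first two
    steps ride on non-negative conditional informations.
    """
    if path.kind != "information":
        raise ValueError("critical dimensions are defined for information paths")
    for j in range(1, len(path.profile)):
        if path.profile[j] > path.profile[j - 1] + tol:
            k = j  # profile[j-1] is the I-value of the degree-j prefix
            assert k >= 3, (
                f"critical dimension {k} < 3 violates conditional-information "
                "non-negativity; the input values are inconsistent"
            )
            return k
    return None


def enumerate_paths(
    structure,
    subset: Iterable[int] | None = None,
    kind: str = "information",
    cap: int = 5040,
    seed: int | None = None,
) -> PathSet:
    """All k! paths of a k-set, or a seeded sample of ``cap`` when k! exceeds it."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if subset is None:
        subset = _indices_of(structure)
    key = tuple(sorted(subset))
    k = len(key)
    total = math.factorial(k)
    if total <= cap:
        orders = list(permutations(key))
        sampled = False
    else:
        rng = np.random.default_rng(seed)
        seen: set[tuple[int, ...]] = set()
        while len(seen) < cap:
            seen.add(tuple(rng.permutation(key).tolist()))
        orders = sorted(seen)
        sampled = True
    return PathSet(
        (path_profile(structure, o, kind) for o in orders), sampled, seed
    )


# ---------------------------------------------------------------------------
# Maximal positive paths and the complex


def maximal_positive_paths(
    structure,
    tol: float = DEFAULT_TOL,
    strict: bool = True,
) -> tuple[tuple[tuple[int, ...], ...], dict]:
    """Facets of the minimum free energy complex, with witness orderings.

    A prefix extends by variable x while the conditional information
    x.I(prefix) exceeds ``tol`` (strictly decreasing profile); with
    ``strict=False`` ties (|cond| <= tol) also extend, for exploratory use.
    Returns ``(facets, info)`` where facets are sorted variable tuples with no
    mutual containment and ``info`` maps each facet to its witness ordering
    and stop reason.
    """
    indices = tuple(sorted(_indices_of(structure)))
    kmax = getattr(structure, "kmax", len(indices))

    info_of = (
        structure.information
        if isinstance(structure, SimplicialInfoStructure)
        else (lambda key: mutual_information(structure, key))
    )

    expanded: set[frozenset] = set()
    stops: dict[frozenset, tuple[tuple[int, ...], str]] = {}

    def explore(order: tuple[int, ...], current: float) -> None:
        S = frozenset(order)
        if S in expanded:
            return
        expanded.add(S)
        extended = False
        truncated = False
        any_tie = False
        if len(order) < kmax:
            for x in indices:
                if x in S:
                    continue
                nxt = info_of(tuple(sorted(order + (x,))))
                cond = current - nxt  # x.I(order)
                if cond > tol or (not strict and cond >= -tol):
                    extended = True
                    explore(order + (x,), nxt)
                elif abs(cond) <= tol:
                    any_tie = True
        else:
            truncated = len(order) < len(indices)
        if not extended:
            reason = (
                "truncated-at-kmax"
                if truncated
                else ("conditional-independence" if any_tie else "negativity")
            )
            if len(order) == len(indices):
                reason = "exhausted"
            if S not in stops:
                stops[S] = (order, reason)

    for x in indices:
        explore((x,), info_of((x,)))

    # containment pruning: drop any stop set included in another
    stop_sets = sorted(stops, key=len, reverse=True)
    facets: list[frozenset] = []
    for S in stop_sets:
        if not any(S < F for F in facets):
            facets.append(S)
    facet_keys = sorted(tuple(sorted(S)) for S in facets)
    info = {
        key: {"witness": stops[frozenset(key)][0], "stop": stops[frozenset(key)][1]}
        for key in facet_keys
    }
    return tuple(facet_keys), info


def _downward_closure(facets: Iterable[tuple[int, ...]]) -> dict[int, set]:
    from itertools import combinations

    faces: dict[int, set] = {}
    for f in facets:
        for s in range(1, len(f) + 1):
            faces.setdefault(s, set()).update(combinations(sorted(f), s))
    return faces


def build_mfe_complex(
    facets: Iterable[tuple[int, ...]],
    structure=None,
    witnesses: dict | None = None,
) -> MFEComplex:
    """Downward closure, face vector, Euler characteristic and H+ from facets.

    ``structure`` (a computed lattice or a joint distribution) is needed only
    for the minimum free energy characteristic H+ — the alternating sum of
    I over every face; face counts and the Euler characteristic are purely
    combinatorial.
    """
    facet_list = sorted({tuple(sorted(int(i) for i in f)) for f in facets})
    if not facet_list:
        raise ValueError("facet list must be non-empty")
    for f in facet_list:
        if len(set(f)) != len(f):
            raise ValueError(f"facet {f} repeats a variable")
    if structure is not None:
        known = set(structure.subset_indices()) if hasattr(
            structure, "subset_indices"
        ) else set(structure.indices)
        for f in facet_list:
            unknown = set(f) - known
            if unknown:
                raise IndexError(f"facet {f} uses unknown variables {sorted(unknown)}")
    # facet minimality
    facet_list = [
        f
        for f in facet_list
        if not any(set(f) < set(g) for g in facet_list)
    ]
    faces = _downward_closure(facet_list)
    max_size = max(len(f) for f in facet_list)
    face_vector = tuple(len(faces.get(s, ())) for s in range(1, max_size + 1))
    euler = sum((-1) ** (s - 1) * c for s, c in enumerate(face_vector, start=1))
    h_plus = None
    if structure is not None:
        h_plus = 0.0
        for s in range(1, max_size + 1):
            sign = 1.0 if s % 2 == 1 else -1.0
            for face in faces.get(s, ()):
                if isinstance(structure, SimplicialInfoStructure):
                    h_plus += sign * structure.information(face)
                else:
                    h_plus += sign * mutual_information(structure, face)
    return MFEComplex(
        facets=tuple(facet_list),
        faces=tuple(tuple(sorted(faces.get(s, ()))) for s in range(1, max_size + 1)),
        face_vector=face_vector,
        dimension=max_size,
        geometric_dimension=max_size - 1,
        euler_characteristic=int(euler),
        h_plus=h_plus,
        witnesses=witnesses or {},
        stop_reasons={
            k: v["stop"] for k, v in (witnesses or {}).items() if isinstance(v, dict)
        },
    )


# ---------------------------------------------------------------------------


def second_law_audit(
    structure,
    subset: Iterable[int] | None = None,
    cap: int = 720,
    seed: int | None = 0,
    tol: float = DEFAULT_TOL,
) -> SecondLawReport:
    """Check that every (sampled) entropy path is nondecreasing.

    Joint entropy cannot decrease when variables are adjoined; any violation
    beyond float tolerance flags an internal inconsistency of the estimated
    values rather than a property of the data.
    """
    paths = enumerate_paths(structure, subset, kind="entropy", cap=cap, seed=seed)
    worst = 0.0
    worst_path = None
    for p in paths:
        if p.derivative:
            drop = -min(p.derivative)
            if drop > worst:
                worst = drop
                worst_path = p.order
    return SecondLawReport(
        n_paths=len(paths),
        max_violation=max(worst, 0.0),
        ok=worst <= tol,
        worst_path=worst_path,
    )
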