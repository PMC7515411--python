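"""The simplicial lattice of variable subsets: entropies, informations, landscapes.

For n variables the simplicial information structure assigns to every
non-empty subset S (up to a maximum degree kmax) its joint entropy H(S) and
its co-information I(S).  Counts per degree follow binomial coefficients, so
the structure holds sum_{k<=kmax} C(n,k) values of each kind; the default
complexity cap refuses larger enumerations unless forced.

Entropies are estimated once per subset (plug-in counting for data matrices,
marginalization for explicit joints) and cached; informations follow by
inclusion-exclusion over the cache, making the lattice pass O(2^n) in the
number of subsets rather than in joint states.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np

from .distributions import DataMatrix, JointDistribution, empirical_joint
from .infometrics import entropy

logger = logging.getLogger(__name__)

#: Default cap on the number of subset evaluations.
DEFAULT_SUBSET_CAP = 1 << 21

__all__ = [
    "SimplicialInfoStructure",
    "Landscape",
    "MeanPath",
    "enumerate_subsets",
    "compute_structure",
    "landscape",
    "mean_paths",
    "plot_landscape",
]

Subset = tuple[int, ...]


@dataclass
class SimplicialInfoStructure:
    """H and I over every variable subset of degree <= kmax (sorted 1-based keys)."""

    n: int
    kmax: int
    H: dict[Subset, float]
    I: dict[Subset, float]
    variables: tuple = ()
    m: int | None = None

    def subset_indices(self) -> Subset:
        """The full (degree-n) variable index set."""
        if self.variables:
            return tuple(v.index for v in self.variables)
        return tuple(range(1, self.n + 1))

    def subsets(self, degree: int) -> list[Subset]:
        return [s for s in self.H if len(s) == degree]

    def entropy(self, subset: Iterable[int]) -> float:
        key = tuple(sorted(subset))
        if not key:
            return 0.0
        return self.H[key]

    def information(self, subset: Iterable[int]) -> float:
        key = tuple(sorted(subset))
        if not key:
            return 0.0
        return self.I[key]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "kmax": self.kmax,
            **({"m": self.m} if self.m is not None else {}),
            "H": {",".join(map(str, k)): v for k, v in self.H.items()},
            "I": {",".join(map(str, k)): v for k, v in self.I.items()},
        }


@dataclass(frozen=True)
class Landscape:
    """Per-degree value multisets with degeneracy counts.

    ``levels[k]`` lists ``(value, count)`` pairs, values grouped within an
    absolute tolerance (empirical values rarely tie exactly); counts at degree
    k sum to C(n, k).
    """

    kind: str
    levels: Mapping[int, tuple[tuple[float, int], ...]]
    tolerance: float = 1e-9

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "levels": {
                str(k): [{"value": v, "count": c} for v, c in pairs]
                for k, pairs in self.levels.items()
            },
        }


@dataclass(frozen=True)
class MeanPath:
    """Degree-wise means <H_k>, <I_k>: the homogeneous (mean-field) summary.

    ``U_hom``/``G_hom`` are the internal and free energy of the idealized
    homogeneous structure in which every k-subset carries the mean values;
    when kmax = n they satisfy H_n = U_hom - G_hom exactly.
    ``critical_dimension`` is the degree of the first local minimum of <I_k>
    (None if the mean information path never rises).
    """

    H_mean: tuple[float, ...]
    I_mean: tuple[float, ...]
    n: int
    U_hom: float
    G_hom: float
    critical_dimension: int | None

    def to_dict(self) -> dict:
        return {
            "H": list(self.H_mean),
            "I": list(self.I_mean),
            "U_hom": self.U_hom,
            "G_hom": self.G_hom,
            "critical_dimension": self.critical_dimension,
        }


# ---------------------------------------------------------------------------


def enumerate_subsets(n: int, kmax: int) -> dict[int, list[Subset]]:
    """All subsets of {1..n} grouped by degree, lexicographic within degree."""
    if not 1 <= kmax <= n:
        raise ValueError(f"kmax must lie in [1, {n}], got {kmax}")
    return {
        k: [tuple(c) for c in combinations(range(1, n + 1), k)]
        for k in range(1, kmax + 1)
    }


def _subset_count(n: int, kmax: int) -> int:
    return sum(math.comb(n, k) for k in range(1, kmax + 1))


def compute_structure(
    source: DataMatrix | JointDistribution,
    kmax: int | None = None,
    cap: int = DEFAULT_SUBSET_CAP,
    force: bool = False,
) -> SimplicialInfoStructure:
    """Compute H and I for every subset up to ``kmax``.

    Refuses (with the projected subset count) when the enumeration exceeds
    ``cap`` and ``force`` is not set.
    """
    indices = source.indices
    n = len(indices)
    if kmax is None:
        kmax = n
    if not 1 <= kmax <= n:
        raise ValueError(f"kmax must lie in [1, {n}], got {kmax}")
    count = _subset_count(n, kmax)
    if count > cap and not force:
        raise RuntimeError(
            f"enumeration of {count} subsets exceeds the cap {cap}; "
            "pass force=True (or --force) to proceed"
        )

    H: dict[Subset, float] = {}
    if isinstance(source, DataMatrix):
        estimator = lambda key: entropy(empirical_joint(source, key))
        m = source.m
    else:
        estimator = lambda key: entropy(source.marginal(key))
        m = None

    for k in range(1, kmax + 1):
        for key in combinations(sorted(indices), k):
            H[key] = estimator(key)

    I: dict[Subset, float] = {}
    for key in H:
        total = 0.0
        for size in range(1, len(key) + 1):
            sign = 1.0 if size % 2 == 1 else -1.0
            for T in combinations(key, size):
                total += sign * H[T]
        I[key] = total

    return SimplicialInfoStructure(
        n=n, kmax=kmax, H=H, I=I, variables=tuple(source.variables), m=m
    )


# ---------------------------------------------------------------------------


def landscape(
    structure: SimplicialInfoStructure, kind: str = "information", tol: float = 1e-9
) -> Landscape:
    """Group the per-degree H or I values into (value, degeneracy) multisets."""
    if kind not in ("entropy", "information"):
        raise ValueError("kind must be 'entropy' or 'information'")
    table = structure.H if kind == "entropy" else structure.I
    levels: dict[int, tuple[tuple[float, int], ...]] = {}
    for k in range(1, structure.kmax + 1):
        values = sorted(v for s, v in table.items() if len(s) == k)
        groups: list[tuple[float, int]] = []
        for v in values:
            if groups and abs(v - groups[-1][0]) <= tol:
                val, c = groups[-1]
                groups[-1] = (val, c + 1)
            else:
                groups.append((v, 1))
        levels[k] = tuple(groups)
    return Landscape(kind=kind, levels=levels, tolerance=tol)


def mean_paths(structure: SimplicialInfoStructure, tol: float = 1e-10) -> MeanPath:
    """Arithmetic means <H_k> and <I_k> over all C(n,k) subsets per degree."""
    n, kmax = structure.n, structure.kmax
    H_mean, I_mean = [], []
    for k in range(1, kmax + 1):
        subs = structure.subsets(k)
        H_mean.append(float(np.mean([structure.H[s] for s in subs])))
        I_mean.append(float(np.mean([structure.I[s] for s in subs])))
    U_hom = n * I_mean[0]
    G_hom = 0.0
    for k in range(2, kmax + 1):
        G_hom += (-1) ** k * math.comb(n, k) * I_mean[k - 1]
    # Homogeneous critical dimension: degree of the first local minimum of
    # <I_k> — either an interior minimum (a strict rise follows) or the final
    # degree when the mean path arrives there strictly decreasing.
    crit = None
    for j in range(1, len(I_mean)):
        if I_mean[j] > I_mean[j - 1] + tol:
            crit = j
            break
    if crit is None and kmax >= 2 and I_mean[-1] < I_mean[-2] - tol:
        crit = kmax
    return MeanPath(
        H_mean=tuple(H_mean),
        I_mean=tuple(I_mean),
        n=n,
        U_hom=U_hom,
        G_hom=G_hom,
        critical_dimension=crit,
    )


def plot_landscape(ls: Landscape, path: str) -> None:
    """Write a degree-vs-bits scatter of a landscape, degeneracy as color."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    xs, ys, cs = [], [], []
    for k, pairs in ls.levels.items():
        for v, c in pairs:
            xs.append(k)
            ys.append(v)
            cs.append(c)
    sc = ax.scatter(xs, ys, c=cs, cmap="viridis")
    fig.colorbar(sc, ax=ax, label="degeneracy")
    ax.set_xlabel("degree k")
    ax.set_ylabel(f"{ls.kind} (bits)")
    ax.axhline(0.0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
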