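"""Discrete joint distributions: discretization, plug-in estimation, marginalization.

Variables carry 1-based indices (matching user-facing output) and finite
alphabets of size ``cardinality``; integer codes in data matrices are 0-based,
``0..cardinality-1``. A :class:`JointDistribution` is a dense probability table
over the product alphabet — the single object every information measure
consumes. Estimation is deliberately the naive plug-in (maximum-likelihood)
estimator: counts divided by the sample size, no pseudocounts, no bias
correction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Hard guard on dense probability tables (joint states).
DENSE_STATE_CAP = 1 << 24

__all__ = [
    "Variable",
    "DataMatrix",
    "JointDistribution",
    "bin_data",
    "empirical_joint",
    "marginalize",
    "gibbs_distribution",
    "read_table",
]


@dataclass(frozen=True)
class Variable:
    """A discrete random variable: 1-based index and alphabet size."""

    index: int
    cardinality: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"variable index must be >= 1, got {self.index}")
        if self.cardinality < 1:
            raise ValueError(f"cardinality must be >= 1, got {self.cardinality}")


@dataclass(frozen=True)
class DataMatrix:
    """Integer-coded samples (rows) x variables (columns).

    ``bin_edges`` records, per column, the boundaries used by :func:`bin_data`
    (``None`` for columns that were already integer-coded).
    """

    values: np.ndarray
    variables: tuple[Variable, ...]
    bin_edges: tuple[np.ndarray | None, ...] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("data matrix must be two-dimensional")
        if vals.shape[0] < 1:
            raise ValueError("data matrix needs at least one sample row")
        if vals.shape[1] != len(self.variables):
            raise ValueError("column count does not match variable count")
        indices = [v.index for v in self.variables]
        if len(set(indices)) != len(indices):
            raise ValueError("variable indices must be unique")
        for j, v in enumerate(self.variables):
            col = vals[:, j]
            if col.min() < 0 or col.max() >= v.cardinality:
                raise ValueError(
                    f"codes in column {j} outside [0, {v.cardinality - 1}]"
                )
        object.__setattr__(self, "values", vals.astype(np.int64, copy=False))

    @property
    def m(self) -> int:
        """Sample count."""
        return int(self.values.shape[0])

    @property
    def n(self) -> int:
        return int(self.values.shape[1])

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(v.index for v in self.variables)

    def column_of(self, index: int) -> int:
        """Position of the variable with the given 1-based index."""
        for j, v in enumerate(self.variables):
            if v.index == index:
                return j
        raise IndexError(f"no variable with index {index}")


class JointDistribution:
    """A probability table over the product alphabet of an ordered variable set.

    ``probs`` is a dense array of shape ``(N1, ..., Nk)``; axis *j* indexes the
    states of ``variables[j]``. The empty variable set yields the unit
    distribution (a single certain state), the identity element of the lattice.
    """

    __slots__ = ("variables", "probs")

    def __init__(
        self,
        variables: Sequence[Variable],
        probs: np.ndarray,
        *,
        _validate: bool = True,
    ) -> None:
        self.variables: tuple[Variable, ...] = tuple(variables)
        arr = np.asarray(probs, dtype=float)
        expected = tuple(v.cardinality for v in self.variables)
        if arr.shape != expected:
            raise ValueError(f"probs shape {arr.shape} != alphabet {expected}")
        if arr.size > DENSE_STATE_CAP:
            raise ValueError(
                f"joint alphabet of {arr.size} states exceeds the dense cap "
                f"{DENSE_STATE_CAP}"
            )
        if _validate:
            if np.any(arr < -1e-15):
                raise ValueError("negative probability entry")
            arr = np.clip(arr, 0.0, None)
            total = arr.sum()
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"probabilities sum to {total!r}, not 1")
            indices = [v.index for v in self.variables]
            if len(set(indices)) != len(indices):
                raise ValueError("variable indices must be unique")
        self.probs = arr

    # -- basic protocol ----------------------------------------------------

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(v.index for v in self.variables)

    @property
    def n(self) -> int:
        return len(self.variables)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"JointDistribution(indices={self.indices}, states={self.probs.size})"

    @classmethod
    def unit(cls) -> "JointDistribution":
        """The single-state certain distribution (empty variable set)."""
        return cls((), np.ones(()), _validate=False)

    def axis_of(self, index: int) -> int:
        for j, v in enumerate(self.variables):
            if v.index == index:
                return j
        raise IndexError(f"no variable with index {index} in {self.indices}")

    def variable(self, index: int) -> Variable:
        return self.variables[self.axis_of(index)]

    # -- marginalization ---------------------------------------------------

    def marginal(self, subset: Iterable[int]) -> "JointDistribution":
        """Marginal over the given 1-based variable indices (original order kept)."""
        keep = set(subset)
        missing = keep - set(self.indices)
        if missing:
            raise IndexError(f"indices {sorted(missing)} not in {self.indices}")
        if not keep:
            return JointDistribution.unit()
        if keep == set(self.indices):
            return self
        drop_axes = tuple(
            j for j, v in enumerate(self.variables) if v.index not in keep
        )
        arr = self.probs.sum(axis=drop_axes)
        kept = tuple(v for v in self.variables if v.index in keep)
        return JointDistribution(kept, arr, _validate=False)

    def states(self) -> Iterable[tuple[tuple[int, ...], float]]:
        """Iterate ``(state, probability)`` over the product alphabet."""
        it = np.nditer(self.probs, flags=["multi_index"])
        for p in it:
            yield it.multi_index, float(p)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "variables": [
                {"index": v.index, "cardinality": v.cardinality,
                 **({"name": v.name} if v.name else {})}
                for v in self.variables
            ],
            "probs": {
                ",".join(map(str, state)): p
                for state, p in self.states()
                if p > 0.0
            },
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "JointDistribution":
        payload = json.loads(text)
        variables = tuple(
            Variable(v["index"], v["cardinality"], v.get("name"))
            for v in payload["variables"]
        )
        shape = tuple(v.cardinality for v in variables)
        arr = np.zeros(shape)
        for key, p in payload["probs"].items():
            state = tuple(int(s) for s in key.split(",")) if key else ()
            arr[state] = p
        return cls(variables, arr)


# ---------------------------------------------------------------------------
# Discretization


def _bin_column(
    col: np.ndarray, bins: int, strategy: str
) -> tuple[np.ndarray, np.ndarray | None]:
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if bins == 1:
        return np.zeros(col.shape, dtype=np.int64), None
    # already-coded columns with exactly the requested alphabet pass through
    if np.all(col == np.floor(col)):
        lo, hi = col.min(), col.max()
        if lo >= 0 and hi <= bins - 1:
            return col.astype(np.int64), None
    if strategy == "equal-width":
        lo, hi = float(col.min()), float(col.max())
        if lo == hi:
            return np.zeros(col.shape, dtype=np.int64), np.array([lo, hi])
        edges = np.linspace(lo, hi, bins + 1)
    elif strategy == "quantile":
        qs = np.linspace(0.0, 1.0, bins + 1)
        edges = np.quantile(col, qs)
        edges = np.unique(edges)
        if len(edges) < bins + 1:
            warnings.warn(
                "fewer distinct quantile boundaries than requested bins; "
                "duplicate boundaries collapsed",
                stacklevel=3,
            )
        if len(edges) < 2:
            return np.zeros(col.shape, dtype=np.int64), edges
    else:
        raise ValueError(f"unknown binning strategy {strategy!r}")
    codes = np.searchsorted(edges[1:-1], col, side="right")
    return codes.astype(np.int64), edges


def bin_data(
    raw,
    bins: int | Sequence[int] = 8,
    strategy: str = "quantile",
    names: Sequence[str] | None = None,
) -> DataMatrix:
    """Discretize a real-valued samples x variables table into integer codes.

    ``bins`` is a single alphabet size or one per column.  Codes are monotone
    in the raw values.  Rows containing missing values are dropped (listwise)
    with a logged count.
    """
    if isinstance(raw, pd.DataFrame):
        if names is None:
            names = [str(c) for c in raw.columns]
        raw = raw.to_numpy()
    arr = np.asarray(raw, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] < 1:
        raise ValueError("input table needs at least one row")
    if not np.all(np.isfinite(arr) | np.isnan(arr)):
        raise ValueError("non-numeric or infinite cell in input table")
    keep = ~np.isnan(arr).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d rows with missing values", dropped)
        arr = arr[keep]
        if arr.shape[0] == 0:
            raise ValueError("all rows contain missing values")
    n = arr.shape[1]
    per_col = [int(bins)] * n if np.isscalar(bins) else [int(b) for b in bins]
    if len(per_col) != n:
        raise ValueError("per-column bins list length mismatch")
    codes = np.empty_like(arr, dtype=np.int64)
    edges: list[np.ndarray | None] = []
    variables = []
    for j in range(n):
        codes[:, j], e = _bin_column(arr[:, j], per_col[j], strategy)
        edges.append(e)
        card = max(per_col[j], int(codes[:, j].max()) + 1)
        name = names[j] if names is not None else None
        variables.append(Variable(j + 1, card, name))
    return DataMatrix(codes, tuple(variables), tuple(edges))


# ---------------------------------------------------------------------------
# Plug-in estimation


def empirical_joint(
    data: DataMatrix, subset: Iterable[int] | None = None
) -> JointDistribution:
    """Plug-in joint distribution of a variable subset: counts / m.

    An empty subset returns the unit distribution (the lattice identity).
    """
    if subset is None:
        subset = data.indices
    wanted = sorted(set(subset))
    if not wanted:
        return JointDistribution.unit()
    cols = [data.column_of(i) for i in wanted]
    variables = tuple(data.variables[c] for c in cols)
    shape = tuple(v.cardinality for v in variables)
    flat = np.ravel_multi_index(tuple(data.values[:, c] for c in cols), shape)
    counts = np.bincount(flat, minlength=int(np.prod(shape)))
    probs = counts.reshape(shape) / data.m
    return JointDistribution(variables, probs, _validate=False)


def marginalize(
    joint: JointDistribution, subset: Iterable[int]
) -> JointDistribution:
    """Sum out every variable not in ``subset``."""
    return joint.marginal(subset)


# ---------------------------------------------------------------------------
# Gibbs distributions


def gibbs_distribution(
    energies: np.ndarray,
    beta: float,
    variables: Sequence[Variable] | None = None,
) -> JointDistribution:
    """Boltzmann–Gibbs law ``p(state) ∝ 2^(-beta * E(state))`` over a product alphabet.

    Energies are dimensionless (bits); ``beta`` is the inverse temperature with
    the physical constants absorbed. Normalization uses a log-sum-exp shift, so
    large energies are safe; ``+inf`` energies receive zero probability.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    E = np.asarray(energies, dtype=float)
    if np.any(np.isnan(E)):
        raise ValueError("energies must not contain NaN")
    logw = -beta * E
    shift = np.max(logw)
    if not np.isfinite(shift):
        raise ValueError("all states have infinite energy; cannot normalize")
    w = np.exp2(logw - shift)
    probs = w / w.sum()
    if variables is None:
        variables = tuple(
            Variable(j + 1, c) for j, c in enumerate(E.shape)
        )
    return JointDistribution(tuple(variables), probs, _validate=False)


# ---------------------------------------------------------------------------
# Input files


def read_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited numeric matrix with a header row of variable names."""
    if delimiter is None:
        return pd.read_csv(path, sep=None, engine="python")
    return pd.read_csv(path, sep=delimiter)
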