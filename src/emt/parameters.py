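"""Flat parameter vectors for political-ecological simulators.

A simulator is parameterized by a single flat vector ``B`` whose entries are
indexed by ``(submodel, context, name)`` keys: the submodel that owns the
scalar, the conditioning context (a tuple of ``(parent, value)`` pairs for
conditional-probability-table rows, empty for global parameters), and a local
name.  The vector partitions into a group block ``B^(Grp)`` and an ecosystem
block ``B^(Eco)``.  Named snapshots of the same structure (hypothesis values
``B_H``, initialized values ``B_initial``, consistent values ``B_C`` and so
on) are plain :class:`ParameterVector` instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

GROUP_BLOCK = "grp"
ECO_BLOCK = "eco"


class ParamKey(NamedTuple):
    """Identifies one scalar parameter.

    ``context`` is a tuple of ``(parent name, value)`` pairs identifying the
    conditioning combination the scalar belongs to (empty for parameters
    shared across combinations, e.g. regression coefficients of a
    conditional-Gaussian node).
    """

    submodel: str
    context: tuple
    name: str

    def label(self) -> str:
        ctx = ",".join(f"{p}={v}" for p, v in self.context)
        return f"{self.submodel}[{ctx}].{self.name}" if ctx else f"{self.submodel}.{self.name}"


@dataclass
class ParameterVector:
    """A flat real vector with a structural index.

    Parameters
    ----------
    values : array of shape (k,)
    index : tuple of :class:`ParamKey`, one per scalar, unique.
    blocks : tuple of block labels per scalar (``"grp"`` or ``"eco"``).
    bounds : array of shape (k, 2) of (lower, upper) box bounds.
    active : boolean mask of the scalars a fit is allowed to move.
    simplex_rows : groups of positions that must form a probability vector
        (one group per conditional-probability-table row).
    """

    values: np.ndarray
    index: tuple
    blocks: tuple
    bounds: np.ndarray
    active: np.ndarray = None
    simplex_rows: tuple = ()
    _pos: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float).reshape(len(self.values), 2)
        if self.active is None:
            self.active = np.zeros(len(self.values), dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool)
        self.index = tuple(ParamKey(*k) for k in self.index)
        self.blocks = tuple(self.blocks)
        if len({*self.index}) != len(self.index):
            raise ValueError("parameter index contains duplicate keys")
        if not (len(self.index) == len(self.values) == len(self.blocks) == len(self.active)):
            raise ValueError("index/values/blocks/active lengths differ")
        self._pos = {k: i for i, k in enumerate(self.index)}

    # -- basic access ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.values)

    def position(self, key: ParamKey) -> int:
        return self._pos[ParamKey(*key)]

    def get(self, key: ParamKey) -> float:
        return float(self.values[self.position(key)])

    def set(self, key: ParamKey, value: float) -> None:
        self.values[self.position(key)] = float(value)

    def copy(self) -> "ParameterVector":
        return ParameterVector(
            self.values.copy(), self.index, self.blocks, self.bounds.copy(),
            self.active.copy(), self.simplex_rows,
        )

    def with_values(self, values) -> "ParameterVector":
        out = self.copy()
        values = np.asarray(values, dtype=float)
        if values.shape != out.values.shape:
            raise ValueError("value vector has wrong length")
        out.values = values
        return out

    # -- blocks ------------------------------------------------------------
    def block_mask(self, block: str) -> np.ndarray:
        if block in (GROUP_BLOCK, ECO_BLOCK):
            return np.array([b == block for b in self.blocks])
        if block == "all":
            return np.ones(len(self), dtype=bool)
        raise ValueError(f"unknown block {block!r}")

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite parameter value")
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        if np.any(self.values < lo - 1e-9) or np.any(self.values > hi + 1e-9):
            bad = self.index[int(np.argmax((self.values < lo - 1e-9) | (self.values > hi + 1e-9)))]
            raise ValueError(f"parameter {bad.label()} outside its bounds")
        for row in self.simplex_rows:
            s = self.values[list(row)].sum()
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"probability row {[self.index[i].label() for i in row]} sums to {s!r}"
                )

    def same_structure(self, other: "ParameterVector") -> bool:
        return self.index == other.index and self.blocks == other.blocks


def assert_same_structure(a: ParameterVector, b: ParameterVector) -> None:
    if not a.same_structure(b):
        raise ValueError("parameter vectors have mismatched index structures")


class ParameterBuilder:
    """Incrementally assembles a :class:`ParameterVector`."""

    def __init__(self):
        self._keys = []
        self._values = []
        self._blocks = []
        self._bounds = []
        self._simplex = []

    def add(self, key: ParamKey, value: float, block: str, bounds=(-np.inf, np.inf)) -> int:
        self._keys.append(ParamKey(*key))
        self._values.append(float(value))
        self._blocks.append(block)
        self._bounds.append(tuple(bounds))
        return len(self._keys) - 1

    def add_simplex_row(self, keys_values: Iterable, block: str) -> None:
        """Add a CPT row: a list of ``(key, probability)`` pairs summing to 1."""
        positions = []
        for key, value in keys_values:
            positions.append(self.add(key, value, block, bounds=(0.0, 1.0)))
        self._simplex.append(tuple(positions))

    def build(self) -> ParameterVector:
        return ParameterVector(
            np.array(self._values, dtype=float),
            tuple(self._keys),
            tuple(self._blocks),
            np.array(self._bounds, dtype=float).reshape(-1, 2),
            simplex_rows=tuple(self._simplex),
        )


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of ``v`` onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    n = v.size
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, n + 1) > 0)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def project_rows(B: ParameterVector, touched: Iterable[int] | None = None) -> ParameterVector:
    """Project every simplex row (optionally only rows containing ``touched``
    positions) back onto the probability simplex after coordinate moves."""
    out = B.copy()
    touched = None if touched is None else set(touched)
    for row in B.simplex_rows:
        if touched is not None and not touched.intersection(row):
            continue
        idx = list(row)
        out.values[idx] = project_simplex(out.values[idx])
    return out
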