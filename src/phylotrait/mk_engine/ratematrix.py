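"""Rate matrices and free/zero/shared constraint patterns for k-state Mk models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["RateMatrix", "ConstraintMap", "build_rate_matrix"]


@dataclass
class RateMatrix:
    """Instantaneous rate matrix: off-diagonals >= 0, rows sum to zero."""

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        k = self.q.shape[0]
        if self.q.shape != (k, k):
            raise ValueError("rate matrix must be square")
        off = self.q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.any(np.abs(self.q.sum(axis=1)) > 1e-12):
            raise ValueError("rows must sum to zero")

    @property
    def k(self) -> int:
        return self.q.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Left null vector of Q, normalized; uniform if Q is all-zero."""
        if np.allclose(self.q, 0):
            return np.full(self.k, 1.0 / self.k)
        a = np.vstack([self.q.T, np.ones(self.k)])
        b = np.zeros(self.k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0, None)
        return pi / pi.sum()

    @classmethod
    def from_offdiagonal(cls, off: np.ndarray) -> "RateMatrix":
        q = np.asarray(off, dtype=float).copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return cls(q)


def _free_label(i: int, j: int) -> str:
    return f"q{i + 1}{j + 1}"


@dataclass(frozen=True)
class ConstraintMap:
    """Labels every ordered state pair free, zero, or shared:<group>.

    Pairs absent from ``labels`` default to free.  Free cells form their own
    one-cell parameter group named ``q<i><j>`` with 1-based states.
    """

    k: int
    labels: Mapping = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        for (i, j), lab in self.labels.items():
            if i == j or not (0 <= i < self.k and 0 <= j < self.k):
                raise ValueError(f"bad cell ({i},{j}) for k={self.k}")
            if lab not in ("free", "zero") and not lab.startswith("shared:"):
                raise ValueError(f"bad label {lab!r}")

    def label(self, i: int, j: int) -> str:
        return self.labels.get((i, j), "free")

    def groups(self) -> list:
        """Ordered parameter-group names (free cells then shared groups)."""
        out = []
        shared = []
        for i in range(self.k):
            for j in range(self.k):
                if i == j:
                    continue
                lab = self.label(i, j)
                if lab == "free":
                    out.append(_free_label(i, j))
                elif lab.startswith("shared:"):
                    g = lab.split(":", 1)[1]
                    if g not in shared:
                        shared.append(g)
        return out + shared

    @property
    def n_free(self) -> int:
        return len(self.groups())

    def assign_array(self) -> np.ndarray:
        """(k,k) int array mapping each cell to its group index (-1 = zero/diag)."""
        order = {g: idx for idx, g in enumerate(self.groups())}
        a = np.full((self.k, self.k), -1, dtype=np.int64)
        for i in range(self.k):
            for j in range(self.k):
                if i == j:
                    continue
                lab = self.label(i, j)
                if lab == "free":
                    a[i, j] = order[_free_label(i, j)]
                elif lab.startswith("shared:"):
                    a[i, j] = order[lab.split(":", 1)[1]]
        return a

    def describe(self) -> str:
        zero = [
            f"{i + 1}->{j + 1}"
            for i in range(self.k)
            for j in range(self.k)
            if i != j and self.label(i, j) == "zero"
        ]
        return f"{self.name or 'constraint'}: {self.n_free} free group(s), zero={zero}"

    @classmethod
    def all_free(cls, k: int, name: str = "free") -> "ConstraintMap":
        return cls(k=k, labels={}, name=name)

    @classmethod
    def equal_rates(cls, k: int, name: str = "ER") -> "ConstraintMap":
        labels = {
            (i, j): "shared:rate" for i in range(k) for j in range(k) if i != j
        }
        return cls(k=k, labels=labels, name=name)


def build_rate_matrix(params: Mapping, constraint: ConstraintMap, k: int | None = None) -> RateMatrix:
    """Fill a rate matrix from per-group rates under a constraint pattern."""
    k = k or constraint.k
    if k != constraint.k:
        raise ValueError("k mismatch with constraint")
    missing = [g for g in constraint.groups() if g not in params]
    if missing:
        raise ValueError(f"missing rate(s) for group(s): {missing}")
    bad = {g: v for g, v in params.items() if g in constraint.groups() and v < 0}
    if bad:
        raise ValueError(f"negative rate(s): {bad}")
    rates = np.array([float(params[g]) for g in constraint.groups()])
    assign = constraint.assign_array()
    off = np.zeros((k, k))
    mask = assign >= 0
    off[mask] = rates[assign[mask]]
    return RateMatrix.from_offdiagonal(off)
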