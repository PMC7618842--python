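"""Pruning log-likelihood for discrete traits, plus the enumeration oracle.

``log_likelihood`` runs Felsenstein pruning through the numba kernels;
``brute_force_log_likelihood`` sums over every internal-state assignment with
scipy's expm and exists purely as an independent cross-check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.linalg

from ..phylo_io import Phylogeny
from . import _kernels
from .ratematrix import RateMatrix

__all__ = [
    "TreeData",
    "tip_partials",
    "root_weights",
    "log_likelihood",
    "brute_force_log_likelihood",
    "NEG_INF",
]

NEG_INF = -np.inf


def tip_partials(tree: Phylogeny, tip_states: Mapping, k: int) -> np.ndarray:
    """(n_nodes, k) partial-likelihood array for the tips.

    States are 0-based ints; an iterable of ints is an ambiguity set and
    ``None`` means fully ambiguous (all ones).
    """
    part = np.zeros((tree.n_nodes, k))
    index = tree.tip_index()
    unknown = set(tip_states) - set(index)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    missing = set(index) - set(tip_states)
    if missing:
        raise ValueError(f"tips without state: {sorted(missing)}")
    for sp, st in tip_states.items():
        u = index[sp]
        if st is None:
            part[u, :] = 1.0
        elif np.isscalar(st) and not isinstance(st, (set, frozenset)):
            s = int(st)
            if not 0 <= s < k:
                raise ValueError(f"{sp}: state {s} outside 0..{k - 1}")
            part[u, s] = 1.0
        else:
            for s in st:
                if not 0 <= int(s) < k:
                    raise ValueError(f"{sp}: state {s} outside 0..{k - 1}")
                part[u, int(s)] = 1.0
    return part


def root_weights(Q: RateMatrix | np.ndarray, root_mode, k: int) -> np.ndarray:
    if isinstance(root_mode, str):
        if root_mode == "flat":
            return np.full(k, 1.0 / k)
        if root_mode == "stationary":
            qm = Q if isinstance(Q, RateMatrix) else RateMatrix(Q)
            return qm.stationary_distribution()
        raise ValueError(f"unknown root mode {root_mode!r}")
    w = np.asarray(root_mode, dtype=float)
    if w.shape != (k,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("root distribution must be a length-k simplex vector")
    return w


@dataclass
class TreeData:
    """Flat arrays for one (tree, tip data) pair, ready for the kernels."""

    lengths: np.ndarray
    parent: np.ndarray
    child_flat: np.ndarray
    child_start: np.ndarray
    tip_partial: np.ndarray
    k: int

    @classmethod
    def build(cls, tree: Phylogeny, tip_states: Mapping, k: int) -> "TreeData":
        return cls(
            lengths=tree.edge_length.astype(float),
            parent=tree.parent,
            child_flat=tree.children_flat,
            child_start=tree.children_start,
            tip_partial=tip_partials(tree, tip_states, k),
            k=k,
        )

    def loglike(self, Q: np.ndarray, weights: np.ndarray) -> float:
        ll = _kernels.mk_loglike(
            np.asarray(Q, dtype=float),
            self.lengths,
            self.parent,
            self.child_flat,
            self.child_start,
            self.tip_partial,
            weights,
        )
        return NEG_INF if ll <= _kernels.NEG_INF / 2 else float(ll)


def log_likelihood(
    tree: Phylogeny, tip_states: Mapping, Q: RateMatrix, root_mode="flat"
) -> float:
    """Pruning log-likelihood of tip states under rate matrix Q.

    ``root_mode`` is ``"flat"``, ``"stationary"`` or an explicit distribution.
    Returns ``-inf`` for impossible data (never raises for it).
    """
    k = Q.k
    data = TreeData.build(tree, tip_states, k)
    w = root_weights(Q, root_mode, k)
    ll = data.loglike(Q.q, w)
    if not np.isfinite(ll) and ll != NEG_INF:
        raise ArithmeticError("non-finite likelihood (bad rate matrix?)")
    return ll


def brute_force_log_likelihood(
    tree: Phylogeny, tip_states: Mapping, Q: RateMatrix, root_mode="flat"
) -> float:
    """Likelihood by explicit summation over all internal-state assignments.

    Test oracle only: uses scipy's expm (an independent code path from the
    kernels) and enumerates k^m assignments for m internal nodes (m <= 8).
    """
    k = Q.k
    internal = [u for u in range(tree.n_nodes) if not tree.is_tip[u]]
    if len(internal) > 8:
        raise ValueError(f"{len(internal)} internal nodes; enumeration capped at 8")
    part = tip_partials(tree, tip_states, k)
    w = root_weights(Q, root_mode, k)
    P = {
        u: scipy.linalg.expm(Q.q * tree.edge_length[u])
        for u in range(tree.n_nodes - 1)
    }
    pos = {u: idx for idx, u in enumerate(internal)}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        prob = w[assign[pos[tree.root]]]
        for u in range(tree.n_nodes - 1):
            pstate = assign[pos[tree.parent[u]]]
            if tree.is_tip[u]:
                prob *= float(P[u][pstate] @ part[u])
            else:
                prob *= P[u][pstate, assign[pos[u]]]
            if prob == 0.0:
                break
        total += prob
    return float(np.log(total)) if total > 0 else NEG_INF
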