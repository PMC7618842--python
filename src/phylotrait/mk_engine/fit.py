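"""Maximum-likelihood fitting of constrained Mk models."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.optimize

from ..phylo_io import Phylogeny
from .likelihood import NEG_INF, TreeData, root_weights
from .ratematrix import ConstraintMap, build_rate_matrix

__all__ = ["MLFit", "fit_ml"]


@dataclass
class MLFit:
    params: dict
    log_likelihood: float
    aic: float
    constraint: ConstraintMap
    root_mode: object = "flat"
    n_restarts_used: int = 0

    @property
    def rate_matrix(self):
        return build_rate_matrix(self.params, self.constraint)


def _observed_states(tip_states: Mapping) -> set:
    obs = set()
    for st in tip_states.values():
        if st is None:
            continue
        if np.isscalar(st) and not isinstance(st, (set, frozenset)):
            obs.add(int(st))
        else:
            obs.update(int(s) for s in st)
    return obs


def fit_ml(
    tree: Phylogeny,
    tip_states: Mapping,
    constraint: ConstraintMap,
    k: int | None = None,
    root_mode="flat",
    n_starts: int = 4,
    seed: int = 0,
    max_restarts: int = 8,
) -> MLFit:
    """Maximize the pruning log-likelihood over nonnegative rates.

    Rates are optimized on the log scale with multiple random restarts;
    AIC = 2 * n_free - 2 * logL.
    """
    k = k or constraint.k
    groups = constraint.groups()
    if not groups:
        raise ValueError("constraint has no free parameters to fit")
    if len(_observed_states(tip_states)) < 2:
        raise ValueError("need at least 2 observed states to fit a model")
    data = TreeData.build(tree, tip_states, k)
    assign = constraint.assign_array()
    flat_root = isinstance(root_mode, str) and root_mode == "stationary"

    def negll(x):
        rates = np.exp(np.clip(x, -25, 12))
        off = np.zeros((k, k))
        mask = assign >= 0
        off[mask] = rates[assign[mask]]
        q = off.copy()
        np.fill_diagonal(q, -off.sum(axis=1))
        if flat_root:
            from .ratematrix import RateMatrix

            w = RateMatrix(q).stationary_distribution()
        else:
            w = root_weights(q, root_mode, k) if not hasattr(negll, "_w") else negll._w
        ll = data.loglike(q, w)
        return 1e10 if ll == NEG_INF else -ll

    if not flat_root:
        negll._w = root_weights(np.zeros((k, k)), root_mode, k)

    # moment-flavoured initial scale: total changes implied by tip variation
    tlen = max(data.lengths.sum(), 1e-9)
    base = np.log(max(len(tip_states), 2) / tlen / max(k, 2))
    rng = np.random.default_rng(seed)
    best = None
    tried = 0
    for attempt in range(max_restarts):
        x0 = base + (0.0 if attempt == 0 else rng.normal(0, 1.5, len(groups)))
        x0 = np.broadcast_to(x0, (len(groups),)).astype(float)
        res = scipy.optimize.minimize(
            negll, x0, method="L-BFGS-B", options={"maxiter": 500}
        )
        tried += 1
        if np.isfinite(res.fun) and res.fun < 1e9:
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        if best is not None and tried >= n_starts:
            break
    if best is None:
        raise RuntimeError(
            f"ML optimization failed to converge after {tried} restarts "
            "(all starts hit impossible-likelihood regions)"
        )
    rates = np.exp(np.clip(best.x, -25, 12))
    params = {g: float(r) for g, r in zip(groups, rates)}
    ll = -float(best.fun)
    aic = 2.0 * len(groups) - 2.0 * ll
    return MLFit(
        params=params,
        log_likelihood=ll,
        aic=aic,
        constraint=constraint,
        root_mode=root_mode,
        n_restarts_used=tried,
    )
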