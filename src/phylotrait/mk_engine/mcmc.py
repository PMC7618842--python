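"""MCMC over constrained rate matrices, with tree-set switching and diagnostics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ..phylo_io import Phylogeny, TreeSet
from . import _kernels
from .likelihood import NEG_INF, TreeData, root_weights
from .ratematrix import ConstraintMap

__all__ = ["PriorSpec", "MCMCSettings", "MkChain", "mcmc_sample", "effective_sample_size"]


@dataclass(frozen=True)
class PriorSpec:
    """Exponential prior on every rate, mean ~ Uniform(0, hyper_upper).

    ``fixed_mean`` pins the hyper-mean (used by the quadrature cross-checks).
    """

    hyper_upper: float = 0.1
    fixed_mean: float | None = None

    def __post_init__(self) -> None:
        if self.hyper_upper <= 0:
            raise ValueError("hyper_upper must be positive")
        if self.fixed_mean is not None and self.fixed_mean <= 0:
            raise ValueError("fixed_mean must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    iterations: int = 150_000
    burn_in: int = 12_000
    thinning: int = 30
    n_chains: int = 2
    seed: int = 0
    proposal_scale: float = 0.7
    tree_switch_every: int = 200

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class MkChain:
    samples: pd.DataFrame  # thinned, post burn-in: rates, hyper_mean, logL, tree_index
    acceptance: dict
    settings: MCMCSettings
    constraint: ConstraintMap

    def ess(self, column: str = "logL") -> float:
        x = self.samples[column].to_numpy()
        try:  # arviz's estimator when available; internal fallback otherwise
            import arviz

            return float(arviz.ess(x))
        except ImportError:
            return effective_sample_size(x)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial positive sequence estimator (Geyer 1992)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    # sum consecutive pairs while positive
    s = 0.0
    for t in range(1, n // 2):
        pair = acf[2 * t - 1] + acf[2 * t] if 2 * t < n else acf[2 * t - 1]
        if pair < 0:
            break
        s += pair
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), n))


def _tree_datas(trees, tip_states: Mapping, k: int) -> list:
    if isinstance(trees, Phylogeny):
        trees = TreeSet([trees])
    return [TreeData.build(t, tip_states, k) for t in trees], trees


def mcmc_sample(
    trees,
    tip_states: Mapping,
    constraint: ConstraintMap,
    prior: PriorSpec = PriorSpec(),
    settings: MCMCSettings = MCMCSettings(),
    root_mode="flat",
    chain_id: int = 0,
) -> MkChain:
    """Metropolis–Hastings sampling of rates (and the prior hyper-mean).

    Rate updates use log-scale proposals inside a compiled kernel; every
    ``tree_switch_every`` iterations a uniform tree-index switch over the
    TreeSet is proposed and accepted by its likelihood ratio.
    """
    k = constraint.k
    groups = constraint.groups()
    if not groups:
        raise ValueError("constraint has no free parameters")
    datas, trees = _tree_datas(trees, tip_states, k)
    assign = constraint.assign_array()
    w = root_weights(np.zeros((k, k)), "flat" if root_mode == "stationary" else root_mode, k)
    rng = np.random.default_rng((settings.seed, chain_id, 0xA11CE))

    m = prior.fixed_mean if prior.fixed_mean is not None else prior.hyper_upper / 2
    rates = rng.exponential(m, size=len(groups))
    update_mean = prior.fixed_mean is None
    hyper_upper = prior.hyper_upper

    seg = max(settings.tree_switch_every, settings.thinning)
    seg -= seg % settings.thinning or 0
    seg = max(seg, settings.thinning)
    tree_idx = int(rng.integers(len(datas)))

    rows = []
    acc_rate = prop_rate = acc_m = prop_m = acc_tree = prop_tree = 0
    done = 0
    while done < settings.iterations:
        n_it = min(seg, settings.iterations - done)
        n_it -= n_it % settings.thinning
        n_it = max(n_it, settings.thinning) if settings.iterations - done >= settings.thinning else n_it
        if n_it == 0:
            break
        d = datas[tree_idx]
        out = _kernels.run_power_chain(
            int(rng.integers(2**31 - 1)),
            n_it,
            settings.thinning,
            1.0,
            rates,
            float(m),
            hyper_upper,
            update_mean,
            assign,
            k,
            d.lengths,
            d.parent,
            d.child_flat,
            d.child_start,
            d.tip_partial,
            w,
            settings.proposal_scale,
            hyper_upper / 10.0,
        )
        ll_trace, samples, a_r, p_r, a_m, p_m, rates, m = out
        acc_rate += a_r
        prop_rate += p_r
        acc_m += a_m
        prop_m += p_m
        for r_i in range(samples.shape[0]):
            it_global = done + (r_i + 1) * settings.thinning
            rows.append(
                (it_global, *samples[r_i, :-1], samples[r_i, -1],
                 ll_trace[(r_i + 1) * settings.thinning - 1], tree_idx)
            )
        done += n_it
        if len(datas) > 1:
            prop_tree += 1
            cand = int(rng.integers(len(datas)))
            if cand != tree_idx:
                from .ratematrix import build_rate_matrix

                q = build_rate_matrix(dict(zip(groups, rates)), constraint).q
                ll_cur = datas[tree_idx].loglike(q, w)
                ll_new = datas[cand].loglike(q, w)
                if np.log(rng.random()) < ll_new - ll_cur:
                    tree_idx = cand
                    acc_tree += 1

    df = pd.DataFrame(rows, columns=["iteration", *groups, "hyper_mean", "logL", "tree_index"])
    df = df[df["iteration"] > settings.burn_in].reset_index(drop=True)
    acc = {
        "rate": acc_rate / max(prop_rate, 1),
        "hyper_mean": acc_m / max(prop_m, 1),
        "tree_switch": acc_tree / max(prop_tree, 1),
    }
    if prop_rate > 50 and acc_rate == 0:
        raise RuntimeError(
            "zero acceptance for rate proposals; decrease proposal_scale"
        )
    return MkChain(samples=df, acceptance=acc, settings=settings, constraint=constraint)
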