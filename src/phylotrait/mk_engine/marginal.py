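"""Stepping-stone marginal likelihoods and Bayes factors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.stats
from scipy.special import logsumexp

from ..phylo_io import Phylogeny, TreeSet
from . import _kernels
from .likelihood import NEG_INF, TreeData, root_weights
from .mcmc import PriorSpec
from .ratematrix import ConstraintMap, RateMatrix, build_rate_matrix

__all__ = [
    "SteppingStoneSettings",
    "MarginalLikelihood",
    "BayesFactorResult",
    "stepping_stone_log_marginal",
    "bayes_factor",
]


@dataclass(frozen=True)
class SteppingStoneSettings:
    """Power-posterior ladder: beta_k = Beta(alpha, beta) quantile of k/K."""

    n_stones: int = 100
    iterations_per_stone: int = 10_000
    alpha: float = 0.4
    beta: float = 1.0
    proposal_scale: float = 0.7
    burn_fraction: float = 0.1

    def powers(self) -> np.ndarray:
        ks = np.arange(self.n_stones + 1) / self.n_stones
        b = scipy.stats.beta.ppf(ks, self.alpha, self.beta)
        b[0], b[-1] = 0.0, 1.0
        return b


@dataclass
class MarginalLikelihood:
    log_ml: float
    per_stone: np.ndarray
    settings: SteppingStoneSettings
    seed: int
    n_free: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_ml):
            raise ArithmeticError("non-finite marginal likelihood estimate")


@dataclass
class BayesFactorResult:
    bf: float
    label: str
    lnml_complex: float
    lnml_simple: float


def stepping_stone_log_marginal(
    trees,
    tip_states: Mapping,
    constraint: ConstraintMap,
    prior: PriorSpec = PriorSpec(),
    ss: SteppingStoneSettings = SteppingStoneSettings(),
    seed: int = 0,
    root_mode="flat",
    fixed_q: RateMatrix | None = None,
) -> MarginalLikelihood:
    """Estimate the log marginal likelihood with a stepping-stone sampler.

    One chain is warm-started up the power ladder; at each stone the mean
    importance ratio to the next power is accumulated:
    log ML = sum_k log E_{beta_k}[ L^(beta_{k+1}-beta_k) ].

    ``fixed_q`` short-circuits to the exact point-prior answer log ML = logL.
    """
    if isinstance(trees, Phylogeny):
        trees = TreeSet([trees])
    tree = trees[0]  # stepping stone runs on one tree; callers loop over sets
    k = constraint.k
    data = TreeData.build(tree, tip_states, k)
    w = root_weights(np.zeros((k, k)), "flat" if root_mode == "stationary" else root_mode, k)

    if fixed_q is not None or constraint.n_free == 0:
        q = fixed_q.q if fixed_q is not None else np.zeros((k, k))
        ll = data.loglike(q, w)
        return MarginalLikelihood(
            log_ml=float(ll), per_stone=np.array([ll]), settings=ss, seed=seed, n_free=0
        )

    groups = constraint.groups()
    assign = constraint.assign_array()
    rng = np.random.default_rng((seed, 0x57E9))
    m = prior.fixed_mean if prior.fixed_mean is not None else prior.hyper_upper / 2
    rates = rng.exponential(m, size=len(groups))
    update_mean = prior.fixed_mean is None

    powers = ss.powers()
    contribs = np.zeros(ss.n_stones)
    burn = int(ss.burn_fraction * ss.iterations_per_stone)
    for s in range(ss.n_stones):
        beta_k, beta_next = powers[s], powers[s + 1]
        out = _kernels.run_power_chain(
            int(rng.integers(2**31 - 1)),
            ss.iterations_per_stone,
            max(ss.iterations_per_stone, 1),  # no need for thinned params
            beta_k,
            rates,
            float(m),
            prior.hyper_upper,
            update_mean,
            assign,
            k,
            data.lengths,
            data.parent,
            data.child_flat,
            data.child_start,
            data.tip_partial,
            w,
            ss.proposal_scale,
            prior.hyper_upper / 10.0,
        )
        ll_trace, _, a_r, p_r, _, _, rates, m = out
        lls = ll_trace[burn:]
        if not np.all(np.isfinite(lls)) or np.any(lls < _kernels.NEG_INF / 2):
            raise ArithmeticError(f"non-finite likelihood samples at stone {s}")
        dbeta = beta_next - beta_k
        contribs[s] = logsumexp(dbeta * lls) - np.log(lls.size)
    return MarginalLikelihood(
        log_ml=float(contribs.sum()),
        per_stone=contribs,
        settings=ss,
        seed=seed,
        n_free=len(groups),
    )


def bayes_factor(lnml_complex: float, lnml_simple: float) -> BayesFactorResult:
    """BF = 2 * (lnML_complex - lnML_simple), with the conventional labels
    (<2 minimal, 2-6 positive, 6-10 strong, >10 very strong)."""
    if not (np.isfinite(lnml_complex) and np.isfinite(lnml_simple)):
        raise ValueError("log marginal likelihoods must be finite")
    bf = 2.0 * (lnml_complex - lnml_simple)
    if bf < 2:
        label = "minimal"
    elif bf < 6:
        label = "positive"
    elif bf <= 10:
        label = "strong"
    else:
        label = "very strong"
    return BayesFactorResult(bf=bf, label=label, lnml_complex=lnml_complex, lnml_simple=lnml_simple)
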