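"""Phylogenetic regression (GLS and Bayesian mixed models), convergence
diagnostics, and phylogenetic path analysis (d-separation, Fisher's C, CICc)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .phylo_io import Phylogeny, TreeSet

__all__ = [
    "PhyloCovariance",
    "RegressionFit",
    "CausalDAG",
    "PathModelComparison",
    "phylo_covariance",
    "pgls_fit",
    "bpmm_fit",
    "gelman_rubin",
    "basis_set",
    "fisher_c",
    "cicc",
    "compare_path_models",
    "hpd_interval",
]


# --------------------------------------------------------------------------
# covariance
# --------------------------------------------------------------------------
@dataclass
class PhyloCovariance:
    matrix: np.ndarray
    species: list

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("covariance must be symmetric")

    def reorder(self, species: Sequence[str]) -> "PhyloCovariance":
        idx = [self.species.index(s) for s in species]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(species))


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance: C[i,j] = root-to-MRCA(i,j) path length."""
    return PhyloCovariance(tree.mrca_depth_matrix(), tree.tip_labels)


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


# --------------------------------------------------------------------------
# regression fits
# --------------------------------------------------------------------------
@dataclass
class RegressionFit:
    coefficients: pd.Series
    se: pd.Series | None
    p_values: pd.Series | None
    sigma2: float
    family: str
    n: int
    method: str  # "pgls" | "bpmm"
    lambda_: float | None = None
    log_likelihood: float | None = None
    pmcmc: pd.Series | None = None
    ci: pd.DataFrame | None = None  # columns lower/upper
    posterior: pd.DataFrame | None = None
    sigma2_phylo: float | None = None
    converged: bool = True
    psrf: pd.Series | None = None


def _design(X, n: int):
    if X is None:
        Xm = pd.DataFrame(index=range(n))
    elif isinstance(X, pd.Series):
        Xm = X.to_frame()
    elif isinstance(X, pd.DataFrame):
        Xm = X.copy()
    else:
        Xm = pd.DataFrame(np.asarray(X))
        Xm.columns = [f"x{i}" for i in range(Xm.shape[1])]
    Xm.insert(0, "(Intercept)", 1.0)
    return Xm


def _gls(y, Xm, V):
    L = np.linalg.cholesky(V)
    yw = scipy.linalg.solve_triangular(L, y, lower=True)
    Xw = scipy.linalg.solve_triangular(L, Xm, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    n, p = Xw.shape
    sigma2 = float(resid @ resid) / max(n - p, 1)
    cov = sigma2 * np.linalg.inv(XtX)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    s2_ml = float(resid @ resid) / n
    ll = -0.5 * (n * np.log(2 * np.pi * max(s2_ml, 1e-300)) + logdet + n)
    return beta, cov, sigma2, ll


def pgls_fit(
    y,
    X,
    tree: Phylogeny,
    lambda_: float | str = 1.0,
    cov: PhyloCovariance | None = None,
) -> RegressionFit:
    """Phylogenetic GLS under Brownian motion with Pagel's lambda.

    ``lambda_`` is a fixed value in [0, 1] or ``"estimated"`` (profile ML).
    With lambda 0 (or a star tree) this is ordinary least squares.
    """
    if isinstance(y, pd.Series):
        species = list(y.index)
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        species = list(tree.tip_labels)
    n = yv.size
    Xm = _design(X, n)
    if isinstance(Xm.index, pd.Index) and not Xm.index.equals(pd.RangeIndex(n)):
        Xm = Xm.loc[species]
    Xv = Xm.to_numpy(dtype=float)
    if n < Xv.shape[1] + 3:
        raise ValueError("too few complete cases for the design")
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("singular design matrix")
    C = (cov or phylo_covariance(tree)).reorder(species).matrix

    def fit_at(lam):
        return _gls(yv, Xv, _lambda_transform(C, lam))

    if lambda_ == "estimated":
        res = scipy.optimize.minimize_scalar(
            lambda lam: -fit_at(lam)[3], bounds=(0.0, 1.0), method="bounded"
        )
        lam = float(res.x)
    else:
        lam = float(lambda_)
        if not 0 <= lam <= 1:
            raise ValueError("lambda must be in [0, 1]")
    beta, covb, sigma2, ll = fit_at(lam)
    se = np.sqrt(np.diag(covb))
    tstat = beta / se
    df = n - Xv.shape[1]
    pvals = 2 * scipy.stats.t.sf(np.abs(tstat), df)
    names = list(Xm.columns)
    return RegressionFit(
        coefficients=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        p_values=pd.Series(pvals, index=names),
        sigma2=sigma2,
        family="gaussian",
        n=n,
        method="pgls",
        lambda_=lam,
        log_likelihood=ll,
    )


def hpd_interval(x: np.ndarray, prob: float = 0.95) -> tuple:
    """Shortest interval containing ``prob`` of the samples."""
    xs = np.sort(np.asarray(x))
    n = xs.size
    m = max(int(np.ceil(prob * n)), 2)
    widths = xs[m - 1 :] - xs[: n - m + 1]
    i = int(np.argmin(widths))
    return float(xs[i]), float(xs[i + m - 1])


def _truncnorm_sample(rng, mean, low, high):
    """Vectorized inverse-CDF truncated normal (unit variance)."""
    a = scipy.stats.norm.cdf(low - mean)
    b = scipy.stats.norm.cdf(high - mean)
    u = rng.uniform(np.minimum(a, b), np.maximum(a, b))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return mean + scipy.stats.norm.ppf(u)


def bpmm_fit(
    y,
    X,
    trees,
    family: str = "gaussian",
    iterations: int = 6000,
    burn_in: int = 1000,
    thinning: int = 5,
    seed: int = 0,
    n_chains: int = 2,
    tree_block: int = 500,
) -> RegressionFit:
    """Bayesian phylogenetic mixed model by Gibbs sampling.

    gaussian: y = Xb + u + e with phylogenetic random effect u ~ N(0, s_p^2 C).
    threshold-binary / threshold-ordinal: probit latent-variable augmentation
    with residual variance fixed at 1.  TreeSets are handled by cycling trees
    every ``tree_block`` iterations.  pMCMC = 2 * min(P(b>0), P(b<0)).
    """
    if family not in ("gaussian", "threshold-binary", "threshold-ordinal"):
        raise ValueError(f"unknown family {family!r}")
    if isinstance(trees, Phylogeny):
        trees = TreeSet([trees])
    if isinstance(y, pd.Series):
        species = list(y.index)
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        species = list(trees[0].tip_labels)
    n = yv.size
    Xm = _design(X, n)
    if not Xm.index.equals(pd.RangeIndex(n)):
        Xm = Xm.loc[species]
    Xv = Xm.to_numpy(dtype=float)
    p = Xv.shape[1]
    names = list(Xm.columns)

    if family == "threshold-binary" and set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("threshold-binary response must be 0/1")
    if family == "threshold-ordinal":
        cats = np.unique(yv)
        if not np.array_equal(cats, np.arange(cats.size)):
            yv = np.searchsorted(cats, yv).astype(float)
        n_cat = int(yv.max()) + 1
        if n_cat < 3:
            family = "threshold-binary"

    eigs = []
    for t in trees:
        C = phylo_covariance(t).reorder(species).matrix
        d, U = np.linalg.eigh(C)
        d = np.clip(d, 1e-10, None)
        eigs.append((d, U))

    a0 = b0 = 0.001  # weak inverse-gamma priors on variance components
    all_chains = []
    for chain in range(n_chains):
        rng = np.random.default_rng((seed, chain, 0xB9))
        beta = np.zeros(p)
        sp2, se2 = 1.0, 1.0
        latent = yv.astype(float).copy()
        if family != "gaussian":
            latent = np.where(yv > 0, 0.5, -0.5).astype(float)
            se2 = 1.0
        cuts = None
        if family == "threshold-ordinal":
            cuts = np.concatenate([[-np.inf, 0.0], np.arange(1, n_cat - 1, dtype=float), [np.inf]])
        ti = 0
        d, U = eigs[ti]
        v = np.zeros(n)
        rows = []
        for it in range(iterations):
            if len(eigs) > 1 and it % tree_block == 0:
                ti = int(rng.integers(len(eigs)))
                d, U = eigs[ti]
            target = latent if family != "gaussian" else yv
            z = U.T @ target
            Xs = U.T @ Xv
            # fixed effects with the phylogenetic effect integrated out:
            # z | beta ~ N(Xs beta, diag(sp2*d + se2)) in the eigenbasis,
            # which avoids the beta-u confounding that stalls mixing
            Vi = sp2 * d + se2
            Xw = Xs / Vi[:, None]
            XtX = Xs.T @ Xw + np.eye(p) * 1e-8
            cov_b = np.linalg.inv(XtX)
            cov_b = (cov_b + cov_b.T) / 2.0
            beta = rng.multivariate_normal(cov_b @ (Xw.T @ z), cov_b, method="cholesky")
            # phylogenetic effect in the eigenbasis (diagonal prior)
            mu_res = z - Xs @ beta
            prec = d * sp2
            varv = prec * se2 / (prec + se2)
            v = rng.normal(mu_res * prec / (prec + se2), np.sqrt(varv))
            # variance components
            sp2 = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * np.sum(v**2 / d)))
            if family == "gaussian":
                resid = z - Xs @ beta - v
                se2 = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * np.sum(resid**2)))
            else:
                mu = Xv @ beta + U @ v
                if family == "threshold-binary":
                    low = np.where(yv > 0, 0.0, -np.inf)
                    high = np.where(yv > 0, np.inf, 0.0)
                else:
                    low = cuts[yv.astype(int)]
                    high = cuts[yv.astype(int) + 1]
                    # cutpoint updates (Albert & Chib style uniform draws)
                    for c in range(2, n_cat):
                        lo = max(latent[yv == c - 1].max(initial=cuts[c - 1]), cuts[c - 1])
                        hi = min(latent[yv == c].min(initial=cuts[c + 1]), cuts[c + 1])
                        if hi > lo:
                            cuts[c] = rng.uniform(lo, hi)
                latent = _truncnorm_sample(rng, mu, low, high)
            if it >= burn_in and (it - burn_in) % thinning == 0:
                rows.append([*beta, sp2, se2, ti])
        cols = [*names, "sigma2_phylo", "sigma2_resid", "tree_index"]
        all_chains.append(pd.DataFrame(rows, columns=cols))

    pooled = pd.concat(all_chains, ignore_index=True)
    psrf = None
    converged = True
    if n_chains >= 2:
        psrf = pd.Series(
            {
                c: gelman_rubin([ch[c].to_numpy() for ch in all_chains])
                for c in names + ["sigma2_phylo"]
            }
        )
        converged = bool((psrf.fillna(1.0) <= 1.1).all())
    post_b = pooled[names]
    m = len(pooled)
    pmcmc = {}
    ci = {}
    for c in names:
        s = post_b[c].to_numpy()
        pos = max((s > 0).sum(), 1) / m
        neg = max((s < 0).sum(), 1) / m
        pmcmc[c] = min(2 * min(pos, neg), 1.0)
        ci[c] = hpd_interval(s)
    return RegressionFit(
        coefficients=post_b.mean(),
        se=post_b.std(),
        p_values=None,
        sigma2=float(pooled["sigma2_resid"].mean()),
        family=family,
        n=n,
        method="bpmm",
        pmcmc=pd.Series(pmcmc),
        ci=pd.DataFrame(ci, index=["lower", "upper"]).T,
        posterior=pooled,
        sigma2_phylo=float(pooled["sigma2_phylo"].mean()),
        converged=converged,
        psrf=psrf,
    )


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor (split-free, classic formulation)."""
    if len(chains) < 2:
        raise ValueError("need at least 2 chains")
    arr = np.array([np.asarray(c, dtype=float) for c in chains])
    m, length = arr.shape
    if length < 10:
        raise ValueError("chains too short for PSRF")
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = length * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (length - 1) / length * W + B / length
    return float(np.sqrt(var_hat / W))


# --------------------------------------------------------------------------
# path analysis
# --------------------------------------------------------------------------
@dataclass
class CausalDAG:
    """A candidate causal structure over trait names."""

    edges: Sequence[tuple]
    nodes: Sequence[str] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes or [])
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"causal model {self.name or self.edges} is cyclic")
        self.graph = g

    @property
    def trait_names(self) -> list:
        return list(self.graph.nodes)

    def parents(self, v: str) -> list:
        return sorted(self.graph.predecessors(v))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def basis_set(dag: CausalDAG) -> list:
    """d-separation basis: one claim per non-adjacent pair.

    Each claim is ``(earlier, later, conditioning_set)`` with the pair ordered
    by topological position and the conditioning set equal to the parents of
    the later node.
    """
    order = list(nx.topological_sort(dag.graph))
    pos = {v: i for i, v in enumerate(order)}
    claims = []
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if dag.graph.has_edge(a, b) or dag.graph.has_edge(b, a):
                continue
            claims.append((a, b, tuple(dag.parents(b))))
    claims.sort(key=lambda c: (pos[c[0]], pos[c[1]]))
    return claims


def fisher_c(p_values: Sequence[float]) -> tuple:
    """Fisher's C = -2 sum(ln p) with df = 2k and a chi-square upper tail."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return 0.0, 0, 1.0
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]; clip zeros explicitly upstream")
    C = float(-2.0 * np.log(ps).sum())
    df = 2 * ps.size
    return C, df, float(scipy.stats.chi2.sf(C, df))


def cicc(C: float, q: int, n: int) -> float:
    """CICc = C + 2q * n / (n - q - 1)."""
    if n <= q + 1:
        raise ValueError(f"sample size {n} too small for {q} parameters")
    return float(C + 2.0 * q * n / (n - q - 1.0))


@dataclass
class PathModelComparison:
    table: pd.DataFrame  # per model: C, df, p, q, CICc, dCICc, weight
    claims: dict  # model name -> claim-level DataFrame
    averaged_coefficients: pd.Series  # edge "a->b" -> averaged standardized coef
    best: str
    per_tree: list = field(default_factory=list)  # per-tree comparison tables


def _claim_pvalue(table: pd.DataFrame, claim, tree, lambda_) -> float:
    a, b, cond = claim
    X = table[list(cond) + [a]]
    fit = pgls_fit(table[b], X, tree, lambda_=lambda_)
    return float(np.clip(fit.p_values[a], 1e-300, 1.0))


def _path_coefficients(dag: CausalDAG, table: pd.DataFrame, tree, lambda_) -> dict:
    coefs = {}
    for v in dag.trait_names:
        parents = dag.parents(v)
        if not parents:
            continue
        fit = pgls_fit(table[v], table[parents], tree, lambda_=lambda_)
        for par in parents:
            coefs[f"{par}->{v}"] = float(fit.coefficients[par])
    return coefs


def compare_path_models(
    dags: Sequence[CausalDAG],
    table: pd.DataFrame,
    trees,
    lambda_: float | str = 1.0,
    standardize: bool = True,
) -> PathModelComparison:
    """Rank candidate causal models by CICc using phylogenetic d-sep tests.

    Claims are tested with PGLS; path coefficients of models within
    dCICc <= 2 of the best are weight-averaged (CICc weights, z-scored traits).
    With a TreeSet the full comparison is repeated per tree and the first
    tree's table is reported as primary.
    """
    if len(dags) < 2:
        raise ValueError("need at least 2 candidate models")
    traits = sorted({v for d in dags for v in d.trait_names})
    missing = set(traits) - set(table.columns)
    if missing:
        raise ValueError(f"table lacks trait column(s): {sorted(missing)}")
    if isinstance(trees, Phylogeny):
        trees = TreeSet([trees])

    results = []
    for t_i, tree in enumerate(trees):
        labels = tree.tip_labels
        sub = table.loc[labels, traits].astype(float)
        if sub.isna().any().any():
            raise ValueError("missing trait values among tree tips")
        if standardize:
            sub = (sub - sub.mean()) / sub.std(ddof=0)
        n = len(sub)
        rows = []
        claim_tables = {}
        for d_i, dag in enumerate(dags):
            name = dag.name or f"model_{d_i}"
            claims = basis_set(dag)
            pvals = [_claim_pvalue(sub, c, tree, lambda_) for c in claims]
            C, df, pC = fisher_c(pvals)
            q = dag.n_edges
            rows.append(
                {"model": name, "C": C, "df": df, "p": pC, "q": q, "CICc": cicc(C, q, n)}
            )
            claim_tables[name] = pd.DataFrame(
                [
                    {"independent": f"{a} _||_ {b}", "given": ", ".join(s) or "-", "p": p}
                    for (a, b, s), p in zip(claims, pvals)
                ]
            )
        tab = pd.DataFrame(rows).set_index("model")
        tab["dCICc"] = tab["CICc"] - tab["CICc"].min()
        w = np.exp(-0.5 * tab["dCICc"])
        tab["weight"] = w / w.sum()
        tab = tab.sort_values("CICc")
        best = tab.index[0]
        close = tab.index[tab["dCICc"] <= 2.0]
        wsub = tab.loc[close, "weight"]
        wsub = wsub / wsub.sum()
        acc: dict = {}
        for name in close:
            dag = next(d for d_i, d in enumerate(dags) if (d.name or f"model_{d_i}") == name)
            for edge, coef in _path_coefficients(dag, sub, tree, lambda_).items():
                acc.setdefault(edge, 0.0)
                acc[edge] += wsub[name] * coef
        results.append(
            {
                "table": tab,
                "claims": claim_tables,
                "avg": pd.Series(acc).sort_index(),
                "best": best,
            }
        )
    primary = results[0]
    return PathModelComparison(
        table=primary["table"],
        claims=primary["claims"],
        averaged_coefficients=primary["avg"],
        best=primary["best"],
        per_tree=[r["table"] for r in results],
    )
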