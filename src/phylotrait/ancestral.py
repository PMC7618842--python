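"""Ancestral state reconstruction, transition counting across tree sets,
continuous-trait ancestral estimates, and transition-context contrasts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .phylo_io import Phylogeny, TreeSet
from .mk_engine.likelihood import tip_partials, root_weights
from .mk_engine.ratematrix import RateMatrix

__all__ = [
    "NodeStateProbabilities",
    "TransitionEvent",
    "TransitionCountSummary",
    "TransitionContext",
    "marginal_asr",
    "summarize_root",
    "count_transitions",
    "sample_history",
    "ancestral_continuous",
    "transition_context_compare",
]


@dataclass
class NodeStateProbabilities:
    """Per-node marginal state probabilities (rows sum to 1)."""

    probs: np.ndarray  # (n_nodes, k_observed)
    tree: Phylogeny

    def __post_init__(self) -> None:
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("node probability vectors must sum to 1")

    @property
    def root_probabilities(self) -> np.ndarray:
        return self.probs[self.tree.root]

    def max_states(self) -> np.ndarray:
        return self.probs.argmax(axis=1)

    def to_frame(self) -> pd.DataFrame:
        k = self.probs.shape[1]
        df = pd.DataFrame(self.probs, columns=[f"state_{i}" for i in range(k)])
        df.index.name = "node"
        return df


def _edge_P(Q: np.ndarray, tree: Phylogeny) -> np.ndarray:
    n = tree.n_nodes
    k = Q.shape[0]
    P = np.empty((n, k, k))
    for u in range(n - 1):
        P[u] = scipy.linalg.expm(Q * tree.edge_length[u])
    P[tree.root] = np.eye(k)
    return np.clip(P, 0.0, None)


def _up_partials(tree: Phylogeny, part: np.ndarray, P: np.ndarray) -> np.ndarray:
    up = part.copy()
    for u in range(tree.n_nodes):
        if tree.is_tip[u]:
            continue
        acc = np.ones(P.shape[1])
        for c in tree.children_of(u):
            acc = acc * (P[c] @ up[c])
        m = acc.max()
        if m <= 0:
            raise ValueError("impossible tip data under this model")
        up[u] = acc / m
    return up


def marginal_asr(
    tree: Phylogeny,
    tip_states: Mapping,
    Q: RateMatrix,
    root_mode="flat",
    collapse: np.ndarray | None = None,
) -> NodeStateProbabilities:
    """Marginal per-node state probabilities by combined up/down pruning.

    ``collapse`` maps expanded (hidden-class) states to observed states; the
    returned marginals are summed within each observed state.
    """
    k = Q.k
    part = tip_partials(tree, tip_states, k)
    P = _edge_P(Q.q, tree)
    up = _up_partials(tree, part, P)
    w = root_weights(Q, root_mode, k)
    n = tree.n_nodes
    down = np.zeros((n, k))
    down[tree.root] = w
    # preorder: root-1 .. 0 plus root handled; iterate parents before children
    for u in range(n - 1, -1, -1):
        if tree.is_tip[u]:
            continue
        kids = tree.children_of(u)
        msgs = [P[c] @ up[c] for c in kids]
        for ci, c in enumerate(kids):
            out = down[u].copy()
            for cj, msg in enumerate(msgs):
                if cj != ci:
                    out = out * msg
            dc = out @ P[c]
            s = dc.sum()
            down[c] = dc / s if s > 0 else dc
    marg = down * up
    marg = marg / marg.sum(axis=1, keepdims=True)
    if collapse is not None:
        k_obs = int(collapse.max()) + 1
        out = np.zeros((n, k_obs))
        for s in range(k):
            out[:, collapse[s]] += marg[:, s]
        marg = out
    return NodeStateProbabilities(probs=marg, tree=tree)


def summarize_root(root_vectors: Sequence[np.ndarray]) -> pd.DataFrame:
    """Mean and 95% quantile interval of per-tree root state probabilities."""
    if len(root_vectors) == 0:
        raise ValueError("need at least one root vector")
    arr = np.asarray(root_vectors, dtype=float)
    return pd.DataFrame(
        {
            "mean": arr.mean(axis=0),
            "ci_lower": np.quantile(arr, 0.025, axis=0),
            "ci_upper": np.quantile(arr, 0.975, axis=0),
        },
        index=[f"state_{i}" for i in range(arr.shape[1])],
    )


@dataclass
class TransitionEvent:
    tree_index: int
    parent: int
    child: int
    from_state: int
    to_state: int
    method: str  # joint-reconstruction | stochastic-map


@dataclass
class TransitionCountSummary:
    mean_counts: np.ndarray  # (k, k) mean per-tree counts
    per_tree: np.ndarray  # (n_trees, k, k)
    events: list  # TransitionEvent list (joint method)
    n_trees: int
    method: str

    def mean(self, i: int, j: int) -> float:
        return float(self.mean_counts[i, j])

    def ci(self, i: int, j: int) -> tuple:
        vals = self.per_tree[:, i, j]
        return float(np.quantile(vals, 0.025)), float(np.quantile(vals, 0.975))

    def gains_losses(self) -> tuple:
        """(gains, losses) means for a binary trait (0->1 gain, 1->0 loss)."""
        return self.mean(0, 1), self.mean(1, 0)


def sample_history(
    tree: Phylogeny,
    tip_states: Mapping,
    Q: RateMatrix,
    root_mode="flat",
    seed: int = 0,
    rng=None,
):
    """One stochastic map: node states by backward sampling, edge paths by
    uniformization conditioned on the endpoints.  Returns (node_states, counts)."""
    rng = rng if rng is not None else np.random.default_rng((seed, 0x5A4))
    k = Q.k
    part = tip_partials(tree, tip_states, k)
    P = _edge_P(Q.q, tree)
    up = _up_partials(tree, part, P)
    n = tree.n_nodes
    state = np.zeros(n, dtype=int)
    w = root_weights(Q, root_mode, k)
    pr = w * up[tree.root]
    state[tree.root] = rng.choice(k, p=pr / pr.sum())
    for u in range(n - 2, -1, -1):
        i = state[tree.parent[u]]
        pr = P[u][i] * up[u]
        s = pr.sum()
        if s <= 0:
            raise ValueError("zero-probability branch in stochastic map")
        state[u] = rng.choice(k, p=pr / s)
    counts = np.zeros((k, k), dtype=int)
    omega = max(-Q.q.diagonal().min(), 1e-12) * 1.05
    R = np.eye(k) + Q.q / omega
    for u in range(n - 1):
        a, b = state[tree.parent[u]], state[u]
        t = tree.edge_length[u]
        _count_path(rng, R, omega, t, a, b, P[u][a, b], counts)
    return state, counts


def _count_path(rng, R, omega, t, a, b, p_ab, counts):
    """Sample jump count and intermediate states along one edge (uniformization)."""
    k = R.shape[0]
    if t <= 0 or p_ab <= 0:
        if a != b:
            counts[a, b] += 1
        return
    lam = omega * t
    # sample number of uniformized jumps N | endpoints
    u = rng.random()
    log_pois = -lam
    Rpow = [np.eye(k)]
    cum = 0.0
    N = 0
    target = u * p_ab
    for n_j in range(0, 600):
        if n_j > 0:
            Rpow.append(Rpow[-1] @ R)
            log_pois += np.log(lam) - np.log(n_j)
        term = np.exp(log_pois) * Rpow[n_j][a, b]
        cum += term
        if cum >= target or n_j >= 599:
            N = n_j
            break
    # sample the chain at the N jump points
    s = a
    for m in range(1, N + 1):
        back = Rpow[N - m]
        pr = R[s] * back[:, b]
        tot = pr.sum()
        if tot <= 0:
            s_new = b
        else:
            s_new = rng.choice(k, p=pr / tot)
        if s_new != s:
            counts[s, s_new] += 1
        s = s_new


def count_transitions(
    trees,
    tip_states: Mapping,
    Q_per_tree,
    root_mode="flat",
    method: str = "joint",
    n_maps: int = 10,
    seed: int = 0,
) -> TransitionCountSummary:
    """Count state transitions per tree, averaged across the TreeSet.

    ``Q_per_tree`` is one RateMatrix, a list (one per tree), or a callable
    ``tree -> RateMatrix`` (e.g. a per-tree ML refit).  Method ``joint``
    assigns each node its max-marginal state and counts discordant edges;
    ``stochastic-map`` averages exact event counts over ``n_maps`` sampled
    histories (multiple hits included).
    """
    if isinstance(trees, Phylogeny):
        trees = TreeSet([trees])
    if method not in ("joint", "stochastic-map"):
        raise ValueError(f"unknown method {method!r}")
    per_tree = []
    events = []
    k = None
    for t_i, tree in enumerate(trees):
        if callable(Q_per_tree):
            Q = Q_per_tree(tree)
        elif isinstance(Q_per_tree, (list, tuple)):
            Q = Q_per_tree[t_i]
        else:
            Q = Q_per_tree
        k = Q.k
        if method == "joint":
            asr = marginal_asr(tree, tip_states, Q, root_mode=root_mode)
            st = asr.max_states()
            counts = np.zeros((k, k))
            for u in range(tree.n_nodes - 1):
                a, b = st[tree.parent[u]], st[u]
                if a != b:
                    counts[a, b] += 1
                    events.append(
                        TransitionEvent(t_i, int(tree.parent[u]), int(u), int(a), int(b), "joint-reconstruction")
                    )
        else:
            rng = np.random.default_rng((seed, t_i, 0x3A9))
            counts = np.zeros((k, k))
            for _ in range(n_maps):
                _, c = sample_history(tree, tip_states, Q, root_mode=root_mode, rng=rng)
                counts += c
            counts /= n_maps
        per_tree.append(counts)
    per_tree = np.asarray(per_tree)
    return TransitionCountSummary(
        mean_counts=per_tree.mean(axis=0),
        per_tree=per_tree,
        events=events,
        n_trees=len(trees),
        method=method,
    )


def ancestral_continuous(tree: Phylogeny, tip_values) -> pd.DataFrame:
    """Brownian-motion GLS estimates of internal node values with SEs.

    The root estimate equals the GLS phylogenetic mean; sigma^2 uses the
    REML-flavoured (n-1) denominator.
    """
    if isinstance(tip_values, pd.Series):
        order = {lab: i for i, lab in enumerate(tree.tip_labels)}
        y = np.empty(tree.n_tips)
        for lab, v in tip_values.items():
            y[order[lab]] = float(v)
        if len(tip_values) != tree.n_tips:
            raise ValueError("tip_values must cover every tip")
    else:
        y = np.asarray(tip_values, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 tips")
    C = tree.mrca_depth_matrix()
    if np.linalg.matrix_rank(C) < n:
        raise ValueError("degenerate tree covariance")
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Cinv @ one
    mu = float(one @ Cinv @ y / denom)
    resid = y - mu
    sigma2 = float(resid @ Cinv @ resid / max(n - 1, 1))

    depth = tree.node_depths()
    sets = tree.descendant_tip_sets()
    tips = tree.tip_ids
    pos = {int(t): i for i, t in enumerate(tips)}
    rows = []
    Cr = Cinv @ resid
    Ci1 = Cinv @ one
    for u in range(tree.n_nodes):
        if tree.is_tip[u]:
            rows.append((u, float(y[pos[u]]), 0.0, True))
            continue
        # cov(node u, tip j) = depth of deepest ancestor of u containing j
        cvec = np.empty(n)
        inside = [pos[t] for t in sets[u]]
        cvec[inside] = depth[u]
        anc = u
        remaining = set(range(n)) - set(inside)
        while remaining and tree.parent[anc] >= 0:
            anc = tree.parent[anc]
            newly = [pos[t] for t in sets[anc] if pos[t] in remaining]
            cvec[newly] = depth[anc]
            remaining -= set(newly)
        est = mu + cvec @ Cr
        var = sigma2 * (
            depth[u] - cvec @ Cinv @ cvec + (1.0 - cvec @ Ci1) ** 2 / denom
        )
        rows.append((u, float(est), float(np.sqrt(max(var, 0.0))), False))
    df = pd.DataFrame(rows, columns=["node", "estimate", "se", "is_tip"]).set_index("node")
    df.attrs["sigma2"] = sigma2
    df.attrs["phylogenetic_mean"] = mu
    return df


@dataclass
class TransitionContext:
    mode: str
    difference: float | None  # mean contrast across trees; None if no transitions
    per_tree: list
    ci: tuple | None
    n_transitions: int

    @property
    def empty(self) -> bool:
        return self.n_transitions == 0


def transition_context_compare(
    transitions: Sequence[TransitionEvent],
    node_values: Mapping[int, pd.DataFrame],
    trees,
    mode: str = "origin-vs-nonorigin",
    direction: tuple | None = None,
) -> TransitionContext:
    """Contrast a continuous trait around discrete-trait transitions.

    mode 'origin-vs-nonorigin': value at parent nodes of transition edges minus
    the mean over all other internal nodes.  mode 'before-vs-after': parent
    minus child value on each transition edge.  ``node_values`` maps tree index
    -> output of :func:`ancestral_continuous`.  ``direction`` optionally
    restricts to (from_state, to_state) transitions.  Per-tree contrasts are
    aggregated as mean plus a 95% quantile interval.
    """
    if mode not in ("origin-vs-nonorigin", "before-vs-after"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(trees, Phylogeny):
        trees = TreeSet([trees])
    ev = [
        e
        for e in transitions
        if direction is None or (e.from_state, e.to_state) == direction
    ]
    if not ev:
        return TransitionContext(mode=mode, difference=None, per_tree=[], ci=None, n_transitions=0)
    diffs = []
    for t_i in sorted({e.tree_index for e in ev}):
        tree = trees[t_i]
        vals = node_values[t_i]["estimate"]
        tev = [e for e in ev if e.tree_index == t_i]
        if mode == "before-vs-after":
            d = float(np.mean([vals[e.parent] - vals[e.child] for e in tev]))
        else:
            origin = sorted({e.parent for e in tev})
            internal = [u for u in range(tree.n_nodes) if not tree.is_tip[u]]
            other = [u for u in internal if u not in set(origin)]
            if not other:
                continue
            d = float(vals[origin].mean() - vals[other].mean())
        diffs.append(d)
    if not diffs:
        return TransitionContext(mode=mode, difference=None, per_tree=[], ci=None, n_transitions=len(ev))
    ci = (float(np.quantile(diffs, 0.025)), float(np.quantile(diffs, 0.975)))
    return TransitionContext(
        mode=mode,
        difference=float(np.mean(diffs)),
        per_tree=diffs,
        ci=ci,
        n_transitions=len(ev),
    )
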