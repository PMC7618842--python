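"""Simulators with recorded ground truth: trees, discrete and continuous traits,
causally linked trait sets, and a study-like dataset emulator.

Every generator is fully determined by its seed and records a TRUTH block
(exact event tallies, true node values, generating DAG) for downstream tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo_io import Phylogeny, TreeSet
from .mk_engine.ratematrix import RateMatrix
from .regression_paths import CausalDAG

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_discrete",
    "simulate_continuous_bm",
    "simulate_causal_traits",
    "jitter_tree_set",
    "generate_study_like_dataset",
    "sequential_rate_matrix",
]


@dataclass
class SimulatedDataset:
    tree: Phylogeny
    tip_data: pd.DataFrame
    truth: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Knobs for the study-like generator; the seed determines everything."""

    seed: int = 0
    n_tips: int = 300
    birth: float = 1.0
    death: float = 0.0
    n_trees: int = 20
    jitter_sd: float = 0.1
    category_freqs: Sequence[float] = (0.08, 0.12, 0.47, 0.33)
    mixing_scale: float = 40.0  # stationary-chain speed (changes per tree depth)
    colony_size_slope: float = 0.6  # log10 colony size per category step
    colony_size_sd: float = 0.35
    dimorphism_slope: float = 0.5
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.birth <= self.death:
            raise ValueError("birth rate must exceed death rate")
        f = np.asarray(self.category_freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("category_freqs must be 4 positive values summing to 1")


def simulate_tree(n_tips: int, birth: float, death: float = 0.0, seed: int = 0) -> Phylogeny:
    """Birth–death tree conditioned on ``n_tips`` extant tips (ultrametric).

    Forward simulation from two root lineages; when the extant count first
    reaches ``n_tips`` the tree is extended by the waiting time to the next
    event, so the expected Yule depth is sum_{k=2..n} 1/(birth*k).
    Extinct-before-n replicates are rejected and retried.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if death >= birth:
        raise ValueError("death rate must be below birth rate")
    rng = np.random.default_rng((seed, 0x7EE))
    for _attempt in range(10_000):
        # active lineages: (parent_slot, birth_time); build edge list
        parent: list = [-1, 0, 0]  # node 0 = root placeholder; re-indexed later
        start = [0.0, 0.0, 0.0]
        end: list = [None, None, None]
        alive = [1, 2]
        t = 0.0
        ok = True
        while len(alive) < n_tips:
            k = len(alive)
            rate = k * (birth + death)
            t += rng.exponential(1.0 / rate)
            u = alive[int(rng.integers(k))]
            if rng.random() < birth / (birth + death):
                for _ in range(2):
                    parent.append(u)
                    start.append(t)
                    end.append(None)
                    alive.append(len(parent) - 1)
                alive.remove(u)
                end[u] = t
            else:
                alive.remove(u)
                end[u] = t
                if len(alive) < 2:
                    ok = False
                    break
        if not ok:
            continue
        t += rng.exponential(1.0 / (len(alive) * (birth + death)))
        for u in alive:
            end[u] = t
        return _assemble_tree(parent, start, end, set(alive))
    raise RuntimeError("birth-death simulation failed to reach target tip count")


def _assemble_tree(parent, start, end, alive) -> Phylogeny:
    """Prune extinct lineages and emit the postordered Phylogeny."""
    n = len(parent)
    children: list = [[] for _ in range(n)]
    for u in range(1, n):
        children[parent[u]].append(u)

    new_parent: list = []
    new_length: list = []
    new_labels: list = []
    counter = [0]

    def emit(child_ids, length, label):
        nid = len(new_parent)
        new_parent.append(-1)
        new_length.append(length)
        new_labels.append(label)
        for c in child_ids:
            new_parent[c] = nid
        return nid

    def build(u, extra_len):
        """Returns new node id or None if subtree fully extinct."""
        length = (end[u] - start[u]) + extra_len
        if not children[u]:
            if u in alive:
                counter[0] += 1
                return emit([], length, f"t{counter[0]}")
            return None
        kids = [build(c, 0.0) for c in children[u]]
        kids = [kk for kk in kids if kk is not None]
        if not kids:
            return None
        if len(kids) == 1:
            new_length[kids[0]] += length
            return kids[0]
        return emit(kids, length, None)

    kids = [build(c, 0.0) for c in children[0]]
    kids = [kk for kk in kids if kk is not None]
    root = emit(kids, 0.0, None)
    new_length[root] = 0.0
    return Phylogeny(np.array(new_parent, dtype=np.int64), np.array(new_length), new_labels)


def simulate_discrete(
    tree: Phylogeny,
    Q: RateMatrix,
    root_dist: Sequence[float] | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Evolve a k-state trait along the tree by exponential waiting times.

    Truth block records per-node states, every transition event (edge, i->j)
    and exact i->j tallies.
    """
    k = Q.k
    pi = (
        Q.stationary_distribution()
        if root_dist is None
        else np.asarray(root_dist, dtype=float)
    )
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("root distribution must sum to 1")
    rng = np.random.default_rng((seed, 0xD15C))
    n = tree.n_nodes
    state = np.zeros(n, dtype=int)
    state[tree.root] = rng.choice(k, p=pi)
    counts = np.zeros((k, k), dtype=int)
    events = []
    for u in range(n - 2, -1, -1):  # preorder (parents have larger ids)
        s = state[tree.parent[u]]
        t_left = tree.edge_length[u]
        while True:
            rate = -Q.q[s, s]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= t_left:
                break
            t_left -= wait
            probs = Q.q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s_new = rng.choice(k, p=probs)
            counts[s, s_new] += 1
            events.append((int(tree.parent[u]), int(u), int(s), int(s_new)))
            s = s_new
        state[u] = s
    tips = tree.tip_ids
    df = pd.DataFrame(
        {"state": state[tips]}, index=[tree.labels[i] for i in tips]
    )
    truth = {
        "node_states": state,
        "events": events,
        "transition_counts": counts,
        "root_state": int(state[tree.root]),
        "n_changes": int(counts.sum()),
    }
    return SimulatedDataset(tree=tree, tip_data=df, truth=truth)


def simulate_continuous_bm(
    tree: Phylogeny, sigma2: float, root_value: float = 0.0, seed: int = 0
) -> SimulatedDataset:
    """Brownian motion: child = parent + Normal(0, sigma2 * branch length)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng((seed, 0xB33))
    n = tree.n_nodes
    vals = np.zeros(n)
    vals[tree.root] = root_value
    for u in range(n - 2, -1, -1):
        vals[u] = vals[tree.parent[u]] + rng.normal(
            0.0, np.sqrt(sigma2 * tree.edge_length[u])
        )
    tips = tree.tip_ids
    df = pd.DataFrame({"value": vals[tips]}, index=[tree.labels[i] for i in tips])
    return SimulatedDataset(
        tree=tree,
        tip_data=df,
        truth={"node_values": vals, "sigma2": sigma2, "root_value": root_value},
    )


def simulate_causal_traits(
    tree: Phylogeny,
    dag: CausalDAG,
    coefficients: Mapping[tuple, float],
    noise: float | Mapping[str, float] = 1.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Traits built in causal order: each = sum(coef * parent trait) + BM noise.

    The linear combination acts on full node-level values, so every trait is
    itself a phylogenetically structured process.
    """
    import networkx as nx

    order = list(nx.topological_sort(dag.graph))
    node_vals = {}
    rng = np.random.default_rng((seed, 0xCA5A))
    for trait in order:
        sd2 = noise[trait] if isinstance(noise, Mapping) else float(noise)
        bm = simulate_continuous_bm(
            tree, sigma2=sd2, root_value=0.0, seed=int(rng.integers(2**31 - 1))
        )
        vals = bm.truth["node_values"].copy()
        for par in dag.parents(trait):
            b = coefficients.get((par, trait), coefficients.get(f"{par}->{trait}", 0.0))
            vals = vals + b * node_vals[par]
        node_vals[trait] = vals
    tips = tree.tip_ids
    labels = [tree.labels[i] for i in tips]
    df = pd.DataFrame({tr: node_vals[tr][tips] for tr in order}, index=labels)
    return SimulatedDataset(
        tree=tree,
        tip_data=df,
        truth={"node_values": node_vals, "dag": dag, "coefficients": dict(coefficients)},
    )


def jitter_tree_set(
    tree: Phylogeny, n_trees: int, sd: float = 0.1, seed: int = 0
) -> TreeSet:
    """Posterior-style TreeSet: lognormal multiplicative branch-length noise
    on a fixed topology (topological uncertainty is out of scope)."""
    rng = np.random.default_rng((seed, 0x117))
    trees = []
    for _ in range(n_trees):
        t = tree.copy()
        mult = rng.lognormal(mean=-0.5 * sd**2, sigma=sd, size=t.n_nodes)
        t.edge_length = t.edge_length * mult
        t.edge_length[t.root] = 0.0
        trees.append(t)
    return TreeSet(trees, provenance="posterior-sample", method_label="jittered")


def sequential_rate_matrix(freqs: Sequence[float], scale: float = 1.0) -> RateMatrix:
    """Adjacent-only (1<->2<->3<->4) reversible chain with stationary ``freqs``.

    Detailed balance: q[i,i+1] = scale * freqs[i+1], q[i+1,i] = scale * freqs[i].
    """
    f = np.asarray(freqs, dtype=float)
    k = f.size
    off = np.zeros((k, k))
    for i in range(k - 1):
        off[i, i + 1] = scale * f[i + 1]
        off[i + 1, i] = scale * f[i]
    return RateMatrix.from_offdiagonal(off)


def generate_study_like_dataset(config: SimulationConfig = SimulationConfig()):
    """Emulate the study's data shape: a jittered posterior TreeSet plus a
    species table with a 4-category trait, correlated log10 colony size,
    a continuous dimorphism measure and binary-ready queen traits.

    Returns ``(TreeSet, SpeciesTable, truth)``.
    """
    cfg = config
    rng = np.random.default_rng((cfg.seed, 0x5DA))
    tree = simulate_tree(cfg.n_tips, cfg.birth, cfg.death, seed=cfg.seed)
    depth = tree.node_depths()[tree.tip_ids].mean()
    # fast-mixing sequential chain => tip categories near the target marginal
    Q = sequential_rate_matrix(cfg.category_freqs, scale=cfg.mixing_scale / depth)
    disc = simulate_discrete(tree, Q, root_dist=cfg.category_freqs, seed=cfg.seed + 1)
    cat_nodes = disc.truth["node_states"]  # 0-based

    # colony size follows the category along the tree plus BM noise
    bm = simulate_continuous_bm(tree, sigma2=cfg.colony_size_sd**2, seed=cfg.seed + 2)
    log_colony_nodes = 3.0 + cfg.colony_size_slope * (cat_nodes - cat_nodes.mean()) + bm.truth["node_values"]

    dim_bm = simulate_continuous_bm(tree, sigma2=cfg.noise_sd**2, seed=cfg.seed + 3)
    dimorphism_nodes = (
        1.8
        + cfg.dimorphism_slope * (log_colony_nodes - log_colony_nodes.mean())
        + dim_bm.truth["node_values"]
    )

    qn_bm = simulate_continuous_bm(tree, sigma2=0.4, seed=cfg.seed + 4)
    mf_bm = simulate_continuous_bm(tree, sigma2=0.4, seed=cfg.seed + 5)

    tips = tree.tip_ids
    labels = [tree.labels[i] for i in tips]
    queen_number = np.round(np.exp(0.3 + qn_bm.truth["node_values"][tips])).clip(1, None)
    mating_freq = np.exp(0.4 + 0.25 * mf_bm.truth["node_values"][tips]).clip(1, None)
    table = pd.DataFrame(
        {
            "repro_potential": cat_nodes[tips] + 1,
            "realised_repro": rng.choice(
                ["none", "male_only"], size=len(tips), p=[0.95, 0.05]
            ),
            "confidence": rng.choice(
                ["described", "inferred"], size=len(tips), p=[0.7, 0.3]
            ),
            "colony_size": np.round(10 ** log_colony_nodes[tips]).clip(1, None),
            "queen_number": queen_number,
            "mating_frequency": mating_freq,
            "dimorphism": np.clip(dimorphism_nodes[tips], 0.5, None),
            "excluded_flags": "",
        },
        index=pd.Index(labels, name="species_id"),
    )
    trees = jitter_tree_set(tree, cfg.n_trees, sd=cfg.jitter_sd, seed=cfg.seed + 6)
    truth = {
        "base_tree": tree,
        "category_nodes": cat_nodes,
        "log_colony_nodes": log_colony_nodes,
        "dimorphism_nodes": dimorphism_nodes,
        "discrete_truth": disc.truth,
        "config": cfg,
    }
    return trees, table, truth
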