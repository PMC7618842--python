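"""Phylogeny containers, Newick/NEXUS I/O, branch scaling and tree/table alignment.

Trees are stored as flat arrays in postorder: every child id is smaller than
its parent's id and the root is always the last node.  This layout feeds the
likelihood kernels directly and makes traversals trivial (`range(n_nodes)` is
a valid postorder).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "TreeSet",
    "TreeParseError",
    "parse_trees",
    "write_trees",
    "scale_branch_lengths",
    "prune_to_shared_taxa",
]


class TreeParseError(ValueError):
    """Raised when a tree file cannot be read or violates an invariant."""


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths, stored in postorder arrays.

    Attributes
    ----------
    parent:
        ``parent[u]`` is the parent id of node ``u``; ``-1`` for the root.
    edge_length:
        Length of the branch above each node (``0.0`` for the root).
    labels:
        Node labels; tips must be labelled, internal labels optional (``None``).
    """

    parent: np.ndarray
    edge_length: np.ndarray
    labels: list

    _children_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.edge_length = np.asarray(self.edge_length, dtype=np.float64)
        n = self.parent.shape[0]
        if self.edge_length.shape[0] != n or len(self.labels) != n:
            raise ValueError("parent, edge_length and labels must have equal length")
        if np.sum(self.parent < 0) != 1 or self.parent[n - 1] != -1:
            raise TreeParseError("tree must have exactly one root, stored last")
        if np.any(self.parent[:-1] <= np.arange(n - 1)) and np.any(
            self.parent[:-1] < 0
        ):
            raise TreeParseError("multiple roots found")
        if np.any(self.parent[:-1] <= np.arange(n - 1)):
            raise TreeParseError("node ids must be postordered (child < parent)")
        if np.any(self.edge_length < 0):
            raise TreeParseError("negative branch length")
        tips = self.tip_ids
        tip_labels = [self.labels[i] for i in tips]
        if any(lab is None for lab in tip_labels):
            raise TreeParseError("all tips must be labelled")
        dupes = {lab for lab in tip_labels if tip_labels.count(lab) > 1}
        if dupes:
            raise TreeParseError(f"duplicated tip label(s): {sorted(dupes)}")

    # -- structure -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def _children(self) -> tuple:
        if self._children_cache is None:
            n = self.n_nodes
            counts = np.zeros(n, dtype=np.int64)
            for u in range(n - 1):
                counts[self.parent[u]] += 1
            start = np.zeros(n + 1, dtype=np.int64)
            start[1:] = np.cumsum(counts)
            flat = np.zeros(n - 1, dtype=np.int64)
            fill = start[:-1].copy()
            for u in range(n - 1):
                p = self.parent[u]
                flat[fill[p]] = u
                fill[p] += 1
            self._children_cache = (flat, start)
        return self._children_cache

    @property
    def children_flat(self) -> np.ndarray:
        return self._children()[0]

    @property
    def children_start(self) -> np.ndarray:
        return self._children()[1]

    @property
    def is_tip(self) -> np.ndarray:
        start = self.children_start
        return (start[1:] - start[:-1]) == 0

    @property
    def tip_ids(self) -> np.ndarray:
        return np.nonzero(self.is_tip)[0]

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_ids]

    def tip_index(self) -> dict:
        """Map tip label -> node id."""
        return {self.labels[i]: int(i) for i in self.tip_ids}

    def children_of(self, u: int) -> np.ndarray:
        flat, start = self._children()
        return flat[start[u] : start[u + 1]]

    # -- geometry ------------------------------------------------------------
    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for u in range(self.n_nodes - 2, -1, -1):
            depth[u] = depth[self.parent[u]] + self.edge_length[u]
        return depth

    def total_length(self) -> float:
        return float(self.edge_length[:-1].sum())

    def mean_edge_length(self) -> float:
        return float(self.edge_length[:-1].mean())

    def descendant_tip_sets(self) -> list:
        """Per node, the frozenset of descendant tip ids (tips contain themselves)."""
        sets: list = [None] * self.n_nodes
        is_tip = self.is_tip
        for u in range(self.n_nodes):
            if is_tip[u]:
                sets[u] = frozenset((u,))
            else:
                acc: set = set()
                for c in self.children_of(u):
                    acc |= sets[c]
                sets[u] = frozenset(acc)
        return sets

    def patristic_distances(self) -> pd.DataFrame:
        """Tip-to-tip path-length matrix, labelled by tip name."""
        depth = self.node_depths()
        mrca_depth = self.mrca_depth_matrix()
        tips = self.tip_ids
        d = depth[tips][:, None] + depth[tips][None, :] - 2 * mrca_depth
        np.fill_diagonal(d, 0.0)
        labs = self.tip_labels
        return pd.DataFrame(d, index=labs, columns=labs)

    def mrca_depth_matrix(self) -> np.ndarray:
        """Matrix of root-to-MRCA depths for every tip pair (tip order)."""
        tips = self.tip_ids
        pos = {int(t): i for i, t in enumerate(tips)}
        depth = self.node_depths()
        n = len(tips)
        out = np.zeros((n, n))
        sets = self.descendant_tip_sets()
        # deepest node containing both tips wins; visit in postorder so
        # shallower (more rootward) nodes only fill still-empty cells
        filled = np.zeros((n, n), dtype=bool)
        for u in range(self.n_nodes):
            if self.is_tip[u]:
                i = pos[u]
                out[i, i] = depth[u]
                filled[i, i] = True
                continue
            kids = self.children_of(u)
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = [pos[t] for t in sets[kids[a]]]
                    ib = [pos[t] for t in sets[kids[b]]]
                    out[np.ix_(ia, ib)] = depth[u]
                    out[np.ix_(ib, ia)] = depth[u]
        return out

    # -- conversion ----------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, index: int = 0) -> "Phylogeny":
        nodes = list(dtree.postorder_node_iter())
        ids = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n)
        labels: list = [None] * n
        for nd in nodes:
            i = ids[id(nd)]
            if nd.parent_node is not None:
                parent[i] = ids[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeParseError(
                        f"tree {index}: missing branch length (all analyses require lengths)"
                    )
                length[i] = float(nd.edge.length)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label is not None:
                labels[i] = nd.label
            elif nd.is_leaf():
                raise TreeParseError(f"tree {index}: unlabelled tip")
        return cls(parent, length, labels)

    def to_dendropy(
        self, taxon_namespace: dendropy.TaxonNamespace | None = None
    ) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for u in range(self.n_nodes - 1):
            dnodes[self.parent[u]].add_child(dnodes[u])
            dnodes[u].edge.length = float(self.edge_length[u])
        for u, lab in enumerate(self.labels):
            if lab is None:
                continue
            if self.is_tip[u]:
                dnodes[u].taxon = tns.require_taxon(label=lab)
            else:
                dnodes[u].label = lab
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.seed_node = dnodes[self.root]
        tree.is_rooted = True
        return tree

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True, rooting="force-rooted"
        )
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip()

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.edge_length.copy(), list(self.labels))


@dataclass
class TreeSet:
    """An ordered collection of trees sharing a tip-label set."""

    trees: list
    provenance: str = "posterior-sample"  # posterior-sample | mcc-consensus
    method_label: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeParseError("TreeSet cannot be empty")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    def harmonized(self) -> bool:
        ref = set(self.trees[0].tip_labels)
        return all(set(t.tip_labels) == ref for t in self.trees)


def parse_trees(
    path, format: str = "newick", provenance: str = "posterior-sample"
) -> TreeSet:
    """Read every tree in a Newick or NEXUS (TREES block) file.

    Branch lengths are required on every non-root edge; underscores in
    unquoted labels are preserved verbatim (matching is exact-string).
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown format: {format!r}")
    try:
        dtrees = dendropy.TreeList.get(
            path=str(path),
            schema=format,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeParseError(f"could not parse {path} as {format}: {exc}") from exc
    if len(dtrees) == 0:
        raise TreeParseError(f"no trees found in {path}")
    trees = []
    for i, dt in enumerate(dtrees):
        try:
            trees.append(Phylogeny.from_dendropy(dt, index=i))
        except TreeParseError as exc:
            raise TreeParseError(f"tree {i}: {exc}") from exc
    return TreeSet(trees, provenance=provenance)


def write_trees(treeset: TreeSet | Phylogeny, path, format: str = "newick") -> None:
    if isinstance(treeset, Phylogeny):
        treeset = TreeSet([treeset])
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in treeset:
        tl.append(t.to_dendropy(taxon_namespace=tns))
    kwargs = {"unquoted_underscores": True}
    if format == "newick":
        kwargs["suppress_rooting"] = True
    tl.write(path=str(path), schema=format, **kwargs)


def scale_branch_lengths(tree: Phylogeny, target_mean: float) -> Phylogeny:
    """Rescale all branches by one constant so their mean equals ``target_mean``."""
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    mean = tree.mean_edge_length()
    if mean <= 0:
        raise ValueError("tree has zero total branch length; cannot scale")
    out = tree.copy()
    out.edge_length = out.edge_length * (target_mean / mean)
    return out


def prune_to_shared_taxa(tree: Phylogeny, table: pd.DataFrame):
    """Restrict a tree and a species table to their shared species.

    The table index (or a ``species_id`` column) holds species labels. Degree-2
    internal nodes created by pruning are collapsed with branch lengths summed;
    a unary root is kept so root-to-tip path lengths are unchanged.
    """
    if "species_id" in table.columns:
        table = table.set_index("species_id")
    keep = [lab for lab in tree.tip_labels if lab in set(table.index)]
    if not keep:
        raise ValueError("tree and table share no species")
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} shared species; at least 3 required for comparative analysis"
        )
    pruned = prune_to_tips(tree, keep)
    return pruned, table.loc[pruned.tip_labels]


def prune_to_tips(tree: Phylogeny, keep_labels: Iterable[str]) -> Phylogeny:
    keep = set(keep_labels)
    missing = keep - set(tree.tip_labels)
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    n = tree.n_nodes
    # reduced[u] = list of (child_new_id, edge_len) surviving below u
    new_parent: list = []
    new_length: list = []
    new_labels: list = []

    def emit(children: list, length: float, label) -> int:
        """children: list of (new_id, ...) already emitted; returns new id."""
        nid = len(new_parent)
        new_parent.append(-1)
        new_length.append(length)
        new_labels.append(label)
        for c in children:
            new_parent[c] = nid
        return nid

    # survive[u]: None (drop), ("pass", new_id, accumulated_len) or emitted node
    carry: list = [None] * n
    for u in range(n):
        if tree.is_tip[u]:
            if tree.labels[u] in keep:
                nid = emit([], float(tree.edge_length[u]), tree.labels[u])
                carry[u] = (nid, float(tree.edge_length[u]))
            continue
        kids = [carry[c] for c in tree.children_of(u) if carry[c] is not None]
        if not kids:
            continue
        if len(kids) == 1 and u != tree.root:
            # suppress unary: extend the child's edge upward
            cid, clen = kids[0]
            clen += float(tree.edge_length[u])
            new_length[cid] = clen
            carry[u] = (cid, clen)
        else:
            nid = emit(
                [cid for cid, _ in kids], float(tree.edge_length[u]), tree.labels[u]
            )
            carry[u] = (nid, float(tree.edge_length[u]))
    root_id = len(new_parent) - 1
    new_length[root_id] = 0.0
    return Phylogeny(
        np.array(new_parent, dtype=np.int64),
        np.array(new_length),
        new_labels,
    )
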