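import numpy as np
import pytest

from phylotrait.phylo_io import Phylogeny
from phylotrait.mk_engine import RateMatrix


@pytest.fixture
def four_tip_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:0.3,B:0.4):0.2,(C:0.5,D:0.1):0.6);")


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    return Phylogeny.from_newick("(A:1,(B:0.5,C:0.5):0.5);")


@pytest.fixture
def star_tree_5() -> Phylogeny:
    return Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def q4_random() -> RateMatrix:
    rng = np.random.default_rng(42)
    off = rng.uniform(0.1, 1.0, (4, 4))
    return RateMatrix.from_offdiagonal(off)


def random_rate_matrix(rng, k: int) -> RateMatrix:
    off = rng.uniform(0.05, 1.5, (k, k))
    # sprinkle structural zeros sometimes
    if rng.random() < 0.3:
        mask = rng.random((k, k)) < 0.3
        off = np.where(mask, 0.0, off)
    return RateMatrix.from_offdiagonal(off)


def random_small_tree(rng, n_tips: int) -> Phylogeny:
    """Random coalescent-ish topology with uniform branch lengths."""
    labels = [f"s{i}" for i in range(n_tips)]
    parent = []
    length = []
    labs = []
    ids = []
    for lab in labels:
        parent.append(-1)
        length.append(float(rng.uniform(0.05, 1.2)))
        labs.append(lab)
        ids.append(len(parent) - 1)
    while len(ids) > 1:
        k = 2 if len(ids) == 2 or rng.random() < 0.8 else 3
        pick = list(rng.choice(len(ids), size=min(k, len(ids)), replace=False))
        merged = [ids[i] for i in pick]
        for i in sorted(pick, reverse=True):
            ids.pop(i)
        parent.append(-1)
        length.append(float(rng.uniform(0.05, 1.2)))
        labs.append(None)
        nid = len(parent) - 1
        for c in merged:
            parent[c] = nid
        ids.append(nid)
    length[ids[0]] = 0.0
    return Phylogeny(np.array(parent), np.array(length), labs)
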