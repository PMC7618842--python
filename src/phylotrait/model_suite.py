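"""Named model comparisons: ordered 4-state transition models, correlated
binary-trait evolution (dependent vs independent product chains), and
hidden-rate-class scans ranked by AIC."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo_io import Phylogeny, TreeSet, prune_to_tips
from .trait_prep import BinaryTrait
from .mk_engine import (
    ConstraintMap,
    MCMCSettings,
    PriorSpec,
    SteppingStoneSettings,
    bayes_factor,
    fit_ml,
    mcmc_sample,
    stepping_stone_log_marginal,
)

__all__ = [
    "ModelComparisonTable",
    "multistate_model_specs",
    "compare_transition_models",
    "pagel_discrete_test",
    "independent_constraint",
    "dependent_constraint",
    "hidden_rate_scan",
    "hidden_constraint",
]


def multistate_model_specs() -> dict:
    """The four candidate 4-state transition models.

    FREE: all 12 rates free.  SEQUENTIAL: only adjacent transitions
    (1<->2<->3<->4), non-sequential rates fixed to zero.
    SEQUENTIAL_PLUS_1to4: sequential plus a free 1->4 rate.
    INTERMEDIATE_SHARED: adjacent rates free, all non-sequential transitions
    pooled into one shared (rarer) rate class.
    """
    k = 4
    nonseq = [(i, j) for i in range(k) for j in range(k) if i != j and abs(i - j) > 1]
    seq = ConstraintMap(k=k, labels={c: "zero" for c in nonseq}, name="SEQUENTIAL")
    plus = dict.fromkeys(nonseq, "zero")
    plus[(0, 3)] = "free"
    seq_plus = ConstraintMap(k=k, labels=plus, name="SEQUENTIAL_PLUS_1to4")
    inter = ConstraintMap(
        k=k, labels={c: "shared:nonseq" for c in nonseq}, name="INTERMEDIATE_SHARED"
    )
    free = ConstraintMap.all_free(k, name="FREE")
    return {
        "FREE": free,
        "SEQUENTIAL": seq,
        "SEQUENTIAL_PLUS_1to4": seq_plus,
        "INTERMEDIATE_SHARED": inter,
    }


@dataclass
class ModelComparisonTable:
    models: pd.DataFrame  # name, description, n_free, lnml
    pairs: pd.DataFrame  # simple, complex, bf, label
    winner: str
    repeats: dict = field(default_factory=dict)  # name -> list of lnml repeats

    def bf(self, complex_name: str, simple_name: str) -> float:
        lnml = self.models["lnml"]
        return 2.0 * (lnml[complex_name] - lnml[simple_name])


def _median_lnml(trees, tip_states, constraint, prior, ss, seed, root_mode, n_repeats):
    vals = []
    for r in range(n_repeats):
        ml = stepping_stone_log_marginal(
            trees, tip_states, constraint, prior=prior, ss=ss,
            seed=seed + 1000 * r, root_mode=root_mode,
        )
        vals.append(ml.log_ml)
    return float(np.median(vals)), vals


def compare_transition_models(
    trees,
    categories: Mapping[str, int],
    prior: PriorSpec = PriorSpec(),
    ss_settings: SteppingStoneSettings = SteppingStoneSettings(),
    seed: int = 0,
    n_repeats: int = 1,
    root_mode="flat",
    specs: Mapping[str, ConstraintMap] | None = None,
) -> ModelComparisonTable:
    """Stepping-stone lnML for every candidate model plus pairwise Bayes factors.

    ``categories`` maps species -> 1..4.  Pairs are ordered simple-vs-complex
    (fewer free rates first); the winner is the model with the highest lnML.
    """
    observed = set(categories.values())
    if len(observed) < 2:
        raise ValueError("only one observed category; no information to compare models")
    bad = observed - {1, 2, 3, 4}
    if bad:
        raise ValueError(f"categories outside 1..4: {sorted(bad)}")
    tip_states = {sp: int(c) - 1 for sp, c in categories.items()}
    specs = dict(specs or multistate_model_specs())
    rows = []
    repeats = {}
    for name, cm in specs.items():
        lnml, vals = _median_lnml(
            trees, tip_states, cm, prior, ss_settings, seed, root_mode, n_repeats
        )
        rows.append({"name": name, "description": cm.describe(), "n_free": cm.n_free, "lnml": lnml})
        repeats[name] = vals
    models = pd.DataFrame(rows).set_index("name")
    order = models.sort_values("n_free").index
    pairs = []
    for i, simple in enumerate(order):
        for cx in order[i + 1 :]:
            if models.loc[cx, "n_free"] <= models.loc[simple, "n_free"]:
                continue
            res = bayes_factor(models.loc[cx, "lnml"], models.loc[simple, "lnml"])
            pairs.append({"simple": simple, "complex": cx, "bf": res.bf, "label": res.label})
    winner = models["lnml"].idxmax()
    return ModelComparisonTable(
        models=models, pairs=pd.DataFrame(pairs), winner=winner, repeats=repeats
    )


# --------------------------------------------------------------------------
# correlated evolution (product chain over two binary traits)
# --------------------------------------------------------------------------
# product states: 0=(0,0), 1=(0,1), 2=(1,0), 3=(1,1); trait A is the first bit
_DOUBLE = [(0, 3), (3, 0), (1, 2), (2, 1)]


def independent_constraint() -> ConstraintMap:
    """4 free rates: each trait's gain/loss ignores the other trait's state."""
    labels = dict.fromkeys(_DOUBLE, "zero")
    labels.update(
        {
            (0, 2): "shared:qA01", (1, 3): "shared:qA01",
            (2, 0): "shared:qA10", (3, 1): "shared:qA10",
            (0, 1): "shared:qB01", (2, 3): "shared:qB01",
            (1, 0): "shared:qB10", (3, 2): "shared:qB10",
        }
    )
    return ConstraintMap(k=4, labels=labels, name="independent")


def dependent_constraint() -> ConstraintMap:
    """8 free single-change rates; simultaneous double changes are impossible."""
    return ConstraintMap(k=4, labels=dict.fromkeys(_DOUBLE, "zero"), name="dependent")


def _binary_values(trait) -> dict:
    if isinstance(trait, BinaryTrait):
        return dict(trait.values)
    return {k: int(v) for k, v in dict(trait).items()}


def pagel_discrete_test(
    trees,
    trait_a,
    trait_b,
    prior: PriorSpec = PriorSpec(),
    ss_settings: SteppingStoneSettings = SteppingStoneSettings(),
    seed: int = 0,
    n_repeats: int = 1,
    rate_summaries: bool = False,
    mcmc_settings: MCMCSettings | None = None,
):
    """Correlated-evolution test for two binary traits on the product chain.

    Compares a dependent model (8 single-change rates) against an independent
    model (4 tied rates) by stepping-stone Bayes factor.  Returns
    ``(BayesFactorResult, details)`` where details holds lnMLs, the species
    count and optional posterior mean rates of the dependent model.
    """
    va, vb = _binary_values(trait_a), _binary_values(trait_b)
    if isinstance(trees, Phylogeny):
        trees = TreeSet([trees])
    shared = sorted(set(va) & set(vb) & set(trees[0].tip_labels))
    if len(shared) < 4:
        raise ValueError("fewer than 4 species shared between traits and tree")
    for nm, v in (("A", va), ("B", vb)):
        states = {v[sp] for sp in shared}
        if len(states) < 2:
            raise ValueError(f"trait {nm} is constant after species matching")
    pruned = TreeSet(
        [prune_to_tips(t, shared) for t in trees],
        provenance=trees.provenance,
        method_label=trees.method_label,
    )
    tip_states = {sp: 2 * va[sp] + vb[sp] for sp in shared}
    dep, ind = dependent_constraint(), independent_constraint()
    lnml_dep, reps_dep = _median_lnml(
        pruned, tip_states, dep, prior, ss_settings, seed, "flat", n_repeats
    )
    lnml_ind, reps_ind = _median_lnml(
        pruned, tip_states, ind, prior, ss_settings, seed + 7, "flat", n_repeats
    )
    res = bayes_factor(lnml_dep, lnml_ind)
    details = {
        "lnml_dependent": lnml_dep,
        "lnml_independent": lnml_ind,
        "repeats": {"dependent": reps_dep, "independent": reps_ind},
        "n_species": len(shared),
    }
    if rate_summaries:
        chain = mcmc_sample(
            pruned,
            tip_states,
            dep,
            prior=prior,
            settings=mcmc_settings or MCMCSettings(iterations=20_000, burn_in=2_000, seed=seed),
        )
        details["posterior_mean_rates"] = chain.samples[dep.groups()].mean().to_dict()
    return res, details


# --------------------------------------------------------------------------
# hidden rate classes
# --------------------------------------------------------------------------
def hidden_constraint(k_obs: int, n_classes: int, structure: str) -> ConstraintMap:
    """Constraint on the (observed x class) expanded space.

    State index = class * k_obs + observed.  Within a class, observed-state
    transitions are one shared rate (ER) or all free (ARD); classes are linked
    by a single shared switching rate; joint state+class changes are zero.
    """
    if structure not in ("ER", "ARD"):
        raise ValueError("structure must be 'ER' or 'ARD'")
    k = k_obs * n_classes
    labels = {}
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            ca, oa = divmod(a, k_obs)
            cb, ob = divmod(b, k_obs)
            if ca == cb:
                labels[(a, b)] = f"shared:w{ca}" if structure == "ER" else "free"
            elif oa == ob:
                labels[(a, b)] = "shared:switch"
            else:
                labels[(a, b)] = "zero"
    return ConstraintMap(k=k, labels=labels, name=f"{structure}-{n_classes}class")


@dataclass
class HiddenScanResult:
    table: pd.DataFrame  # classes, structure, n_free, logL, AIC, dAIC
    best_fit: object
    best_name: str
    k_obs: int

    def collapse_map(self, n_classes: int) -> np.ndarray:
        return np.arange(self.k_obs * n_classes) % self.k_obs


def hidden_rate_scan(
    tree: Phylogeny,
    tip_states: Mapping[str, int],
    rate_cats: Sequence[int] = (1, 2, 3),
    structures: Sequence[str] = ("ER", "ARD"),
    seed: int = 0,
    root_mode="flat",
) -> HiddenScanResult:
    """Fit ER/ARD models with 1-3 hidden rate classes by ML and rank by AIC.

    Tips are ambiguous over classes; reported AICs use the expanded models'
    free-parameter counts.
    """
    k_obs = int(max(tip_states.values())) + 1
    rows = []
    fits = {}
    for nc in rate_cats:
        for st in structures:
            cm = hidden_constraint(k_obs, nc, st)
            expanded = {
                sp: frozenset(c * k_obs + int(s) for c in range(nc))
                for sp, s in tip_states.items()
            }
            fit = fit_ml(tree, expanded, cm, root_mode=root_mode, seed=seed)
            name = f"{st}-{nc}"
            fits[name] = fit
            rows.append(
                {
                    "model": name,
                    "classes": nc,
                    "structure": st,
                    "n_free": cm.n_free,
                    "logL": fit.log_likelihood,
                    "AIC": fit.aic,
                }
            )
    table = pd.DataFrame(rows).set_index("model")
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    table = table.sort_values("AIC")
    best = table.index[0]
    return HiddenScanResult(table=table, best_fit=fits[best], best_name=best, k_obs=k_obs)
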