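"""End-to-end orchestration: config validation, stage wiring, reporting.

Stages run in dependency order (prep -> models -> asr -> regressions ->
paths -> transition_context); every artifact lands in the output directory
with seed/settings provenance and completed artifacts survive a later
stage failure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phylo_io import TreeSet, parse_trees, prune_to_shared_taxa, scale_branch_lengths
from .trait_prep import binarize_repro_potential, filter_species, log10_transform
from .synthetic_data import SimulationConfig, generate_study_like_dataset
from .mk_engine import (
    ConstraintMap,
    PriorSpec,
    SteppingStoneSettings,
    fit_ml,
)
from .model_suite import compare_transition_models
from .ancestral import (
    ancestral_continuous,
    count_transitions,
    marginal_asr,
    summarize_root,
    transition_context_compare,
)
from .regression_paths import CausalDAG, bpmm_fit, compare_path_models, pgls_fit

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

ALL_STAGES = ("prep", "models", "asr", "regressions", "paths", "transition_context")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "phylotrait_out"
    trees_path: str | None = None
    trees_format: str = "newick"
    table_path: str | None = None
    simulate: dict | None = None
    stages: tuple = ALL_STAGES
    n_trees_used: int = 5
    scale_mean: float = 0.1
    ss: dict = field(default_factory=lambda: {"n_stones": 20, "iterations_per_stone": 400})
    bpmm: dict = field(default_factory=lambda: {"iterations": 3000, "burn_in": 500})
    paper_scale: bool = False
    dags: list | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        if self.simulate is None and (self.trees_path is None or self.table_path is None):
            raise ValueError(
                "config needs either a simulate block or both trees_path and table_path"
            )
        if self.paper_scale:
            self.ss = {"n_stones": 100, "iterations_per_stone": 10_000}
            self.bpmm = {"iterations": 11_000_000, "burn_in": 1_000_000, "thinning": 5_000}

    def settings_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every enabled stage and return the report bundle."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "version": __version__,
        "settings_hash": config.settings_hash(),
    }

    # ---- inputs ----------------------------------------------------------
    if config.simulate is not None:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulate)
        trees, table, truth = generate_study_like_dataset(sim_cfg)
        report["data_source"] = "simulated"
    else:
        trees = parse_trees(config.trees_path, format=config.trees_format)
        table = pd.read_csv(config.table_path, index_col=0)
        report["data_source"] = str(config.table_path)

    def _stage(name, fn):
        if name not in config.stages:
            return
        try:
            report[name] = fn()
            _dump(out / f"{name}.json", report[name])
        except Exception as exc:  # noqa: BLE001 - halt with stage name
            raise PipelineStageError(name, exc) from exc

    state: dict = {}

    def prep():
        filtered, filt_report = filter_species(table, required_fields=["repro_potential", "colony_size"])
        tree0, aligned = prune_to_shared_taxa(trees[0], filtered)
        pruned = TreeSet(
            [scale_branch_lengths(prune_to_shared_taxa(t, filtered)[0], config.scale_mean)
             for t in trees],
            provenance=trees.provenance,
        )
        state["trees"] = pruned
        state["table"] = aligned
        cats = aligned["repro_potential"].astype(int)
        dist = (cats.value_counts(normalize=True).sort_index() * 100).round(1)
        aligned.to_csv(out / "species_prepared.csv")
        return {
            "n_species": len(aligned),
            "filtered": filt_report,
            "category_percent": {int(k): float(v) for k, v in dist.items()},
        }

    def models():
        cats = state["table"]["repro_potential"].astype(int).to_dict()
        cmp_ = compare_transition_models(
            TreeSet(list(state["trees"])[: config.n_trees_used]),
            cats,
            prior=PriorSpec(0.1),
            ss_settings=SteppingStoneSettings(**config.ss),
            seed=config.seed + 11,
        )
        cmp_.models.to_csv(out / "model_comparison.csv")
        cmp_.pairs.to_csv(out / "model_pairs.csv", index=False)
        state["model_comparison"] = cmp_
        return {
            "winner": cmp_.winner,
            "lnml": cmp_.models["lnml"].to_dict(),
            "pairs": cmp_.pairs.to_dict("records"),
        }

    def asr():
        sterile = {
            sp: binarize_repro_potential(int(c), "sterility")
            for sp, c in state["table"]["repro_potential"].items()
        }
        used = list(state["trees"])[: config.n_trees_used]
        er2 = ConstraintMap.equal_rates(2)
        fits = {id(t): fit_ml(t, sterile, er2, seed=config.seed) for t in used}
        roots = [
            marginal_asr(t, sterile, fits[id(t)].rate_matrix).root_probabilities
            for t in used
        ]
        root_df = summarize_root(roots)
        counts = count_transitions(
            TreeSet(used), sterile, lambda t: fits[id(t)].rate_matrix,
            method="joint", seed=config.seed,
        )
        root_df.to_csv(out / "root_state.csv")
        state["transition_events"] = counts.events
        state["asr_trees"] = TreeSet(used)
        gains, losses = counts.gains_losses()
        return {
            "root": root_df.to_dict(),
            "mean_gains_sterility": gains,
            "mean_losses_sterility": losses,
        }

    def regressions():
        tbl = state["table"]
        y = tbl["dimorphism"].astype(float)
        x = pd.Series(log10_transform(tbl["colony_size"].astype(float).to_numpy()),
                      index=tbl.index, name="log10_colony_size")
        tree0 = state["trees"][0]
        g = pgls_fit(y, x, tree0, lambda_="estimated")
        b = bpmm_fit(y, x, state["trees"][0], family="gaussian",
                     seed=config.seed + 5, **config.bpmm)
        rows = pd.DataFrame(
            {
                "pgls_coef": g.coefficients,
                "pgls_p": g.p_values,
                "bpmm_mean": b.coefficients,
                "bpmm_pmcmc": b.pmcmc,
            }
        )
        rows.to_csv(out / "regressions.csv")
        return {
            "pgls": {"coef": g.coefficients.to_dict(), "p": g.p_values.to_dict(),
                     "lambda": g.lambda_},
            "bpmm": {"mean": b.coefficients.to_dict(), "pmcmc": b.pmcmc.to_dict(),
                     "converged": b.converged},
        }

    def paths():
        tbl = state["table"]
        pt = pd.DataFrame(
            {
                "colony": log10_transform(tbl["colony_size"].astype(float).to_numpy()),
                "repro": tbl["repro_potential"].astype(float),
                "dimorphism": tbl["dimorphism"].astype(float),
                "queens": np.log10(tbl["queen_number"].astype(float)),
            },
            index=tbl.index,
        )
        if config.dags:
            dags = [CausalDAG(edges=[tuple(e) for e in d["edges"]],
                              nodes=list(pt.columns), name=d["name"])
                    for d in config.dags]
        else:
            dags = [
                CausalDAG([("colony", "repro"), ("colony", "dimorphism")],
                          nodes=list(pt.columns), name="size_drives"),
                CausalDAG([("repro", "colony"), ("dimorphism", "colony")],
                          nodes=list(pt.columns), name="dol_drives"),
                CausalDAG([("queens", "repro"), ("colony", "dimorphism")],
                          nodes=list(pt.columns), name="queens_drive"),
            ]
        cmp_ = compare_path_models(dags, pt, state["trees"][0])
        cmp_.table.to_csv(out / "path_comparison.csv")
        return {
            "best": cmp_.best,
            "table": cmp_.table.reset_index().to_dict("records"),
            "averaged_coefficients": cmp_.averaged_coefficients.to_dict(),
        }

    def transition_context():
        events = state.get("transition_events", [])
        tbl = state["table"]
        used = state.get("asr_trees") or TreeSet(list(state["trees"])[: config.n_trees_used])
        logc = pd.Series(
            log10_transform(tbl["colony_size"].astype(float).to_numpy()), index=tbl.index
        )
        node_vals = {i: ancestral_continuous(t, logc) for i, t in enumerate(used)}
        res = {}
        for mode in ("origin-vs-nonorigin", "before-vs-after"):
            ctx = transition_context_compare(events, node_vals, used, mode=mode)
            res[mode] = {
                "difference": ctx.difference,
                "ci": ctx.ci,
                "n_transitions": ctx.n_transitions,
            }
        return res

    _stage("prep", prep)
    _stage("models", models)
    _stage("asr", asr)
    _stage("regressions", regressions)
    _stage("paths", paths)
    _stage("transition_context", transition_context)
    _dump(out / "report.json", report)
    return report


def _dump(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
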