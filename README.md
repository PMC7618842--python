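# phylotrait

Comparative phylogenetics of discrete and continuous traits:

- **Constrained Mk models** (`phylotrait.mk_engine`): k-state continuous-time
  Markov models on trees with free/zero/shared rate constraints, Felsenstein
  pruning likelihoods (numba-accelerated, with a brute-force enumeration
  oracle), ML fitting with AIC, Metropolis–Hastings MCMC with an
  exponential-rate prior under a uniform hyperprior, stepping-stone marginal
  likelihoods, and Bayes factors (`BF = 2·ΔlnML`, labelled minimal / positive /
  strong / very strong).
- **Named model comparisons** (`phylotrait.model_suite`): ordered 4-state
  transition models (FREE / SEQUENTIAL / SEQUENTIAL_PLUS_1to4 /
  INTERMEDIATE_SHARED), correlated evolution of binary trait pairs on the
  product chain (dependent vs independent, double transitions disallowed), and
  ER/ARD hidden-rate-class scans ranked by AIC.
- **Ancestral states** (`phylotrait.ancestral`): marginal reconstruction by
  two-pass pruning, cross-tree root summaries, transition counting (joint
  max-marginal and stochastic mapping by uniformization), Brownian-motion GLS
  ancestral values, and transition-context contrasts
  (origin-vs-nonorigin, before-vs-after).
- **Regression & path analysis** (`phylotrait.regression_paths`): phylogenetic
  GLS with Pagel's λ, Bayesian phylogenetic mixed models (gaussian and
  latent-threshold binary/ordinal families, pMCMC and HPD intervals,
  Gelman–Rubin diagnostics), d-separation basis sets, Fisher's C, CICc, and
  CICc-weighted model averaging of path coefficients.
- **Data handling** (`phylotrait.phylo_io`, `phylotrait.trait_prep`):
  Newick/NEXUS tree sets, branch-length scaling to a target mean, tree/table
  alignment with pruning, species filtering, the queen–worker dimorphism
  statistic (mean queen head width / minimum worker head width), log10
  transforms, and every binarization rule (median/mean center with rank
  buffer zones, fixed threshold at two, category collapses).
- **Synthetic data** (`phylotrait.synthetic_data`): seeded birth–death trees,
  discrete and Brownian trait simulators with exact event-level truth blocks,
  causally linked trait sets, and a study-like dataset generator.

## CLI

```bash
phylotrait simulate --n-tips 300 --n-trees 20 --seed 1 --outdir data/
phylotrait prep data/species.csv --require colony_size
phylotrait fit-multistate data/trees.nwk data/species.csv --column repro_potential
phylotrait test-correlated data/trees.nwk data/species.csv --trait-a a --trait-b b
phylotrait hidden-scan data/trees.nwk data/states.csv --column state
phylotrait asr data/trees.nwk data/states.csv --column state
phylotrait count-transitions data/trees.nwk data/states.csv --method stochastic-map
phylotrait transition-context data/trees.nwk data/table.csv --discrete state --continuous value
phylotrait pgls data/trees.nwk data/table.csv --response y --predictor x
phylotrait bpmm data/trees.nwk data/table.csv --response y --predictor x --family gaussian
phylotrait pathfit data/trees.nwk data/table.csv models.yaml
phylotrait run-all config.yaml
```

`run-all` takes a YAML config with either a `simulate:` block or
`trees_path:`/`table_path:` inputs, a `stages:` list, desk-scale MCMC defaults
and a `paper_scale: true` switch that restores full-length chain schedules
(100 stones × 10,000 iterations, 11M-iteration mixed-model chains).

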