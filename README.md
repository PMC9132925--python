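# seedburial

Analysis pipeline for multi-year seed-burial experiments comparing invasive
and naturalized alien herbs:

- **`seedburial.core`** — bag-level burial records with strict count
  validation, the three derived seed-fate variables (viability,
  germinability, germination), and transient / short-term / long-term
  seed-bank persistence classification.
- **`seedburial.phylo`** — Newick input, genus-level grafting of missing
  species, and the unit-diagonal phylogenetic correlation matrix used as
  random-effect structure.
- **`seedburial.pglmm`** — Bayesian phylogenetic binomial-logistic mixed
  models: per-bag (success, failure) counts on the logit scale, fixed
  effects (time crossed with invasion status, log seed mass, life form, or
  external seed-bank type), Gaussian random effects (phylogeny, species
  identity, triplet, row sequence, row number) plus a fixed-variance
  overdispersion term.  Posteriors are drawn with a custom Hamiltonian
  Monte Carlo sampler (non-centered parameterization, interweaved
  centered variance updates, exact Gibbs redistribution of the
  phylogenetic vs. species-identity split, and recentering moves along
  likelihood-flat ridges).  Summaries include Pagel's lambda per sample,
  CI-based significance, and 0-10 year posterior-predictive decline
  curves.
- **`seedburial.viability`** — probit-linear survival-equation fits
  (`nu = K_i - p / sigma`) per species, closed-form P50 (time to 50%
  viability), and group-level P50 summaries.
- **`seedburial.simulate`** — synthetic burial experiments with known
  ground truth: pure-birth phylogeny, phylogenetically correlated species
  decline parameters (`sd_phylo^2 [lambda C + (1 - lambda) I]`), a rows-of-six
  spatial layout with separated replicates, and binomial bag counts.
- **`seedburial.cli`** — `simulate` / `classify` / `analyze` / `recover`
  subcommands.

## Command-line usage

```bash
# generate a synthetic dataset (records, traits, tree, ground truth)
seedburial simulate --seed 1 --out scratch/sim

# classify seed-bank persistence only
seedburial classify --records scratch/sim/records.csv --out scratch/persistence.csv

# full analysis: fate summaries, persistence, mixed models, lambda,
# prediction curves, viability fits, group P50
seedburial analyze \
    --records scratch/sim/records.csv \
    --traits scratch/sim/traits.csv \
    --tree scratch/sim/tree.nwk \
    --models viability:status,germinability:status \
    --seed 1 --out scratch/results

# score the estimates against the generator's truth record
seedburial recover --data-dir scratch/sim --results-dir scratch/results \
    --out scratch/recovery.json
```

Chain settings default to a reduced 20,000 iterations (burn-in 2,000,
thinning 20, i.e. 900 retained samples); the full-scale configuration
(10^6 steps, burn-in 10^4, thinning 100, 9,900 retained samples) is
available via `--n-iter/--burn-in/--thin`.

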