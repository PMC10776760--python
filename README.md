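# retellchain

Analysis toolkit for serial-reproduction ("transmission chain") story
corpora: each chain is an original story (retelling index 0) plus three
ordered retellings produced either by human participants or by an LLM
account. The package covers the full analysis pipeline:

- **chain_corpus** — data model, CSV/JSONL readers/writers, validation
  (including a gibberish heuristic based on in-lexicon token fraction).
- **annotate** — tokenization (contraction splitting, "n't" → "not"),
  a self-contained rule/lexicon Penn-Treebank tagger, and bucketing into
  verb / adverb / noun / adjective / pronoun / preposition / negation /
  other categories.
- **concepts** — concept extraction at three granularities (synset via
  simplified-Lesk disambiguation against a WordNet-style JSON inventory,
  lemma, root hypernym) and per-transition survival / novelty / density
  metrics.
- **lexical_norms** — psycholinguistic norm merging (AOA, concreteness,
  valence, arousal, frequency), lemma-type preservation coding, logistic
  preservation regression with a producer × AOA interaction, and
  story-mean AOA.
- **transmission_stats** — negative-binomial word-count trends with
  producer-specific dispersions, beta-binomial part-of-speech share models
  with a binomial boundary fallback, and the negation producer × condition
  contrast.
- **affect_trend** — Bayesian linear-spine + compression model for rating
  trajectories (story offsets marginalized analytically; adaptive
  Metropolis MCMC; ROPE decisions on ±0.1 with 95% HDIs; arviz
  diagnostics with a loud R-hat failure).
- **synthetic_data** — a seeded generator for lexicons, chains (with exact
  ground-truth concept bookkeeping and closed-form expected metrics), and
  ratings drawn from the same spine/compression model, so every stage is
  testable offline.
- **pipeline / cli** — end-to-end orchestration with per-stage CSV/JSON
  outputs and a seeded, config-hashed summary report.

## CLI

```bash
# generate a synthetic corpus with ground truth
retellchain simulate --preset human --n-chains 100 --seed 7 --out simdir/

# validate a corpus (exit 0 only when clean)
retellchain validate --corpus simdir/chains.csv --inventory simdir/sim_inventory.json

# per-story and per-token annotation tables
retellchain annotate --corpus simdir/chains.csv --out annotations.csv

# transition metrics at a chosen granularity
retellchain concepts --corpus simdir/chains.csv --level synset --out metrics.csv

# Bayesian trend model on ratings
retellchain trend --ratings simdir/ratings.csv --item happiness --out trend.json

# everything, from a flat key = value config
retellchain run --config run.cfg
```

Config keys for `run`: `corpus`, `ratings`, `inventory`, `norms`,
`sim_lexicon`, `out_dir`, `gibberish_threshold`, `level`, `rating_item`,
`seed`, `mcmc_chains`, `mcmc_draws`, `mcmc_warmup`, `run_stats`,
`run_trend`. Exit codes: 0 ok, 2 configuration, 3 data/validation,
4 sampler non-convergence.

## Data fixtures

A miniature sense inventory (`retellchain/data/toy_inventory.json`,
84 synsets in a plain JSON synset-list format) and matching norm table
ship with the package so no download is required. Synthetic corpora emit
their own consistent inventory, norms, tagger lexicon, and a ground-truth
sidecar (`ground_truth.json`) with the exact concept sets placed in each
story version.
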