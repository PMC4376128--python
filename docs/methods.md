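# Methods

## Problem and model

Community Q&A archives for consumer health accumulate tens of thousands of
answered questions, and newcomers keep re-asking paraphrases of them. `simq`
retrieves archived questions similar to a new one by combining three layers
of representation:

1. **Concept annotation.** A term lexicon maps surface strings to concept
   identifiers (CUI, `C`+digits) and coarse semantic types ("Pharmacologic
   Substance", "Sign or Symptom", ...). A question is chunked into
   non-overlapping segments — recognized entities or single unmapped words —
   so "blurred eyes" and "blurry vision" collapse onto the same concept id
   even though they share no wording.
2. **Dependency semantics.** Entities are merged into single parse tokens
   and a dependency parse supplies (governor, dependent, relation) triples.
   Triples whose two endpoints both carry a semantic type become semantic
   relations; their ordered type pairs (e.g. `Functional_Concept →
   Disease_or_Syndrome`) abstract *what kind of thing acts on what kind of
   thing*, independently of wording.
3. **Binary feature sets and set similarity.** Six compositional
   representations (B bag-of-words, N normalized words, C concept ids,
   P = N + word/POS, NC = N + C, NCT = NC + type pairs) are each a *set* of
   namespaced feature strings. Similarity between questions is
   Dice `2|A∩B|/(|A|+|B|)` or binary cosine `|A∩B|/√(|A||B|)`; retrieval
   scores the whole archive exhaustively and ranks descending.

An evaluation harness reproduces the standard retrieval protocol: per-seed
confusion counts over a fixed candidate pool at a score threshold,
precision/recall/F per seed, macro-averaged over seeds (fractional mean
counts are expected). A network aggregator tallies semantic types (nodes)
and unordered type pairs (edges) over a topic category for an overview of
what the category talks about.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| similarity algorithm | `dice` | Dice generally separates paraphrases from distractors more sharply than cosine on short questions |
| retrieval threshold | 0.5 | score at/above which a candidate counts as a retrieved positive in the evaluation harness; it is a free protocol parameter, always echoed into reports |
| `k` (top-k retrieval) | 5 | presentation depth of the ranked list |
| `SynthConfig.n_clusters` | 10 | paraphrase clusters in the synthetic benchmark |
| `SynthConfig.cluster_size` | 3 | questions per cluster (1 seed + 2 relevant) |
| `SynthConfig.n_distractors` | 20 | lexically overlapping, concept-disjoint near-misses |
| `SynthConfig.synonym_rate` | 0.8 | probability that a cluster member swaps each slot's canonical surface form for a synonym |
| `SynthConfig.rng_seed` | 42 | generation is a pure function of the config |

Scores are rendered to 4 decimals but ranked at full precision. Ranking ties
break by question id ascending; category-recommendation ties break
alphabetically. Self-matches are kept unless the caller excludes them.

## Design choices where the design was open

- **Normalization.** Lowercasing plus rule-based suffix stripping
  (`-ies/-ied → -y`; `-es` after s/x/z/ch/sh; `-s` unless `-ss`; `-ed`),
  applied to a fixed point with a minimum stem length of 3 so the function
  is idempotent, with a bundled exception table that wins over the rules
  (irregular plurals, non-plural `-s` words like "arthritis", `-e`-stem
  verbs like "caused" → "cause"). Doubled-consonant restoration is not
  attempted. Lexicon terms are normalized at load, so matching happens
  entirely in normalized space.
- **Matching.** Greedy leftmost-longest dictionary matching, verified
  against a brute-force enumeration of all tilings. Ambiguous terms
  (several CUIs) resolve to the first lexicon entry; this is deterministic
  and the pipeline attempts no word-sense disambiguation.
- **Parser.** Dependency parsing is a pluggable adapter; the bundled
  adapter replays CoNLL-U fixtures keyed by question id and fails loudly on
  any token/form divergence. This keeps every result reproducible without
  pinning an external parser version. Any live parser can be dropped in by
  satisfying the same contract (each non-root token is the dependent of
  exactly one triple).
- **Type-pair features** are ordered (governor type → dependent type) and
  exclude the dependency label; the label is kept on `SemanticRelation` for
  the network module. Type *pairs* rather than through-governor triples are
  used; a triple variant would be a straightforward extension.
- **P features** are joint `normalized_form/TAG` strings added on top of N —
  the strictest reading of "normalized terms combined with POS"; weaker
  readings (separate POS features) would only dilute the sets further.
- **Empty feature sets** score 0 against everything (a question with no
  features is not similar to anything); this avoids division by zero and is
  logged. Dice/cosine of identical non-empty sets is exactly 1.
- **Macro-averaging**: metrics are averaged per seed, not pooled, which is
  why mean confusion counts are fractional.
- **Network counts** are per entity occurrence, not per distinct question,
  and edges are stored unordered.

## What the synthetic generator emulates — and what it does not

Generated questions follow a fixed six-slot subject–verb–object template
(auxiliary, possessive, subject entity, verb entity, object entity, adverb).
Every slot is a synonym group; cluster members share all three concept ids
and the verb-mediated type pattern while swapping surface forms at
`synonym_rate`, so paraphrases are word-disjoint at rate 1 and
word-identical at rate 0. Distractors reuse the canonical filler words and
the first word of a target cluster's entity terms, but all their concepts
are distractor-specific — they are lexically attractive and semantically
wrong. Templates also determine each question's dependency parse, so the
CoNLL-U fixtures cover the corpus by construction.

This reproduces the *mechanism* by which concept and type features beat
bag-of-words — synonymy collapse plus lexical decoys — under clean, separable
conditions. It does not emulate real consumer questions: no natural-language
fluency, no length/style variation, no spelling errors, no genuinely
ambiguous short queries, no concept hierarchy (a "breast lump" never needs
to match a "swelling"). Passing the benchmark therefore demonstrates that
the pipeline exploits shared concepts and type patterns as designed, not
that it reaches any particular accuracy on real archives.

## Problem sizes

The benchmark runs 10 clusters × 3 questions + 20 distractors (50 questions,
10 seeds, 40-question candidate pool) — large enough for stable mean-F
ordering across representations, small enough to regenerate from scratch on
every run. Scorer-oracle agreement is checked on 1000 random feature-set
pairs against explicit 0/1-vector arithmetic (tolerance 1e-12).

## Known limitations

- Dictionary matching only: no spelling correction, no consumer-vocabulary
  mapping, no disambiguation beyond first-entry-wins.
- No concept-importance weighting (all features are binary and equal) and
  no hierarchy-based expansion; both are natural extensions.
- The evaluation threshold is a protocol choice, not a fitted quantity;
  absolute precision/recall numbers depend on it and on the archive, so only
  the relative ordering of representations is meaningful across settings.
- Retrieval is exhaustive O(archive) per query, which is fine at desk scale
  and deliberate: no approximate-nearest-neighbor machinery.
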