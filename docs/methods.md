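# Methods

This note documents the models, parameter choices and numerical conventions
behind `fcig`, and what the synthetic benchmark does and does not establish.

## Pipeline model and assumptions

The pipeline treats core-ingredient selection as a ranked-prefix problem on
top of three graphs: a disease gene regulatory network (PPI induced on
above-mean-scored pathogenic genes), a bipartite compound–target (C-T)
network, and their merged C-T-P network (all C-T edges plus PPI edges whose
endpoints are drug targets or pathogenic genes — the minimal union that keeps
the drug and disease layers connected without importing the whole
interactome).  Underlying assumptions: gene identity is adequately captured
by uppercased symbols (no alias resolution); the PPI is undirected and
unweighted (an optional confidence cutoff is applied at load time and the
column is otherwise ignored, since merged multi-source PPIs rarely share a
confidence scale); and ADME values are taken as given, not predicted.

### BD importance and the median split

BD<sub>h</sub> = √(T<sub>h</sub> · btw<sub>h</sub>) with btw the raw
(unnormalised) Freeman betweenness over **unordered** pairs, endpoints
excluded.  Ordered-pair counting would exactly double btw and rescale every
BD by √2 — a monotone transformation that leaves rankings and the median
split unchanged; it is exposed as `ordered_pairs` for completeness, with
unordered the default.  No (m−1)(m−2)/2 normalisation is applied: selection
is rank-based, so normalisation would be inert.  Pairs in different
components contribute 0 (a 0/0 shortest-path fraction is skipped, never
propagated).  Betweenness is computed by single-source dependency
accumulation (Brandes, via networkx); correctness is anchored to a
brute-force all-shortest-paths enumeration oracle in the test suite —
exhaustive over all labeled connected graphs up to 5 nodes, the full graph
atlas up to 7 nodes, and 200 random graphs up to 12 nodes, at 1e−9.

The median split keeps every node whose BD ties the threshold.  When more
than half the nodes score 0 (forests, sparse PES graphs) the threshold is 0
and everything is selected; the code warns on this degenerate case rather
than guessing a different rule.

### Effect space

"Direct interaction" is graph distance ≤ 1 in the protein layer, and a drug
target that *is* a pathogenic gene counts (distance 0) — excluding shared
genes from the common category would discard exactly the strongest evidence
of drug–disease contact.  A pathogenic gene that is not a target but touches
one is intentionally in no category: the categories describe endpoints of
drug action, and such genes are represented through their common-target
neighbours.  Response proteins are scored on the PES-induced subgraph, not
the full C-T-P (`full_graph` overrides), because the selection is meant to
rank proteins *within* the candidate effect region.

### Contribution index

No closed form for the contribution index is standard, so the package
declares one: CI<sub>i</sub> = Σ BD(t) over ingredient *i*'s
response-protein targets — the simplest aggregation that uses the pipeline's
own importance score.  `ci_mode` offers `count` (targets only) and
`bd_fraction` (a rescaling with identical ranking).  The FCIG threshold
defaults to 0.90: the selected prefix is the first to cross 90 % cumulative
contribution.  Ties in CI are broken lexicographically by ingredient id so
results are platform-independent; raising the threshold can only grow the
prefix, and input row order never matters.

### Enrichment

Enrichment is the exact hypergeometric upper tail P[X ≥ k]; the background
defaults to the union of all GMT genes (the conservative standard when no
universe is stated) and the call is unadjusted p < 0.05 by default, with
Benjamini–Hochberg behind a flag.  The Venn retention ratio is rounded
half-up to one decimal.  "Functional similarity" between two analyses is the
Jaccard index of their enriched-term sets — a deliberately flat metric; no
GO-graph semantics are attempted.

## Synthetic data: what it emulates

The generator produces study conditions, not fitted data: no distribution is
calibrated to TCMSP/GeneCards dumps.

| parameter | default | rationale |
|---|---|---|
| `n_genes`, `attach_m` | 300, 3 | preferential-attachment interactome; heavy-tailed degrees so BD has hubs to find; desk-scale |
| `n_pathogenic` | 60 | 20 % designated disease genes; above-mean filter then recovers them plus the background's upper tail, mimicking the bloat of relevance-score cutoffs |
| `score_mean`, `score_sd`, `score_shift` | 5.0, 1.5, 5.0 | Gaussian background, > 3 sd separation for designated genes |
| `n_herbs` × `ingredients_per_herb` | 3 × 10 | compact formula; 5-ingredient planted core |
| `targets_per_core/filler_ingredient` | 20 / 4 | ~5× spread, mirroring the gap between hub ingredients (degree ~300) and the mean (~47) in real C-T networks |
| `core_target_bias` | 0.9 | probability a core target is drawn (degree-weighted) from pathogenic genes ∪ neighbours |
| `n_pathways`, `pathway_size` | 30, 15 | random-walk neighbourhoods; half seeded inside the pathogenic set |

Pathogenic genes are grown as three random-walk modules rather than sampled
uniformly or degree-weighted: uniform sets do not cluster (so no pathway can
be enriched for them), while degree-weighted sets let a handful of hubs'
neighbourhoods blanket a scale-free graph until every target is
"pathogenic-adjacent" and the PES partition collapses.  Module growth is the
standard disease-module picture and keeps both failure modes at bay.

One global seed drives ordered `SeedSequence` spawn keys per stage (PPI,
scores, formula, pathways), so adding a later stage never perturbs an
earlier one, and identical configurations are byte-identical on disk.

**What passing tests do not show.**  The benchmark plants a strong, clean
signal: cores always pass ADME, their target counts are well separated from
fillers', and the interactome is a single connected scale-free component.
Recovery of the planted core (mean recall 1.0, precision ≈ 0.83 over 20
seeds) demonstrates that the statistical machinery is implemented correctly,
not that the method would achieve those rates on real formulas, where target
maps are noisy, ADME values disputed, and the disease signal diffuse.
Similarly, at 30 annotation terms the coverage metric between
response-protein and pathogenic-gene enrichment is noisy and often low or
undefined — published coverage figures in the 80–90 % range arise from
database-scale collections with hundreds of enriched terms and are not
reproducible at this problem size.  The per-replicate permutation test of
response-protein placement is likewise nearly powerless (common targets are
pathogenic-adjacent by definition), so the suite tests that property
aggregated across 12 seeded replicates, where it holds at p ≈ 0.001.

## Numerical and I/O conventions

- Strict `>` for the above-mean pathogenic filter (all-equal scores select
  nothing); OB/DL inclusive, Caco-2 exclusive in the ADME screen — the
  retained DL = 0.18 rows in the bundled formula table fix the boundary.
- "Shared" ingredients means ≥ 2 herbs (the published shared-ingredient
  table contains two-herb rows); `min_herbs=3` gives the stricter reading.
- Rows with missing/non-numeric ADME or score fields are rejected with a
  warning, never silently passed; whitelisted ingredients bypass the ADME
  evaluation entirely.
- Problem sizes in the test suite and acceptance script (300-gene graphs,
  20-seed benchmarks, ≤ 12-node oracle graphs) are chosen so every check
  runs exactly, without sampling approximations, on a single CPU.
- Report JSON is written with sorted keys and relative paths; reruns with
  one seed are bit-identical regardless of output directory.

## Known limitations

- No alias/ID mapping; inputs must share a symbol namespace.
- The C-T-P scope rule is the minimal union; an `all-ppi` variant is not
  implemented (the induced rule is the only one the counts narrative of
  published analyses supports).
- No diffusion/propagation scoring and no subset optimisation over
  ingredients: selection is strictly the ranked-prefix rule.
- Exact betweenness only; desk-scale networks need no sampling, and the
  package refuses no input, but graphs beyond ~10⁴ nodes will be slow.
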