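# Methods

## Model and assumptions

`seedmod` discovers a gene module around a single seed gene by
combining three independent layers of evidence over a shared universe
of gene symbols:

* a **co-expression layer** — pairwise Pearson correlation of the
  provided (assumed normalised, e.g. log-scale) expression values,
  computed globally across all samples. Correlations that are undefined
  because a gene has zero variance are imputed to 0 rather than
  dropping the gene, keeping the universe stable. Gene symbols are
  matched case-sensitively; no alias resolution is attempted.
* an **interaction layer** — the unweighted union of one or more
  undirected PPI edge lists, deduplicated regardless of orientation,
  self-loops removed. Confidence/weight columns are ignored: no
  principled cross-source weighting scheme exists for merged HPRD- and
  STRING-style inputs, and the union errs on the side of recall.
* a **control-variant layer** — per-gene counts of loss-of-function
  variants in unaffected individuals. Genes absent from the table count
  as 0.

The working universe is the intersection of the co-expression and
interaction gene sets. The genome-wide total used as the denominator of
phenotype enrichment scores is a separate constant (default 19,986
protein-coding genes, Gencode GRCh38.p12): a module can only be built
from networked genes, but annotation odds are relative to the genome.

## Gene scores

For seed *s* and each non-seed gene *i*, let `r_i = |corr(i, s)|`.
Scores are percentile ranks: `s_i = rank(r_i) / m` with ties averaged,
where *m* is the number of non-seed genes, so `s_i ∈ (0, 1]` and any
strictly monotone transform of the magnitudes leaves scores unchanged.
Absolute correlation is used so that strong negative co-regulation also
counts; a signed variant would be a one-line change in
`seed_scoring.score_genes`. The seed's own score is pinned to 1 so the
seed is never disadvantaged in the module score. With no ties the
non-seed scores sum to `(m + 1) / 2` exactly.

The control-LOF filter is a hard eligibility cutoff (`max_lof`,
default 5): genes above it keep their scores (and stay in the universe
for enrichment denominators) but may not enter paths or modules. The
seed is always eligible, with a logged warning if its own count exceeds
the cap. A soft down-weighting alternative was considered and rejected
because a hard filter makes the feasibility diagnostics of a failed
seed interpretable.

## Seed pathways

A seed pathway is a simple path of `len_min`–`len_max` genes (node
count, defaults 5 and 8) in the PPI graph that contains the seed, uses
only eligible genes, and is valued by its summed gene scores. On graphs
with at most `exhaustive_threshold` eligible nodes (default 16) all
such paths are enumerated by DFS extending from both free ends (the
seed may sit anywhere along a pathway). Larger graphs use a randomized
strategy: starting from the seed, the path is repeatedly extended at
either free end to an unvisited eligible neighbour chosen with
probability proportional to its score; every prefix of admissible
length is recorded; the process restarts `n_restarts` times (default
5000). The top `K` (default 1000) paths with distinct gene sets are
kept, sorted by score with a lexicographic tie-break so output is
deterministic for a fixed rng seed.

## Module assembly

Paths are vertices of a **path graph** whose edges join paths sharing
at least `overlap_min` genes (default 1), weighted by the Jaccard
similarity of their gene sets. From every vertex, `n_walks`
weight-proportional random walks of `walk_len` steps (defaults 1 and 4)
produce candidate gene sets as unions of visited paths' genes; walks
preferentially traverse heavily overlapping paths, so candidates are
coherent neighbourhoods of the seed.

Each candidate is refined under one constraint cell
(size bounds, minimum mean |corr(g, seed)| over non-seed members,
minimum PPI density = within-module edges / C(|M|, 2), induced-subgraph
connectivity):

1. **Repair**: restrict to the seed's connected component, then
   greedily move one gene at a time — dropping the gene whose removal
   most improves the currently violated constraint while preserving
   connectivity (lowest seed-correlation for the size and co-expression
   constraints, lowest within-degree for density), or adding the
   highest-correlation frontier gene when below the size floor. If the
   repair loop stalls the candidate is infeasible.
2. **Hill-climb**: steepest-ascent over single-gene moves (add an
   eligible PPI neighbour, remove a non-seed non-articulation gene, or
   swap one for the other), accepting a move only if `S_M` strictly
   increases and every constraint stays satisfied, with ties broken by
   the lexicographically smallest gene symbol. The search is
   deterministic; the rng seed is recorded for provenance only.

Discovery sweeps a constraint grid (default: sizes
(20–40, 40–80, 60–100) × min co-expression (0.4, 0.5, 0.6) × min
density (0.05, 0.10, 0.15)) and returns the feasible module with
maximal `S_M`, ties resolved toward the smaller module and then the
lexicographically smallest gene list. Two failure modes are defined:
`no_paths` (the seed has no admissible pathway) and
`constraint_infeasible` (no feasible module under any grid cell; in
particular, a seed whose best single-gene |correlation| is below every
co-expression floor short-circuits to this failure before any search).
One master rng seed derives the per-stage path-search and random-walk
seeds through `numpy.random.SeedSequence`, making a whole discovery
reproducible bit for bit.

The mean seed co-expression constraint is defined over non-seed
members' correlation *with the seed* (the module concept is seed-centred
co-expression); an all-pairs mean would instead reward internally
coherent clusters detached from the seed.

## Enrichment statistics

**Variant classes.** Loss-of-function = {frameshift, splice-donor,
splice-acceptor, stop-gained, stop-gained-near-splice, stop-lost};
missense includes missense-near-splice; non-synonymous = LOF ∪
missense. Unknown labels map to "other" with a warning and are never
silently dropped. The CADD filter removes missense records with score
≤ threshold (default 15) or no score; other classes pass untouched.

**Contingency tables** are oriented case/control × in-/out-of-module
*mutation counts* relative to the gene universe. Counting mutations
rather than mutated individuals is the default (an individual-level
table can be assembled from the same classified records); cohort-size
imbalance is addressed by the bootstrap, not the table orientation.
The Fisher p-value is the exact central hypergeometric tail of the
top-left cell conditional on the margins (one-sided "greater" by
default, since the scientific question is enrichment); the odds ratio
is the unconditional cross-product ratio with `+inf` flagged when
`b·c = 0` and `a·d > 0` and 1 when both products vanish — no continuity
correction by default, so degenerate tables are visible rather than
smoothed.

**Permutation test**: case/control labels are permuted over samples,
preserving each sample's mutation list; the empirical p is
`(1 + #{OR_perm ≥ OR_obs}) / (n_iter + 1)` (default 5000 iterations),
which is never 0 and is super-uniform under a label-exchangeable null.
Samples with no mutation in the selected classes remain in the
permutation roster — excluding them would bias the null.

**Bootstrap** (default 20,000 iterations): individuals are resampled
with replacement within each arm; the 2.5/97.5 percentile interval of
the mean per-individual mutation count is reported. Because a variant
table only names individuals with ≥ 1 record, the full per-arm roster
can be supplied explicitly.

**Gene-group rate comparison**: per group and class, total counts per
arm are normalised by arm size; the p-value is a two-sided exact
binomial allocation test — conditional on the total count, case
mutations are Binomial(total, n_cases/(n_cases+n_controls)) under equal
per-individual rates. This conditional test avoids distributional
assumptions on the per-individual counts; an unconditional Poisson
rate-ratio test gives practically identical answers at these counts.

**Phenotype enrichment score**: `(M_P/M_P′)/(G_P/(G_total − G_P))`,
module annotation odds over genome-wide annotation odds; 0 when no
module gene is annotated, `+inf` when all are. Scale-consistent:
doubling both `M_P` and `M_P′` leaves it unchanged.

**CNV overlap**: coordinates are 0-based half-open (BED convention);
a CNV hits a gene iff the intervals intersect by ≥ 1 bp. The
contingency is case/control × (hits ≥ 1 module gene / not), with the
Fisher OR and a sample-label permutation p.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with known ground truth:

* **Expression**: planted genes share a single latent factor per
  sample, `x = √ρ_in·z + √(1−ρ_in)·ε`, so every planted pair has
  expected Pearson correlation exactly `ρ_in` — a deliberately simple
  construction whose recovery behaviour is analytically interpretable.
  Background genes are independent noise (or share their own factor at
  `ρ_bg`).
* **PPI**: independent edges at `density_in` within the planted set and
  `density_bg` elsewhere, plus a spanning path through the planted set
  so its induced subgraph is always connected.
* **Control LOF**: Poisson(0.5) per gene, with a configurable number of
  background "constraint-violating" genes inflated by a large constant.
* **Variants**: per-individual counts are Poisson (mean 1.0); classes
  follow a coding-spectrum mix (missense 0.42, LOF 0.15, synonymous
  0.28, other 0.15); genes are drawn uniformly (a per-gene weight
  vector can emulate gene-length effects) except that case
  non-synonymous mutations up-weight planted genes by
  `enrichment_factor` — synonymous and control mutations are never
  enriched, providing a built-in negative control. CADD scores are
  class-specific clipped normals (LOF ~ N(35,4), missense ~ N(15,8),
  synonymous ~ N(4,3)).
* **CNVs**: genes tiled on one synthetic chromosome (10 kb genes, 2 kb
  gaps); CNVs anchor at a gene (planted genes up-weighted by
  `cnv_case_bias` in cases) and span 1 + Poisson(2) consecutive genes.

Default scale: 500 genes × 50 samples, a 30-gene planted module with
`ρ_in = 0.9` over `ρ_bg = 0`, PPI densities 0.5 / 0.02, 1000 cases and
1000 controls, enrichment factor 5, CNV case bias 4. Stages derive
their rng streams from `(rng_seed, stage_index)`, so each output is
independently reproducible.

What the generator does **not** emulate: developmental-stage structure
in expression (correlations are stationary across samples), scale-free
PPI degree distributions, study heterogeneity and ascertainment
differences between cohorts, gene-length variation (unless configured),
and linkage between nearby genes' mutation rates. Passing the planted
benchmarks therefore demonstrates algorithmic correctness under the
model's assumptions, not performance on real atlases and variant
databases.

## Benchmarks and problem sizes

The acceptance checks (`tests/test_acceptance.py`,
`scripts/acceptance.py`) use these sizes, chosen so the full suite
runs comfortably on a single CPU:

* **Fisher oracle**: all 635,375 non-degenerate 2×2 tables with grand
  total ≤ 60 against exact integer tail sums (one-sided); all tables
  with total ≤ 30 two-sided. The two-sided tie rule (include tables
  with probability ≤ observed × (1 + 1e−7)) follows the conventional
  relative-tolerance definition.
* **Planted recovery**: 10 instances at the default generator scale;
  path search with 1000 restarts, K = 500. The benchmark grid is one
  cell — size band planted ± 10, minimum mean seed co-expression
  `ρ_in − 0.05` (one sampling-noise band below the planted correlation
  at 50 samples), density floor 0.10 — encoded as
  `simulate.benchmark_grid`. Looser co-expression floors admit
  high-ranked background bystanders and dilute recovery; this is the
  constraint the method's failure mode is built around, so the
  benchmark exercises it at its intended operating point.
* **Calibration**: 200 null replicates (enrichment factor 1) for the
  Fisher and permutation type-I error at α = 0.05 (permutations at 199
  iterations per replicate for runtime; single-module analyses default
  to 5000); 100 replicates at factor 5 for power and the synonymous
  negative control.

## Numerical choices and edge cases

* Constraint comparisons use an absolute slack of 1e−12 to absorb
  float accumulation in the incremental bookkeeping.
* Local-search and best-module ties are broken lexicographically so
  identical inputs always give identical outputs.
* Zero-variance genes correlate 0 with everything; the all-zero
  contingency table, empty bootstrap arms, empty CNV tables, and a
  phenotype annotating the whole genome are errors, not silent results.
* An absent seed raises a distinct `SeedNotInUniverseError`, separate
  from module-discovery failure.
* Duplicate expression rows collapse by mean, duplicate LOF rows by
  sum, both with warnings.

## Known limitations

* Co-expression is global across samples; per-developmental-window
  networks are a natural extension the data model already permits.
* The randomized path search offers no optimality guarantee above the
  exhaustive threshold; the stochastic-completeness test covers small
  graphs only.
* Local search is a single-trajectory steepest ascent; a basin-hopping
  or multi-start variant could escape poor candidates, at the cost of
  determinism simplicity.
* One module per seed: overlap-aware simultaneous discovery across many
  seeds is out of scope.
* Identifier harmonisation (aliases, Ensembl ↔ symbol) must happen
  upstream.
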