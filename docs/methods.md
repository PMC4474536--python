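# Methods

## Data model and exchange formats

All pipeline inputs and outputs are UTF-8 tab-separated text with a header
row (`#` lines are comments).  The association exchange table carries one
row per raw assertion: source name, free-text drug name, four optional
cross-references (compound ID, substance ID, DrugBank ID, ChEBI ID), a
target reference in one of three namespaces (`uniprot-ac`, `gene-id`,
`gene-symbol`), an NCBI taxon (0 = unknown, treated as non-human), and a
`;`-delimited list of PubMed IDs.  PubMed IDs are opaque grouping keys —
they are never validated against the literature, because the method only
uses them to group associations by supporting publication.  Readers are
loss-accounting: every input row becomes either a record or an entry in a
rejects list, never silently disappears.

## Identifier normalization

Drug unification tries, in order: (1) an explicit compound-ID
cross-reference → UID `CID:<id>`; (2) an exact synonym match against the
compound synonym table → `CID:<mapped>`; (3) fallback to the source's own
name → `NAME:<normalized name>`.  "Exact" matching uses Unicode case-fold +
trim + internal-whitespace collapse, applied exactly once when the synonym
table is loaded and once per lookup key.  Byte-exact matching would make
the synonym route nearly useless across sources that differ only in
capitalisation or spacing; anything fuzzier is out of scope (approximate
name matching and structure-based deduplication are deliberately not
attempted).  Substance/ChEBI/DrugBank references are retained as metadata
but never drive UID assignment.

Targets are normalized to gene IDs.  A UniProt accession mapping to several
genes expands the association to one per mapped human gene (the expansion
is visible to the scoring stage: the shared reference's profile then has
t > 1).  Gene symbols are resolved against the human subset of the gene
table; a symbol claimed by several gene IDs resolves to the
lexicographically smallest for determinism.  Unresolvable targets are
counted and reported, not fatal.

Purification removes associations where (1) the drug's display name is
shorter than three characters, (2) the name is purely numeric, or (3) the
resolved target is not human (taxon ≠ 9606).  Rules are evaluated in that
order on the original (pre-casefold) display name; the filter runs after
identifier resolution, so a numeric synonym that resolved to a compound ID
is still dropped by its display name.  The kept set is invariant under
input permutation.

## Scoring

For each unique (drug UID, gene ID) pair:

* **Score_S** = number of distinct sources asserting the pair.  Duplicate
  assertions within one source count once.

* **Score_R** = Σᵢ dᵢ·tᵢ/fᵢ² over the pair's distinct supporting
  references, where fᵢ counts the distinct normalized pairs reference i
  supports across the entire dataset (pooled over sources) and dᵢ, tᵢ the
  distinct drugs/targets among them.  The per-reference term
  (its *specificity*) is isolated in one function
  (`ReferenceProfile.specificity`) so an alternative reading of the
  formula would be a one-line change.  Two properties motivate this form:
  at equal f, a screen spread over many drugs or targets scores lower than
  a focused study (d·t/f² is maximal when f = d·t is small), and adding a
  reference always adds score.  Pairs with no references keep Score_R = 0
  rather than being dropped — source concordance is still informative for
  reference-free sources.

Counts d, t, f are computed over the dataset's own associations citing the
reference, not over the original publication's full content — only the
former is computable from the data model.

`stratify_by_threshold` tabulates drugs/targets/pairs and mean Score_R
(with SEM) for each Score_S threshold stratum; `score_correlation` is the
plain Pearson coefficient between the two scores over pairs (error if
either vector is constant).  Both accept an optional ATC restriction (pairs
whose drug carries ≥ 1 ATC code).

## Overlap statistic

For any two sources the overlap proportion of an entity kind (drugs,
targets, pairs) is |A∩B| / min(|A|, |B|) — the coverage of the smaller
source — reported at 3 decimals with the raw value retained.  Per-source
entity sets are taken *after* normalization, so the statistic measures true
redundancy rather than identifier collisions.

## Two-route inference

Given disease inputs (known drugs, their targets, disease genes) and a PPI
network:

* Route 1 (*shared-target*): drugs ∉ known set with ≥ 1 association
  (Score_S ≥ θ, default θ = 3) to a known target.
* Route 2 (*ppi-neighbor*): anchors are disease genes that are direct
  (1-hop) PPI neighbors of known targets, minus the known targets
  themselves — this keeps the two routes' anchor sets disjoint; candidates
  are non-known drugs with Score_S ≥ θ associations to an anchor.

The threshold applies only to the candidate→anchor association; the known
target list is taken as given.  Hop count is fixed at 1 (multi-hop
propagation is a non-goal).  A drug found by both routes keeps both labels;
per drug the best supporting association is the (Score_S, Score_R)
lexicographic maximum.  Candidate sets are monotone: raising θ can only
shrink them.

## Evaluation

A candidate is a *hit* for a condition if it has at least one row in the
trial-label table for that condition; the hit rate is reported as a
1-decimal percentage.  Matching is by UID first, then case-folded display
name (trial registries index by name).  The related-condition class (e.g.
"other mental disorders" vs the primary disease) is just a second condition
token, keeping the machinery disease-agnostic.  `sum_trials` adds up the
per-drug trial counts over hit candidates; note that a trial investigating
several candidate drugs contributes once per drug, so this sum is an
incidence count, not a count of unique trials.  `compare_configurations`
runs the full inference per configuration (threshold variants,
single-source interactomes, external interactomes at threshold 1) and
tabulates the rates; duplicate labels are rejected.  No significance
testing is attempted — the metric is a raw proportion.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, at a
scale of seconds on one CPU (defaults: 6 sources, 500 background drugs, 80
background targets, ≈ 2,000 raw assertions):

* **Multiplicity is assigned, not sampled**: each background pair gets an
  exact source multiplicity from a configured count table (default
  {1: 500, 2: 230, 3: 110, 4: 45, 5: 18, 6: 9}), emitted into that many
  sources by deterministic rotation.  The pipeline's empirical Score_S
  histogram must therefore match the planted histogram *exactly*, which is
  what the recovery tests assert.  Randomness (seeded, via
  `numpy.random.default_rng`) only places pairs on the drug×target grid,
  draws synonym noise, and wires background PPI edges.
* **Identifier heterogeneity**: sources differ in emission style (compound
  ID vs name-only; UniProt vs gene ID vs symbol), ≈ 10% of drugs have no
  compound ID anywhere (they unify by name), ≈ 20% circulate under an
  alternate synonym, and one drug's UniProt accession expands to two genes
  — so the record-linkage stage is genuinely exercised, not bypassed.
* **References**: two of the six sources carry no references (mirroring
  curated resources without literature links).  Each reference-bearing
  assertion of a background pair gets a fresh single-pair reference
  (profile f = d = t = 1), so a pair's expected Score_R equals its number
  of reference-bearing sources — computable at generation time and frozen
  into the manifest.  HTS-style references each span 10 drugs × 1 target
  (per-pair contribution 0.1); their number is set so they are ≈ 2% of all
  references — a visible minority, as in real resources.  One shared
  reference supports the two-gene expansion (per-pair contribution
  2/2² = 0.5).
* **Disease module**: known drugs/targets, anchor disease genes planted as
  PPI neighbors of known targets, non-anchor disease genes wired away from
  the neighborhood, route-1/route-2/dual-route candidate drugs planted at
  multiplicity ≥ 3, and decoy candidates at multiplicity 1–2 that appear
  only below the default threshold.  Reserved entities never occur in the
  background grid, so threshold-3 recovery is exact by construction.
* **Trial labels**: per-stratum precision (defaults 0.6/0.25/0.05 for the
  primary condition over the θ=3 / θ=2-only / θ=1-only strata; 0.8/0.4/0.1
  for the related class) assigned deterministically to the lexicographic
  prefix of each stratum, so hit rates are strictly ordered in θ.
* **Contamination**: degenerate drug names ("ab", "12345") and non-human
  target records (≈ 3% of assertions, mouse genes) exercise the three
  purification rules; two unresolvable UniProt records exercise reject
  accounting.

What the generator does **not** emulate: real chemical structures or
affinity values, correlated source biases, name misspellings requiring
fuzzy matching, and trial-registry name variants.  Passing recovery tests
therefore demonstrate the pipeline's correctness on well-posed inputs, not
robustness to dirty real-world nomenclature.

`validate_against_manifest` compares pipeline outputs to the manifest:
pair-set identity, Score_S vs planted multiplicity, Score_R vs the
constructed expectation (tolerance 1e-9), and exact candidate recovery at
θ = 3.  The same seed always yields a byte-identical output directory.

## Numerical choices

* Scores are serialized with 17 significant digits (exact float round
  trip); overlap proportions are reported at 3 decimals and percentages at
  1 decimal, with raw values retained in memory.
* Conflicting synonym→compound mappings keep the lexicographically
  smallest compound ID (logged); conflicting gene symbols likewise.
* Pearson correlation on a constant score vector raises an explicit error
  rather than returning NaN.
* Empty candidate sets yield an undefined (None) percentage with a
  warning, never a division error.

## Packaged reference tables

`windtome/data/` ships three small published count tables (source overlap
counts, the 39 trial-verified candidate drugs with per-drug trial counts,
and the per-configuration evaluation counts).  They serve as worked-example
inputs for the overlap and hit-rate arithmetic; the package never treats
them as something it could recompute, since that would require the original
database snapshots.

## Known limitations

* Reconstruction of the original full-scale interactome (hundreds of
  thousands of associations) is out of scope; correctness is established
  on published worked examples and planted-structure recovery instead.
* Single-hop PPI expansion only; no network propagation or
  structure-similarity routes.
* The published total of unique trials across the 39 trial-verified drugs
  cannot be derived from the published per-drug counts (trials testing
  several drugs are double-counted in any per-drug sum); `sum_trials`
  documents and reports the incidence sum.
* Name-based trial matching is exact after case-folding; registry synonyms
  ("acetylsalicylic acid" vs "aspirin") must be resolved upstream via the
  synonym table.
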