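# Methods

## Model and procedure

The pipeline implements a network-pharmacology workflow for a family of
structurally related natural products (here, licorice flavonoids) against a
disease gene background (hepatocellular carcinoma). Its stages are
independent library functions chained by `pipeline.run_full`:

1. **Fingerprints.** SMILES are parsed and hashed into radius-2 circular
   (Morgan/ECFP) fingerprints. Two widths coexist deliberately: 2048 bits
   feed the Dice similarity matrix, 1024 bits feed the embedding — the two
   settings the original workflow used in different steps. Chirality is
   ignored when hashing by default (one input SMILES carries an `[C@H]`
   flag; the published setting is unstated), switchable via
   `use_chirality`. Duplicate structures are detected on canonical SMILES,
   not raw text, keeping the first occurrence.
2. **Chemical-space network.** t-SNE (exact gradient, precomputed
   1 − Dice distances, random initialisation) embeds the library in 2-D.
   Edges join pairs with embedded distance strictly below θ = D_max/24.
   Clusters are connected components — the most literal reading of
   "traverse all molecules to complete the clustering" (single-linkage
   transitive closure over threshold edges).
3. **Member scores.** MWGS_i = (Σ_j S_ij − 1)/n: the member's Dice
   similarities are summed over the whole group, the self term (= 1) is
   subtracted, and the result divided by group size. The typeset source
   formula is ambiguous between this reading and a reciprocal one; the
   reciprocal would make the *least* similar member the representative,
   contradicting the surrounding text, so the subtractive reading is used.
   A singleton scores 0; (n−1)/n is attained only when all pairwise Dice
   equal 1. Closeness is computed on the full network (all components)
   with Wasserman–Faust scaling, ((k−1)/(N−1))·((k−1)/Σd), so values are
   bounded by 1 and comparable across components; isolated nodes score 0.
   The method description nominates representatives twice — by maximal
   closeness and by maximal MWGS. Both are computed and reported;
   closeness is the default selector, with MWGS then lexicographic id as
   tie-breaks.
4. **Targets.** Source score filters are strict (>), exactly as the
   published cut-offs are written (DisGeNET > 0.1, GeneCards > 5, PharmGKB
   unfiltered). The DE consensus rule behind the published up/down counts
   is not recoverable from the text; a k-of-3 vote per direction is
   exposed (`deg_consensus_k`, default 3 = three-method intersection).
   Gene identity is the uppercased symbol; no alias resolution.
5. **Hubs.** MCC is implemented from its definition, Σ (|C|−1)! over
   maximal cliques (Bron–Kerbosch with pivoting); the degree fallback for
   locally edge-free neighbourhoods emerges from the formula (each
   incident edge is a maximal 2-clique) and needs no special case.
   Singleton "cliques" are excluded, so isolated nodes score 0. The STRING
   confidence cut-off defaults to 0.4 (the database's "medium"); the
   published setting is unstated. Top-k truncation breaks ties
   lexicographically and never expands beyond k.
6. **Statistics.** The hypergeometric upper tail is summed exactly over
   rationals before conversion to float, so 10⁻²⁰-scale tails lose nothing
   to cancellation. BH is the step-up formula with suffix cummin; the
   top-rank factor is computed as `m/m` first so q ≥ p holds exactly.
   Enrichment significance is strict at both cut-offs (p < 0.01 and
   q < 0.01). The enrichment universe defaults to all annotated genes and
   can be overridden by an explicit universe file (the published choice is
   unstated). Correlation p-values use the exact t transform on S − 2
   degrees of freedom — the magnitudes in the published correlation table
   (10⁻¹⁶–10⁻²⁰) imply the parametric test, not permutation.
   Zero-variance genes are excluded from the BH adjustment and flagged.
7. **Descriptors.** No quantum chemistry is computed; the module ingests
   HOMO/LUMO tables, recomputes gaps at full precision (reporting rounds
   to 2 decimals, matching the published precision) and ranks ascending.
   The validator flags printed-vs-recomputed discrepancies beyond 0.005 eV
   (exact-at-two-decimals) and never alters the inputs; whether the two
   0.01 eV inconsistencies in the published table arose from pre-rounding
   is unknowable from the data.

## Synthetic data: what it emulates, and what it does not

The generator replaces the workflow's database retrievals with seeded
simulations whose ground truth is written to a `truth.json` sidecar.

* **Compound library** — clusters are prototype bit vectors (each bit on
  with probability `bit_density` = 0.02, so ≈ 41 of 2048 bits, the sparsity
  of small-molecule circular fingerprints) whose members flip bits
  independently with `flip_rate`; background compounds are fresh
  prototypes, keeping bit density matched rather than trivially separable.
  Defaults are 10 clusters × 8 members + 20 background (~100 compounds): a
  herb-scale library with a focal ~10-member family, the situation the
  published clustering addressed. The closed-form expected within-cluster
  Dice (ratio of per-bit expectations) is exposed as
  `expected_intra_cluster_dice` and checked by Monte Carlo.
* **Gene tables** — seven compounds with 25-gene target sets sharing
  exactly a 17-gene core (published per-compound intersections are 21–28
  genes around a 17-gene core); a fix-up pass guarantees the all-compound
  intersection equals the core. Planted genes clear their source
  thresholds and are called consistently by all three DE methods, so the
  three-way intersections recover the full planted sets; decoys fall
  strictly below thresholds or below the consensus vote.
* **PPI graph** — a planted clique (default size 6, placed on core genes)
  plus Erdős–Rényi noise edges at 0.01 over the remaining pairs of a
  100-node graph.
* **Annotation** — one term drawing 5× its null-expected share of the
  study set, among uniform-random terms.
* **Expression** — planted genes constructed as ρ·q + √(1−ρ²)·z against a
  standard-normal query (exact population correlation), default ρ = 0.45,
  the magnitude of the strongest published query correlations.

One global seed expands into independent per-stream child seeds
(compounds, genes, graph, expression, annotation) via
`numpy.random.SeedSequence.spawn`, so enlarging one stream never perturbs
another; identical configs write byte-identical files.

What the generator does **not** emulate: real chemistry (fingerprints are
sampled directly, never derived from synthetic SMILES — real-SMILES paths
are exercised by the packaged ten-compound table), gene-symbol aliasing,
correlated term annotations (GO's ontology structure), scale-free PPI
topology, and expression heteroscedasticity. Passing recovery tests
therefore show the pipeline's logic is correct under its stated model, not
that the published database snapshots would be reproduced.

## Numerical choices

* t-SNE runs with `method="exact"` and `max_iter=5000`. The exact gradient
  and long budget matter: the D_max/24 rule needs near-duplicate compounds
  to collapse to a few percent of the global extent, which the library
  default of 1000 iterations does not reliably reach on small libraries.
  Perplexity defaults to min(30, (n−1)/3); the embedding consumes the
  1024-bit fingerprints (`embedding_source="bits"`), with the 2048-bit
  Dice matrix available as the alternative the source text leaves open.
* The threshold comparison is strict (d < θ), as is every score filter.
* Deterministic orderings everywhere: clusters by smallest member id,
  hubs by (−MCC, symbol), enrichment rows by (p, term), mergesort
  throughout; all files UTF-8 TSV with a single header row.
* Degenerate inputs: two empty fingerprints are an error (0/0 Dice is
  undefined), as are < 3 compounds for embedding, < 2 for network
  construction, < 2 gene sets for a core, < 4 samples for correlation,
  E_HOMO ≥ E_LUMO, and probabilities outside [0, 1].

## Problem sizes

Default test and acceptance runs use desk-scale instances chosen to make
the planted structure unambiguous: 48–100-compound libraries, a 2000-gene
universe, 100-node graphs, 40 × 50-gene annotations over a 1000-gene
universe, 50–200-sample expression matrices; Monte-Carlo checks use
100–200 seeds. Oracle-equivalence suites run exhaustively where
enumeration is exact (all graphs ≤ 12 nodes, all hypergeometric universes
N ≤ 12).

## Known limitations

* With only the ten packaged compounds (no full supplementary library),
  the D_max/24 network is edgeless — ten mutually similar molecules spread
  by t-SNE leave no pair inside the threshold — so every compound is a
  singleton with closeness 0. Reproducing the published per-compound
  closeness values (e.g. Echinatin's 0.512) requires the full ~230-entry
  supplementary SMILES list and the original embedding seed, neither of
  which is printed in the source text.
* Background compounds can land adjacent in the embedding by chance and
  link into spurious 2-clusters; recovery metrics on default bundles are
  therefore scored on the planted (clustered) compounds.
* MCC via maximal-clique enumeration is exponential in the worst case;
  intended for the few-hundred-node graphs this workflow produces.
* Whether the published per-compound "significantly associated" targets
  were intersected with the DEG-filtered or unfiltered disease set is
  ambiguous in the source; both operands are supported
  (`compound_disease_intersection` takes any three sets).
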