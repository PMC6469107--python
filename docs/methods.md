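# Methods

`regprof` re-traces the phylogenetic history of a transcriptional regulon —
concretely, the Crl regulon of *Escherichia coli* K-12 — from a curated gene
table through homology search, reciprocal-best-hit orthology, taxonomic
profiling, and a bootstrapped distance phylogeny. This note records the
models, conventions, and numerical choices behind each stage, and what the
synthetic benchmark does and does not establish.

## The curated regulon table

Crl does not bind operator DNA; it promotes the association of the
stationary-phase sigma factor σ^S (RpoS) with RNA polymerase core. Its
"regulon" is therefore a literature-curated set of genes whose transcription
responds to Crl, each annotated with the direction of the effect (+, −, or
±), the supporting evidence classes (APPH: assay with purified protein; GEA:
gene expression analysis; MSI: mapping of signal intensities; IMP: inferred
from mutant phenotype), the transcription units (TUs) the gene belongs to,
and any co-regulating transcription factors with their own signs.

Counting conventions, fixed once and used everywhere:

* **Gene identity.** Gene records are keyed by symbol (86 records in the
  packaged table). The table intentionally preserves a duplicated locus tag
  (b0885 appears under two symbols), so *sign tallies* deduplicate by
  bnumber (85 distinct loci → 73 activated + 12 repressed), while the
  exclusive/co-regulated partition runs over symbols (24 + 62).
* **Regulator entities.** A complex printed as one token ("GadE-RcsB",
  "FlhDC", "RcsAB") counts as one regulator; a dual-sign annotation such as
  GadW(+/−) is a single edge with effect ±. The per-gene co-regulator degree
  is the number of distinct regulator names.
* **TU structure.** A TU's gene content is expanded from standard operon
  nomenclature (`csgBAC` → csgB, csgA, csgC; hyphenated segments expand
  independently). TU members outside the regulon are retained as context.
  A TU is *monogenic* when its expanded gene list has length 1; the
  percentage is rounded to the nearest integer. A gene listed under several
  TUs contributes to each TU but counts once in gene totals.

The curation choices that reconcile the table with its printed aggregate
statistics are documented in the header comments of
`src/regprof/data/table1.tsv` itself.

Functional enrichment is a one-sided hypergeometric test: for category *c*
with *K* of *N* background genes and *k* of *n* query genes, the p-value is
P(X ≥ k) for X ~ Hypergeom(N, K, n), with Benjamini–Hochberg adjustment
across categories. Category maps (GO/MultiFun) are user-supplied; no
external annotation service is queried.

## Alignment core and search statistics

Local alignment is exact Smith–Waterman and global alignment exact
Needleman–Wunsch, both with affine gaps via the Gotoh three-state
recurrence. There is no heuristic seeding or word indexing: every search is
a full quadratic DP (numba-compiled), which is the right trade-off at panel
scale and keeps the statistics exact.

* **Scoring defaults.** BLOSUM62 with gap open 11, gap extend 1; a gap run
  of length L costs `open + L·extend` (the BLAST convention — a length-1 gap
  costs 12). User matrices in NCBI text format are supported.
* **E-values.** Karlin–Altschul expectation `E = K·m·n·exp(−λS)` with the
  database size *n* fixed at 5×10⁸ residues so that E-values are comparable
  across searches regardless of the panel actually scanned. λ = 0.267 and
  K = 0.041, the standard gapped BLOSUM62/11,1 constants; all three are
  configurable on the `ScoringScheme`.
* **Coverage** is the query-side footprint `(q_end − q_start + 1)/m`.
* **Determinism.** Equal-scoring optimal alignments resolve to the smallest
  `(q_start, s_start)`, then the smallest end coordinates; the DP propagates
  path-start coordinates to implement this exactly.
* An optional low-complexity mask is deliberately **not** implemented; decoy
  sequences in the benchmark are composition-shuffled instead.

## Orthology

Orthologs are defined operationally as bidirectional best hits (BDBH): the
seed's best hit in the target genome must find the seed back as its own best
hit in the reference proteome. Both directions enforce E ≤ 10⁻⁶ and
coverage ≥ 60%; the survey-style homolog scan uses the permissive E ≤ 10⁻³
and returns *all* passing subjects, not only the best per genome. Best hits
rank by raw score with E-value and subject id as tie-breakers (E is monotone
in score at fixed lengths, so this only resolves floating-point ties).
Each seed yields at most one ortholog per genome; co-ortholog expansion is
out of scope. The coverage filter is applied in both search directions — a
symmetric-by-construction choice. An optional exact-duplicate filter drops
genomes whose protein sequence set is identical to another's; it is a
strict-identity stand-in, not a genome-similarity score.

## Profiling

The presence/absence matrix collapses to a division × gene profile:
cell (d, g) = carriers of g in d ÷ genomes in d, so 1 means universal
presence and 0 a division with no ortholog. Two clustering conventions are
implemented because the source analysis states both: **complete linkage with
uncentered correlation** (the default; uncentered correlation distance is
1 − Σxᵢyᵢ/√(Σxᵢ²Σyᵢ²), i.e. cosine distance) and **single linkage with
Pearson distance** (1 − r). Outputs record which convention produced them.
The agglomeration is deterministic: among equal minimal distances, the pair
with the lexicographically smallest original row indices merges first, and
the leaf order is purely merge-induced (no leaf-order optimization). Zero
vectors (uncentered) and zero-variance vectors (Pearson) are validation
errors naming the offending pair — a division row of all zeros means the
distance is genuinely undefined, and silently imputing it would fabricate
structure.

## Phylogeny

* **Progressive alignment.** Pairwise global alignments give p-distances; an
  average-linkage guide tree orders profile–profile merges (column score =
  mean cross-pair substitution score, gap pairs contributing 0). With two
  sequences this reduces exactly to the pairwise global alignment. No
  iterative refinement.
* **TN93 distances.** The Tamura–Nei closed form with empirical base
  frequencies pooled over each sequence pair and pairwise deletion of
  gapped/ambiguous sites. Pairs whose observed divergence makes a logarithm
  argument non-positive are flagged saturated (distance ∞) and rejected by
  tree building with the pair named. With uniform composition and equal
  transition classes the value reduces to the Kimura two-parameter formula
  (checked in the tests).
* **Neighbor joining.** Standard Saitou–Nei; exact on additive matrices.
  Negative branch-length estimates are clamped to zero and the clamped total
  logged. Tree search beyond NJ (e.g. maximum-likelihood topology search)
  is deliberately out of scope; the TN93 log-likelihood evaluator
  (Felsenstein pruning with the closed-form TN93 transition probabilities,
  missing data as all-ones partials) is provided to score candidate trees,
  and is invariant to rooting by reversibility.
* **Bootstrap.** Columns are resampled with replacement B times (default
  1000 in the CLI; tests and the acceptance script use B = 100) and the NJ
  tree rebuilt per replicate. Support for a bipartition of the full-data
  tree is the percentage of replicates containing it. A bipartition is
  *resolved* only if its branch length is positive — an alignment of
  identical sequences therefore has no supported splits rather than
  spuriously certain ones. Supports below the display threshold (default
  60%) are masked in rendered Newick output but retained on the tree.
* The TN93 model is a nucleotide model; the module therefore operates on
  coding/nucleotide sequences and the generator emits nucleotide homolog
  sets. Protein substitution models and rate heterogeneity (+Γ) are
  non-goals.

## The synthetic panel

The generator emulates the study design rather than any particular genome
set: divisions grouped into archaeal and bacterial domains (the full shape
is 18 + 69 divisions; the test profile is 5 divisions × 4 genomes, chosen so
the whole suite runs in minutes while preserving every qualitative feature),
a reference genome carrying one seed protein per family, per-(division,
family) retention probabilities creating gain/loss structure, and sequence
evolution on a random bifurcating family tree with exponential branch
lengths (mean = the divergence parameter, in expected substitutions per
site) under TN93 with rates normalized to one expected substitution per site
per unit time. Mutated codons that would become stops are re-evolved from
the parent codon, keeping translation total. Decoys are residue-shuffled
family translations: realistic composition, no positional homology, so they
exercise the E-value threshold without passing it. Defaults: 300 nt
families, 10 families, 5 decoys per genome, 50% retention in the benchmark
panels.

What passing the benchmark shows: the search, thresholds, reciprocity logic,
matrix plumbing, profiling arithmetic, and tree machinery are correct, and
recovery degrades gracefully with divergence (precision stays at 1.0; recall
≥ 0.95 at 5% per-branch divergence under the fixed benchmark seed). What it
does not show: robustness to indels and alignment error (no indel
evolution), paralog-rich families (single copy per genome by construction
apart from the explicit paralog-trap test), horizontal transfer,
annotation noise, or genome-scale contamination — conclusions about real
proteome panels need those checks separately.

## Limitations

* The exact-DP search is quadratic per pair; the package targets curated
  panels, not database-scale search.
* The confined-family construction and the planted-ortholog benchmark are
  emulations: they reproduce the *logic* of tracing a clade-restricted
  regulator, not any specific genome panel's content.
* The duplicate-genome filter is strict sequence-set identity, far cruder
  than similarity-score-based redundancy removal.
* Newick output encodes dendrogram heights and bootstrap supports but no
  confidence intervals on branch lengths.
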