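# regprof

Tools for tracing the evolutionary history of a transcriptional regulon —
built around the Crl regulon of *Escherichia coli* K-12.

Crl is not a classical DNA-binding transcription factor: it is an RNA
polymerase holoenzyme assembly factor that promotes association of the
stationary-phase sigma factor σ^S (RpoS) with the polymerase core. Its
regulon is therefore a *curated* object — a literature-derived table of
genes whose transcription responds to Crl, with effect signs, evidence
codes, transcription units, and co-regulating transcription factors.
`regprof` turns that table into a signed network with summary statistics,
then follows the regulon's genes across genome panels:

1. **Curation** (`regprof.regulon`) — load and validate the gene table,
   tally activation/repression, split exclusively Crl-controlled genes from
   co-regulated ones, summarize transcription-unit structure, export the
   signed edge list, and run hypergeometric enrichment
   (P(X ≥ k), X ~ Hypergeom(N, K, n), with Benjamini–Hochberg adjustment).
2. **Search** (`regprof.alignment`) — exact affine-gap Smith–Waterman /
   Needleman–Wunsch (Gotoh recurrences, numba-compiled), BLOSUM62 defaults,
   and Karlin–Altschul E-values `E = K·m·n·e^(−λS)` at a fixed database size
   n = 5×10⁸ so E-values are comparable across panels.
3. **Orthology** (`regprof.orthology`) — bidirectional best hits (BDBH):
   a seed's best hit in the target genome must find the seed back as its
   own best hit in the reference, both directions passing E ≤ 10⁻⁶ and
   coverage ≥ 60%; a permissive scan mode (E ≤ 10⁻³) lists all homologs.
4. **Profiling** (`regprof.profiling`) — collapse presence/absence to
   division × gene relative abundances (1 = universal presence, 0 = absent
   from the division) and cluster hierarchically: complete linkage with
   uncentered correlation by default, single linkage with Pearson distance
   as the alternative.
5. **Phylogeny** (`regprof.phylogeny`) — progressive multiple alignment,
   closed-form Tamura–Nei (TN93) distances, Saitou–Nei neighbor joining,
   TN93 log-likelihood by Felsenstein pruning, and nonparametric bootstrap
   supports with a 60% display threshold.
6. **Synthetic panels** (`regprof.simulate`) — ground-truthed proteome
   panels (archaeal + bacterial divisions, per-division gene retention,
   TN93 sequence divergence, decoy proteins) so every stage is testable
   without downloading genomes.

It is intended for computational biologists studying regulon evolution who
want the whole chain — from a curated table to a phylogenetic profile — in
one inspectable, deterministic package. See `docs/methods.md` for models,
conventions and limitations.

## Worked example

The packaged table reproduces the regulon's summary statistics:

```bash
$ regprof curate
genes   86
edges   297
activated       73
repressed       12
crl_only        24
co_regulated    62
tus     77
tus_monogenic_pct       52
tf_degree_1     19
tf_degree_2     11
tf_degree_3     14
...
```

86 curated genes carry 297 signed regulatory edges; 73 distinct loci are
activated by Crl and 12 repressed; 24 genes have no other known regulator
while 62 are co-regulated (19 by one additional transcription factor, 11 by
two, 14 by three); the genes sit in 77 transcription units, 52% of which
are single-gene.

A synthetic panel exercises the orthology stage end to end:

```bash
$ regprof simulate --out sim/ --seed 7 \
    --config <(echo -e "n_families: 3\ngenomes_per_division: 2\ndivergence: 0.05\nretention: 0.5")
genomes 10
families        3
planted_pairs   18

$ regprof orthologs --reference sim/ref.faa --genomes sim/genomes \
    --taxonomy sim/taxonomy.tsv --out presence.tsv
orthologs       18
```

All 18 planted orthologs are recovered (and none of the decoy proteins pass
the reciprocal-best-hit test); `presence.tsv` holds the genes × genomes 0/1
matrix that `regprof profile` collapses into per-division abundances and
clusters. `regprof tree --seqs sim/fam01.fna --bootstrap 1000 --seed 42
--out tree.nwk` builds the bootstrapped NJ tree for a family.

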