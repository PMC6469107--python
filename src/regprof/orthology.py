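"""Homolog scanning and bidirectional-best-hit (BDBH) orthology.

Orthologs are approximated operationally as reciprocal best hits: the seed
protein's best hit in a target genome must itself find the seed as its best
hit back in the reference proteome, with both directions passing the E-value
and coverage thresholds (defaults E <= 1e-6, coverage >= 60%, matching the
permissive homolog-scan threshold of E <= 1e-3 for survey searches).  Best
hits rank by raw Smith-Waterman score, with the E-value and then the subject
identifier as deterministic tie-breakers; each seed yields at most one
ortholog per genome (no co-ortholog expansion).

The per-genome boolean outcome feeds the presence/absence matrix consumed by
the profiling stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import SearchHit, blosum62_scheme, evalue, local_align

__all__ = [
    "ProteomeSet",
    "OrthologAssignment",
    "PresenceAbsenceMatrix",
    "best_hit",
    "bdbh",
    "homolog_scan",
    "presence_matrix",
    "ortholog_survey",
    "drop_duplicate_genomes",
    "DEFAULT_ORTHOLOG_EVALUE",
    "DEFAULT_HOMOLOG_EVALUE",
    "DEFAULT_MIN_COVERAGE",
]

DEFAULT_ORTHOLOG_EVALUE = 1e-6
DEFAULT_HOMOLOG_EVALUE = 1e-3
DEFAULT_MIN_COVERAGE = 0.60


@dataclass
class ProteomeSet:
    """Per-genome protein lists plus the genome -> division -> domain maps."""

    genomes: dict  # genome_id -> list[(protein_id, sequence)]
    taxonomy: dict  # genome_id -> division name
    division_domain: dict = field(default_factory=dict)  # division -> archaeal|bacterial

    def __post_init__(self):
        for gid, prots in self.genomes.items():
            ids = [p[0] for p in prots]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate protein ids in genome {gid}")
            if gid not in self.taxonomy:
                raise ValueError(f"genome {gid} has no taxonomic division")

    @classmethod
    def from_directory(cls, genome_dir, taxonomy_tsv, domain_tsv=None, suffix=".faa"):
        """Load one multi-FASTA per genome (genome id = file stem) plus the
        2-column taxonomy TSV (genome_id, division) and optionally the
        2-column (division, domain) TSV."""
        from .alignment import read_fasta

        genome_dir = Path(genome_dir)
        genomes = {
            p.stem: read_fasta(p) for p in sorted(genome_dir.glob(f"*{suffix}"))
        }
        taxonomy = _read_two_col(taxonomy_tsv)
        domains = _read_two_col(domain_tsv) if domain_tsv else {}
        return cls(genomes=genomes, taxonomy=taxonomy, division_domain=domains)

    def protein(self, genome_id, protein_id):
        for pid, seq in self.genomes[genome_id]:
            if pid == protein_id:
                return pid, seq
        raise KeyError(f"{protein_id} not in genome {genome_id}")


def _read_two_col(path):
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        a, b = line.split("\t")[:2]
        out[a] = b
    return out


@dataclass(frozen=True)
class OrthologAssignment:
    seed_gene: str
    genome_id: str
    subject_id: str | None = None
    forward_hit: SearchHit | None = None
    reverse_hit: SearchHit | None = None

    def __post_init__(self):
        if (self.subject_id is not None) != (
            self.forward_hit is not None and self.reverse_hit is not None
        ):
            raise ValueError("subject present iff both directional hits present")

    @property
    def present(self) -> bool:
        return self.subject_id is not None


def _scan_proteome(query, proteome, genome_id, scheme, min_coverage, max_evalue):
    """Score the query against every subject; yield hits passing thresholds."""
    qid, qseq = query
    hits = []
    for sid, sseq in proteome:
        aln = local_align(qseq, sseq, scheme, query_id=qid, subject_id=sid)
        if aln.is_empty:
            continue
        ev = evalue(aln.raw_score, len(qseq), scheme)
        if ev <= max_evalue and aln.q_coverage >= min_coverage:
            hits.append(SearchHit(qid, sid, genome_id, aln.raw_score, ev, aln.q_coverage))
    return hits


def best_hit(
    query,
    proteome,
    scheme=None,
    min_coverage=DEFAULT_MIN_COVERAGE,
    max_evalue=DEFAULT_ORTHOLOG_EVALUE,
    genome_id="",
):
    """Highest-raw-score subject passing both thresholds, or None.

    Ties break by smaller E-value, then lexicographic subject id.
    """
    scheme = scheme or blosum62_scheme()
    if not proteome:
        raise ValueError("proteome must be non-empty")
    hits = _scan_proteome(query, proteome, genome_id, scheme, min_coverage, max_evalue)
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.raw_score, h.evalue, h.subject_id))


def bdbh(
    seed,
    target_proteome,
    reference_proteome,
    scheme=None,
    min_coverage=DEFAULT_MIN_COVERAGE,
    max_evalue=DEFAULT_ORTHOLOG_EVALUE,
    genome_id="",
    reference_id="reference",
):
    """Bidirectional best hit of ``seed`` (a (id, seq) pair from the reference
    proteome) in a target genome.

    The assignment carries a subject only when the forward best hit's own best
    hit back in the reference is the seed itself; both directions enforce the
    E-value and coverage thresholds.
    """
    scheme = scheme or blosum62_scheme()
    seed_id, seed_seq = seed
    if not any(pid == seed_id and s == seed_seq for pid, s in reference_proteome):
        raise ValueError(f"seed {seed_id} is not part of the reference proteome")
    fwd = best_hit(seed, target_proteome, scheme, min_coverage, max_evalue, genome_id)
    if fwd is None:
        return OrthologAssignment(seed_id, genome_id)
    subject = next(p for p in target_proteome if p[0] == fwd.subject_id)
    rev = best_hit(subject, reference_proteome, scheme, min_coverage, max_evalue, reference_id)
    if rev is None or rev.subject_id != seed_id:
        return OrthologAssignment(seed_id, genome_id)
    return OrthologAssignment(seed_id, genome_id, fwd.subject_id, fwd, rev)


def homolog_scan(
    seed,
    proteomes: ProteomeSet,
    scheme=None,
    max_evalue=DEFAULT_HOMOLOG_EVALUE,
    min_coverage=DEFAULT_MIN_COVERAGE,
):
    """All subjects in all genomes passing the survey thresholds (not only the
    best per genome), sorted by E-value then (genome, subject) id."""
    scheme = scheme or blosum62_scheme()
    hits = []
    for gid in sorted(proteomes.genomes):
        hits.extend(
            _scan_proteome(seed, proteomes.genomes[gid], gid, scheme, min_coverage, max_evalue)
        )
    hits.sort(key=lambda h: (h.evalue, h.genome_id, h.subject_id))
    return hits


@dataclass
class PresenceAbsenceMatrix:
    """Genes x genomes ortholog indicator grid."""

    genes: list
    genomes: list
    values: np.ndarray  # bool, shape (n_genes, n_genomes)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.genes), len(self.genomes)):
            raise ValueError("presence grid shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genomes)

    def to_tsv(self, path):
        self.to_frame().astype(int).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.values.astype(bool))


def presence_matrix(assignments, gene_order, genome_order) -> PresenceAbsenceMatrix:
    """Materialize assignments into a boolean genes x genomes grid.

    Duplicate (gene, genome) assignments naming different subjects raise a
    consistency error.
    """
    gi = {g: i for i, g in enumerate(gene_order)}
    mi = {m: i for i, m in enumerate(genome_order)}
    seen = {}
    grid = np.zeros((len(gene_order), len(genome_order)), dtype=bool)
    for a in assignments:
        if a.seed_gene not in gi or a.genome_id not in mi:
            raise ValueError(f"assignment references unknown gene/genome: {a.seed_gene}, {a.genome_id}")
        key = (a.seed_gene, a.genome_id)
        if key in seen and seen[key] != a.subject_id:
            raise ValueError(f"conflicting subjects for {key}: {seen[key]} vs {a.subject_id}")
        seen[key] = a.subject_id
        if a.present:
            grid[gi[a.seed_gene], mi[a.genome_id]] = True
    return PresenceAbsenceMatrix(list(gene_order), list(genome_order), grid)


def ortholog_survey(
    seeds,
    proteomes: ProteomeSet,
    reference_proteome,
    scheme=None,
    min_coverage=DEFAULT_MIN_COVERAGE,
    max_evalue=DEFAULT_ORTHOLOG_EVALUE,
    reference_id="reference",
):
    """Run BDBH for every seed against every genome; returns the assignment
    list and the presence/absence matrix (genes and genomes sorted)."""
    scheme = scheme or blosum62_scheme()
    assignments = []
    genome_ids = sorted(proteomes.genomes)
    for seed in seeds:
        for gid in genome_ids:
            assignments.append(
                bdbh(
                    seed,
                    proteomes.genomes[gid],
                    reference_proteome,
                    scheme,
                    min_coverage,
                    max_evalue,
                    genome_id=gid,
                    reference_id=reference_id,
                )
            )
    matrix = presence_matrix(assignments, [s[0] for s in seeds], genome_ids)
    return assignments, matrix


def hits_to_frame(hits) -> pd.DataFrame:
    """Tabulate hits as query/subject/genome/score/evalue/coverage."""
    return pd.DataFrame(
        [
            (h.query_id, h.subject_id, h.genome_id, h.raw_score, h.evalue, h.q_coverage)
            for h in hits
        ],
        columns=["query", "subject", "genome", "score", "evalue", "coverage"],
    )


def drop_duplicate_genomes(proteomes: ProteomeSet) -> ProteomeSet:
    """Synthetic stand-in for genome-redundancy removal: drop genomes whose
    exact protein *sequence set* duplicates an earlier (lexicographically
    first) genome.  This is a strict-identity filter only, not a similarity
    score."""
    seen = {}
    keep = {}
    for gid in sorted(proteomes.genomes):
        key = frozenset(seq for _, seq in proteomes.genomes[gid])
        if key in seen:
            continue
        seen[key] = gid
        keep[gid] = proteomes.genomes[gid]
    return ProteomeSet(
        genomes=keep,
        taxonomy={g: proteomes.taxonomy[g] for g in keep},
        division_domain=dict(proteomes.division_domain),
    )
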