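"""Exact pairwise alignment with substitution matrices, affine gaps and
Karlin-Altschul E-values.

This is the search core behind homology scanning and reciprocal-best-hit
orthology: optimal Smith-Waterman local alignment and Needleman-Wunsch global
alignment (Gotoh three-state recurrences, numba-compiled), query/subject
coverage, and the Karlin-Altschul expectation

    E = K * m * n * exp(-lambda * S)

evaluated at a *fixed* database size ``n`` so that E-values are comparable
across searches regardless of the proteome actually scanned.  Defaults are
BLOSUM62 with gap open 11 / extend 1 and the standard gapped constants
lambda = 0.267, K = 0.041; the database size defaults to 5e8 residues.

No heuristic seeding is performed — every search is an exact quadratic DP —
so this scales to desk-size proteome panels, not to sequence databases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _kernels

__all__ = [
    "AlphabetError",
    "ScoringScheme",
    "PairwiseAlignment",
    "SearchHit",
    "blosum62_scheme",
    "parse_ncbi_matrix",
    "local_align",
    "global_align",
    "align_profiles",
    "evalue",
    "query_coverage",
    "score_alignment",
    "read_fasta",
    "write_fasta",
]

GAP = "-"


class AlphabetError(KeyError):
    """A residue is not covered by the substitution matrix."""


def _matrix_from_biopython(name: str):
    arr = substitution_matrices.load(name)
    alphabet = str(arr.alphabet)
    mat = np.asarray(arr, dtype=np.float64)
    return alphabet, mat


def parse_ncbi_matrix(path):
    """Parse a substitution matrix in NCBI text format (rows/cols labelled,
    ``#`` comments).  Returns (alphabet string, square numpy array)."""
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    cols = lines[0].split()
    alphabet = "".join(cols)
    mat = np.zeros((len(cols), len(cols)))
    for ln in lines[1:]:
        parts = ln.split()
        i = cols.index(parts[0])
        mat[i, :] = [float(x) for x in parts[1 : len(cols) + 1]]
    if not np.allclose(mat, mat.T):
        raise ValueError("substitution matrix is not symmetric")
    return alphabet, mat


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters for alignment and E-value statistics.

    ``db_length`` is the fixed database size n in the Karlin-Altschul formula
    (default 5e8 residues); ``lam``/``K`` are the gapped statistics constants.
    """

    alphabet: str
    matrix: np.ndarray = field(repr=False)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    db_length: float = 5e8

    def __post_init__(self):
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must be <= gap_open")
        if min(self.lam, self.K, self.db_length) <= 0:
            raise ValueError("lambda, K and db_length must be positive")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    def encode(self, seq: str) -> np.ndarray:
        idx = np.empty(len(seq), dtype=np.int64)
        for i, ch in enumerate(seq):
            pos = self.alphabet.find(ch)
            if pos < 0:
                raise AlphabetError(f"residue {ch!r} not covered by the substitution matrix")
            idx[i] = pos
        return idx

    def pair_score(self, a: str, b: str) -> float:
        ia, ib = self.alphabet.find(a), self.alphabet.find(b)
        if ia < 0 or ib < 0:
            raise AlphabetError(f"residue {a if ia < 0 else b!r} not in matrix")
        return float(self.matrix[ia, ib])


def blosum62_scheme(**kwargs) -> ScoringScheme:
    """Default protein scheme: BLOSUM62, gap 11/1, gapped KA constants."""
    alphabet, mat = _matrix_from_biopython("BLOSUM62")
    return ScoringScheme(alphabet=alphabet, matrix=mat, **kwargs)


def simple_dna_scheme(match: float = 2.0, mismatch: float = -3.0, **kwargs) -> ScoringScheme:
    """Plain match/mismatch nucleotide scheme (used by the progressive aligner)."""
    alphabet = "ACGTN"
    mat = np.full((5, 5), mismatch)
    np.fill_diagonal(mat, match)
    mat[4, :] = mat[:, 4] = 0.0
    kwargs.setdefault("gap_open", 5)
    kwargs.setdefault("gap_extend", 2)
    return ScoringScheme(alphabet=alphabet, matrix=mat, **kwargs)


@dataclass(frozen=True)
class PairwiseAlignment:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    raw_score: float
    q_start: int  # 1-based inclusive; 0 for an empty alignment
    q_end: int
    s_start: int
    s_end: int
    identity: float
    q_coverage: float
    s_coverage: float

    @property
    def is_empty(self) -> bool:
        return self.q_end == 0


@dataclass(frozen=True)
class SearchHit:
    """One thresholded hit of a query against a subject protein."""

    query_id: str
    subject_id: str
    genome_id: str
    raw_score: float
    evalue: float
    q_coverage: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0.0 <= self.q_coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")


def _build_alignment(query, subject, scheme, score, ai, aj, qs, ss, query_id, subject_id):
    aq = "".join(GAP if x < 0 else query[x] for x in ai)
    asu = "".join(GAP if x < 0 else subject[x] for x in aj)
    if not ai:
        return PairwiseAlignment(query_id, subject_id, "", "", 0.0, 0, 0, 0, 0, 0.0, 0.0, 0.0)
    qe = max((x + 1 for x in ai if x >= 0), default=0)
    se = max((x + 1 for x in aj if x >= 0), default=0)
    matches = sum(1 for a, b in zip(aq, asu) if a == b and a != GAP)
    ident = matches / len(aq)
    qcov = (qe - qs + 1) / len(query) if qe else 0.0
    scov = (se - ss + 1) / len(subject) if se else 0.0
    return PairwiseAlignment(
        query_id, subject_id, aq, asu, float(score), qs, qe, ss, se, ident, qcov, scov
    )


def local_align(query, subject, scheme=None, query_id="query", subject_id="subject"):
    """Optimal affine-gap Smith-Waterman local alignment.

    Returns an empty alignment (score 0) when no residue pair scores
    positively.  Ties between optimal alignments resolve to the smallest
    (q_start, s_start), then the smallest end coordinates.
    """
    scheme = scheme or blosum62_scheme()
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    q, s = scheme.encode(str(query)), scheme.encode(str(subject))
    score, bi, bj, Hp, Ep, Fp = _kernels.local_dp(
        q, s, scheme.matrix, float(scheme.gap_open), float(scheme.gap_extend)
    )
    if score <= 0:
        return _build_alignment(query, subject, scheme, 0.0, [], [], 0, 0, query_id, subject_id)
    ai, aj, qs, ss = _kernels.traceback(q, s, Hp, Ep, Fp, bi, bj, True)
    return _build_alignment(query, subject, scheme, score, ai, aj, qs, ss, query_id, subject_id)


def local_score(query_idx, subject_idx, scheme) -> float:
    """Score-only Smith-Waterman on pre-encoded sequences (no traceback)."""
    score, _, _, _, _, _ = _kernels.local_dp(
        query_idx, subject_idx, scheme.matrix, float(scheme.gap_open), float(scheme.gap_extend)
    )
    return float(score)


def global_align(query, subject, scheme=None, query_id="query", subject_id="subject"):
    """Optimal affine-gap Needleman-Wunsch global alignment of two sequences."""
    scheme = scheme or blosum62_scheme()
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    q, s = scheme.encode(str(query)), scheme.encode(str(subject))
    score, Hp, Ep, Fp = _kernels.global_dp(
        q, s, scheme.matrix, float(scheme.gap_open), float(scheme.gap_extend)
    )
    ai, aj, qs, ss = _kernels.traceback(q, s, Hp, Ep, Fp, len(q), len(s), False)
    return _build_alignment(query, subject, scheme, score, ai, aj, qs, ss, query_id, subject_id)


def _profile_counts(rows, scheme):
    L = len(rows[0])
    counts = np.zeros((L, len(scheme.alphabet)))
    ngap = np.zeros(L)
    for row in rows:
        for j, ch in enumerate(row):
            if ch == GAP:
                ngap[j] += 1
            else:
                pos = scheme.alphabet.find(ch)
                if pos < 0:
                    raise AlphabetError(f"residue {ch!r} not covered by the matrix")
                counts[j, pos] += 1
    return counts, ngap


def align_profiles(rows_a, rows_b, scheme=None):
    """Affine-gap global alignment of two gapped profiles.

    The column score is the mean substitution score over all cross pairs of
    residues; pairs involving an existing gap contribute 0.  Returns the
    merged rows (rows of A then rows of B) and the DP score.  With two single
    ungapped sequences this reduces exactly to :func:`global_align`.
    """
    scheme = scheme or blosum62_scheme()
    if not rows_a or not rows_b or not rows_a[0] or not rows_b[0]:
        raise ValueError("profiles must be non-empty")
    ca, _ = _profile_counts(rows_a, scheme)
    cb, _ = _profile_counts(rows_b, scheme)
    npairs = len(rows_a) * len(rows_b)
    colscore = (ca @ scheme.matrix @ cb.T) / npairs  # (La, Lb)
    La, Lb = colscore.shape
    # encode profile columns as pseudo-sequences indexing the colscore matrix
    qi = np.arange(La, dtype=np.int64)
    sj = np.arange(Lb, dtype=np.int64)
    score, Hp, Ep, Fp = _kernels.global_dp(
        qi, sj, colscore, float(scheme.gap_open), float(scheme.gap_extend)
    )
    ai, aj, _, _ = _kernels.traceback(qi, sj, Hp, Ep, Fp, La, Lb, False)
    merged = []
    for row in rows_a:
        merged.append("".join(GAP if x < 0 else row[x] for x in ai))
    for row in rows_b:
        merged.append("".join(GAP if x < 0 else row[x] for x in aj))
    return merged, float(score)


def evalue(raw_score, query_len, scheme) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    return scheme.K * query_len * scheme.db_length * math.exp(-scheme.lam * raw_score)


def query_coverage(aln: PairwiseAlignment, query_len: int) -> float:
    """Fraction of the query spanned by the alignment footprint."""
    if aln.is_empty:
        return 0.0
    return (aln.q_end - aln.q_start + 1) / query_len


def score_alignment(aligned_query, aligned_subject, scheme) -> float:
    """Re-score a pair of gapped strings under the scheme's gap convention."""
    if len(aligned_query) != len(aligned_subject):
        raise ValueError("aligned strings must have equal length")
    score = 0.0
    gap_side = 0  # 0 none, 1 gap in query, 2 gap in subject
    for a, b in zip(aligned_query, aligned_subject):
        if a == GAP and b == GAP:
            raise ValueError("column with gaps in both rows")
        if a == GAP or b == GAP:
            side = 1 if a == GAP else 2
            if gap_side != side:
                score -= scheme.gap_open
                gap_side = side
            score -= scheme.gap_extend
        else:
            gap_side = 0
            score += scheme.pair_score(a, b)
    return score


def read_fasta(path):
    """Read a FASTA file into an ordered list of (id, sequence) tuples."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path):
    """Write (id, sequence) tuples as wrapped FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")
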