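"""Distance phylogenetics under the Tamura-Nei (TN93) substitution model.

Pipeline: progressive multiple alignment (guide tree from pairwise global
alignments, then profile-profile merges), pairwise TN93 distances with
pairwise deletion of gapped/ambiguous sites, Saitou-Nei neighbor joining,
TN93 log-likelihood evaluation by Felsenstein pruning, and nonparametric
bootstrap support from column resampling.

TN93 distinguishes purine transitions (A<->G, rate alpha1), pyrimidine
transitions (C<->T, rate alpha2) and transversions (rate beta) with arbitrary
stationary base frequencies; it admits both a closed-form pairwise distance
and closed-form transition probabilities, which makes the whole pipeline
analytic.  Tree search is neighbor joining only — NJ is exact on additive
matrices and serves as a tractable stand-in for a full maximum-likelihood
topology search; the likelihood evaluator is provided to score candidate
trees.

A bipartition is considered *resolved* only when its internal branch length
is positive; bootstrap supports are reported for resolved bipartitions of the
full-data tree (percentage of replicates containing the same split).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, align_profiles, global_align, simple_dna_scheme

logger = logging.getLogger(__name__)

__all__ = [
    "MultipleAlignment",
    "TN93Params",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "progressive_align",
    "tn93_distance",
    "tn93_distance_matrix",
    "nj_tree",
    "tn93_loglik",
    "bootstrap_support",
]

BASES = "ACGT"
_B = {b: i for i, b in enumerate(BASES)}


@dataclass
class MultipleAlignment:
    """Gapped rows of equal length keyed by sequence id (insertion-ordered)."""

    rows: dict

    def __post_init__(self):
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self):
        return list(self.rows)

    def degapped(self, name) -> str:
        return self.rows[name].replace(GAP, "")

    def subsample_columns(self, idx):
        return MultipleAlignment(
            {k: "".join(v[i] for i in idx) for k, v in self.rows.items()}
        )

    def to_fasta(self, path):
        from .alignment import write_fasta

        write_fasta(list(self.rows.items()), path)

    @classmethod
    def from_fasta(cls, path):
        from .alignment import read_fasta

        return cls(dict(read_fasta(path)))


def progressive_align(sequences, scheme=None) -> MultipleAlignment:
    """Progressive multiple alignment.

    A guide tree is built by average-linkage clustering of pairwise p-distances
    (from global alignments), then profiles are merged bottom-up with
    affine-gap profile-profile alignment.  With two sequences this is exactly
    the pairwise global alignment.
    """
    scheme = scheme or simple_dna_scheme()
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    for name, seq in items:
        if not seq:
            raise ValueError(f"empty sequence: {name}")
    n = len(items)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        aln = global_align(items[i][1], items[j][1], scheme)
        pairs = [
            (a, b)
            for a, b in zip(aln.aligned_query, aln.aligned_subject)
            if a != GAP and b != GAP
        ]
        ident = sum(1 for a, b in pairs if a == b) / len(pairs) if pairs else 0.0
        D[i, j] = D[j, i] = 1.0 - ident
    # average-linkage guide tree with deterministic tie-breaks
    clusters = {i: ([items[i][1]], [i], 1) for i in range(n)}  # rows, leaf idx, size
    dist = {(i, j): D[i, j] for i, j in itertools.combinations(range(n), 2)}
    active = sorted(clusters)
    next_id = n
    while len(active) > 1:
        best = min(
            ((dist[(a, b)], a, b) for a, b in itertools.combinations(active, 2)),
        )
        _, a, b = best
        rows_a, leaves_a, na = clusters[a]
        rows_b, leaves_b, nb = clusters[b]
        merged, _ = align_profiles(rows_a, rows_b, scheme)
        clusters[next_id] = (merged, leaves_a + leaves_b, na + nb)
        for c in active:
            if c in (a, b):
                continue
            da = dist[tuple(sorted((a, c)))]
            db = dist[tuple(sorted((b, c)))]
            dist[tuple(sorted((c, next_id)))] = (na * da + nb * db) / (na + nb)
        active = sorted(set(active) - {a, b} | {next_id})
        next_id += 1
    rows, leaves, _ = clusters[active[0]]
    out = {}
    for row, leaf in zip(rows, leaves):
        out[items[leaf][0]] = row
    # restore the input ordering
    return MultipleAlignment({name: out[name] for name, _ in items})


@dataclass(frozen=True)
class TN93Params:
    """Stationary base frequencies (A, C, G, T) and substitution rates."""

    base_freqs: tuple  # (piA, piC, piG, piT)
    alpha1: float  # purine transition rate (A<->G)
    alpha2: float  # pyrimidine transition rate (C<->T)
    beta: float  # transversion rate

    def __post_init__(self):
        pi = np.asarray(self.base_freqs, dtype=float)
        if pi.shape != (4,) or (pi <= 0).any():
            raise ValueError("need 4 positive base frequencies")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if min(self.alpha1, self.alpha2, self.beta) <= 0:
            raise ValueError("rates must be positive")

    @property
    def pi(self):
        return np.asarray(self.base_freqs, dtype=float)

    def transition_matrix(self, t: float) -> np.ndarray:
        """Closed-form P(t) in base order A, C, G, T."""
        piA, piC, piG, piT = self.base_freqs
        piR, piY = piA + piG, piC + piT
        e2 = math.exp(-self.beta * t)
        e3 = math.exp(-(piR * self.alpha1 + piY * self.beta) * t)
        e4 = math.exp(-(piY * self.alpha2 + piR * self.beta) * t)
        P = np.empty((4, 4))
        # transversions
        for i in (0, 2):  # purine rows -> pyrimidine cols
            P[i, 1] = piC * (1 - e2)
            P[i, 3] = piT * (1 - e2)
        for i in (1, 3):
            P[i, 0] = piA * (1 - e2)
            P[i, 2] = piG * (1 - e2)
        # purines
        P[0, 2] = piG + piG * piY / piR * e2 - piG / piR * e3
        P[2, 0] = piA + piA * piY / piR * e2 - piA / piR * e3
        P[0, 0] = piA + piA * piY / piR * e2 + piG / piR * e3
        P[2, 2] = piG + piG * piY / piR * e2 + piA / piR * e3
        # pyrimidines
        P[1, 3] = piT + piT * piR / piY * e2 - piT / piY * e4
        P[3, 1] = piC + piC * piR / piY * e2 - piC / piY * e4
        P[1, 1] = piC + piC * piR / piY * e2 + piT / piY * e4
        P[3, 3] = piT + piT * piR / piY * e2 + piC / piY * e4
        return P


class SaturatedDistanceError(ValueError):
    """The observed divergence exceeds what TN93 can invert."""


def _comparable(a: str, b: str):
    for x, y in zip(a.upper(), b.upper()):
        if x in _B and y in _B:
            yield _B[x], _B[y]


def tn93_distance(a: str, b: str) -> float:
    """Closed-form TN93 distance between two aligned nucleotide sequences.

    Sites where either sequence has a gap or ambiguity are skipped (pairwise
    deletion); base frequencies are the empirical frequencies over the
    comparable sites of both sequences.  Returns ``inf`` for saturated pairs.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be pre-aligned to equal length")
    pairs = list(_comparable(a, b))
    if not pairs:
        raise ValueError("no comparable sites")
    n = len(pairs)
    counts = np.zeros(4)
    P1 = P2 = Q = 0
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
        if x != y:
            s = {x, y}
            if s == {0, 2}:
                P1 += 1
            elif s == {1, 3}:
                P2 += 1
            else:
                Q += 1
    if P1 == 0 and P2 == 0 and Q == 0:
        return 0.0
    pi = counts / counts.sum()
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    p1, p2, q = P1 / n, P2 / n, Q / n
    if piR == 0 or piY == 0:
        raise SaturatedDistanceError("degenerate base composition")
    k1 = 2 * piA * piG / piR
    k2 = 2 * piC * piT / piY
    k3 = 2 * (piR * piY - piA * piG * piY / piR - piC * piT * piR / piY)
    d = 0.0
    for k, p, denom in ((k1, p1, 2 * piR), (k2, p2, 2 * piY)):
        if k > 0:
            w = 1 - p / k - q / denom
            if w <= 0:
                return math.inf
            d += -k * math.log(w)
        elif p > 0:
            return math.inf
    w3 = 1 - q / (2 * piR * piY)
    if w3 <= 0:
        return math.inf
    d += -k3 * math.log(w3)
    return d


@dataclass
class DistanceMatrix:
    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(self.values).any():
            raise ValueError("diagonal must be zero")

    def saturated_pairs(self):
        out = []
        for i, j in itertools.combinations(range(len(self.ids)), 2):
            if not np.isfinite(self.values[i, j]):
                out.append((self.ids[i], self.ids[j]))
        return out


def tn93_distance_matrix(aln: MultipleAlignment) -> DistanceMatrix:
    ids = aln.ids
    n = len(ids)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = tn93_distance(aln.rows[ids[i]], aln.rows[ids[j]])
    return DistanceMatrix(ids, D)


@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # (TreeNode, branch length)
    support: float | None = None  # percent, internal nodes only

    def is_leaf(self):
        return not self.children

    def leaves(self):
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary root (trifurcating for NJ)."""

    root: TreeNode

    @property
    def leaf_names(self):
        return self.root.leaves()

    def bipartitions(self, resolved_only=True):
        """Map frozenset(one side) -> branch length for internal edges.

        Sides are canonicalized as the side *not* containing the
        alphabetically first leaf.  Trivial splits are excluded; with
        ``resolved_only`` splits on zero-length branches are excluded too.
        """
        all_leaves = set(self.leaf_names)
        anchor = min(all_leaves)
        out = {}

        def walk(node):
            for child, length in node.children:
                below = set(child.leaves())
                if 2 <= len(below) <= len(all_leaves) - 2:
                    side = below if anchor not in below else all_leaves - below
                    if (not resolved_only) or length > 1e-12:
                        out[frozenset(side)] = length
                walk(child)

        walk(self.root)
        return out

    def newick(self, display_threshold: float | None = None) -> str:
        """Newick with supports as internal node labels.  With a display
        threshold, supports below it are masked (omitted) in the rendered
        string but retained on the tree."""

        def fmt(node):
            if node.is_leaf():
                return node.name
            inner = ",".join(f"{fmt(c)}:{l:.6g}" for c, l in node.children)
            label = ""
            if node.support is not None and (
                display_threshold is None or node.support >= display_threshold
            ):
                label = f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; exact on additive distance matrices.

    Negative branch-length estimates are clamped to zero and the clamped
    deficit logged.  Saturated (non-finite) entries are an error.
    """
    sat = D.saturated_pairs()
    if sat:
        raise ValueError(f"saturated distance for pairs: {sat}")
    n = len(D.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = {i: TreeNode(name=D.ids[i]) for i in range(n)}
    d = {
        (i, j): float(D.values[i, j])
        for i, j in itertools.combinations(range(n), 2)
    }

    def get(i, j):
        return d[(i, j) if i < j else (j, i)]

    active = sorted(nodes)
    next_id = n
    clamped = 0.0
    while len(active) > 2:
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        m = len(active)
        best = min(
            ((m - 2) * get(i, j) - r[i] - r[j], i, j)
            for i, j in itertools.combinations(active, 2)
        )
        _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        for val in (li, lj):
            if val < 0:
                clamped += -val
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            d[tuple(sorted((k, next_id)))] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = sorted(set(active) - {i, j} | {next_id})
        next_id += 1
    i, j = active
    dij = get(i, j)
    if dij < 0:
        clamped += -dij
        dij = 0.0
    # join the last two clusters through a trifurcating-ish root
    a, b = nodes[i], nodes[j]
    if not b.is_leaf():
        root = b
        root.children.append((a, dij))
    elif not a.is_leaf():
        root = a
        root.children.append((b, dij))
    else:
        root = TreeNode(children=[(a, dij / 2), (b, dij / 2)])
    if clamped > 0:
        logger.info("neighbor joining clamped %.6g of negative branch length", clamped)
    return PhyloTree(root=root)


_AMBIG_ROW = np.ones(4)


def tn93_loglik(tree: PhyloTree, aln: MultipleAlignment, params: TN93Params) -> float:
    """Log-likelihood of the alignment on the tree by Felsenstein pruning.

    Gapped/ambiguous states contribute a partial likelihood of 1 for every
    base (missing data).  The root is treated as the stationary distribution;
    by reversibility the value is invariant to the rooting.
    """
    leaves = set(tree.leaf_names)
    if leaves != set(aln.ids):
        raise ValueError("tree leaves do not match alignment rows")
    L = aln.length
    cols = [
        {name: aln.rows[name][k] for name in aln.rows} for k in range(L)
    ]

    def prune(node, col):
        if node.is_leaf():
            ch = col[node.name].upper()
            if ch in _B:
                v = np.zeros(4)
                v[_B[ch]] = 1.0
                return v
            return _AMBIG_ROW.copy()
        v = np.ones(4)
        for child, t in node.children:
            P = params.transition_matrix(max(t, 0.0))
            v *= P @ prune(child, col)
        return v

    total = 0.0
    for col in cols:
        site = float(params.pi @ prune(tree.root, col))
        if site <= 0:
            return -math.inf
        total += math.log(site)
    return total


def estimate_tn93_params(aln: MultipleAlignment, kappa1=2.0, kappa2=2.0) -> TN93Params:
    """Empirical base frequencies from the alignment with default
    transition/transversion rate ratios; rates normalized so beta = 1."""
    counts = np.zeros(4)
    for row in aln.rows.values():
        for ch in row.upper():
            if ch in _B:
                counts[_B[ch]] += 1
    if counts.sum() == 0:
        raise ValueError("alignment has no unambiguous bases")
    pi = counts / counts.sum()
    pi = np.clip(pi, 1e-6, None)
    pi = pi / pi.sum()
    return TN93Params(tuple(pi), alpha1=kappa1, alpha2=kappa2, beta=1.0)


def bootstrap_support(
    aln: MultipleAlignment,
    B: int = 1000,
    display_threshold: float = 60.0,
    seed: int | None = None,
    rng=None,
) -> PhyloTree:
    """Nonparametric bootstrap: resample alignment columns with replacement,
    rebuild the NJ tree each time, and annotate the full-data tree's resolved
    bipartitions with the percentage of replicates containing them.

    Supports below ``display_threshold`` are masked only when rendering
    (see :meth:`PhyloTree.newick`); the values themselves are retained.
    """
    if len(aln.rows) < 4:
        raise ValueError("need at least 4 sequences for meaningful supports")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    main = nj_tree(tn93_distance_matrix(aln))
    targets = main.bipartitions(resolved_only=True)
    counts = {s: 0 for s in targets}
    L = aln.length
    for _ in range(B):
        idx = rng.integers(0, L, size=L)
        try:
            rep = nj_tree(tn93_distance_matrix(aln.subsample_columns(idx)))
        except ValueError:
            continue  # saturated replicate: counts as non-support
        splits = rep.bipartitions(resolved_only=False)
        for s in counts:
            if s in splits:
                counts[s] += 1
    supports = {s: 100.0 * c / B for s, c in counts.items()}

    def annotate(node):
        for child, length in node.children:
            if not child.is_leaf():
                below = frozenset(child.leaves())
                all_leaves = set(main.leaf_names)
                anchor = min(all_leaves)
                side = below if anchor not in below else frozenset(all_leaves - below)
                if side in supports:
                    child.support = supports[side]
            annotate(child)

    annotate(main.root)
    main.bootstrap_supports = supports
    return main
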