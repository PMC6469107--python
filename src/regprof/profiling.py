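"""Phylogenetic profiling: per-division ortholog abundance and clustering.

The presence/absence matrix is collapsed into a division x gene profile where
cell (d, g) is the fraction of genomes in taxonomic division d carrying an
ortholog of gene g — 1 means universal presence in the division, 0 means the
division lacks the ortholog entirely.  Profiles are then clustered
agglomeratively.  Two similarity conventions are supported because the source
analysis states both: uncentered correlation (cosine similarity without mean
centering) with complete linkage — the default — and Pearson correlation with
single linkage.  No leaf-order optimization is applied: the dendrogram's leaf
order is the merge-induced order under a deterministic tie rule (equal
minimal distances merge the pair with the lexicographically smallest original
row indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cosine as _cosine, correlation as _correlation

__all__ = [
    "ProfileMatrix",
    "LinkageDendrogram",
    "relative_abundance",
    "uncentered_correlation_distance",
    "pearson_distance",
    "hcluster",
]


@dataclass
class ProfileMatrix:
    """Division x gene relative-abundance grid with domain tags."""

    divisions: list
    genes: list
    values: np.ndarray  # shape (n_divisions, n_genes), in [0, 1]
    domains: list = field(default_factory=list)  # archaeal/bacterial per division

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.divisions), len(self.genes)):
            raise ValueError("profile shape does not match labels")
        if len(set(self.divisions)) != len(self.divisions):
            raise ValueError("division names must be unique")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene names must be unique")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("relative abundances must lie in [0, 1]")
        if not self.domains:
            self.domains = ["unknown"] * len(self.divisions)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.divisions, columns=self.genes)
        df.insert(0, "domain", self.domains)
        return df

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t", index_col=0)
        domains = list(df.pop("domain"))
        return cls(list(df.index), list(df.columns), df.values, domains)


def relative_abundance(matrix, taxonomy, division_domain=None) -> ProfileMatrix:
    """Collapse a genes x genomes presence grid into division x gene fractions.

    ``taxonomy`` maps genome id -> division.  Every genome must carry a
    division and every division must contain at least one genome.
    """
    missing = [g for g in matrix.genomes if g not in taxonomy]
    if missing:
        raise ValueError(f"genomes without a division: {missing}")
    divisions = sorted({taxonomy[g] for g in matrix.genomes})
    values = np.zeros((len(divisions), len(matrix.genes)))
    for i, d in enumerate(divisions):
        cols = [j for j, g in enumerate(matrix.genomes) if taxonomy[g] == d]
        if not cols:
            raise ValueError(f"division {d} has no genomes")
        values[i] = matrix.values[:, cols].mean(axis=1)
    domains = [
        (division_domain or {}).get(d, "unknown") for d in divisions
    ]
    return ProfileMatrix(divisions, list(matrix.genes), values, domains)


def uncentered_correlation_distance(x, y) -> float:
    """1 - dot(x, y) / (||x|| ||y||): cosine-style distance in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if not x.any() or not y.any():
        raise ValueError("uncentered correlation undefined for a zero vector")
    return float(_cosine(x, y))


def pearson_distance(x, y) -> float:
    """1 - sample Pearson correlation, in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a zero-variance vector")
    return float(_correlation(x, y))


_DISTANCES = {
    "uncentered": uncentered_correlation_distance,
    "pearson": pearson_distance,
}


@dataclass
class LinkageDendrogram:
    """Agglomerative merge sequence over labelled items.

    Cluster ids follow the scipy convention: leaves are 0..n-1 in input
    order; the t-th merge creates cluster n+t.  ``leaf_order`` is the
    merge-induced permutation (no leaf-order optimization).
    """

    labels: list
    merges: list  # (cluster_a, cluster_b, height)
    leaf_order: list  # permutation of range(n)

    def ordered_labels(self):
        return [self.labels[i] for i in self.leaf_order]

    def to_newick(self) -> str:
        """Serialize with merge heights as node heights (branch length =
        parent height - child height; leaves sit at height 0)."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for t, (a, b, h) in enumerate(self.merges):
            # single linkage can be non-monotone; negative spans clamp to 0
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[n + t] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + t] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return node[root] + ";"


def _pairwise(matrix, metric):
    n = matrix.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                D[i, j] = D[j, i] = metric(matrix[i], matrix[j])
            except ValueError as exc:
                raise ValueError(f"distance undefined for items ({i}, {j}): {exc}") from exc
    return D


def hcluster(profile, axis="rows", linkage="complete", distance="uncentered"):
    """Agglomerative clustering of profile rows or columns.

    ``linkage`` is "single" or "complete"; ``distance`` is "uncentered" or
    "pearson".  Deterministic: among equal minimal inter-cluster distances the
    pair with the smallest (min original index a, min original index b) is
    merged first.
    """
    if axis == "rows":
        data = profile.values
        labels = list(profile.divisions)
    elif axis == "cols":
        data = profile.values.T
        labels = list(profile.genes)
    else:
        raise ValueError("axis must be 'rows' or 'cols'")
    if linkage not in ("single", "complete"):
        raise ValueError("linkage must be 'single' or 'complete'")
    metric = _DISTANCES[distance]
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    D = _pairwise(np.asarray(data, dtype=float), metric)

    agg = np.minimum if linkage == "single" else np.maximum
    # cluster id -> (member leaf set, ordered leaves); dist holds current
    # inter-cluster distances keyed by cluster id
    members = {i: [i] for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        best_key = None
        best_pair = None
        for a in active:
            for b in active:
                if a >= b:
                    continue
                d = dist[(a, b)]
                ra, rb = min(members[a]), min(members[b])
                key = (d, min(ra, rb), max(ra, rb))
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (a, b)
        a, b = best_pair
        h = dist[(a, b)]
        # merge-induced order: cluster with the smaller min original index first
        first, second = (a, b) if min(members[a]) <= min(members[b]) else (b, a)
        members[next_id] = members[first] + members[second]
        merges.append((first, second, float(h)))
        active -= {a, b}
        for c in active:
            da = dist[tuple(sorted((a, c)))]
            db = dist[tuple(sorted((b, c)))]
            dist[(c, next_id) if c < next_id else (next_id, c)] = float(agg(da, db))
        active.add(next_id)
        next_id += 1
    leaf_order = members[next_id - 1] if merges else [0]
    return LinkageDendrogram(labels=labels, merges=merges, leaf_order=leaf_order)
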