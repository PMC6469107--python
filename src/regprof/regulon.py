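"""Data model and summary statistics for the curated Crl regulon.

Crl is not a DNA-binding regulator: it promotes association of the stationary
phase sigma factor sigma-S (RpoS) with RNA polymerase core, so its "regulon"
is the curated set of genes whose transcription responds to Crl.  This module
loads a curated gene table (gene, locus tag, transcription units, co-regulating
transcription factors with signs, Crl effect, evidence codes), validates it
into a small signed network, and computes the descriptive statistics used to
summarize regulon composition: activation/repression tallies, the split
between exclusively Crl-controlled and co-regulated genes, the per-gene count
of additional transcription factors, and transcription-unit structure.  A
hypergeometric enrichment test replaces external annotation services.

Counting conventions
--------------------
* Gene records are keyed by gene symbol; the curated table may repeat a locus
  tag (bnumber) across two symbols, so sign tallies are deduplicated by
  bnumber while the exclusive/co-regulated partition runs over gene symbols.
* A regulator written as a complex ("GadE-RcsB", "FlhDC") is one entity.
* A transcription unit's gene content is expanded from operon nomenclature
  ("csgBAC" -> csgB, csgA, csgC); TU members outside the regulon are kept as
  context only.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegulatoryInteraction",
    "RegulonGene",
    "TranscriptionUnit",
    "RegulonNetwork",
    "SchemaError",
    "TableParseError",
    "load_regulon_table",
    "effect_sign_tally",
    "exclusive_gene_partition",
    "tf_degree_histogram",
    "tu_summary",
    "export_edge_list",
    "enrichment_test",
    "expand_tu_name",
]

EFFECT_SIGNS = ("+", "-", "+/-")
EVIDENCE_CODES = frozenset({"APPH", "GEA", "MSI", "IMP"})


class SchemaError(ValueError):
    """A required column is missing from the regulon table."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message names the offending row."""


@dataclass(frozen=True)
class RegulatoryInteraction:
    regulator: str
    target_gene: str
    effect: str  # one of EFFECT_SIGNS
    evidence: frozenset = frozenset()
    references: tuple = ()

    def __post_init__(self):
        if self.effect not in EFFECT_SIGNS:
            raise ValueError(f"invalid effect sign {self.effect!r}")
        if self.regulator == "Crl" and not self.evidence:
            raise ValueError(f"Crl edge to {self.target_gene} lacks evidence")


@dataclass
class RegulonGene:
    name: str
    bnumber: str
    tus: list
    go_terms: list = field(default_factory=list)
    synonyms: list = field(default_factory=list)

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if not self.tus:
            raise ValueError(f"gene {self.name} has no transcription unit")
        if not re.fullmatch(r"b\d{4}", self.bnumber):
            raise ValueError(f"gene {self.name}: bad bnumber {self.bnumber!r}")


@dataclass
class TranscriptionUnit:
    name: str
    genes: list

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"TU {self.name} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"TU {self.name} lists a gene twice")


@dataclass
class RegulonNetwork:
    """Signed regulator->gene network curated from the gene table."""

    genes: dict  # name -> RegulonGene
    tus: dict  # name -> TranscriptionUnit
    edges: list  # RegulatoryInteraction

    def crl_edges(self):
        return [e for e in self.edges if e.regulator == "Crl"]

    def co_regulator_edges(self):
        return [e for e in self.edges if e.regulator != "Crl"]

    def validate(self):
        for e in self.edges:
            if e.target_gene not in self.genes:
                raise ValueError(f"edge targets unknown gene {e.target_gene}")


_TU_TOKEN = re.compile(r"^([a-z]+)([A-Z][A-Za-z]*)?$")


def expand_tu_name(name: str) -> list:
    """Expand an operon name into its member gene symbols.

    ``"csgBAC"`` -> ``["csgB", "csgA", "csgC"]``; hyphenated segments are
    expanded independently (``"hdeAB-yhiD"`` -> hdeA, hdeB, yhiD).  A segment
    without a capital suffix ("crl", "uof") is a single gene.
    """
    genes = []
    for token in name.split("-"):
        m = _TU_TOKEN.match(token)
        if m is None:
            raise ValueError(f"cannot parse TU segment {token!r} in {name!r}")
        stem, suffix = m.groups()
        if not suffix:
            genes.append(stem)
        else:
            genes.extend(stem + letter for letter in suffix)
    return genes


_REGULATOR = re.compile(r"^(?P<name>[A-Za-z0-9-]+)\((?P<sign>\+/-|\+|-)\)$")

REQUIRED_COLUMNS = (
    "gene",
    "bnumber",
    "tus",
    "co_regulators",
    "crl_effect",
    "evidence",
    "references",
    "go_terms",
)


def _split(cell: str) -> list:
    return [part.strip() for part in cell.split(";") if part.strip()]


def load_regulon_table(path) -> RegulonNetwork:
    """Load a curated regulon table (TSV, ``#`` comments allowed) into a network.

    Each row yields one Crl->gene edge carrying the row's effect sign and
    evidence codes, plus one signed edge per co-regulating transcription
    factor.  Duplicate bnumbers are reported as warnings, not errors.
    """
    path = Path(path)
    rows = []
    with path.open(encoding="utf-8") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise SchemaError(f"missing required column(s): {', '.join(missing)}")
                continue
            if len(fields) < len(header):  # trailing empty cells may be omitted
                fields = fields + [""] * (len(header) - len(fields))
            rows.append((lineno, dict(zip(header, fields))))
    if header is None:
        raise SchemaError("empty file: no header row found")

    genes, tus, edges = {}, {}, []
    tu_members = {}
    for lineno, row in rows:
        name = row["gene"].strip()
        effect = row["crl_effect"].strip()
        if effect not in EFFECT_SIGNS:
            raise TableParseError(f"row {lineno} (gene {name!r}): unknown effect symbol {effect!r}")
        tu_names = _split(row["tus"])
        gene = RegulonGene(
            name=name,
            bnumber=row["bnumber"].strip(),
            tus=tu_names,
            go_terms=_split(row["go_terms"]),
            synonyms=_split(row.get("synonyms", "")),
        )
        if name in genes:
            raise TableParseError(f"row {lineno}: duplicate gene symbol {name!r}")
        genes[name] = gene
        for tu_name in tu_names:
            tu_members.setdefault(tu_name, expand_tu_name(tu_name))
        evidence = frozenset(_split(row["evidence"]))
        unknown = evidence - EVIDENCE_CODES
        if unknown:
            raise TableParseError(
                f"row {lineno} (gene {name!r}): unknown evidence code(s) {sorted(unknown)}"
            )
        refs = tuple(_split(row["references"]))
        edges.append(RegulatoryInteraction("Crl", name, effect, evidence, refs))
        for item in _split(row["co_regulators"]):
            m = _REGULATOR.match(item)
            if m is None:
                raise TableParseError(
                    f"row {lineno} (gene {name!r}): cannot parse regulator {item!r}"
                )
            edges.append(RegulatoryInteraction(m["name"], name, m["sign"]))

    dup = [b for b, c in Counter(g.bnumber for g in genes.values()).items() if c > 1]
    if dup:
        warnings.warn(f"duplicate bnumber(s) across gene rows: {sorted(dup)}", stacklevel=2)

    for tu_name, members in tu_members.items():
        tus[tu_name] = TranscriptionUnit(tu_name, members)

    net = RegulonNetwork(genes=genes, tus=tus, edges=edges)
    net.validate()
    return net


def effect_sign_tally(net: RegulonNetwork) -> dict:
    """Count distinct loci (bnumber-deduplicated) per Crl effect sign.

    Two gene symbols sharing a locus tag count once; if their signs disagree
    the locus is tallied under each sign it carries (does not occur in the
    curated table).
    """
    sign_by_locus = {}
    for e in net.crl_edges():
        locus = net.genes[e.target_gene].bnumber
        sign_by_locus.setdefault(locus, set()).add(e.effect)
    tally = Counter()
    for signs in sign_by_locus.values():
        for s in signs:
            tally[s] += 1
    return dict(tally)


def exclusive_gene_partition(net: RegulonNetwork):
    """Split gene symbols into (exclusively Crl-controlled, co-regulated)."""
    co_regulated = {e.target_gene for e in net.co_regulator_edges()}
    crl_only = set(net.genes) - co_regulated
    return crl_only, co_regulated


def tf_degree_histogram(net: RegulonNetwork) -> dict:
    """Histogram of k = number of distinct non-Crl regulators per co-regulated gene."""
    regs = {}
    for e in net.co_regulator_edges():
        regs.setdefault(e.target_gene, set()).add(e.regulator)
    return dict(Counter(len(v) for v in regs.values()))


def tu_summary(net: RegulonNetwork):
    """Return (number of distinct TUs, percent with exactly one gene, to nearest int)."""
    n = len(net.tus)
    if n == 0:
        return 0, 0
    mono = sum(1 for tu in net.tus.values() if len(tu.genes) == 1)
    return n, round(100.0 * mono / n)


def export_edge_list(net: RegulonNetwork, path, header: bool = False) -> None:
    """Write a 3-column TSV edge list (regulator, target, sign), sorted rows."""
    rows = sorted((e.regulator, e.target_gene, e.effect) for e in net.edges)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write("regulator\ttarget\tsign\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


def load_edge_list(path, header: bool = False) -> list:
    """Read an exported edge list back into (regulator, target, sign) tuples."""
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if header and i == 0:
                continue
            reg, tgt, sign = line.rstrip("\n").split("\t")
            out.append((reg, tgt, sign))
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int  # query genes in category
    K: int  # background genes in category
    n: int  # query size
    N: int  # background size
    p: float  # hypergeometric upper tail P(X >= k)
    p_adj: float  # Benjamini-Hochberg adjusted


def enrichment_test(
    query: Iterable[str],
    background: Iterable[str],
    categories: Mapping[str, Iterable[str]],
) -> dict:
    """One-sided hypergeometric over-representation test per category.

    ``categories`` maps gene -> iterable of category labels.  Returns a dict
    category -> :class:`EnrichmentResult` with raw upper-tail p-values and
    Benjamini-Hochberg adjusted values.  Genes with no category are tallied
    under the reserved label ``"(uncategorized)"``.
    """
    query = set(query)
    background = set(background)
    stray = sorted(query - background)
    if stray:
        raise ValueError(f"query gene(s) absent from background: {stray}")
    by_cat = {}
    for gene in background:
        cats = list(categories.get(gene, ())) or ["(uncategorized)"]
        for c in cats:
            by_cat.setdefault(c, set()).add(gene)
    N, n = len(background), len(query)
    names = sorted(by_cat)
    raw = []
    for c in names:
        members = by_cat[c]
        K = len(members)
        k = len(members & query)
        # upper tail P(X >= k); sf(k-1) is exact for the hypergeometric
        p = float(hypergeom.sf(k - 1, N, K, n))
        raw.append((c, k, K, min(p, 1.0)))
    if not raw:
        return {}
    p_adj = multipletests([r[3] for r in raw], method="fdr_bh")[1]
    return {
        c: EnrichmentResult(c, k, K, n, N, p, float(adj))
        for (c, k, K, p), adj in zip(raw, p_adj)
    }


def packaged_table1_path() -> Path:
    """Path of the curated regulon table shipped with the package."""
    return Path(__file__).parent / "data" / "table1.tsv"
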