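"""Promoter extraction and cis-regulatory element census.

Promoters are the 1500 bp upstream of the annotated CDS start, taken on
the gene's strand. Elements are IUPAC consensus strings from an editable
catalog grouped into the four functional categories (hormone, stress,
development, other); occurrences are counted on both strands pooled,
with palindromic double-hits counted once.

The shipped catalog carries literature-standard consensus strings; the
element names and categories follow the PlantCARE vocabulary, but any
TSV (name, consensus, category) can be substituted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .core_io import GeneModel, SequenceRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CATEGORIES = ("hormone", "stress", "development", "other")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CisElementEntry:
    name: str
    consensus: str
    category: str

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if not self.consensus:
            raise ValueError(f"element {self.name!r}: empty consensus")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(
                f"element {self.name!r}: non-IUPAC symbols {sorted(bad)}")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"element {self.name!r}: unknown category {self.category!r}")

    def regex(self) -> str:
        return "".join(IUPAC[c] for c in self.consensus)


@dataclass
class CisCatalog:
    elements: list[CisElementEntry]
    version: str = "builtin-1"

    def __post_init__(self) -> None:
        names = [e.name for e in self.elements]
        if len(names) != len(set(names)):
            raise ValueError("element names must be unique")
        self._by_name = {e.name: e for e in self.elements}

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> CisElementEntry:
        return self._by_name[name]

    def names(self) -> list[str]:
        return [e.name for e in self.elements]

    @classmethod
    def from_tsv(cls, path, version: str = "") -> "CisCatalog":
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["name", "consensus", "category"])
        elements = [CisElementEntry(r.name, r.consensus, r.category)
                    for r in df.itertuples(index=False)]
        return cls(elements, version or str(path))


def default_catalog() -> CisCatalog:
    """The shipped PlantCARE-style element catalog."""
    path = resources.files("kincascade.data") / "cis_catalog.tsv"
    with resources.as_file(path) as p:
        return CisCatalog.from_tsv(p, version="builtin-1")


def extract_promoter(
    gene: GeneModel,
    genome: dict[str, str],
    length: int = 1500,
) -> SequenceRecord:
    """The ``length`` bp upstream of a gene, 5'->3' relative to the gene.

    Plus strand: bases [start-length, start-1] (1-based inclusive),
    truncated at position 1. Minus strand: bases [end+1, end+length],
    truncated at the chromosome end, reverse-complemented. A truncated
    promoter is flagged in the record description.
    """
    if gene.chromosome not in genome:
        raise KeyError(f"chromosome {gene.chromosome!r} not in genome")
    chrom = genome[gene.chromosome]
    truncated = False
    if gene.strand == "+":
        lo = gene.start - length
        if lo < 1:
            lo = 1
            truncated = True
        region = chrom[lo - 1: gene.start - 1]
    else:
        hi = gene.end + length
        if hi > len(chrom):
            hi = len(chrom)
            truncated = True
        region = reverse_complement(chrom[gene.end: hi])
    if not region:
        raise ValueError(f"gene {gene.gene_id}: empty promoter region")
    desc = "truncated" if truncated else ""
    return SequenceRecord(f"{gene.gene_id}_promoter", region, desc, "dna")


def _match_intervals(seq: str, pattern: str) -> set[tuple[int, int]]:
    width = len(pattern)
    rx = re.compile("(?=(" + "".join(IUPAC[c] for c in pattern) + "))")
    return {(m.start(), m.start() + width) for m in rx.finditer(seq)}


@dataclass
class PromoterScanResult:
    gene_id: str
    counts: dict[str, int]
    category_totals: dict[str, int]


def scan_elements(promoter, catalog: CisCatalog) -> PromoterScanResult:
    """Count every (overlapping) occurrence of each element, both strands.

    An occurrence is an interval of the promoter matching the consensus
    on either strand; a palindromic site matching both strands at the
    same interval is counted once.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    seq = (promoter.seq if hasattr(promoter, "seq") else str(promoter)).upper()
    gene_id = getattr(promoter, "id", "")
    counts: dict[str, int] = {}
    for entry in catalog.elements:
        fwd = _match_intervals(seq, entry.consensus)
        rev = _match_intervals(seq, reverse_complement(entry.consensus))
        counts[entry.name] = len(fwd | rev)
    totals = {c: 0 for c in CATEGORIES}
    for entry in catalog.elements:
        totals[entry.category] += counts[entry.name]
    return PromoterScanResult(gene_id, counts, totals)


def category_rollup(
    results: list[PromoterScanResult],
    catalog: CisCatalog,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate element occurrences and gene-level presences across genes.

    Returns ``(per_element, per_category)``: the element table carries
    total occurrences and the number of genes with at least one
    occurrence; the category table sums member elements.
    """
    if not results:
        raise ValueError("no scan results to aggregate")
    for res in results:
        unknown = set(res.counts) - set(catalog.names())
        if unknown:
            raise KeyError(
                f"element(s) {sorted(unknown)} missing from catalog")
    rows = []
    for entry in catalog.elements:
        total = sum(r.counts.get(entry.name, 0) for r in results)
        genes_with = sum(r.counts.get(entry.name, 0) > 0 for r in results)
        rows.append({"element": entry.name, "category": entry.category,
                     "total_occurrences": total, "genes_with_element": genes_with})
    per_element = pd.DataFrame(rows)
    per_category = (per_element.groupby("category", sort=False)
                    ["total_occurrences"].sum().reset_index())
    return per_element, per_category
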