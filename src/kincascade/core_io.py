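"""Readers/writers for the standard formats the pipeline touches.

The shared data model (sequences, gene models, annotations, interaction
edge lists) lives here; every downstream module consumes these types.
Coordinates are GFF3-style 1-based inclusive throughout.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

# '-' is tolerated so aligned FASTA round-trips through the same type
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX-")
DNA_ALPHABET = frozenset("ACGTN-")

_ALPHABETS = {"protein": PROTEIN_ALPHABET, "dna": DNA_ALPHABET}


@dataclass
class SequenceRecord:
    """A named biological sequence (protein or DNA), stored uppercase."""

    id: str
    seq: str
    description: str = ""
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"empty sequence for id {self.id!r}")
        allowed = _ALPHABETS[self.alphabet]
        for pos, res in enumerate(self.seq):
            if res not in allowed:
                raise ValueError(
                    f"residue {res!r} at position {pos} of {self.id!r} "
                    f"not in {self.alphabet} alphabet"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A gene with chromosome placement and its transcript isoforms.

    ``transcripts`` maps each transcript id to the encoded protein length
    in amino acids (0 when unknown).
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    transcripts: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates "
                f"{self.start}..{self.end} (need 1 <= start <= end)"
            )


class GenomeAnnotation:
    """Ordered gene collection with per-chromosome gene ranks.

    Ranks are 1-based ordinal positions along each chromosome, sorted by
    ascending start coordinate (ties broken by gene id).
    """

    def __init__(
        self,
        genes: list[GeneModel],
        chromosome_lengths: dict[str, int] | None = None,
    ):
        self.genes = list(genes)
        self.chromosome_lengths = dict(chromosome_lengths or {})
        self._by_id = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            self._by_id[g.gene_id] = g
            length = self.chromosome_lengths.get(g.chromosome)
            if length is not None and g.end > length:
                raise ValueError(
                    f"gene {g.gene_id} ends at {g.end} beyond chromosome "
                    f"{g.chromosome} length {length}"
                )
        self.gene_rank: dict[str, int] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom_genes in by_chrom.values():
            chrom_genes.sort(key=lambda g: (g.start, g.gene_id))
            for rank, g in enumerate(chrom_genes, start=1):
                self.gene_rank[g.gene_id] = rank

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id


@dataclass
class EdgeList:
    """Undirected interaction network: unordered node pairs, no self-loops."""

    edges: set[tuple[str, str]] = field(default_factory=set)
    confidence: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        return (a, b) if a < b else (b, a)

    def add(self, a: str, b: str, confidence: float | None = None) -> None:
        key = self._key(a, b)
        self.edges.add(key)
        if confidence is not None:
            if not 0.0 <= confidence <= 1.0:
                raise ValueError("confidence must lie in [0,1]")
            self.confidence[key] = confidence


def read_fasta(path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Wrapped lines are concatenated, trailing ``*`` stop symbols are
    stripped (with a logged note), and duplicate ids or residues outside
    the declared alphabet raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.info("stripping %d '*' stop symbol(s) from %s",
                        seq.count("*"), rec.id)
            seq = seq.replace("*", "")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, seq, desc, alphabet))
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def read_gff3(path) -> GenomeAnnotation:
    """Parse a GFF3 file (gene + mRNA features) into a GenomeAnnotation.

    mRNA features must name a parent gene; chromosome lengths are taken
    from ``##sequence-region`` pragmas when present.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    chrom_lengths: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                chrom_lengths[parts[1]] = int(parts[3])

    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type("gene"):
        if feat.start > feat.end:
            raise ValueError(
                f"gene {feat.id}: start {feat.start} > end {feat.end}")
        genes[feat.id] = GeneModel(
            gene_id=feat.id,
            chromosome=feat.seqid,
            strand=feat.strand if feat.strand in "+-" else "+",
            start=feat.start,
            end=feat.end,
        )
    for feat in db.features_of_type("mRNA"):
        parents = feat.attributes.get("Parent", [])
        if not parents or parents[0] not in genes:
            raise ValueError(f"mRNA {feat.id} has no parent gene")
        plen = feat.attributes.get("protein_length", ["0"])[0]
        genes[parents[0]].transcripts.append((feat.id, int(plen)))
    return GenomeAnnotation(list(genes.values()), chrom_lengths)


def read_edge_list(path) -> EdgeList:
    """Read a TSV edge list (node_a, node_b[, confidence])."""
    net = EdgeList()
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for row in df.itertuples(index=False):
        conf = float(row[2]) if len(row) > 2 and pd.notna(row[2]) else None
        net.add(str(row[0]), str(row[1]), conf)
    return net


def degree_summary(net: EdgeList) -> pd.DataFrame:
    """Per-node degree table, sorted by degree descending then node id.

    The sum of degrees always equals twice the edge count.
    """
    degrees: dict[str, int] = {}
    for a, b in net.edges:
        degrees[a] = degrees.get(a, 0) + 1
        degrees[b] = degrees.get(b, 0) + 1
    df = pd.DataFrame(
        sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["node", "degree"],
    )
    return df


def write_newick(tree, path) -> None:
    """Serialize a phylogeny-module tree to a Newick file.

    Branch lengths are written to 6 decimals and internal-node bootstrap
    supports become internal labels; round-tripping preserves topology.
    """
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path):
    from .phylogeny import PhyloTree

    return PhyloTree.from_newick(Path(path).read_text().strip())
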