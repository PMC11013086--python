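"""Candidate identification by sequence similarity and profile scoring.

Family members are found by global affine-gap alignment of a proteome
against seed/query proteins (with a shared k-mer prefilter), optionally
unioned with hits of a position-specific scoring matrix built from a seed
alignment. Redundancy removal keeps the longest isoform per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import GenomeAnnotation, SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    identity: float
    aligned_length: int
    query_coverage: float
    subject_coverage: float


def _make_aligner(matrix=None, gap_open: float = 10.0,
                  gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = (
        matrix if matrix is not None
        else substitution_matrices.load("BLOSUM62")
    )
    # a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _seq_str(seq) -> str:
    return seq.seq if hasattr(seq, "seq") else str(seq)


def global_align(a, b, matrix=None, gap_open: float = 10.0,
                 gap_extend: float = 1.0) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment with affine gaps.

    A gap of length L is penalized ``gap_open + L * gap_extend``; scores
    are symmetric in the two inputs. Identity is the fraction of matches
    over paired (gap-free) columns; coverage is the fraction of each
    sequence's residues in paired columns.
    """
    sa, sb = _seq_str(a), _seq_str(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(sa, sb)[0]
    matches = paired = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        paired += qe - qs
        for i, j in zip(range(qs, qe), range(ts, te)):
            if sa[i] == sb[j]:
                matches += 1
    return AlignmentResult(
        query_id=getattr(a, "id", ""),
        subject_id=getattr(b, "id", ""),
        score=float(aln.score),
        identity=matches / paired if paired else 0.0,
        aligned_length=aln.length,
        query_coverage=paired / len(sa),
        subject_coverage=paired / len(sb),
    )


def _kmer_set(s: str, k: int = 4) -> set[str]:
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def find_candidates(
    proteome: list[SequenceRecord],
    seeds: list[SequenceRecord],
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
    k: int = 4,
    prefilter: bool = True,
) -> list[tuple[str, str, AlignmentResult]]:
    """Identify family candidates by alignment against seed proteins.

    A shared k-mer count prefilter skips seed/protein pairs with no word
    in common; a protein qualifies when any seed alignment reaches both
    the identity and (two-sided) coverage thresholds. Returns one row per
    candidate: (protein id, best seed id, best AlignmentResult).
    """
    if not seeds:
        raise ValueError("empty seed set")
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    seed_kmers = [(s, _kmer_set(s.seq, k)) for s in seeds]
    out = []
    for prot in proteome:
        pk = _kmer_set(prot.seq, k)
        ranked = sorted(
            seed_kmers,
            key=lambda sk: (-len(pk & sk[1]), sk[0].id),
        )
        best: AlignmentResult | None = None
        for seed, kmers in ranked:
            if prefilter and not (pk & kmers):
                continue
            res = global_align(prot, seed)
            if (res.identity >= min_identity
                    and res.query_coverage >= min_coverage
                    and res.subject_coverage >= min_coverage):
                if best is None or res.score > best.score:
                    best = res
        if best is not None:
            out.append((prot.id, best.subject_id, best))
    return out


@dataclass
class Pssm:
    """Position-specific log-odds profile against a uniform background."""

    scores: np.ndarray  # width x 20, log2 odds
    alphabet: str = AA20

    @property
    def width(self) -> int:
        return len(self.scores)

    @classmethod
    def from_alignment(cls, seqs: list, pseudocount: float = 1.0) -> "Pssm":
        """Build a profile from equal-length (gap-free) seed sequences."""
        strs = [_seq_str(s) for s in seqs]
        width = len(strs[0])
        if width < 3:
            raise ValueError("profile width must be >= 3")
        if any(len(s) != width for s in strs):
            raise ValueError("seed sequences must have equal length")
        idx = {a: i for i, a in enumerate(AA20)}
        counts = np.full((width, 20), pseudocount, dtype=float)
        for s in strs:
            for j, r in enumerate(s):
                if r in idx:
                    counts[j, idx[r]] += 1
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(scores=np.log2(probs / (1.0 / 20.0)))

    def window_score(self, window: str) -> float:
        idx = {a: i for i, a in enumerate(AA20)}
        total = 0.0
        for j, r in enumerate(window):
            if r not in idx:
                return -math.inf  # X never matches
            total += self.scores[j, idx[r]]
        return total


def pssm_scan(seq, profile: Pssm, threshold: float) -> list[tuple[int, float]]:
    """All windows scoring >= threshold bits, sorted by offset."""
    s = _seq_str(seq)
    if profile.width > len(s):
        return []
    hits = []
    for off in range(len(s) - profile.width + 1):
        score = profile.window_score(s[off:off + profile.width])
        if score >= threshold:
            hits.append((off, score))
    return hits


def remove_redundancy(
    candidates: list[SequenceRecord],
    annotation: GenomeAnnotation,
    transcript_to_gene: dict[str, str] | None = None,
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """One representative per gene: the longest isoform (ties by id).

    ``transcript_to_gene`` maps candidate ids to gene ids; when omitted it
    is derived from the annotation's transcript lists. Identical
    full-length sequences shared across genes are all retained but
    reported in the returned ``flags`` mapping (sequence -> gene ids).
    """
    if transcript_to_gene is None:
        transcript_to_gene = {
            tid: g.gene_id
            for g in annotation.genes for tid, _ in g.transcripts
        }
    by_gene: dict[str, list[SequenceRecord]] = {}
    for rec in candidates:
        gene = transcript_to_gene.get(rec.id)
        if gene is None:
            raise KeyError(f"candidate {rec.id!r} maps to no gene")
        by_gene.setdefault(gene, []).append(rec)
    kept = []
    for gene in by_gene:
        reps = sorted(by_gene[gene], key=lambda r: (-len(r.seq), r.id))
        kept.append(reps[0])
    kept.sort(key=lambda r: r.id)
    seq_to_genes: dict[str, list[str]] = {}
    for rec in kept:
        seq_to_genes.setdefault(rec.seq, []).append(
            transcript_to_gene[rec.id])
    flags = {
        rec.id: seq_to_genes[rec.seq]
        for rec in kept if len(seq_to_genes[rec.seq]) > 1
    }
    return kept, flags


def identify_family(
    proteome: list[SequenceRecord],
    seeds: list[SequenceRecord],
    profile: "Pssm | None" = None,
    profile_threshold: float = 10.0,
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
) -> list[str]:
    """Union of similarity-search candidates and profile-scan hits.

    Mirrors the two-pronged search design of family surveys: a protein
    qualifies if it aligns to any seed above the thresholds or if any
    window clears the profile's log-odds threshold.
    """
    members = {pid for pid, _, _ in find_candidates(
        proteome, seeds, min_identity, min_coverage)}
    if profile is not None:
        for rec in proteome:
            if rec.id not in members and pssm_scan(
                    rec, profile, profile_threshold):
                members.add(rec.id)
    return sorted(members)


@dataclass
class HomologPair:
    """A homologous gene pair (ids stored lexicographically, a < b)."""

    a: str
    b: str
    identity: float = 0.0
    coverage: float = 0.0
    reciprocal_best: bool = False

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("homolog pair members must differ")
        if self.a > self.b:
            self.a, self.b = self.b, self.a

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b)


def call_homolog_pairs(
    members: list[SequenceRecord],
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
) -> list[HomologPair]:
    """All-vs-all alignment among family members; emit qualifying pairs."""
    if len(members) < 2:
        raise ValueError("need at least two members")
    n = len(members)
    best_partner: dict[str, tuple[float, str]] = {}
    results: dict[tuple[int, int], AlignmentResult] = {}
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(members[i], members[j])
            results[(i, j)] = res
            for x, y in ((members[i].id, members[j].id),
                         (members[j].id, members[i].id)):
                cur = best_partner.get(x)
                if cur is None or res.score > cur[0]:
                    best_partner[x] = (res.score, y)
    pairs = []
    for (i, j), res in sorted(results.items()):
        cov = min(res.query_coverage, res.subject_coverage)
        if res.identity >= min_identity and cov >= min_coverage:
            a, b = members[i].id, members[j].id
            recip = (best_partner[a][1] == b and best_partner[b][1] == a)
            pairs.append(HomologPair(a, b, res.identity, cov, recip))
    pairs.sort(key=lambda p: p.key)
    return pairs
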