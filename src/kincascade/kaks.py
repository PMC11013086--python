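"""Molecular evolution of duplicated gene pairs.

Implements the Nei-Gojobori (1986) method: synonymous and nonsynonymous
site counting by enumeration of the nine single-nucleotide neighbors of
each codon (stop-codon neighbors excluded from the denominator),
difference counting averaged over all minimal stop-free mutational
pathways, Jukes-Cantor multiple-hit correction
d = -(3/4) ln(1 - (4/3) p), and divergence dating T = Ks / (2 lambda)
with the rice/wheat-standard synonymous clock lambda = 6.5e-9
substitutions per site per year.

Duplication typing distinguishes tandem copies (nearby gene ranks on one
chromosome), segmental copies (anchors of a collinear block found by
monotone-chain detection), and dispersed copies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .core_io import GenomeAnnotation
from .homology import HomologPair

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

#: synonymous substitution clock (substitutions / site / year)
DEFAULT_LAMBDA = 6.5e-9

NUCS = "ACGT"


@dataclass
class CodonAlignment:
    """A gap-free, equal-length, in-frame CDS pair."""

    a: str
    b: str

    def __post_init__(self) -> None:
        self.a, self.b = self.a.upper(), self.b.upper()
        if len(self.a) != len(self.b):
            raise ValueError("CDS pair must have equal lengths")
        if len(self.a) % 3 != 0:
            raise ValueError("CDS length must be a multiple of 3")
        if not self.a:
            raise ValueError("empty CDS")
        for s, name in ((self.a, "first"), (self.b, "second")):
            if set(s) - set(NUCS):
                raise ValueError(f"{name} CDS contains non-ACGT characters")
            for i in range(0, len(s), 3):
                if s[i:i + 3] in STOP_CODONS:
                    raise ValueError(
                        f"stop codon {s[i:i+3]} at position {i} in {name} CDS")

    @property
    def n_codons(self) -> int:
        return len(self.a) // 3


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float  # nan when undefined
    Ka: float
    omega: float  # nan when undefined
    T_mya: float
    purifying: bool | None
    high_pS: bool
    flag: str = ""


def _syn_fraction(codon: str) -> float:
    """Synonymous-site count of one codon (0..3), stop neighbors excluded."""
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = denom = 0
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            denom += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if denom:
            total += syn / denom
    return total


def _codon_path_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average (syn, nonsyn) step counts over minimal stop-free paths."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = ca
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if not blocked:
            paths.append((syn, nonsyn))
    if not paths:
        # every ordering crosses a stop; fall back to all orderings
        for order in itertools.permutations(diff_pos):
            cur = ca
            syn = nonsyn = 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            paths.append((syn, nonsyn))
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p); nan if p >= 3/4."""
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def divergence_time(ks: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Divergence time in Mya: T = Ks / (2 lambda), reported in 1e6 years."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if math.isnan(ks):
        return math.nan
    if ks < 0:
        raise ValueError("Ks must be nonnegative")
    return ks / (2.0 * lam) * 1e-6


def ng86(aln: CodonAlignment, lam: float = DEFAULT_LAMBDA) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Site counts are averaged over the two sequences; multi-difference
    codons are resolved by averaging over all minimal stop-free
    mutational pathways. ``omega`` is reported as nan (with a reason in
    ``flag``) when Ks is zero or a proportion exceeds the correction
    domain p < 3/4.
    """
    S = Sd = Nd = 0.0
    for i in range(0, len(aln.a), 3):
        ca, cb = aln.a[i:i + 3], aln.b[i:i + 3]
        S += 0.5 * (_syn_fraction(ca) + _syn_fraction(cb))
        s, n = _codon_path_counts(ca, cb)
        Sd += s
        Nd += n
    N = 3.0 * aln.n_codons - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    flag = ""
    if math.isnan(Ks):
        flag = "Ks undefined: pS >= 3/4"
    elif math.isnan(Ka):
        flag = "Ka undefined: pN >= 3/4"
    if math.isnan(Ks) or math.isnan(Ka):
        omega = math.nan
    elif Ks == 0.0:
        omega = math.nan
        flag = "omega undefined: Ks = 0"
    else:
        omega = Ka / Ks
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        omega=omega,
        T_mya=divergence_time(Ks, lam) if not math.isnan(Ks) else math.nan,
        purifying=(omega < 1.0) if not math.isnan(omega) else None,
        high_pS=pS >= 0.75,
        flag=flag,
    )


@dataclass
class SyntenyBlock:
    """A chained run of collinear homolog anchors on a chromosome pair."""

    chrom_a: str
    chrom_b: str
    anchors: list[tuple[int, int, HomologPair]]  # (rank_a, rank_b, pair)
    orientation: str = "+"  # "+" increasing, "-" decreasing on chrom_b

    @property
    def length(self) -> int:
        return len(self.anchors)

    def pair_keys(self) -> set[tuple[str, str]]:
        return {p.key for _, _, p in self.anchors}


def _best_chain(anchors: list[tuple[int, int]], sign: int,
                max_gap: int) -> list[int]:
    """Longest chain with strictly monotone second ranks and bounded gaps.

    ``anchors`` are (rank_a, rank_b) sorted by rank_a; ``sign`` +1 for an
    increasing, -1 for a decreasing second-chromosome run. Among maximal
    chains the lexicographically smallest index sequence is returned, so
    the result is deterministic and matches exhaustive search.
    """
    n = len(anchors)
    best_len = [1] * n  # best chain length starting at i
    order = sorted(range(n), key=lambda i: -anchors[i][0])
    for i in order:
        for j in range(n):
            if _chainable(anchors[i], anchors[j], sign, max_gap):
                best_len[i] = max(best_len[i], 1 + best_len[j])
    if n == 0:
        return []
    target = max(best_len)
    # reconstruct lexicographically smallest index path of maximal length
    starts = [i for i in range(n) if best_len[i] == target]
    path = [min(starts)]
    remaining = target - 1
    while remaining:
        cur = path[-1]
        nxt = min(
            j for j in range(n)
            if _chainable(anchors[cur], anchors[j], sign, max_gap)
            and best_len[j] == remaining
        )
        path.append(nxt)
        remaining -= 1
    return path


def _chainable(a: tuple[int, int], b: tuple[int, int], sign: int,
               max_gap: int) -> bool:
    da = b[0] - a[0]
    db = sign * (b[1] - a[1])
    return 0 < da <= max_gap and 0 < db <= max_gap


def detect_synteny(
    pairs: list[HomologPair],
    annotation: GenomeAnnotation,
    min_block: int = 3,
    max_gap: int = 10,
) -> list[SyntenyBlock]:
    """Find collinear blocks by greedy longest-monotone-chain extraction.

    For each (inter-chromosomal) chromosome pair, anchors are sorted by
    rank on the first chromosome and maximal chains with strictly
    monotone second-chromosome ranks and consecutive rank gaps at most
    ``max_gap`` on both chromosomes are peeled off longest-first (ties:
    increasing orientation, then leftmost start). Chains shorter than
    ``min_block`` are discarded; each anchor joins at most one block.
    """
    if min_block < 2:
        raise ValueError("min_block must be >= 2")
    by_chrom_pair: dict[tuple[str, str], list[tuple[int, int, HomologPair]]] = {}
    for pair in pairs:
        ga, gb = annotation.gene(pair.a), annotation.gene(pair.b)
        if ga.chromosome == gb.chromosome:
            continue  # intra-chromosomal collinearity out of scope
        if ga.chromosome > gb.chromosome:
            ga, gb = gb, ga
        key = (ga.chromosome, gb.chromosome)
        by_chrom_pair.setdefault(key, []).append(
            (annotation.gene_rank[ga.gene_id],
             annotation.gene_rank[gb.gene_id], pair))

    blocks: list[SyntenyBlock] = []
    for (ca, cb), anchors in sorted(by_chrom_pair.items()):
        pool = sorted(anchors, key=lambda t: (t[0], t[1]))
        while len(pool) >= min_block:
            coords = [(a, b) for a, b, _ in pool]
            inc = _best_chain(coords, +1, max_gap)
            dec = _best_chain(coords, -1, max_gap)
            path, sign = (inc, "+") if len(inc) >= len(dec) else (dec, "-")
            if len(path) < min_block:
                break
            blocks.append(SyntenyBlock(
                ca, cb, [pool[i] for i in path], orientation=sign))
            used = set(path)
            pool = [p for i, p in enumerate(pool) if i not in used]
    return blocks


@dataclass
class DuplicationCall:
    pair: HomologPair
    kind: str  # tandem | segmental | dispersed


def classify_duplication(
    pair: HomologPair,
    annotation: GenomeAnnotation,
    blocks: list[SyntenyBlock],
    tandem_gap: int = 5,
) -> DuplicationCall:
    """Label a homolog pair tandem, segmental, or dispersed.

    Tandem: same chromosome (excluding the unplaced bin "Un") with at
    most ``tandem_gap`` intervening genes. Segmental: an anchor of any
    collinear block. Everything else: dispersed.
    """
    ga, gb = annotation.gene(pair.a), annotation.gene(pair.b)
    if ga.chromosome == gb.chromosome and ga.chromosome != "Un":
        rank_diff = abs(annotation.gene_rank[pair.a]
                        - annotation.gene_rank[pair.b])
        if rank_diff <= tandem_gap + 1:
            return DuplicationCall(pair, "tandem")
    for block in blocks:
        if pair.key in block.pair_keys():
            return DuplicationCall(pair, "segmental")
    return DuplicationCall(pair, "dispersed")
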