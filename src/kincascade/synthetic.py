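"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure the analysis assumes —
proteomes with planted tier-signature motifs, gene layouts with tandem
arrays and collinear blocks, codon pairs evolved at a known Ka/Ks ratio,
promoters with planted cis-elements on a match-free background,
log-normal expression matrices with planted condition effects, and
replicate Ct tables with known fold changes — and returns a truth table
alongside the data. Backgrounds are rejection-sampled (or iteratively
repaired) to be motif-free, so expected counts are exact oracles rather
than approximations.

One global seed drives a named substream per generator, so a fixed seed
reproduces every output byte-for-byte while generators stay independent.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GeneModel, GenomeAnnotation, SequenceRecord
from .homology import HomologPair
from .kaks import CODON_TO_AA, STOP_CODONS
from .motifs import AA20, MotifPattern, SIGNATURES, compile_pattern, scan
from .promoters import CisCatalog, default_catalog, reverse_complement

NUCS = "ACGT"

# stable substream ids, one per generator
_STREAMS = {
    "proteome": 1, "layout": 2, "codon": 3, "promoter": 4,
    "expression": 5, "ct": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class ExprDesign:
    """Design of the synthetic expression matrix."""

    n_genes: int = 100
    conditions: tuple[str, ...] = ("control", "drought", "heat")
    control: str = "control"
    replicates: int = 3
    #: planted log2 fold changes: {(gene index, condition): effect}
    effects: dict[tuple[int, str], float] = field(default_factory=dict)
    noise_sd: float = 0.25  # sd of log2-scale replicate noise
    base_mean: float = 5.0  # mean of log2 baseline abundance
    base_sd: float = 2.0


@dataclass
class CtDesign:
    """Design of the synthetic qPCR Ct table."""

    genes: tuple[str, ...] = ("g1", "g2", "g3", "g4")
    conditions: tuple[str, ...] = ("control", "drought")
    control: str = "control"
    replicates: int = 3
    #: true fold changes vs control: {(gene, condition): fold}
    fold_changes: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.2  # Gaussian Ct replicate noise
    reference_ct: float = 18.0
    base_dct: float = 4.0


@dataclass
class SynthesisConfig:
    """All knobs of the synthetic study, with the study-scale defaults.

    Tier counts default to the family composition of the wheat MAPK
    cascade census (48 MAPK, 17 MAP2K, 27 MEKK, 107 RAF, 10 ZIK,
    25 MAP4K) plus 200 non-kinase decoys.
    """

    seed: int = 0
    tier_counts: dict[str, int] = field(default_factory=lambda: {
        "MAPK": 48, "MAP2K": 17, "MEKK": 27, "RAF": 107,
        "ZIK": 10, "MAP4K": 25,
    })
    decoy_count: int = 200
    protein_length: tuple[int, int] = (300, 600)
    map4k_substituted_fraction: float = 0.76  # third-G -> A, as in wheat

    #: (name, length bp, gene count)
    chromosomes: list[tuple[str, int, int]] = field(default_factory=lambda: [
        ("1A", 3_000_000, 30), ("1B", 3_000_000, 30),
        ("2A", 3_000_000, 30), ("2B", 3_000_000, 30),
        ("3A", 3_000_000, 30), ("3B", 3_000_000, 30),
    ])
    #: (chromosome, array size)
    tandem_arrays: list[tuple[str, int]] = field(default_factory=lambda: [
        ("1A", 3), ("2A", 4), ("3B", 3),
    ])
    #: (chrom a, chrom b, anchor count)
    synteny_blocks: list[tuple[str, str, int]] = field(default_factory=lambda: [
        ("1A", "1B", 6), ("2A", "2B", 5), ("3A", "3B", 4),
    ])
    dispersed_pairs: int = 4

    #: (omega target, codon count, proposals per lineage)
    omega_settings: list[tuple[float, int, int]] = field(
        default_factory=lambda: [(0.2, 300, 90), (1.0, 300, 90)])
    pairs_per_setting: int = 200

    n_promoters: int = 50
    promoter_length: int = 1500
    #: planted occurrences per promoter, by element name
    promoter_plants: dict[str, int] = field(default_factory=lambda: {
        "ABRE": 2, "MBS": 1, "LTR": 1, "GCN4_motif": 1,
    })

    expr_design: ExprDesign = field(default_factory=ExprDesign)
    ct_design: CtDesign = field(default_factory=CtDesign)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.tier_counts.values()):
            raise ValueError("tier counts must be nonnegative")
        if any(w <= 0 for w, _, _ in self.omega_settings):
            raise ValueError("omega targets must be positive")
        if self.expr_design.noise_sd < 0 or self.ct_design.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


# ---------------------------------------------------------------------------
# proteome


def _instantiate(pattern: MotifPattern, rng: np.random.Generator) -> str:
    out = []
    for tok in pattern.tokens:
        if tok[0] == "lit":
            out.append(tok[1])
        elif tok[0] == "alt":
            out.append(sorted(tok[1])[rng.integers(len(tok[1]))])
        elif tok[0] == "any":
            out.append(AA20[rng.integers(20)])
        else:  # gap
            out.extend(AA20[i] for i in rng.integers(0, 20, size=tok[1]))
    return "".join(out)


_SIG_PATTERNS = {t: compile_pattern(s, name=t, tier=t)
                 for t, s in SIGNATURES.items()}
_SIG_REGEXES = [re.compile(p.to_regex()) for p in _SIG_PATTERNS.values()]


def _clean_background(n: int, rng: np.random.Generator,
                      max_tries: int = 200) -> str:
    """Uniform random protein segment free of any tier-signature match."""
    for _ in range(max_tries):
        s = "".join(AA20[i] for i in rng.integers(0, 20, size=n))
        if not any(rx.search(s) for rx in _SIG_REGEXES):
            return s
    raise RuntimeError("could not sample a signature-free background")


def gen_proteome(cfg: SynthesisConfig) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Proteome with one planted signature per tier member, plus decoys.

    MAP4K members carry the four kinase hallmarks (glycine-rich loop,
    invariant K, HRD, DFG) N-to-C before the signature; a configured
    fraction has the third glycine substituted by alanine. Decoys are
    rejection-sampled to contain no tier signature. Every assembled
    sequence is verified to classify as its planted tier (backgrounds
    are resampled otherwise), so recovery tests have an exact oracle.
    """
    from .motifs import classify_tier

    if all(c == 0 for c in cfg.tier_counts.values()):
        raise ValueError("empty design: all tier counts are zero")
    rng = _rng(cfg.seed, "proteome")
    records: list[SequenceRecord] = []
    truth_rows = []

    for tier in ("MAPK", "MAP2K", "MEKK", "RAF", "ZIK", "MAP4K"):
        pat = _SIG_PATTERNS[tier]
        for i in range(cfg.tier_counts.get(tier, 0)):
            rec_id = f"KIN_{tier}_{i + 1:03d}"
            for _attempt in range(100):
                lo, hi = cfg.protein_length
                total = int(rng.integers(lo, hi + 1))
                sig = _instantiate(pat, rng)
                row: dict = {"id": rec_id, "tier": tier}
                if tier == "MAP4K":
                    substituted = rng.random() < cfg.map4k_substituted_fraction
                    third_g = "A" if substituted else "G"
                    grich = ("G" + AA20[rng.integers(20)] + "G"
                             + AA20[rng.integers(20)] + AA20[rng.integers(20)]
                             + third_g)
                    spacer_k = "".join(
                        AA20.replace("K", "")[j]
                        for j in rng.integers(0, 19, size=int(rng.integers(9, 25))))
                    core = (grich + spacer_k + "K"
                            + _clean_background(int(rng.integers(5, 20)), rng)
                            + "HRD"
                            + _clean_background(int(rng.integers(5, 20)), rng)
                            + "DFG"
                            + _clean_background(int(rng.integers(3, 10)), rng)
                            + sig)
                    row["glycine_status"] = (
                        "substituted A" if substituted else "canonical G")
                else:
                    core = sig
                    if tier == "MAPK":
                        row["activation_loop"] = sig[:3]
                nterm_len = int(rng.integers(20, max(21, total - len(core) - 20)))
                cterm_len = max(10, total - len(core) - nterm_len)
                seq = (_clean_background(nterm_len, rng) + core
                       + _clean_background(cterm_len, rng))
                offset = seq.find(sig)
                call = classify_tier(seq)
                if call.tier != tier:
                    continue
                if tier == "MAP4K":
                    # the audit must read the planted hallmarks, not a
                    # spurious background match of the glycine-rich loop
                    from .motifs import audit_map4k
                    audit = audit_map4k(seq)
                    if (audit.glycine_rich != row["glycine_status"]
                            or not (audit.invariant_k and audit.hrd
                                    and audit.dfg)):
                        continue
                break
            else:
                raise RuntimeError(f"could not assemble a clean {tier} member")
            row["motif_offset"] = offset
            records.append(SequenceRecord(rec_id, seq))
            truth_rows.append(row)

    for i in range(cfg.decoy_count):
        rec_id = f"DECOY_{i + 1:03d}"
        lo, hi = cfg.protein_length
        seq = _clean_background(int(rng.integers(lo, hi + 1)), rng)
        records.append(SequenceRecord(rec_id, seq))
        truth_rows.append({"id": rec_id, "tier": "decoy"})

    truth = pd.DataFrame(truth_rows).set_index("id")
    return records, truth


# ---------------------------------------------------------------------------
# gene layout


def gen_layout(cfg: SynthesisConfig) -> tuple[
        GenomeAnnotation, list[HomologPair], pd.DataFrame]:
    """Gene layout with planted tandem arrays, collinear blocks, and
    dispersed homolog pairs.

    Tandem arrays occupy consecutive gene ranks on one chromosome;
    synteny-block anchors appear in the same relative rank order on both
    chromosomes with rank gaps of at most 2; dispersed pairs are placed
    on chromosome pairs no block uses. Returns the annotation, the full
    homolog-pair list, and a truth table with each pair's planted class.
    """
    if not cfg.chromosomes:
        raise ValueError("no chromosomes configured")
    rng = _rng(cfg.seed, "layout")
    gene_counts = {name: count for name, _, count in cfg.chromosomes}
    for chrom, size in cfg.tandem_arrays:
        if size > gene_counts.get(chrom, 0):
            raise ValueError(
                f"tandem array of {size} exceeds gene count on {chrom}")

    genes: list[GeneModel] = []
    ids_by_chrom: dict[str, list[str]] = {}
    for name, length, count in cfg.chromosomes:
        gene_len = 3000
        gap = (length - 2 * gene_len) // max(count, 1)
        starts = sorted(rng.choice(
            np.arange(gene_len, length - gene_len, gap // 2 or 1),
            size=count, replace=False))
        ids = []
        for i, start in enumerate(starts):
            gid = f"G{name}_{i + 1:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(
                gid, name, strand, int(start), int(start) + gene_len - 1,
                transcripts=[(f"{gid}.1", 400)]))
            ids.append(gid)
        ids_by_chrom[name] = ids

    annotation = GenomeAnnotation(
        genes, {name: length for name, length, _ in cfg.chromosomes})

    # ranks are 1..n in id order by construction (starts sorted)
    pairs: list[HomologPair] = []
    truth_rows = []
    used_ranks: dict[str, set[int]] = {c: set() for c in ids_by_chrom}

    def reserve(chrom: str, count: int, consecutive: bool) -> list[int]:
        n = len(ids_by_chrom[chrom])
        free = [r for r in range(1, n + 1) if r not in used_ranks[chrom]]
        if consecutive:
            runs = [free[i:i + count] for i in range(len(free) - count + 1)
                    if free[i + count - 1] - free[i] == count - 1]
            if not runs:
                raise ValueError(f"no room for a run of {count} on {chrom}")
            chosen = runs[int(rng.integers(len(runs)))]
        else:
            # spaced ranks with gaps <= 2 so chains stay within max_gap
            start = int(rng.integers(1, max(2, n - 3 * count)))
            chosen, r = [], start
            while len(chosen) < count and r <= n:
                if r not in used_ranks[chrom]:
                    chosen.append(r)
                    r += int(rng.integers(1, 3))
                else:
                    r += 1
            if len(chosen) < count:
                raise ValueError(f"no room for {count} anchors on {chrom}")
        used_ranks[chrom].update(chosen)
        return chosen

    for chrom, size in cfg.tandem_arrays:
        ranks = reserve(chrom, size, consecutive=True)
        members = [ids_by_chrom[chrom][r - 1] for r in ranks]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pair = HomologPair(members[i], members[j])
                pairs.append(pair)
                truth_rows.append({"a": pair.a, "b": pair.b,
                                   "class": "tandem"})

    block_chrom_pairs = set()
    for ca, cb, count in cfg.synteny_blocks:
        block_chrom_pairs.add(tuple(sorted((ca, cb))))
        ranks_a = reserve(ca, count, consecutive=False)
        ranks_b = reserve(cb, count, consecutive=False)
        for ra, rb in zip(ranks_a, ranks_b):
            pair = HomologPair(ids_by_chrom[ca][ra - 1],
                               ids_by_chrom[cb][rb - 1])
            pairs.append(pair)
            truth_rows.append({"a": pair.a, "b": pair.b,
                               "class": "segmental"})

    chroms = list(ids_by_chrom)
    free_chrom_pairs = [
        (a, b) for i, a in enumerate(chroms) for b in chroms[i + 1:]
        if (a, b) not in block_chrom_pairs
    ]
    for i in range(cfg.dispersed_pairs):
        ca, cb = free_chrom_pairs[i % len(free_chrom_pairs)]
        ra = reserve(ca, 1, consecutive=True)[0]
        rb = reserve(cb, 1, consecutive=True)[0]
        pair = HomologPair(ids_by_chrom[ca][ra - 1], ids_by_chrom[cb][rb - 1])
        pairs.append(pair)
        truth_rows.append({"a": pair.a, "b": pair.b, "class": "dispersed"})

    truth = pd.DataFrame(truth_rows)
    return annotation, pairs, truth


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Serialize an annotation to GFF3 (genes + mRNA children)."""
    lines = ["##gff-version 3"]
    for chrom, length in sorted(annotation.chromosome_lengths.items()):
        lines.append(f"##sequence-region {chrom} 1 {length}")
    for g in sorted(annotation.genes, key=lambda g: (g.chromosome, g.start)):
        lines.append("\t".join([
            g.chromosome, "kincascade", "gene", str(g.start), str(g.end),
            ".", g.strand, ".", f"ID={g.gene_id}"]))
        for tid, plen in g.transcripts:
            lines.append("\t".join([
                g.chromosome, "kincascade", "mRNA", str(g.start), str(g.end),
                ".", g.strand, ".",
                f"ID={tid};Parent={g.gene_id};protein_length={plen}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# codon pairs


_NONSTOP = [c for c in (a + b + c for a in NUCS for b in NUCS for c in NUCS)
            if c not in STOP_CODONS]


def _evolve(cds: str, m: int, omega: float,
            rng: np.random.Generator) -> tuple[str, int, int]:
    """Apply m accepted/rejected point-mutation proposals to one lineage."""
    seq = list(cds)
    syn_acc = nonsyn_acc = 0
    p_nonsyn = min(1.0, omega)
    p_syn = min(1.0, 1.0 / omega)
    for _ in range(m):
        while True:  # redraw proposals that create stop codons
            pos = int(rng.integers(len(seq)))
            old = seq[pos]
            new = NUCS[int(rng.integers(4))]
            if new == old:
                continue
            cstart = 3 * (pos // 3)
            codon = seq[cstart:cstart + 3]
            new_codon = codon.copy()
            new_codon[pos - cstart] = new
            if "".join(new_codon) in STOP_CODONS:
                continue
            break
        synonymous = (CODON_TO_AA["".join(codon)]
                      == CODON_TO_AA["".join(new_codon)])
        accept_p = p_syn if synonymous else p_nonsyn
        if rng.random() < accept_p:
            seq[pos] = new
            if synonymous:
                syn_acc += 1
            else:
                nonsyn_acc += 1
    return "".join(seq), syn_acc, nonsyn_acc


def gen_codon_pairs(cfg: SynthesisConfig) -> tuple[
        list[SequenceRecord], pd.DataFrame]:
    """Codon-aligned CDS pairs evolved from one ancestor at known omega.

    Each pair descends from a random stop-free ancestor by ``m`` point
    mutation proposals per lineage; synonymous proposals are accepted
    with probability min(1, 1/omega), nonsynonymous with min(1, omega),
    so the realized Ka/Ks expectation tracks the target. The truth table
    stores the accepted synonymous/nonsynonymous counts per pair.
    """
    rng = _rng(cfg.seed, "codon")
    records: list[SequenceRecord] = []
    truth_rows = []
    for s_idx, (omega, codons, m) in enumerate(cfg.omega_settings):
        if codons <= 0:
            raise ValueError("codon count must be positive")
        for p_idx in range(cfg.pairs_per_setting):
            ancestor = "".join(
                _NONSTOP[i] for i in rng.integers(0, len(_NONSTOP),
                                                  size=codons))
            a, sa, na = _evolve(ancestor, m, omega, rng)
            b, sb, nb = _evolve(ancestor, m, omega, rng)
            base = f"pair_s{s_idx}_{p_idx + 1:04d}"
            records.append(SequenceRecord(f"{base}_a", a, alphabet="dna"))
            records.append(SequenceRecord(f"{base}_b", b, alphabet="dna"))
            truth_rows.append({
                "pair": base, "omega_target": omega, "codons": codons,
                "syn_accepted": sa + sb, "nonsyn_accepted": na + nb,
            })
    return records, pd.DataFrame(truth_rows).set_index("pair")


# ---------------------------------------------------------------------------
# promoters


def _repair_background(seq: list[str], catalog: CisCatalog,
                       rng: np.random.Generator,
                       protected: list[tuple[int, int]] = (),
                       max_rounds: int = 200) -> bool:
    """Randomize bases inside residual catalog matches until none remain.

    Positions inside ``protected`` intervals are never touched; returns
    False if a match overlapping a protected region cannot be cleared.
    """
    from .promoters import _match_intervals

    prot = set()
    for lo, hi in protected:
        prot.update(range(lo, hi))
    for _ in range(max_rounds):
        s = "".join(seq)
        dirty = []
        for entry in catalog.elements:
            for pat in {entry.consensus, reverse_complement(entry.consensus)}:
                dirty.extend(_match_intervals(s, pat))
        dirty = [iv for iv in dirty
                 if not all(p in prot for p in range(iv[0], iv[1]))]
        if not dirty:
            return True
        for lo, hi in dirty:
            candidates = [p for p in range(lo, hi) if p not in prot]
            if not candidates:
                return False
            p = candidates[int(rng.integers(len(candidates)))]
            seq[p] = NUCS[int(rng.integers(4))]
    return False


def gen_promoters(
    cfg: SynthesisConfig,
    catalog: CisCatalog | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Promoters with exact planted cis-element counts on clean background.

    Each promoter is uniform-random DNA repaired to contain no catalog
    match, into which the configured number of non-overlapping element
    instances is planted (forward or reverse strand, recorded in the
    truth table). After planting, the sequence is re-scanned and layouts
    whose plants collide or cross-match another element are redrawn, so
    per-element scan counts equal the planted truth exactly.
    """
    from .promoters import scan_elements

    catalog = catalog or default_catalog()
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    plants = {k: v for k, v in cfg.promoter_plants.items() if v > 0}
    for name in plants:
        if name not in catalog:
            raise KeyError(f"planted element {name!r} not in catalog")
    total_bp = sum(len(catalog[n].consensus) * c for n, c in plants.items())
    if total_bp > cfg.promoter_length // 2:
        raise ValueError("requested plants exceed promoter capacity")

    rng = _rng(cfg.seed, "promoter")
    records: list[SequenceRecord] = []
    truth_rows = []
    expected = {name: plants.get(name, 0) for name in catalog.names()}

    for i in range(cfg.n_promoters):
        rec_id = f"PROM_{i + 1:03d}"
        for _attempt in range(100):
            seq = [NUCS[j] for j in rng.integers(0, 4, size=cfg.promoter_length)]
            if not _repair_background(seq, catalog, rng):
                continue
            placements = []
            slots: list[tuple[int, int]] = []
            ok = True
            for name, count in sorted(plants.items()):
                width = len(catalog[name].consensus)
                for _ in range(count):
                    for _try in range(200):
                        start = int(rng.integers(0, cfg.promoter_length - width))
                        iv = (start, start + width)
                        if all(iv[1] + 1 <= lo or iv[0] >= hi + 1
                               for lo, hi in slots):
                            break
                    else:
                        ok = False
                        break
                    strand = "+" if rng.random() < 0.5 else "-"
                    inst = _instantiate_dna(catalog[name].consensus, rng)
                    if strand == "-":
                        inst = reverse_complement(inst)
                    seq[iv[0]:iv[1]] = list(inst)
                    slots.append(iv)
                    placements.append((name, iv[0], strand))
                if not ok:
                    break
            if not ok:
                continue
            result = scan_elements(SequenceRecord(rec_id, "".join(seq),
                                                  alphabet="dna"), catalog)
            if result.counts == expected:
                break
        else:
            raise RuntimeError(
                "could not realize the planted design; the planted elements "
                "likely cross-match other catalog entries")
        records.append(SequenceRecord(rec_id, "".join(seq), alphabet="dna"))
        for name, off, strand in placements:
            truth_rows.append({"id": rec_id, "element": name,
                               "offset": off, "strand": strand})
    truth = pd.DataFrame(
        truth_rows, columns=["id", "element", "offset", "strand"])
    return records, truth


_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
    "S": "GC", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _instantiate_dna(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        _IUPAC_CHOICES[c][int(rng.integers(len(_IUPAC_CHOICES[c])))]
        for c in consensus)


# ---------------------------------------------------------------------------
# expression and qPCR


def gen_expression(cfg: SynthesisConfig) -> tuple["ExpressionMatrix", pd.DataFrame]:
    """Log-normal expression matrix with planted log2 condition effects.

    Per gene, a log2 baseline is drawn N(base_mean, base_sd); each
    replicate value is 2**(baseline + effect + N(0, noise_sd)). The truth
    table records the planted log2 fold change per gene and condition.
    """
    from .expression import ExpressionMatrix

    d = cfg.expr_design
    if d.replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = _rng(cfg.seed, "expression")
    genes = [f"gene_{i + 1:03d}" for i in range(d.n_genes)]
    base = rng.normal(d.base_mean, d.base_sd, size=d.n_genes)
    cols, col_meta = [], []
    data = np.zeros((d.n_genes, len(d.conditions) * d.replicates))
    truth_rows = []
    j = 0
    for cond in d.conditions:
        effects = np.array([d.effects.get((g, cond), 0.0)
                            for g in range(d.n_genes)])
        for rep in range(1, d.replicates + 1):
            noise = rng.normal(0.0, d.noise_sd, size=d.n_genes)
            data[:, j] = 2.0 ** (base + effects + noise)
            cols.append(f"{cond}_r{rep}")
            col_meta.append({"sample": f"{cond}_r{rep}", "condition": cond,
                             "replicate": rep,
                             "is_control": cond == d.control})
            j += 1
        if cond != d.control:
            for g in range(d.n_genes):
                truth_rows.append({"gene": genes[g], "condition": cond,
                                   "true_log2fc": d.effects.get((g, cond), 0.0)})
    values = pd.DataFrame(data, index=genes, columns=cols)
    samples = pd.DataFrame(col_meta).set_index("sample")
    truth = pd.DataFrame(truth_rows,
                         columns=["gene", "condition", "true_log2fc"])
    return ExpressionMatrix(values, samples), truth


def gen_ct(cfg: SynthesisConfig) -> tuple["CtTable", pd.DataFrame]:
    """Replicate Ct tables with known fold changes.

    E[ddCt] = -log2(true fold change); the reference-gene Ct is constant
    in expectation across conditions. With zero noise the Livak analysis
    recovers every fold change exactly.
    """
    from .expression import CtTable

    d = cfg.ct_design
    if d.replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = _rng(cfg.seed, "ct")
    rows = []
    truth_rows = []
    for gene in d.genes:
        for cond in d.conditions:
            fold = d.fold_changes.get((gene, cond), 1.0)
            if cond == d.control:
                fold = 1.0
            dct = d.base_dct - math.log2(fold)
            for rep in range(1, d.replicates + 1):
                ref = d.reference_ct + rng.normal(0.0, d.noise_sd)
                tgt = ref + dct + rng.normal(0.0, d.noise_sd)
                rows.append({"gene": gene, "condition": cond,
                             "replicate": rep, "ct_target": tgt,
                             "ct_reference": ref})
            if cond != d.control:
                truth_rows.append({"gene": gene, "condition": cond,
                                   "true_fold": fold})
    truth = pd.DataFrame(truth_rows, columns=["gene", "condition", "true_fold"])
    return CtTable(pd.DataFrame(rows)), truth
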