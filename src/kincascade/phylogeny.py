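"""Distance-based phylogeny: p/Poisson distances, neighbor joining, bootstrap.

Trees are unrooted and represented with a trifurcating root node, the
standard convention for NJ output. Negative branch-length estimates are
clamped to zero (the logged deficit is the standard NJ practice). Bootstrap
support of an internal edge is the percentage of column-resampled replicate
trees containing the same leaf bipartition.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Node:
    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Unrooted tree (trifurcating root) with named leaves."""

    def __init__(self, root: Node):
        self.root = root
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("leaf labels must be unique")

    def leaves(self) -> list[Node]:
        out = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def to_newick(self) -> str:
        def fmt(node: Node, top: bool = False) -> str:
            if node.is_leaf:
                if not node.name:
                    raise ValueError("unnamed leaf cannot be serialized")
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = (f"{int(node.support)}"
                         if float(node.support).is_integer()
                         else f"{node.support:g}")
            if top:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.6f}"

        return fmt(self.root, top=True) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        from Bio import Phylo

        clade_tree = Phylo.read(io.StringIO(text), "newick")

        def convert(clade) -> Node:
            node = Node(
                name=clade.name or "",
                length=clade.branch_length or 0.0,
                support=(float(clade.confidence)
                         if clade.confidence is not None else None),
            )
            node.children = [convert(c) for c in clade.clades]
            return node

        return cls(convert(clade_tree.root))

    def splits(self) -> set[frozenset[str]]:
        """Canonical nontrivial leaf bipartitions (internal edges)."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if ref not in below else all_leaves - below
                out.add(side)
            return below

        walk(self.root)
        return out

    def internal_nodes(self) -> list[Node]:
        out = []

        def walk(node: Node) -> None:
            if not node.is_leaf:
                if node is not self.root:
                    out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def leaf_distances(self) -> "DistanceMatrix":
        """Path-length metric between all leaf pairs."""
        labels = sorted(self.leaf_names())
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: dict[str, float] = {}
            child_maps = []
            for c in node.children:
                cm = {k: v + c.length for k, v in walk(c).items()}
                child_maps.append(cm)
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for la, da in child_maps[a].items():
                        for lb, db in child_maps[b].items():
                            d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
            for cm in child_maps:
                below.update(cm)
            return below

        walk(self.root)
        return DistanceMatrix(labels, d)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")


def _seq_str(seq) -> str:
    return seq.seq if hasattr(seq, "seq") else str(seq)


def pairwise_distance(alignment: list, model: str = "poisson") -> DistanceMatrix:
    """Distances from an equal-length alignment.

    ``p`` is the mismatch fraction over columns where neither member of
    the pair is gapped; ``poisson`` applies -ln(1 - p). Columns gapped in
    either member are excluded pairwise.
    """
    seqs = [_seq_str(s) for s in alignment]
    labels = [getattr(s, "id", f"seq{i}") for i, s in enumerate(alignment)]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("alignment rows must have equal length")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatches = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a == "-" or b == "-":
                    continue
                comparable += 1
                if a != b:
                    mismatches += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}")
            p = mismatches / comparable
            if model == "p":
                dist = p
            elif model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair {labels[i]}/{labels[j]} (p = 1)")
                dist = -math.log(1.0 - p)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the smallest (i, j) index pair
    in the input label order. On additive matrices the returned tree's
    path-length metric reproduces the input exactly.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    size = 2 * n
    d = np.zeros((size, size))
    d[:n, :n] = dm.d
    nodes: dict[int, Node] = {i: Node(name=dm.labels[i]) for i in range(n)}
    active = list(range(n))
    nxt = n

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamping negative branch length %.6g to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        limb_i = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        limb_j = d[i, j] - limb_i
        u = Node()
        ci, cj = nodes.pop(i), nodes.pop(j)
        ci.length, cj.length = clamp(limb_i), clamp(limb_j)
        u.children = [ci, cj]
        for k in active:
            if k in (i, j):
                continue
            d[nxt, k] = d[k, nxt] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[nxt] = u
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    i, j, k = active
    root = Node()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, limb in ((i, li), (j, lj), (k, lk)):
        child = nodes.pop(idx)
        child.length = clamp(limb)
        root.children.append(child)
    return PhyloTree(root)


def bootstrap(
    alignment: list,
    B: int = 1000,
    model: str = "poisson",
    seed: int = 0,
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap support labels.

    Columns are resampled with replacement per replicate; the support of
    each internal edge of the full-data tree is the percentage of
    replicate trees containing the same bipartition.
    """
    if B < 1:
        raise ValueError("need at least one replicate")
    seqs = [_seq_str(s) for s in alignment]
    labels = [getattr(s, "id", f"seq{i}") for i, s in enumerate(alignment)]
    width = len(seqs[0])
    if width < 2:
        raise ValueError("insufficient columns for bootstrap")
    tree = neighbor_joining(pairwise_distance(alignment, model))
    counts: dict[frozenset[str], int] = {s: 0 for s in tree.splits()}
    rng = np.random.default_rng(seed)

    @dataclass
    class _Row:
        id: str
        seq: str

    for _ in range(B):
        cols = rng.integers(0, width, size=width)
        rep = [_Row(lab, "".join(s[c] for c in cols))
               for lab, s in zip(labels, seqs)]
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep, model))
        except ValueError:
            continue  # saturated or degenerate resample
        rep_splits = rep_tree.splits()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    all_leaves = frozenset(labels)
    ref = min(all_leaves)

    def assign(node: Node, below: frozenset[str]) -> None:
        side = below if ref not in below else all_leaves - below
        if side in counts:
            node.support = 100.0 * counts[side] / B

    def walk(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root:
            assign(node, below)
        return below

    walk(tree.root)
    return tree


def align_family(records: list, matrix=None, gap_open: float = 10.0,
                 gap_extend: float = 1.0) -> list:
    """Simple center-star multiple alignment (convenience, not ClustalW).

    The center is the member with the greatest total pairwise alignment
    score; all others are aligned to it and merged under the
    once-a-gap-always-a-gap rule. Adequate for closely related family
    members; use a dedicated aligner for distant sequences.
    """
    from .core_io import SequenceRecord
    from .homology import _make_aligner

    if len(records) == 1:
        return list(records)
    seqs = [_seq_str(r) for r in records]
    ids = [getattr(r, "id", f"seq{i}") for i, r in enumerate(records)]
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    n = len(records)
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            sc = aligner.score(seqs[i], seqs[j])
            totals[i] += sc
            totals[j] += sc
    center = int(np.lexsort((ids, -totals))[0])

    master = list(seqs[center])
    rows: list[list[str]] = []
    row_ids: list[str] = []

    for j in range(n):
        if j == center:
            continue
        aln = aligner.align(seqs[center], seqs[j])[0]
        c_aln = list(str(aln[0]))
        s_aln = list(str(aln[1]))
        # merge gap pattern of c_aln with accumulated master
        mi = ai = 0
        new_master: list[str] = []
        new_rows: list[list[str]] = [[] for _ in rows]
        new_s: list[str] = []
        while mi < len(master) or ai < len(c_aln):
            m_gap = mi < len(master) and master[mi] == "-"
            a_gap = ai < len(c_aln) and c_aln[ai] == "-"
            m_res = mi < len(master) and not m_gap
            a_res = ai < len(c_aln) and not a_gap
            if m_res and a_res:
                new_master.append(master[mi])
                for r, nr in zip(rows, new_rows):
                    nr.append(r[mi])
                new_s.append(s_aln[ai])
                mi += 1
                ai += 1
            elif m_gap:
                new_master.append("-")
                for r, nr in zip(rows, new_rows):
                    nr.append(r[mi])
                new_s.append("-")
                mi += 1
            else:  # gap in this pairwise center row only
                new_master.append("-")
                for nr in new_rows:
                    nr.append("-")
                new_s.append(s_aln[ai])
                ai += 1
        master = new_master
        rows = new_rows
        rows.append(new_s)
        row_ids.append(ids[j])

    out = {ids[center]: "".join(master)}
    for rid, row in zip(row_ids, rows):
        out[rid] = "".join(row)
    width = len(out[ids[center]])
    result = []
    for rid in ids:
        aligned = out[rid]
        if len(aligned) != width:
            raise AssertionError("center-star merge produced ragged rows")
        result.append(SequenceRecord(rid, aligned, alphabet="protein"))
    return result
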