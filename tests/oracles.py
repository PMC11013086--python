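"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by exhaustive enumeration or direct
definition, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def motif_matches_window(tokens, window: str) -> bool:
    """Token-by-token check of one window against a degenerate pattern."""
    pos = 0
    for tok in tokens:
        if tok[0] == "gap":
            for _ in range(tok[1]):
                if window[pos] == "X":
                    return False
                pos += 1
            continue
        res = window[pos]
        if res == "X":
            return False
        if tok[0] == "lit" and res != tok[1]:
            return False
        if tok[0] == "alt" and res not in tok[1]:
            return False
        if tok[0] == "any" and res == "X":
            return False
        pos += 1
    return True


def brute_force_scan(pattern, seq: str) -> list[int]:
    """All match offsets of a pattern by checking every window."""
    width = pattern.length
    return [
        off for off in range(len(seq) - width + 1)
        if motif_matches_window(pattern.tokens, seq[off:off + width])
    ]


def brute_force_global_score(
    a: str, b: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Optimal global affine-gap score by enumerating every alignment.

    A gap of length L costs gap_open + L * gap_extend; feasible only for
    short sequences.
    """
    best = -math.inf

    def rec(i: int, j: int, prev: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "D", score + matrix[a[i], b[j]])
        if i < len(a):
            cost = gap_extend if prev == "U" else gap_open + gap_extend
            rec(i + 1, j, "U", score - cost)
        if j < len(b):
            cost = gap_extend if prev == "L" else gap_open + gap_extend
            rec(i, j + 1, "L", score - cost)

    rec(0, 0, "", 0.0)
    return best


def _chain_valid(coords, idxs, sign: int, max_gap: int) -> bool:
    for u, v in zip(idxs, idxs[1:]):
        da = coords[v][0] - coords[u][0]
        db = sign * (coords[v][1] - coords[u][1])
        if not (0 < da <= max_gap and 0 < db <= max_gap):
            return False
    return True


def exhaustive_best_chain(coords, max_gap: int):
    """Longest valid monotone chain by enumerating every subsequence.

    Returns (index tuple, orientation), preferring increasing runs and
    the lexicographically smallest index sequence — the same tie rules
    the chain detector documents.
    """
    n = len(coords)
    for r in range(n, 0, -1):
        found = []
        for comb in itertools.combinations(range(n), r):
            for sign, name in ((1, "+"), (-1, "-")):
                if _chain_valid(coords, comb, sign, max_gap):
                    found.append((name != "+", comb))
        if found:
            found.sort()
            is_dec, comb = found[0]
            return comb, ("-" if is_dec else "+")
    return (), "+"


def exhaustive_blocks(coords, min_block: int, max_gap: int):
    """Greedy longest-first block extraction with an exhaustive chain finder."""
    pool = sorted(range(len(coords)), key=lambda i: coords[i])
    blocks = []
    while len(pool) >= min_block:
        sub = [coords[i] for i in pool]
        path, orient = exhaustive_best_chain(sub, max_gap)
        if len(path) < min_block:
            break
        blocks.append(([pool[i] for i in path], orient))
        pool = [p for i, p in enumerate(pool) if i not in set(path)]
    return blocks


def all_five_leaf_topologies(labels):
    """The 15 unrooted binary topologies on 5 leaves, as split-set pairs.

    Each topology is determined by its two disjoint cherries; returned
    as (cherry_a, cherry_b, outlier) label tuples.
    """
    out = []
    labels = list(labels)
    for pair_a in itertools.combinations(labels, 2):
        rest = [x for x in labels if x not in pair_a]
        for pair_b in itertools.combinations(rest, 2):
            if pair_a < pair_b:
                outlier = next(x for x in rest if x not in pair_b)
                out.append((pair_a, pair_b, outlier))
    assert len(out) == 15
    return out


def least_squares_topology(labels, d: np.ndarray):
    """Best 5-leaf topology by OLS branch fitting over all 15 candidates.

    Edge set: five pendant edges plus two internal edges; the design
    matrix maps leaf pairs to the edges on their path.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    pairs = list(itertools.combinations(labels, 2))
    y = np.array([d[idx[a], idx[b]] for a, b in pairs])
    best = None
    for cherry_a, cherry_b, outlier in all_five_leaf_topologies(labels):
        # edges: pendant per leaf (0..4), internal to cherry_a (5), cherry_b (6)
        rows = []
        for a, b in pairs:
            row = np.zeros(7)
            row[idx[a]] = row[idx[b]] = 1
            # an internal edge lies on the path iff exactly one endpoint
            # sits inside its cherry
            if sum(x in cherry_a for x in (a, b)) == 1:
                row[5] = 1
            if sum(x in cherry_b for x in (a, b)) == 1:
                row[6] = 1
            rows.append(row)
        A = np.array(rows)
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        ssq = float(((A @ x - y) ** 2).sum())
        splits = {frozenset(cherry_a), frozenset(cherry_b)}
        if best is None or ssq < best[0] - 1e-12:
            best = (ssq, splits)
    return best[1]
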