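"""Degenerate signature-motif engine for MAPK-cascade tier classification.

The kinase tiers of the MAPK cascade (MAPK, MAP2K, and the three MAP3K
subtypes MEKK/RAF/ZIK, plus MAP4K) each carry a short degenerate consensus
in the kinase domain:

    MAPK    T(E/D)YVxTRWYRAPE(L/V)    (activation loop TEY/TDY)
    MAP2K   VGTxxYMSPER               (plus a supporting S/T-x5-S/T site)
    MEKK    G(T/S)Px(W/Y/F)MAPEV
    RAF     GTxx(W/Y)MAPE
    ZIK     GTPEFMAPE(L/V)Y
    MAP4K   VGTPxWMAPEV

Because the consensi nest (the MAP4K signature contains a MEKK and a RAF
match), classification is by *specificity*: the matched pattern with the
most non-wildcard positions wins, with a fixed tie order. MAP4K proteins
are additionally audited for the catalytic hallmarks of an active kinase
domain: the glycine-rich loop GxGxxG (third G substituted by A or S in
inactive members), the invariant lysine, and the HRD and DFG triplets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_CLASS = f"[{AA20}]"  # 'X' in a sequence matches nothing

TIERS = ("MAPK", "MAP2K", "MEKK", "RAF", "ZIK", "MAP4K")

#: fixed precedence used to break specificity ties (most specific first)
TIE_ORDER = ("MAP4K", "ZIK", "MEKK", "MAP2K", "MAPK", "RAF")

#: shipped tier signatures, in the field's consensus notation
SIGNATURES: dict[str, str] = {
    "MAPK": "T(E/D)YVxTRWYRAPE(L/V)",
    "MAP2K": "VGTxxYMSPER",
    "MEKK": "G(T/S)Px(W/Y/F)MAPEV",
    "RAF": "GTxx(W/Y)MAPE",
    "ZIK": "GTPEFMAPE(L/V)Y",
    "MAP4K": "VGTPxWMAPEV",
}

#: auxiliary feature patterns (not tier signatures)
FEATURES: dict[str, str] = {
    "glycine_rich": "GxGxx(G/A/S)",
    "activation_loop": "T(E/D)Y",
    "activation_loop_TEH": "TEH",
    "map2k_st_site": "S/T-x5-S/T",
}


class PatternParseError(ValueError):
    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


# Tokens: ("lit", residue) | ("any",) | ("alt", frozenset) | ("gap", n)
Token = tuple


@dataclass
class MotifPattern:
    """A compiled degenerate consensus motif."""

    name: str
    tokens: list[Token]
    tier: str = "feature"

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("pattern has no tokens")
        for tok in self.tokens:
            if tok[0] == "alt" and len(tok[1]) < 2:
                raise ValueError("alternation set needs >= 2 residues")

    @property
    def length(self) -> int:
        """Number of residue positions the pattern spans."""
        return sum(t[1] if t[0] == "gap" else 1 for t in self.tokens)

    @property
    def specificity(self) -> int:
        """Count of non-wildcard positions (literals + alternations)."""
        return sum(1 for t in self.tokens if t[0] in ("lit", "alt"))

    def to_regex(self) -> str:
        parts = []
        for tok in self.tokens:
            if tok[0] == "lit":
                parts.append(tok[1])
            elif tok[0] == "any":
                parts.append(_AA_CLASS)
            elif tok[0] == "alt":
                parts.append("[" + "".join(sorted(tok[1])) + "]")
            else:  # gap
                parts.append(_AA_CLASS + "{%d}" % tok[1])
        return "".join(parts)


def compile_pattern(spec: str, name: str = "", tier: str = "feature") -> MotifPattern:
    """Compile a consensus string in the field's notation into a pattern.

    Supported notation: literal residues, ``x`` wildcards, ``xN`` fixed
    gaps, parenthesized alternations ``(E/D)``, bare-slash shorthand on
    the preceding literal (``G/A`` -> alternation (G/A)), and ``-``
    separators (ignored).
    """
    tokens: list[Token] = []
    i, n = 0, len(spec)
    while i < n:
        c = spec[i]
        if c == "-":
            i += 1
        elif c == "(":
            close = spec.find(")", i)
            if close < 0:
                raise PatternParseError("unbalanced parenthesis", i + 1)
            body = spec[i + 1:close]
            residues = [r for r in body.split("/") if r]
            if len(residues) < 2 or any(
                len(r) != 1 or r not in AA20 for r in residues
            ):
                raise PatternParseError(f"bad alternation {body!r}", i + 1)
            tokens.append(("alt", frozenset(residues)))
            i = close + 1
        elif c == ")":
            raise PatternParseError("unbalanced parenthesis", i + 1)
        elif c == "x":
            j = i + 1
            while j < n and spec[j].isdigit():
                j += 1
            if j > i + 1:
                tokens.append(("gap", int(spec[i + 1:j])))
            else:
                tokens.append(("any",))
            i = j
        elif c in AA20:
            # collect slash-chained alternation: S/T, G/A, W/Y/F ...
            residues = [c]
            j = i + 1
            while j + 1 < n and spec[j] == "/" and spec[j + 1] in AA20:
                residues.append(spec[j + 1])
                j += 2
            if len(residues) > 1:
                tokens.append(("alt", frozenset(residues)))
            else:
                tokens.append(("lit", c))
            i = j
        else:
            raise PatternParseError(f"unexpected character {c!r}", i + 1)
    if not tokens:
        raise PatternParseError("empty pattern", 1)
    return MotifPattern(name=name or spec, tokens=tokens, tier=tier)


@dataclass
class MotifHit:
    pattern: str
    seq_id: str
    offset: int  # 0-based
    matched: str


def scan(seq, patterns: list[MotifPattern]) -> list[MotifHit]:
    """Report every window of ``seq`` matching each pattern.

    Overlapping occurrences are all reported; ``X`` residues match no
    token. Results are ordered by offset, then pattern name.
    """
    seq_id = getattr(seq, "id", "")
    s = seq.seq if hasattr(seq, "seq") else str(seq)
    hits: list[MotifHit] = []
    for pat in patterns:
        rx = re.compile("(?=(" + pat.to_regex() + "))")
        for m in rx.finditer(s):
            hits.append(MotifHit(pat.name, seq_id, m.start(), m.group(1)))
    hits.sort(key=lambda h: (h.offset, h.pattern))
    return hits


def _compiled_signatures() -> dict[str, MotifPattern]:
    return {
        tier: compile_pattern(spec, name=tier, tier=tier)
        for tier, spec in SIGNATURES.items()
    }


_SIG_CACHE = _compiled_signatures()


@dataclass
class Map4kAudit:
    """Kinase-activity audit of the four MAP4K catalytic hallmarks."""

    seq_id: str
    glycine_rich: str = "absent"  # canonical G | substituted A | substituted S
    glycine_rich_offset: int | None = None
    invariant_k: bool = False
    invariant_k_offset: int | None = None
    hrd: bool = False
    hrd_offset: int | None = None
    dfg: bool = False
    dfg_offset: int | None = None

    @property
    def n_features(self) -> int:
        return sum([
            self.glycine_rich != "absent",
            self.invariant_k,
            self.hrd,
            self.dfg,
        ])

    @property
    def predicted_active(self) -> bool:
        return (
            self.glycine_rich == "canonical G"
            and self.invariant_k and self.hrd and self.dfg
        )


def audit_map4k(seq, k_window: tuple[int, int] = (10, 35)) -> Map4kAudit:
    """Audit a protein for the four MAP4K kinase-activity hallmarks.

    The glycine-rich loop is located by GxGxx(G/A/S) and its status read
    from the sixth position; the invariant lysine is the first K found
    ``k_window`` residues C-terminal of the loop end (absent without a
    loop anchor); HRD and DFG are literal triplets with DFG required
    C-terminal of HRD. ``predicted_active`` demands the canonical loop
    plus all three catalytic features.
    """
    seq_id = getattr(seq, "id", "")
    s = seq.seq if hasattr(seq, "seq") else str(seq)
    audit = Map4kAudit(seq_id)

    gpat = compile_pattern(FEATURES["glycine_rich"])
    gm = re.search(gpat.to_regex(), s)
    if gm:
        audit.glycine_rich_offset = gm.start()
        third_g = s[gm.start() + 5]
        audit.glycine_rich = {
            "G": "canonical G", "A": "substituted A", "S": "substituted S",
        }[third_g]
        gend = gm.start() + 6  # index just past the loop
        lo, hi = k_window
        window = s[gend + lo - 1: gend + hi]
        k_rel = window.find("K")
        if k_rel >= 0:
            audit.invariant_k = True
            audit.invariant_k_offset = gend + lo - 1 + k_rel

    hrd = s.find("HRD")
    if hrd >= 0:
        audit.hrd = True
        audit.hrd_offset = hrd
        dfg = s.find("DFG", hrd + 3)
    else:
        dfg = s.find("DFG")
    if dfg >= 0:
        audit.dfg = True
        audit.dfg_offset = dfg
    return audit


@dataclass
class TierCall:
    """Tier/subfamily assignment of one protein with supporting hits."""

    seq_id: str
    tier: str = "unclassified"
    supporting: list[MotifHit] = field(default_factory=list)
    ambiguous_with: list[str] = field(default_factory=list)
    activation_loop: str | None = None  # TEY | TDY | TEH | absent (MAPK only)
    map4k_audit: Map4kAudit | None = None


def classify_tier(
    seq,
    signatures: dict[str, MotifPattern] | None = None,
    min_map4k_features: int = 2,
) -> TierCall:
    """Assign a protein to a cascade tier by its signature motifs.

    All six tier signatures are scanned; the winner is the matched
    pattern of greatest specificity, ties broken by the fixed order
    MAP4K > ZIK > MEKK > MAP2K > MAPK > RAF. A MAP4K call additionally
    requires at least ``min_map4k_features`` of the four catalytic
    hallmarks. Losing tiers are recorded in ``ambiguous_with``.
    """
    sigs = signatures or _SIG_CACHE
    seq_id = getattr(seq, "id", "")
    s = seq.seq if hasattr(seq, "seq") else str(seq)

    hits_by_tier: dict[str, list[MotifHit]] = {}
    for tier, pat in sigs.items():
        tier_hits = scan(s, [pat])
        if tier_hits:
            for h in tier_hits:
                h.seq_id = seq_id
            hits_by_tier[tier] = tier_hits

    call = TierCall(seq_id)
    matched = list(hits_by_tier)
    eligible = list(matched)
    audit = None
    if "MAP4K" in eligible:
        audit = audit_map4k(s)
        audit.seq_id = seq_id
        if audit.n_features < min_map4k_features:
            eligible.remove("MAP4K")
    if not eligible:
        call.ambiguous_with = sorted(matched)
        return call

    def rank(tier: str) -> tuple[int, int]:
        return (-sigs[tier].specificity, TIE_ORDER.index(tier))

    winner = min(eligible, key=rank)
    call.tier = winner
    call.supporting = hits_by_tier[winner]
    call.ambiguous_with = sorted(t for t in matched if t != winner)

    if winner == "MAPK":
        tdy = scan(s, [compile_pattern(FEATURES["activation_loop"], "act")])
        if tdy:
            call.activation_loop = tdy[0].matched[:3]
        elif "TEH" in s:
            call.activation_loop = "TEH"
        else:
            call.activation_loop = "absent"
    elif winner == "MAP2K":
        st = scan(s, [compile_pattern(FEATURES["map2k_st_site"], "S/T-x5-S/T")])
        for h in st:
            h.seq_id = seq_id
        call.supporting.extend(st)
    elif winner == "MAP4K":
        call.map4k_audit = audit
    return call


def classify_proteome(records, **kwargs) -> list[TierCall]:
    """Classify every record; convenience wrapper over classify_tier."""
    return [classify_tier(r, **kwargs) for r in records]
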