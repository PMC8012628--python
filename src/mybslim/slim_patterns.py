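"""PROSITE-notation motif parsing, matching and candidate screening.

ELM (Eukaryotic Linear Motif) entries are published as PROSITE-notation
patterns: hyphen-separated elements where a bare letter is a fixed residue,
``[RK]`` a residue class, ``x`` any residue, ``x(2,4)`` a bounded repeat,
``<``/``>`` terminal anchors, and a trailing alternative such as
``((x(0,1)-[ED]) | (*))`` offers two endings, ``*`` anchoring its branch at
the C-terminus.  The matcher enumerates every distinct (start, end) span a
pattern can occupy in a peptide; multiple internal repeat decompositions of
one span collapse to a single match, because motif biology cares about
sites, not parses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

from .records import AMINO_ACIDS
from .disorder_morf import HYDROPHOBIC_SET

_AA_SET = frozenset(AMINO_ACIDS)
_REJECTED = frozenset("UBZJO")


class PatternSyntaxError(ValueError):
    def __init__(self, message: str, column: int):
        super().__init__(f"column {column}: {message}")
        self.column = column


@dataclass(frozen=True)
class Element:
    """A residue class with a bounded repeat count."""

    residue_class: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if not self.residue_class:
            raise ValueError("empty residue class")
        if not 0 <= self.min_repeat <= self.max_repeat:
            raise ValueError("require 0 <= min_repeat <= max_repeat")

    @property
    def is_wildcard(self) -> bool:
        return self.residue_class == _AA_SET


@dataclass(frozen=True)
class Branch:
    elements: tuple[Element, ...]
    c_anchored: bool = False

    @property
    def min_length(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_repeat for e in self.elements)


@dataclass(frozen=True)
class SlimPattern:
    identifier: str
    elements: tuple[Element, ...]
    n_anchor: bool = False
    c_anchor: bool = False
    alternatives: Optional[tuple[Branch, ...]] = None

    @property
    def min_length(self) -> int:
        base = sum(e.min_repeat for e in self.elements)
        if self.alternatives:
            base += min(b.min_length for b in self.alternatives)
        return base

    @property
    def max_length(self) -> int:
        base = sum(e.max_repeat for e in self.elements)
        if self.alternatives:
            base += max(b.max_length for b in self.alternatives)
        return base

    def serialize(self) -> str:
        parts = [_element_text(e) for e in self.elements]
        if self.alternatives:
            branches = []
            for b in self.alternatives:
                if not b.elements and b.c_anchored:
                    branches.append("(*)")
                else:
                    branches.append(
                        "(" + "-".join(_element_text(e) for e in b.elements) + ")"
                    )
            parts.append("((" + ") | (".join(t.strip("()") for t in branches) + "))")
        text = "-".join(parts)
        if self.n_anchor:
            text = "<" + text
        if self.c_anchor:
            text = text + ">"
        return text


@dataclass(frozen=True)
class PatternMatch:
    start: int
    end: int
    matched: str
    full_peptide_match: bool


def _element_text(e: Element) -> str:
    if e.is_wildcard:
        core = "x"
    elif len(e.residue_class) == 1:
        core = next(iter(e.residue_class))
    else:
        core = "[" + "".join(sorted(e.residue_class)) + "]"
    if (e.min_repeat, e.max_repeat) == (1, 1):
        return core
    if e.min_repeat == e.max_repeat:
        return f"{core}({e.min_repeat})"
    return f"{core}({e.min_repeat},{e.max_repeat})"


# --- parser ----------------------------------------------------------------

def _split_top_level(text: str, sep: str, offset: int) -> list[tuple[str, int]]:
    """Split on ``sep`` at bracket/paren depth 0, keeping column offsets."""
    parts, depth, cur, start = [], 0, [], 0
    for i, ch in enumerate(text):
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
            if depth < 0:
                raise PatternSyntaxError("unbalanced bracket", offset + i + 1)
        if ch == sep and depth == 0:
            parts.append(("".join(cur), offset + start))
            cur, start = [], i + 1
        else:
            cur.append(ch)
    if depth != 0:
        raise PatternSyntaxError("unbalanced bracket", offset + len(text))
    parts.append(("".join(cur), offset + start))
    return parts


def _parse_repeat(text: str, offset: int) -> tuple[int, int]:
    if not (text.startswith("(") and text.endswith(")")):
        raise PatternSyntaxError(f"malformed repeat {text!r}", offset + 1)
    body = text[1:-1]
    try:
        if "," in body:
            lo_s, hi_s = body.split(",", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(body)
    except ValueError:
        raise PatternSyntaxError(f"non-integer repeat {body!r}", offset + 2) from None
    if lo < 0 or lo > hi:
        raise PatternSyntaxError(
            f"invalid repeat range ({lo},{hi})", offset + 2
        )
    return lo, hi


def _parse_element(token: str, offset: int) -> Element:
    token = token.strip()
    if not token:
        raise PatternSyntaxError("empty element", offset + 1)
    if token[0] == "[":
        close = token.find("]")
        if close < 0:
            raise PatternSyntaxError("unterminated class", offset + 1)
        members = token[1:close].upper()
        if not members:
            raise PatternSyntaxError("empty residue class", offset + 1)
        bad = set(members) - _AA_SET
        if bad:
            raise PatternSyntaxError(
                f"invalid residues {sorted(bad)} in class", offset + 2
            )
        cls = frozenset(members)
        rest = token[close + 1 :]
    elif token[0] in ("x", "X"):
        cls = _AA_SET
        rest = token[1:]
    else:
        aa = token[0].upper()
        if aa not in _AA_SET:
            raise PatternSyntaxError(f"invalid residue {token[0]!r}", offset + 1)
        cls = frozenset(aa)
        rest = token[1:]
    if rest:
        lo, hi = _parse_repeat(rest, offset + len(token) - len(rest))
        return Element(cls, lo, hi)
    return Element(cls)


def _parse_elements(text: str, offset: int) -> tuple[Element, ...]:
    return tuple(
        _parse_element(tok, off) for tok, off in _split_top_level(text, "-", offset)
    )


def parse_prosite(text: str, identifier: str = "") -> SlimPattern:
    """Parse a PROSITE-notation pattern string.

    Supports fixed residues, classes ``[..]``, wildcard ``x``, repeats
    ``x(n)`` / ``x(m,n)``, anchors ``<`` and ``>``, and a terminal
    alternative ``((A) | (B))`` where a branch of ``*`` anchors the match
    at the C-terminus.  Raises PatternSyntaxError with a column number on
    malformed input.
    """
    raw = text.strip().rstrip(".")
    if not raw:
        raise PatternSyntaxError("empty pattern", 1)
    n_anchor = raw.startswith("<")
    if n_anchor:
        raw = raw[1:]
    c_anchor = raw.endswith(">")
    if c_anchor:
        raw = raw[:-1]
    tokens = _split_top_level(raw, "-", 0)
    alternatives: Optional[tuple[Branch, ...]] = None
    if tokens and tokens[-1][0].strip().startswith("(("):
        alt_text, alt_off = tokens[-1]
        alternatives = _parse_alternatives(alt_text.strip(), alt_off)
        tokens = tokens[:-1]
    elements = tuple(_parse_element(tok, off) for tok, off in tokens)
    if not elements and not alternatives:
        raise PatternSyntaxError("pattern has no elements", 1)
    return SlimPattern(identifier, elements, n_anchor, c_anchor, alternatives)


def _parse_alternatives(text: str, offset: int) -> tuple[Branch, ...]:
    if not (text.startswith("(") and text.endswith(")")):
        raise PatternSyntaxError("malformed alternative group", offset + 1)
    inner = text[1:-1]
    branches = []
    for part, off in _split_top_level(inner, "|", offset + 1):
        part = part.strip()
        if not (part.startswith("(") and part.endswith(")")):
            raise PatternSyntaxError("branch must be parenthesised", off + 1)
        body = part[1:-1].strip()
        if body == "*":
            branches.append(Branch((), c_anchored=True))
        else:
            branches.append(Branch(_parse_elements(body, off + 1)))
    if len(branches) < 2:
        raise PatternSyntaxError("alternative needs at least 2 branches", offset + 1)
    return tuple(branches)


# --- matcher ---------------------------------------------------------------

def _advance(positions: set[int], elements: Sequence[Element], peptide: str) -> set[int]:
    """DP over elements: the set of end offsets reachable from ``positions``."""
    cur = positions
    for el in elements:
        nxt: set[int] = set()
        for p in cur:
            # extend residue by residue while class membership holds
            limit = min(len(peptide), p + el.max_repeat)
            q = p
            if el.min_repeat == 0:
                nxt.add(p)
            while q < limit and peptide[q] in el.residue_class:
                q += 1
                if q - p >= el.min_repeat:
                    nxt.add(q)
        cur = nxt
        if not cur:
            break
    return cur


MatchMode = Literal["all", "leftmost", "full_only"]


def match_pattern(
    pattern: SlimPattern, peptide: str, mode: MatchMode = "all"
) -> list[PatternMatch]:
    """Enumerate distinct match spans of a pattern in a peptide.

    Overlapping spans are all reported; distinct internal repeat
    decompositions of the same span are collapsed.  ``leftmost`` keeps only
    matches at the first matching start; ``full_only`` keeps spans equal to
    the whole peptide.
    """
    peptide = peptide.upper()
    bad = set(peptide) - _AA_SET
    if bad & _REJECTED:
        raise ValueError(
            f"ambiguous/non-standard residues {sorted(bad & _REJECTED)} rejected"
        )
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in peptide")
    n = len(peptide)
    spans: set[tuple[int, int]] = set()
    starts = [0] if pattern.n_anchor else range(n + 1)
    for start in starts:
        mids = _advance({start}, pattern.elements, peptide)
        ends: set[int] = set()
        if pattern.alternatives is None:
            ends = mids
        else:
            for branch in pattern.alternatives:
                reach = _advance(mids, branch.elements, peptide)
                if branch.c_anchored:
                    reach = {e for e in reach if e == n}
                ends |= reach
        if pattern.c_anchor:
            ends = {e for e in ends if e == n}
        for e in ends:
            if e > start:  # zero-length spans are not motif sites
                spans.add((start, e))
    ordered = sorted(spans)
    matches = [
        PatternMatch(s, e, peptide[s:e], full_peptide_match=(s == 0 and e == n))
        for s, e in ordered
    ]
    if mode == "full_only":
        matches = [m for m in matches if m.full_peptide_match]
    elif mode == "leftmost":
        if matches:
            first = matches[0].start
            matches = [m for m in matches if m.start == first]
    return matches


# --- bundled motif set -----------------------------------------------------

_PHI = "[" + "".join(sorted(HYDROPHOBIC_SET)) + "]"

BUNDLED_PATTERN_TEXTS: tuple[tuple[str, str], ...] = (
    ("DOC_MAPK_MEF2A_6", "[RK]-x(2,4)-[LIVMP]-x-[LIV]-x-[LIVMF]"),
    ("LIG_PALB2_WD40_1", "x-x-x-x-W-F-x-x-L"),
    ("LIG_WD40_WDR5_VDV_2", "[EDSTY]-x(0,4)-[VIPLA]-[TSDEKR]-[ILVA]"),
    ("LIG_WD40_WDR5_VDV_1", "[ED]-x(0,3)-[VIL]-D-[VI]"),
    ("DOC_WD40_RPTOR_TOS_1", "F-[EDQS]-[MILV]-[ED]-[MILV]-((x(0,1)-[ED]) | (*))"),
    ("SUBGROUP15_MOTIF", "W-V-x-x-D-x-F-E-L-S-x-L"),
    ("SUBGROUP5_MOTIF", "D-E-x-W-R-L-x-x-T"),
    ("GENERIC_ACTIVATION_PHI", f"{_PHI}-x-x-{_PHI}-{_PHI}"),
)


def bundled_patterns() -> list[SlimPattern]:
    """The packaged motif set: the five ELM entries relevant to the
    subgroup 6 C-terminal motifs, the related subgroup 15 and subgroup 5
    motifs, and the generic hydrophobic activation-domain SLiM."""
    return [parse_prosite(text, ident) for ident, text in BUNDLED_PATTERN_TEXTS]


def read_pattern_file(path: str | Path) -> list[SlimPattern]:
    """One pattern per line: ``identifier<TAB>pattern``."""
    patterns = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            ident, text = line.split("\t", 1)
        except ValueError:
            raise ValueError(f"{path}:{ln}: expected 'identifier<TAB>pattern'")
        patterns.append(parse_prosite(text, ident))
    return patterns


MatchKind = Literal["full", "partial", "none"]


def screen_peptide(pattern: SlimPattern, peptide: str) -> MatchKind:
    matches = match_pattern(pattern, peptide, "all")
    if any(m.full_peptide_match for m in matches):
        return "full"
    return "partial" if matches else "none"


def screen_candidates(
    peptides_by_key: dict[tuple[str, str], str],
    patterns: Optional[Sequence[SlimPattern]] = None,
) -> list[tuple[str, str, str, MatchKind]]:
    """Screen candidate-core peptides against a motif set.

    ``peptides_by_key`` maps (record_id, motif_label) to the candidate's
    core peptide; returns (record, motif_label, pattern_id, match_kind)
    rows, sorted for reproducibility.
    """
    pats = list(patterns) if patterns is not None else bundled_patterns()
    rows = []
    for (rid, label), peptide in sorted(peptides_by_key.items()):
        for pat in pats:
            rows.append((rid, label, pat.identifier, screen_peptide(pat, peptide)))
    return rows


def write_screen_tsv(
    rows: Sequence[tuple[str, str, str, MatchKind]], path: str | Path
) -> None:
    lines = ["record_id\tmotif_label\tpattern_id\tmatch_kind"]
    lines += ["\t".join(r) for r in rows]
    Path(path).write_text("\n".join(lines) + "\n")
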