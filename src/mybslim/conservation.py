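"""Codon-alignment conservation statistics, window discovery and NJ trees.

The C-terminus of anthocyanin-activating R2R3 MYBs is mostly disordered and
poorly conserved; the short regions that stay conserved among activators
(the S6A/S6B/S6C-type regions) are the candidate functional motifs.  This
module back-threads CDS through a protein alignment to obtain a codon
alignment, computes per-column identity with the three-tier colouring
convention (full identity / >=30% / <30%), discovers windows more conserved
than the regional average, and builds a neighbour-joining dendrogram from
p-distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .records import MultipleAlignment, SequenceRecord, ungap

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Fig-style identity tiers: full = 100%, mid = [30%, 100%), low = < 30%
TIER_MID_MIN = 0.30

Tier = Literal["full", "mid", "low"]


@dataclass(frozen=True)
class ColumnStats:
    column: int
    identity: float
    tier: Tier
    consensus_symbol: str
    information_content: float


@dataclass(frozen=True)
class ConservedWindow:
    """Half-open column span whose mean identity beats the regional baseline."""

    start_col: int
    end_col: int
    mean_identity: float
    label: str = ""

    @property
    def length(self) -> int:
        return self.end_col - self.start_col


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


def thread_codon_alignment(
    protein_alignment: MultipleAlignment,
    cds_by_id: dict[str, SequenceRecord],
) -> MultipleAlignment:
    """Replace each aligned residue by its source codon (back-threading).

    Protein gaps become ``---``; a terminal stop codon on the CDS is
    dropped.  Each CDS must be exactly 3x the ungapped protein length (or
    3x + 3 with the terminal stop).  Internal stop codons are reported as
    errors here and belong to defect calling, not threading.
    """
    if protein_alignment.alphabet != "protein":
        raise ValueError("expected a protein alignment")
    rows = []
    for rid, gapped in protein_alignment.rows:
        if rid not in cds_by_id:
            raise KeyError(f"no CDS for alignment row {rid!r}")
        cds = cds_by_id[rid].residues
        plen = len(ungap(gapped))
        if len(cds) == 3 * plen + 3:
            if cds[-3:] not in STOP_CODONS:
                raise ValueError(
                    f"{rid}: CDS length {len(cds)} implies terminal stop, "
                    f"found {cds[-3:]!r}"
                )
            cds = cds[:-3]
        elif len(cds) != 3 * plen:
            raise ValueError(
                f"{rid}: CDS length {len(cds)} does not match "
                f"3 x protein length ({3 * plen} or {3 * plen + 3})"
            )
        for ci in range(plen):
            if cds[3 * ci : 3 * ci + 3] in STOP_CODONS:
                raise ValueError(
                    f"{rid}: internal stop codon at codon {ci + 1}; "
                    "run defect detection before threading"
                )
        out = []
        pos = 0
        for aa in gapped:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds[3 * pos : 3 * pos + 3])
                pos += 1
        rows.append((rid, "".join(out)))
    return MultipleAlignment(rows, "codon")


def column_conservation(
    alignment: MultipleAlignment, ignore_gaps: bool = True
) -> list[ColumnStats]:
    """Per-column modal identity, tier and information content.

    Identity is the frequency of the modal symbol among counted entries
    (gaps excluded when ``ignore_gaps``, else counted as a symbol, so
    absence is signal).  Consensus ties break alphabetically, with '-'
    sorting after letters.  Information content is log2(K) minus the
    Shannon entropy of symbol frequencies with gaps always excluded,
    K = 4 for dna/codon, 20 for protein.
    """
    if len(alignment) < 2:
        raise ValueError("conservation needs at least 2 rows")
    K = 20 if alignment.alphabet == "protein" else 4
    stats = []
    for c in range(alignment.n_columns):
        col = alignment.column(c)
        counted = col if not ignore_gaps else [s for s in col if s != "-"]
        if not counted:
            stats.append(ColumnStats(c, 0.0, "low", "-", 0.0))
            continue
        # symbols sorted alphabetically with '-' last: first maximum wins ties
        symbols = sorted(set(counted), key=lambda s: (s == "-", s))
        counts = {s: counted.count(s) for s in symbols}
        best = max(counts.values())
        consensus = next(s for s in symbols if counts[s] == best)
        identity = best / len(counted)
        tier: Tier = (
            "full" if identity == 1.0 else "mid" if identity >= TIER_MID_MIN else "low"
        )
        residues = [s for s in col if s != "-"]
        if residues:
            freqs = np.array(
                [residues.count(s) for s in sorted(set(residues))], float
            ) / len(residues)
            entropy = float(-(freqs * np.log2(freqs)).sum())
            ic = max(0.0, math.log2(K) - entropy)
        else:
            ic = 0.0
        stats.append(ColumnStats(c, identity, tier, consensus, ic))
    return stats


def find_conserved_windows(
    stats: Sequence[ColumnStats],
    region: tuple[int, int],
    min_len: int = 15,
    max_len: int = 17,
    margin: float = 0.10,
) -> list[ConservedWindow]:
    """Discover windows more conserved than the regional average.

    The baseline is the mean identity over ``region`` (half-open columns);
    every window of length min_len..max_len whose mean identity exceeds
    baseline + margin is kept, and overlapping keepers merge into maximal
    runs labelled W1, W2, ... left to right.
    """
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    start, end = region
    if end - start < min_len:
        raise ValueError("region shorter than min_len")
    ident = np.array([s.identity for s in stats])
    baseline = float(ident[start:end].mean())
    cutoff = baseline + margin

    kept: list[tuple[int, int]] = []
    for L in range(min_len, max_len + 1):
        for s in range(start, end - L + 1):
            if ident[s : s + L].mean() > cutoff:
                kept.append((s, s + L))
    if not kept:
        return []
    kept.sort()
    merged = [list(kept[0])]
    for s, e in kept[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        ConservedWindow(s, e, float(ident[s:e].mean()), f"W{i + 1}")
        for i, (s, e) in enumerate(merged)
    ]


def p_distance_matrix(alignment: MultipleAlignment) -> DistanceMatrix:
    """Pairwise p-distances over columns where neither row is gapped."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    seqs = [np.frombuffer(seq.encode(), dtype="S1") for _, seq in alignment.rows]
    gap = np.frombuffer(b"-", dtype="S1")[0]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (seqs[i] != gap) & (seqs[j] != gap)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"rows {alignment.ids[i]!r} and {alignment.ids[j]!r} share "
                    "no comparable columns"
                )
            d[i, j] = d[j, i] = float((seqs[i][ok] != seqs[j][ok]).sum()) / m
    return DistanceMatrix(list(alignment.ids), d)


# --- neighbour joining -----------------------------------------------------

class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name: Optional[str] = None,
                 children: Optional[list[tuple["_Node", float]]] = None):
        self.name = name
        self.children = children or []


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Classical Saitou-Nei neighbour joining; returns an unrooted Newick.

    Q(i, j) = (n - 2) d(i, j) - r_i - r_j is minimised with ties broken by
    the lowest index pair; negative branch lengths are clamped to zero with
    a warning.  Exact on additive matrices.
    """
    ids = dm.ids
    n = len(ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[_Node] = [_Node(name=i) for i in ids]
    active = list(range(n))

    def _clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0")
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
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        new = _Node(children=[(nodes[i], _clamp(li)), (nodes[j], _clamp(lj))])
        # grow the matrix by one row/column for the new internal node
        k_new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
            d[k_new, k] = d[k, k_new] = dk
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [k_new]

    a, b, c = active
    la = _clamp((d[a, b] + d[a, c] - d[b, c]) / 2.0)
    lb = _clamp((d[a, b] + d[b, c] - d[a, c]) / 2.0)
    lc = _clamp((d[a, c] + d[b, c] - d[a, b]) / 2.0)
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return _to_newick(root) + ";"


def _to_newick(node: _Node) -> str:
    if not node.children:
        return node.name or ""
    inner = ",".join(
        f"{_to_newick(child)}:{length:.10g}" for child, length in node.children
    )
    return f"({inner})"


def write_column_stats_tsv(stats: Sequence[ColumnStats], path: str | Path) -> None:
    lines = ["column\tidentity\ttier\tconsensus\tIC_bits"]
    for s in stats:
        lines.append(
            f"{s.column}\t{s.identity:.6f}\t{s.tier}\t{s.consensus_symbol}\t"
            f"{s.information_content:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def logo_matrix(
    alignment: MultipleAlignment, region: Optional[tuple[int, int]] = None
) -> tuple[list[str], np.ndarray]:
    """Position x symbol frequency matrix (gaps ignored) for logo plotting."""
    start, end = region or (0, alignment.n_columns)
    symbols = sorted({
        s for c in range(start, end) for s in alignment.column(c) if s != "-"
    })
    mat = np.zeros((end - start, len(symbols)))
    for c in range(start, end):
        col = [s for s in alignment.column(c) if s != "-"]
        for k, sym in enumerate(symbols):
            mat[c - start, k] = col.count(sym) / len(col) if col else 0.0
    return symbols, mat
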