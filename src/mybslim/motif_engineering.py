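"""Motif-swap chimera design and Golden Gate domestication.

Functional testing of candidate C-terminal motifs proceeds by swapping the
motif (plus disordered flanking sequence, which tunes SLiM interactions)
between closely related genes that differ in activation strength, then
assembling constructs by Golden Gate cloning.  That requires (i) chimeric
CDS built on a shared codon alignment so donor and acceptor coordinates
stay synchronised, (ii) compact naming of amino-acid substitutions between
natural variants, and (iii) synonymous removal of Type IIS recognition
sites (BsaI by default) from the CDS before assembly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio.Seq import Seq

from .records import MultipleAlignment, SequenceRecord

BSAI_SITE = "GGTCTC"

# aa -> synonymous codons under the standard nuclear code
_CODON_TABLE: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            _aa = str(Seq(_codon).translate())
            _CODON_TABLE.setdefault(_aa, []).append(_codon)

# Relative codon usage (dicot-like) used only to rank synonymous choices;
# absolute accuracy is irrelevant, stable ordering is what matters.
CODON_USAGE = {
    "TTT": 0.52, "TTC": 0.48, "TTA": 0.14, "TTG": 0.22, "CTT": 0.26,
    "CTC": 0.17, "CTA": 0.11, "CTG": 0.10, "ATT": 0.41, "ATC": 0.35,
    "ATA": 0.24, "ATG": 1.00, "GTT": 0.40, "GTC": 0.19, "GTA": 0.15,
    "GTG": 0.26, "TCT": 0.28, "TCC": 0.13, "TCA": 0.20, "TCG": 0.10,
    "AGT": 0.16, "AGC": 0.13, "CCT": 0.38, "CCC": 0.11, "CCA": 0.33,
    "CCG": 0.18, "ACT": 0.34, "ACC": 0.20, "ACA": 0.31, "ACG": 0.15,
    "GCT": 0.43, "GCC": 0.16, "GCA": 0.27, "GCG": 0.14, "TAT": 0.52,
    "TAC": 0.48, "TAA": 0.36, "TAG": 0.20, "TGA": 0.44, "CAT": 0.61,
    "CAC": 0.39, "CAA": 0.56, "CAG": 0.44, "AAT": 0.52, "AAC": 0.48,
    "AAA": 0.49, "AAG": 0.51, "GAT": 0.68, "GAC": 0.32, "GAA": 0.52,
    "GAG": 0.48, "TGT": 0.60, "TGC": 0.40, "TGG": 1.00, "CGT": 0.17,
    "CGC": 0.07, "CGA": 0.12, "CGG": 0.09, "AGA": 0.35, "AGG": 0.20,
    "GGT": 0.34, "GGC": 0.14, "GGA": 0.37, "GGG": 0.15,
}


@dataclass
class ChimeraDesign:
    acceptor_id: str
    donor_id: str
    column_span: tuple[int, int]  # half-open codon columns
    flank_cols: int
    chimera_cds: SequenceRecord
    chimera_protein: SequenceRecord
    provenance: list[str]  # per codon column: 'acceptor' | 'donor'
    warnings: list[str] = field(default_factory=list)


@dataclass
class DomesticationReport:
    site: str
    hits_before: list[tuple[int, str]]  # (0-based position, '+' | '-')
    edits: list[tuple[int, str, str]]   # (1-based codon index, old, new)
    hits_after: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "site": self.site,
                "hits_before": [
                    {"position": p, "strand": s} for p, s in self.hits_before
                ],
                "edits": [
                    {"codon_index": i, "old_codon": o, "new_codon": n}
                    for i, o, n in self.edits
                ],
                "hits_after": self.hits_after,
            },
            indent=1,
        )


@dataclass(frozen=True)
class SubstitutionList:
    """Substitutions as ``XnY`` strings, n 1-based in the ungapped reference."""

    items: tuple[str, ...]

    def __post_init__(self) -> None:
        last = 0
        for item in self.items:
            ref, var = item[0], item[-1]
            pos = int(item[1:-1])
            if ref == var:
                raise ValueError(f"{item}: reference equals variant")
            if pos <= last:
                raise ValueError("positions must be strictly increasing")
            last = pos


def design_chimera(
    codon_alignment: MultipleAlignment,
    acceptor_id: str,
    donor_id: str,
    span: tuple[int, int],
    flank_cols: int = 0,
    domain_end_col: Optional[int] = None,
) -> ChimeraDesign:
    """Swap donor codons into the acceptor over ``span`` +/- flanks.

    ``span`` is half-open in codon columns of the shared alignment.  Donor
    gaps inside the swapped region delete the position; acceptor gaps
    outside it stay gaps.  The chimera is rejected if the swap introduces
    an internal stop codon, and a warning is attached when the span touches
    the DNA-binding domain (swaps target C-terminal motifs only).
    """
    if codon_alignment.alphabet != "codon":
        raise ValueError("design_chimera needs a codon alignment")
    n_cols = codon_alignment.n_columns // 3
    start, end = span
    if not (0 <= start < end <= n_cols):
        raise ValueError(f"span {span} outside 0..{n_cols}")
    lo = max(0, start - flank_cols)
    hi = min(n_cols, end + flank_cols)

    acc = codon_alignment.row(acceptor_id)
    don = codon_alignment.row(donor_id)
    codons: list[str] = []
    provenance: list[str] = []
    warns: list[str] = []
    for c in range(n_cols):
        src, tag = (don, "donor") if lo <= c < hi else (acc, "acceptor")
        provenance.append(tag)
        cod = src[3 * c : 3 * c + 3]
        if cod != "---":
            codons.append(cod)
    cds_seq = "".join(codons)
    protein = str(Seq(cds_seq).translate())
    # threaded codon rows carry no terminal stop, so any stop is internal
    if "*" in protein:
        raise ValueError("chimera rejected: swap introduces an internal stop codon")
    if domain_end_col is not None and lo < domain_end_col:
        warns.append(
            f"swap region [{lo}, {hi}) touches the DNA-binding domain "
            f"(ends at column {domain_end_col})"
        )
        warnings.warn(warns[-1])
    name = f"{acceptor_id}::{donor_id}[{start}:{end}]"
    return ChimeraDesign(
        acceptor_id,
        donor_id,
        span,
        flank_cols,
        SequenceRecord(name, cds_seq, "dna"),
        SequenceRecord(name, protein, "protein"),
        provenance,
        warns,
    )


def name_substitutions(
    reference: str, variant: str
) -> tuple[SubstitutionList, list[str]]:
    """Name residue substitutions between two aligned protein rows.

    Returns the ``XnY`` substitution list (n 1-based in the ungapped
    reference) and a separate list of indel descriptors; indels are never
    reported as substitutions.
    """
    if len(reference) != len(variant):
        raise ValueError("aligned rows must have equal length")
    items: list[str] = []
    indels: list[str] = []
    ref_pos = 0
    for col, (a, b) in enumerate(zip(reference.upper(), variant.upper())):
        if a != "-":
            ref_pos += 1
        if a == "-" and b == "-":
            continue
        if a == "-":
            indels.append(f"ins{ref_pos}{b}")
        elif b == "-":
            indels.append(f"del{a}{ref_pos}")
        elif a != b:
            items.append(f"{a}{ref_pos}{b}")
    return SubstitutionList(tuple(items)), indels


def apply_substitutions(reference: str, subs: SubstitutionList) -> str:
    """Apply an ``XnY`` list to an ungapped reference (round-trip check)."""
    out = list(reference.upper())
    for item in subs.items:
        ref, var = item[0], item[-1]
        pos = int(item[1:-1]) - 1
        if out[pos] != ref:
            raise ValueError(f"{item}: reference has {out[pos]} at {pos + 1}")
        out[pos] = var
    return "".join(out)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def find_site_hits(cds: str, site: str) -> list[tuple[int, str]]:
    """All occurrences of ``site`` on either strand, in + coordinates."""
    hits = []
    for needle, strand in ((site, "+"), (_revcomp(site), "-")):
        p = cds.find(needle)
        while p >= 0:
            hits.append((p, strand))
            p = cds.find(needle, p + 1)
    return sorted(hits)


def domesticate(
    cds: SequenceRecord,
    site: str = BSAI_SITE,
    codon_preference: Optional[dict[str, float]] = None,
) -> tuple[SequenceRecord, DomesticationReport]:
    """Remove every occurrence of a restriction site by synonymous edits.

    Each occurrence (either strand) is destroyed by recoding one
    overlapping codon: among synonymous codons that remove the occurrence
    without increasing the total site count, the one changing the most
    bases inside the site footprint wins, ties broken by codon-usage
    preference then lexicographically.  Iterates to a fixed point; failure
    (e.g. a site covered only by Met/Trp codons) is reported with the
    position.  Translation is invariant by construction.
    """
    if len(cds.residues) % 3:
        raise ValueError("CDS length must be divisible by 3")
    if len(site) < 4:
        raise ValueError("site too short")
    site = site.upper()
    usage = CODON_USAGE if codon_preference is None else codon_preference
    seq = cds.residues
    hits_before = find_site_hits(seq, site)
    edits: list[tuple[int, str, str]] = []

    for _ in range(10 * max(1, len(hits_before))):
        hits = find_site_hits(seq, site)
        if not hits:
            break
        pos, _strand = hits[0]
        footprint = range(pos, pos + len(site))
        first_codon = pos // 3
        last_codon = (pos + len(site) - 1) // 3
        best = None
        for ci in range(first_codon, last_codon + 1):
            old = seq[3 * ci : 3 * ci + 3]
            aa = str(Seq(old).translate())
            for alt in _CODON_TABLE[aa]:
                if alt == old:
                    continue
                candidate = seq[: 3 * ci] + alt + seq[3 * ci + 3 :]
                if len(find_site_hits(candidate, site)) >= len(hits):
                    continue
                changed = sum(
                    1
                    for k in range(3)
                    if 3 * ci + k in footprint and alt[k] != old[k]
                )
                key = (changed, usage.get(alt, 0.0), [-ord(c) for c in alt])
                if best is None or key > best[0]:
                    best = (key, ci, old, alt, candidate)
        if best is None:
            raise ValueError(
                f"cannot remove {site} occurrence at position {pos + 1}: "
                "no synonymous escape"
            )
        _, ci, old, alt, seq = best
        edits.append((ci + 1, old, alt))
    else:
        raise RuntimeError("domestication did not converge")

    report = DomesticationReport(site, hits_before, edits, len(find_site_hits(seq, site)))
    edited = SequenceRecord(cds.id, seq, "dna", cds.description)
    if str(Seq(seq).translate()) != str(Seq(cds.residues).translate()):
        raise AssertionError("domestication altered the translation")
    return edited, report


def write_provenance_tsv(design: ChimeraDesign, path: str | Path) -> None:
    lines = ["codon_column\tsource"]
    lines += [f"{c}\t{tag}" for c, tag in enumerate(design.provenance)]
    Path(path).write_text("\n".join(lines) + "\n")
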