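"""MYB repeat detection, architecture classification and functional calling.

The plant MYB family is defined by one to four tandem ~50-residue
helix-turn-helix repeats at the N-terminus.  This module detects repeats
with a gap-free position-specific scoring matrix (PSSM) built from a seed
alignment of repeat instances, classifies records into the R3 / R2R3 / 3R /
4R architecture classes by counting chained tandem hits, and labels gene
models non-functional when their CDS carries a premature termination codon
or frameshift inside the repeat (DNA-binding domain) region.

A PSSM with greedy non-overlap resolution deliberately replaces profile-HMM
scanning: the discriminating signal for family membership is tandem-repeat
presence, not fine HMM alignment, and a gap-free scorer is exactly
reproducible by a brute-force oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .records import AMINO_ACIDS, MultipleAlignment, SequenceRecord

# Defaults: 15-bit hit threshold and a 30-residue maximum linker between
# repeats of one tandem chain (R2-R3 linkers are short).
DEFAULT_THRESHOLD_BITS = 15.0
DEFAULT_TANDEM_GAP_MAX = 30

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

ArchClass = Literal["none", "R3", "R2R3", "3R", "4R"]


@dataclass(frozen=True)
class ScoringProfile:
    """Per-column amino-acid frequencies with a shared background.

    ``frequencies`` has shape (length, 20) in the order of ``AMINO_ACIDS``;
    every column and the background sum to one, and with a positive
    pseudocount every entry is strictly positive so log-odds are finite.
    """

    frequencies: np.ndarray
    background: np.ndarray
    pseudocount: float
    profile_id: str = "profile"

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "background", bg)
        if freqs.ndim != 2 or freqs.shape[1] != 20:
            raise ValueError("frequencies must have shape (length, 20)")
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("column frequencies must sum to 1")
        if not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return int(self.frequencies.shape[0])

    @property
    def log_odds(self) -> np.ndarray:
        """(length, 20) log2(freq / background); -inf where freq is 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.frequencies) - np.log2(self.background)


@dataclass(frozen=True)
class RepeatHit:
    """One detected repeat unit in 0-based half-open protein coordinates."""

    start: int
    end: int
    score: float
    profile_id: str = "profile"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("hit end must exceed start")
        if not math.isfinite(self.score):
            raise ValueError("hit score must be finite")


@dataclass(frozen=True)
class Defect:
    """A loss-of-function lesion.

    ``position`` is 1-based: the codon index for premature stops, the
    alignment column for frameshifts.
    """

    kind: Literal["premature_stop", "frameshift"]
    position: int
    in_domain: bool

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("defect position is 1-based")


@dataclass
class ArchitectureCall:
    record_id: str
    hits: list[RepeatHit]
    arch_class: ArchClass
    functional: Optional[bool]
    defects: list[Defect] = field(default_factory=list)
    status: str = "functional"
    needs_manual_review: bool = False


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def build_profile(
    seed_alignment: MultipleAlignment,
    pseudocount: float = 0.5,
    background: Optional[np.ndarray] = None,
    profile_id: str = "myb_repeat",
) -> ScoringProfile:
    """Estimate a PSSM from a gapped seed alignment.

    Column frequencies are ``(count + pseudocount) / (occupancy + 20 *
    pseudocount)`` with gaps excluded from counts; all-gap columns are
    dropped, shortening the profile.
    """
    if seed_alignment.alphabet != "protein":
        raise ValueError("seed alignment must be protein")
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs at least 2 rows")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    bg = uniform_background() if background is None else np.asarray(background, float)

    columns = []
    for c in range(seed_alignment.n_columns):
        col = seed_alignment.column(c)
        counts = np.zeros(20)
        occupancy = 0
        for sym in col:
            if sym == "-":
                continue
            if sym not in _AA_INDEX:
                raise ValueError(f"non-standard residue {sym!r} in seed column {c}")
            counts[_AA_INDEX[sym]] += 1
            occupancy += 1
        if occupancy == 0:
            continue  # all-gap column dropped
        denom = occupancy + 20.0 * pseudocount
        columns.append((counts + pseudocount) / denom)
    if not columns:
        raise ValueError("all seed columns are gaps")
    return ScoringProfile(np.array(columns), bg, pseudocount, profile_id)


def score_windows(profile: ScoringProfile, residues: str) -> np.ndarray:
    """Log-odds score (bits) of every gap-free window; empty if too short."""
    L, W = len(residues), profile.length
    if L < W:
        return np.zeros(0)
    lo = profile.log_odds
    idx = np.array(
        [_AA_INDEX.get(aa, -1) for aa in residues], dtype=int
    )
    scores = np.empty(L - W + 1)
    for s in range(L - W + 1):
        win = idx[s : s + W]
        # unknown residues (X, read-through stops) are uninformative: 0 bits
        vals = np.where(win >= 0, lo[np.arange(W), np.clip(win, 0, 19)], 0.0)
        scores[s] = float(vals.sum())
    return scores


def scan_profile(
    profile: ScoringProfile,
    protein: SequenceRecord,
    threshold_bits: float = DEFAULT_THRESHOLD_BITS,
) -> list[RepeatHit]:
    """Find non-overlapping repeat hits scoring at or above threshold.

    Every window is scored as the sum of per-column log2(freq/background);
    overlapping candidates are resolved greedily by descending score with
    ties going to the leftmost start.  The result is sorted by start.
    """
    scores = score_windows(profile, protein.residues)
    W = profile.length
    candidates = [
        (float(scores[s]), s) for s in range(len(scores)) if scores[s] >= threshold_bits
    ]
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken: list[RepeatHit] = []
    for score, s in candidates:
        if all(s + W <= h.start or s >= h.end for h in taken):
            taken.append(RepeatHit(s, s + W, score, profile.profile_id))
    taken.sort(key=lambda h: h.start)
    return taken


def classify_architecture(
    hits: Sequence[RepeatHit], tandem_gap_max: int = DEFAULT_TANDEM_GAP_MAX
) -> ArchClass:
    """Name the repeat architecture from the longest tandem chain of hits.

    Consecutive hits belong to one chain when separated by at most
    ``tandem_gap_max`` residues; chain length 1 -> R3, 2 -> R2R3, 3 -> 3R,
    4 or more -> 4R, and no hits -> none.
    """
    if not hits:
        return "none"
    starts = [h.start for h in hits]
    if starts != sorted(starts):
        raise ValueError("hits must be sorted by start")
    for a, b in zip(hits, hits[1:]):
        if b.start < a.end:
            raise ValueError("hits must be non-overlapping")
    best = run = 1
    for a, b in zip(hits, hits[1:]):
        run = run + 1 if b.start - a.end <= tandem_gap_max else 1
        best = max(best, run)
    return {1: "R3", 2: "R2R3", 3: "3R"}.get(best, "4R")


def detect_defects(
    cds: SequenceRecord,
    domain_span: tuple[int, int],
    reference_codon_alignment: Optional[tuple[str, str]] = None,
) -> tuple[Optional[bool], list[Defect], str]:
    """Call premature stops and frameshifts against a protein domain span.

    ``domain_span`` is 0-based half-open in protein coordinates.  Frame-0
    translation with the standard code; a stop codon strictly before the
    domain end is a premature stop.  If a pairwise nucleotide alignment
    (reference row, cds row) is supplied, any gap run inside the domain
    whose length is not a multiple of 3 is a frameshift.  Returns
    (functional, defects, status) where status is 'functional',
    'non_functional' or 'ambiguous'; functional is None when ambiguous.
    """
    if cds.alphabet != "dna":
        raise ValueError("detect_defects requires a CDS (dna) record")
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    dstart, dend = domain_span
    seq = cds.residues
    n_codons = len(seq) // 3
    if dend > n_codons:
        raise ValueError(
            f"domain span {domain_span} outside translated length {n_codons}"
        )

    defects: list[Defect] = []
    ambiguous = False
    stop_codons = {"TAA", "TAG", "TGA"}
    first_stop = None  # 0-based codon index
    for ci in range(n_codons):
        codon = seq[3 * ci : 3 * ci + 3]
        if "N" in codon:
            # a stop verdict cannot be made for this codon
            could_stop = any(
                c in stop_codons
                for c in _expand_n(codon)
            )
            if could_stop and ci < dend:
                ambiguous = True
            continue
        if codon in stop_codons:
            first_stop = ci
            break
    if first_stop is not None and first_stop < dend:
        defects.append(
            Defect("premature_stop", first_stop + 1, in_domain=first_stop >= dstart)
        )

    if reference_codon_alignment is not None:
        ref_row, cds_row = reference_codon_alignment
        if len(ref_row) != len(cds_row):
            raise ValueError("pairwise alignment rows differ in length")
        # map alignment columns to reference codon index to locate the domain
        ref_pos = 0
        col = 0
        gap_start = None
        gap_len = 0
        domain_nt = (dstart * 3, dend * 3)
        for col in range(len(ref_row)):
            gapped = ref_row[col] == "-" or cds_row[col] == "-"
            if gapped:
                if gap_start is None:
                    gap_start, gap_len = col, 0
                gap_len += 1
            else:
                if gap_start is not None and gap_len % 3 != 0:
                    if domain_nt[0] <= ref_pos < domain_nt[1]:
                        defects.append(Defect("frameshift", gap_start + 1, True))
                    else:
                        defects.append(Defect("frameshift", gap_start + 1, False))
                gap_start = None
            if ref_row[col] != "-":
                ref_pos += 1
        if gap_start is not None and gap_len % 3 != 0:
            in_dom = domain_nt[0] <= ref_pos <= domain_nt[1]
            defects.append(Defect("frameshift", gap_start + 1, in_dom))

    has_in_domain = any(d.in_domain for d in defects)
    if ambiguous and not has_in_domain:
        return None, defects, "ambiguous"
    functional = not has_in_domain
    return functional, defects, "non_functional" if has_in_domain else "functional"


def _expand_n(codon: str) -> list[str]:
    out = [""]
    for base in codon:
        opts = "ACGT" if base == "N" else base
        out = [p + b for p in out for b in opts]
    return out


def repair_frame(pair: tuple[str, str]) -> str:
    """Restore the reading frame of a CDS from a reference pairwise alignment.

    Deleted bases are filled from the reference row and inserted bases are
    dropped, so substitutions are kept while indels no longer shift the
    frame.  This mirrors codon-alignment-guided curation of defective gene
    models: the repaired conceptual translation reveals the underlying
    repeat architecture even when the native translation is garbled
    downstream of a frameshift.
    """
    ref_row, cds_row = pair
    if len(ref_row) != len(cds_row):
        raise ValueError("pairwise alignment rows differ in length")
    out = []
    for r, c in zip(ref_row, cds_row):
        if r == "-":
            continue  # insertion in the record: drop
        out.append(r if c == "-" else c)
    return "".join(out)


def annotate_family(
    proteins: Sequence[SequenceRecord],
    profile: ScoringProfile,
    cds_by_id: Optional[dict[str, SequenceRecord]] = None,
    threshold_bits: float = DEFAULT_THRESHOLD_BITS,
    tandem_gap_max: int = DEFAULT_TANDEM_GAP_MAX,
    alignments_by_id: Optional[dict[str, tuple[str, str]]] = None,
) -> list[ArchitectureCall]:
    """Scan, classify and (when CDS are provided) functionally call records.

    Records with more than 4 chained hits, or hits beyond the N-terminal
    half of the protein, are flagged for manual review rather than excluded
    (fused annotations and MYB-related genes are curated by hand).
    """
    calls = []
    for prot in proteins:
        scan_target = prot
        pair = alignments_by_id.get(prot.id) if alignments_by_id else None
        if pair is not None:
            # architecture is read from the frame-repaired translation so a
            # frameshift downstream does not hide genuine repeats
            repaired = SequenceRecord(prot.id, repair_frame(pair), "dna")
            scan_target = repaired.translate()
        hits = scan_profile(profile, scan_target, threshold_bits)
        arch = classify_architecture(hits, tandem_gap_max)
        review = len(hits) > 4 or any(
            h.start > len(prot) / 2 for h in hits
        )
        functional: Optional[bool] = True
        defects: list[Defect] = []
        status = "functional"
        if cds_by_id is not None and prot.id in cds_by_id and hits:
            span = (hits[0].start, hits[-1].end)
            functional, defects, status = detect_defects(
                cds_by_id[prot.id], span, pair
            )
        calls.append(
            ArchitectureCall(prot.id, hits, arch, functional, defects, status, review)
        )
    return calls


def write_annotation_tsv(calls: Sequence[ArchitectureCall], path: str | Path) -> None:
    """TSV report with 1-based inclusive hit coordinates; JSON mirror alongside."""
    lines = ["record_id\tarch_class\tn_hits\thit_coords\tfunctional\tdefects"]
    payload = []
    for c in calls:
        coords = ",".join(f"{h.start + 1}-{h.end}" for h in c.hits)
        defs = ";".join(
            f"{d.kind}@{d.position}{'(domain)' if d.in_domain else ''}"
            for d in c.defects
        )
        lines.append(
            f"{c.record_id}\t{c.arch_class}\t{len(c.hits)}\t{coords}\t"
            f"{c.status}\t{defs}"
        )
        payload.append(
            {
                "record_id": c.record_id,
                "arch_class": c.arch_class,
                "hits": [
                    {"start": h.start + 1, "end": h.end, "score_bits": h.score}
                    for h in c.hits
                ],
                "status": c.status,
                "defects": [
                    {"kind": d.kind, "position": d.position, "in_domain": d.in_domain}
                    for d in c.defects
                ],
                "needs_manual_review": c.needs_manual_review,
            }
        )
    Path(path).write_text("\n".join(lines) + "\n")
    Path(path).with_suffix(".json").write_text(json.dumps(payload, indent=1))
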