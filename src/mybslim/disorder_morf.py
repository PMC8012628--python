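"""Disorder profiles, MoRF candidate calling and consensus divergence.

Molecular recognition features (MoRFs) are short segments that are
relatively ordered inside an intrinsically disordered region and often
coincide with short linear motifs.  Three lines of evidence are combined
here: conservation among activators (from the conservation module), a dip
in the disorder profile relative to the flanks, and enrichment of
hydrophobic plus acidic residues against the regional background.

The per-residue disorder predictor is a deliberate stand-in: a windowed
average of the TOP-IDP disorder-propensity scale, min-max rescaled so that
0.5 separates disorder-promoting from order-promoting composition (the
0.5-to-1 convention for "disordered").  It reproduces the relative-order
contrast the analysis needs; it does not emulate any trained predictor's
numeric output, and ``scale_id`` records provenance in every profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

from .conservation import ConservedWindow
from .records import MultipleAlignment, SequenceRecord, ungap

# TOP-IDP disorder propensities (Campen et al.-style scale): positive values
# promote disorder, negative promote order.
TOP_IDP_SCALE = {
    "A": 0.06, "R": 0.18, "N": 0.007, "D": 0.192, "C": 0.02,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.51, "V": -0.121,
}
SCALE_ID = "top-idp-minmax"

# Residue classes for composition enrichment; exposed because the choice of
# "hydrophobic" set is a convention, not a measurement.
HYDROPHOBIC_SET = frozenset("ACFILMVWY")
ACIDIC_SET = frozenset("DE")


@dataclass(frozen=True)
class DisorderProfile:
    record_id: str
    scores: np.ndarray
    window: int
    scale_id: str = SCALE_ID

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if np.any((s < 0) | (s > 1)):
            raise ValueError("disorder scores must lie in [0, 1]")


@dataclass(frozen=True)
class PhenotypeLabel:
    """Colour-development score (0-8) from a transient activation assay.

    Scores are experimental inputs, never computed; a record is an
    activator when its score exceeds 1 (moderate-to-strong activation).
    """

    record_id: str
    colour_score: int

    def __post_init__(self) -> None:
        if not 0 <= self.colour_score <= 8:
            raise ValueError("colour score must be 0..8")

    @property
    def activator(self) -> bool:
        return self.colour_score > 1


@dataclass
class MorfCandidate:
    window: ConservedWindow
    spans_by_record: dict[str, tuple[int, int]]
    order_dip: float
    dip_pass_fraction: float
    enrichment_fraction: float
    enrichment_p: float
    flags: frozenset[str]

    @property
    def called(self) -> bool:
        return {"conserved", "ordered_dip", "enriched"} <= self.flags


@dataclass(frozen=True)
class DivergenceReport:
    record_id: str
    motif_label: str
    mismatch_positions: tuple[int, ...]

    @property
    def mismatch_count(self) -> int:
        return len(self.mismatch_positions)


@dataclass
class MorfParams:
    """Tunables for MoRF candidate calling."""

    flank: int = 25                 # residues of flank averaged on each side
    dip_margin: float = 0.05        # minimum flank-minus-span score gap
    dip_fraction: float = 0.5       # fraction of activators that must dip
    alpha: float = 0.05             # enrichment significance level
    bonferroni: bool = False        # correct alpha by the number of windows
    min_mean_identity: float = 0.5  # conservation gate on the window itself
    near_cterm_within: int = 30     # aa from the C-terminus for the flag
    max_gap_fraction: float = 0.5   # a gappier row abstains from voting
    hydrophobic: frozenset = HYDROPHOBIC_SET
    acidic: frozenset = ACIDIC_SET


def disorder_profile(
    protein: SequenceRecord, window: int = 21,
    scale: Optional[dict[str, float]] = None,
) -> DisorderProfile:
    """Windowed propensity average rescaled to [0, 1] (0.5 = boundary).

    score(i) is the mean propensity over the window centred at i (edges
    truncate the window), mapped linearly so the scale minimum is 0 and the
    maximum is 1.  Unknown residues (X) take the scale mean.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    table = TOP_IDP_SCALE if scale is None else scale
    if set(table) < set(TOP_IDP_SCALE):
        raise ValueError("scale must cover the 20 amino acids")
    lo, hi = min(table.values()), max(table.values())
    mean_prop = float(np.mean(list(table.values())))
    vals = np.array([table.get(aa, mean_prop) for aa in protein.residues])
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    n = len(vals)
    starts = np.maximum(np.arange(n) - half, 0)
    ends = np.minimum(np.arange(n) + half + 1, n)
    means = (csum[ends] - csum[starts]) / (ends - starts)
    scores = np.clip((means - lo) / (hi - lo), 0.0, 1.0)
    return DisorderProfile(protein.id, scores, window)


def order_dip(
    profile: DisorderProfile,
    span: tuple[int, int],
    flank: int = 25,
    margin: float = 0.05,
) -> tuple[float, bool]:
    """Flank-mean minus span-mean of disorder scores; pass if >= margin.

    Flanks truncate at the termini; at least 5 flank residues on one side
    are required.
    """
    start, end = span
    if end <= start:
        raise ValueError("empty span")
    s = profile.scores
    left = s[max(0, start - flank) : start]
    right = s[end : end + flank]
    if len(left) < 5 and len(right) < 5:
        raise ValueError("fewer than 5 flank residues on both sides")
    flank_scores = np.concatenate([left, right])
    dip = float(flank_scores.mean() - s[start:end].mean())
    return dip, dip >= margin


def composition_enrichment(
    span_residues: str,
    background_residues: str,
    hydrophobic: frozenset = HYDROPHOBIC_SET,
    acidic: frozenset = ACIDIC_SET,
) -> tuple[float, float, bool]:
    """Hydrophobic+acidic fraction of a span and its one-sided binomial p.

    The null success probability is the background fraction of
    hydrophobic-or-acidic residues (span excluded by the caller).  Returns
    (fraction, p, boundary_flag); a degenerate background (fraction 0 or 1)
    reports the boundary p with the flag set.
    """
    if not span_residues:
        raise ValueError("empty span")
    target = hydrophobic | acidic
    k = sum(1 for aa in span_residues if aa in target)
    n = len(span_residues)
    fraction = k / n
    if not background_residues:
        raise ValueError("empty background")
    p0 = sum(1 for aa in background_residues if aa in target) / len(background_residues)
    if p0 in (0.0, 1.0):
        return fraction, float(p0 == 1.0 or k == 0), True
    p = float(binom.sf(k - 1, n, p0))  # P(X >= k)
    return fraction, p, False


def window_spans_by_record(
    window: ConservedWindow, alignment: MultipleAlignment,
    max_gap_fraction: float = 0.5,
) -> dict[str, tuple[int, int]]:
    """Map an alignment-column window to per-record protein coordinates.

    Rows with more than ``max_gap_fraction`` gap inside the window are
    skipped (they abstain from MoRF voting).
    """
    spans = {}
    for rid, seq in alignment.rows:
        inside = seq[window.start_col : window.end_col]
        gapf = inside.count("-") / len(inside)
        if gapf > max_gap_fraction:
            continue
        start = len(seq[: window.start_col].replace("-", ""))
        spans[rid] = (start, start + len(inside.replace("-", "")))
    return spans


def call_morf_candidates(
    windows: Sequence[ConservedWindow],
    profiles: dict[str, DisorderProfile],
    alignment: MultipleAlignment,
    phenotypes: dict[str, PhenotypeLabel],
    params: Optional[MorfParams] = None,
) -> list[MorfCandidate]:
    """Intersect conservation, order-dip and composition evidence.

    A window is called a MoRF candidate when it is conserved, the disorder
    profile dips at its span in at least ``dip_fraction`` of activator
    records, and the pooled activator span composition is enriched in
    hydrophobic+acidic residues at level alpha against the pooled
    non-window sequence of the same records.
    """
    params = params or MorfParams()
    activators = sorted(
        rid for rid, ph in phenotypes.items() if ph.activator and rid in dict(alignment.rows)
    )
    if not activators:
        raise ValueError("no activator records supplied")
    alpha = params.alpha / max(1, len(windows)) if params.bonferroni else params.alpha

    out = []
    for window in windows:
        spans = window_spans_by_record(window, alignment, params.max_gap_fraction)
        dips, passes = [], 0
        voters = 0
        span_pool, bg_pool = [], []
        near_cterm = False
        for rid in activators:
            if rid not in spans or rid not in profiles:
                continue
            span = spans[rid]
            if span[1] <= span[0]:
                continue
            voters += 1
            dip, ok = order_dip(profiles[rid], span, params.flank, params.dip_margin)
            dips.append(dip)
            passes += ok
            residues = ungap(alignment.row(rid))
            span_pool.append(residues[span[0] : span[1]])
            bg_pool.append(residues[: span[0]] + residues[span[1] :])
            if len(residues) - span[1] <= params.near_cterm_within:
                near_cterm = True
        flags = set()
        if window.mean_identity >= params.min_mean_identity:
            flags.add("conserved")
        pass_fraction = passes / voters if voters else 0.0
        if voters and pass_fraction >= params.dip_fraction:
            flags.add("ordered_dip")
        fraction, p = 0.0, 1.0
        if span_pool:
            fraction, p, _ = composition_enrichment(
                "".join(span_pool), "".join(bg_pool),
                params.hydrophobic, params.acidic,
            )
            if p < alpha:
                flags.add("enriched")
        if near_cterm:
            flags.add("near_cterm")
        out.append(
            MorfCandidate(
                window=window,
                spans_by_record=spans,
                order_dip=float(np.mean(dips)) if dips else 0.0,
                dip_pass_fraction=pass_fraction,
                enrichment_fraction=fraction,
                enrichment_p=p,
                flags=frozenset(flags),
            )
        )
    return out


def activator_consensus(
    alignment: MultipleAlignment,
    window: ConservedWindow,
    phenotypes: dict[str, PhenotypeLabel],
) -> str:
    """Column-wise modal residue among activator rows (ties alphabetical)."""
    activators = [rid for rid, ph in phenotypes.items() if ph.activator]
    cols = []
    for c in range(window.start_col, window.end_col):
        residues = [
            alignment.row(rid)[c] for rid in activators if rid in dict(alignment.rows)
        ]
        residues = [r for r in residues if r != "-"] or ["-"]
        counts = {}
        for r in residues:
            counts[r] = counts.get(r, 0) + 1
        best = max(counts.values())
        cols.append(sorted(r for r in counts if counts[r] == best)[0])
    return "".join(cols)


def divergence_to_consensus(
    record_region: str, consensus: str, record_id: str = "", motif_label: str = ""
) -> DivergenceReport:
    """Positional mismatches of an aligned motif region to the consensus.

    Both strings cover the same columns; gaps compare as mismatches.
    Positions are 1-based within the motif.
    """
    if len(record_region) != len(consensus):
        raise ValueError(
            f"region length {len(record_region)} != consensus {len(consensus)}"
        )
    mismatches = tuple(
        i + 1 for i, (a, b) in enumerate(zip(record_region.upper(), consensus.upper()))
        if a != b
    )
    return DivergenceReport(record_id, motif_label, mismatches)


def read_phenotype_tsv(path: str | Path) -> dict[str, PhenotypeLabel]:
    labels = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("record_id"):
            continue
        rid, score = line.split("\t")[:2]
        labels[rid] = PhenotypeLabel(rid, int(score))
    return labels


def write_phenotype_tsv(labels: dict[str, PhenotypeLabel], path: str | Path) -> None:
    lines = ["record_id\tcolour_score"]
    for rid in sorted(labels):
        lines.append(f"{rid}\t{labels[rid].colour_score}")
    Path(path).write_text("\n".join(lines) + "\n")
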