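"""Synthetic MYB-like families with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, without any external download: families of ~10-30 proteins with
two tandem conserved ~50-aa N-terminal repeats, an intrinsically
disordered C-terminus of 100-200 residues whose composition is
disorder-promoting, one to three planted motifs (5-17 aa cores drawn from
hydrophobic + acidic residues, hence relatively order-promoting) that stay
conserved among "activator" records and are heavily diverged in
"non-activators", plus optional loss-of-function variants carrying
premature stops or frameshifts inside the repeat region.  Every planted
feature is recorded in a machine-readable truth manifest, and everything
is deterministic given the seed.

Colour scores are labels emulating a transient activation assay (0-8,
activator <=> score > 1); they are sampled, never computed from sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from Bio.Seq import Seq

from .disorder_morf import PhenotypeLabel, write_phenotype_tsv
from .motif_engineering import CODON_USAGE, _CODON_TABLE
from .records import (
    AMINO_ACIDS,
    MultipleAlignment,
    SequenceRecord,
    write_alignment,
    write_fasta,
)

# Fixed 50-aa repeat consensus (helix-turn-helix-like, tryptophan-anchored).
REPEAT_CONSENSUS = "GAWTAEEDLLLVAFIRLHGEGRWRSLARLAGLKRTGKSCRLRWLNYLRPD"
LEADER = "MGRAPKSE"       # shared N-terminal leader
REPEAT_LINKER = "GSGSPK"  # short linker between tandem repeats

# Disorder-promoting background for the C-terminus and order-promoting
# motif composition: chosen so the windowed-propensity disorder stand-in
# separates the two by construction.
DISORDER_ALPHABET = "PESQKGRD"
MOTIF_HYDROPHOBIC = "ILVFWAM"
MOTIF_ACIDIC = "DE"

DEFAULT_MOTIF_CORES = (
    ("S6A", "LIDEWFVMLADEIVF"),      # 15 aa
    ("S6B", "FVEDLWAMIVDELFAI"),     # 16 aa
    ("S6C", "WILDEFAVMLEDIVFAL"),    # 17 aa
)

SPACER_LEN = 30  # disordered spacer preceding each planted motif


@dataclass(frozen=True)
class MotifSpec:
    """A motif to plant: conserved in activators, diverged otherwise."""

    label: str
    core: str
    sub_activator: float = 0.05
    sub_nonactivator: float = 0.5

    def __post_init__(self) -> None:
        if not 3 <= len(self.core) <= 17:
            raise ValueError("motif core length must be 3..17")
        for p in (self.sub_activator, self.sub_nonactivator):
            if not 0.0 <= p <= 1.0:
                raise ValueError("substitution probabilities must be in [0,1]")


def default_motifs() -> tuple[MotifSpec, ...]:
    return tuple(MotifSpec(label, core) for label, core in DEFAULT_MOTIF_CORES)


@dataclass
class FamilySpec:
    """Conditions for one simulated family (defaults = study conditions)."""

    n_activators: int = 12
    n_nonactivators: int = 4
    repeat_length: int = 50
    n_repeats: int = 2
    cterm_min: int = 100
    cterm_max: int = 200
    planted_motifs: tuple[MotifSpec, ...] = field(default_factory=default_motifs)
    repeat_sub_rate: float = 0.02
    lof_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_activators < 2:
            raise ValueError("need at least 2 activators for conservation")
        if not 0.0 <= self.lof_fraction <= 1.0:
            raise ValueError("lof_fraction must be in [0,1]")


@dataclass
class TruthManifest:
    """Per-record ground truth for recovery evaluation."""

    records: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.records, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(json.loads(text))


@dataclass
class SimulatedFamily:
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    alignment: MultipleAlignment          # generative truth, protein
    phenotypes: dict[str, PhenotypeLabel]
    manifest: TruthManifest
    seed_alignment: MultipleAlignment     # repeat instances for the PSSM


def _repeat_consensus(length: int) -> str:
    reps = (REPEAT_CONSENSUS * (length // len(REPEAT_CONSENSUS) + 1))[:length]
    return reps


def _mutate(seq: str, rate: float, alphabet: str, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in alphabet if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_string(alphabet: str, n: int, rng: np.random.Generator) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))


def _sample_motif(spec: MotifSpec, activator: bool, rng: np.random.Generator) -> str:
    rate = spec.sub_activator if activator else spec.sub_nonactivator
    return _mutate(spec.core, rate, MOTIF_HYDROPHOBIC + MOTIF_ACIDIC, rng)


def reverse_translate(
    protein: str, rng: np.random.Generator, terminal_stop: bool = True
) -> str:
    """Sample a CDS encoding ``protein``, codons weighted by usage."""
    codons = []
    for aa in protein:
        opts = _CODON_TABLE[aa]
        w = np.array([CODON_USAGE.get(c, 0.01) for c in opts])
        codons.append(opts[rng.choice(len(opts), p=w / w.sum())])
    if terminal_stop:
        codons.append("TGA")
    return "".join(codons)


def simulate_family(spec: FamilySpec) -> SimulatedFamily:
    """Generate one family with planted motifs and a truth manifest.

    The protein alignment returned is the generative alignment (truth, not
    inferred): all records share the leader/repeat/spacer layout, motifs
    sit at homologous columns, and only the variable tail is padded with
    gaps.  Loss-of-function variants (when ``lof_fraction`` > 0) are
    excluded from the alignment but present in the FASTA and manifest.
    """
    rng = np.random.default_rng(spec.seed)
    consensus = _repeat_consensus(spec.repeat_length)
    total_fixed = (
        10  # disordered linker entering the C-terminus
        + sum(SPACER_LEN + len(m.core) for m in spec.planted_motifs)
    )
    if total_fixed > spec.cterm_max:
        raise ValueError("planted motifs do not fit the C-terminal length range")
    n = spec.n_activators + spec.n_nonactivators
    tail_max = min(60, spec.cterm_max - total_fixed)
    tail_min = max(0, spec.cterm_min - total_fixed)
    if tail_min > tail_max:
        raise ValueError("impossible C-terminal length range")

    domain_start = len(LEADER)
    repeat_block_len = (
        spec.n_repeats * spec.repeat_length
        + (spec.n_repeats - 1) * len(REPEAT_LINKER)
    )
    domain_end = domain_start + repeat_block_len

    proteins, cds_list, aln_rows = [], [], []
    phenotypes: dict[str, PhenotypeLabel] = {}
    manifest = TruthManifest()
    tails = rng.integers(tail_min, tail_max + 1, size=n)
    tail_width = int(tails.max()) if n else 0

    n_lof = int(round(spec.lof_fraction * n))
    lof_indices = set(rng.choice(n, size=n_lof, replace=False)) if n_lof else set()

    for k in range(n):
        activator = k < spec.n_activators
        rid = f"{'ACT' if activator else 'NON'}{k:02d}"
        repeats = [
            _mutate(consensus, spec.repeat_sub_rate, AMINO_ACIDS, rng)
            for _ in range(spec.n_repeats)
        ]
        nterm = LEADER + REPEAT_LINKER.join(repeats)
        parts = [_random_string(DISORDER_ALPHABET, 10, rng)]
        motif_spans: dict[str, list[int]] = {}
        pos = len(nterm) + 10
        for m in spec.planted_motifs:
            parts.append(_random_string(DISORDER_ALPHABET, SPACER_LEN, rng))
            pos += SPACER_LEN
            inst = _sample_motif(m, activator, rng)
            parts.append(inst)
            motif_spans[m.label] = [pos, pos + len(inst)]
            pos += len(inst)
        tail = _random_string(DISORDER_ALPHABET, int(tails[k]), rng)
        parts.append(tail)
        protein = nterm + "".join(parts)
        aligned = protein + "-" * (tail_width - len(tail))

        score = int(rng.integers(2, 9)) if activator else int(rng.integers(0, 2))
        cds_seq = reverse_translate(protein, rng)
        entry: dict = {
            "colour_score": score,
            "activator": activator,
            "motif_spans": motif_spans,
            "domain_span": [domain_start, domain_end],
            "arch_class": {1: "R3", 2: "R2R3", 3: "3R"}.get(spec.n_repeats, "4R"),
            "defect": None,
        }
        cds_rec = SequenceRecord(rid, cds_seq, "dna")
        if k in lof_indices:
            kind = "premature_stop" if rng.random() < 0.5 else "frameshift"
            codon = int(rng.integers(domain_start + 2, domain_end - 2))
            cds_rec, _pair, defect = inject_loss_of_function(
                cds_rec, kind, codon + 1, int(rng.integers(2**31))
            )
            entry["defect"] = defect
            entry["colour_score"] = 0
            entry["activator"] = False
            score = 0
            protein_rec = cds_rec.translate()
            prot_seq = protein_rec.residues.split("*")[0] or "M"
            proteins.append(SequenceRecord(rid, prot_seq, "protein"))
        else:
            proteins.append(SequenceRecord(rid, protein, "protein"))
            aln_rows.append((rid, aligned))
        phenotypes[rid] = PhenotypeLabel(rid, entry["colour_score"])
        cds_list.append(cds_rec)
        manifest.records[rid] = entry

    seed_rows = [
        (f"seed{j}", _mutate(consensus, spec.repeat_sub_rate, AMINO_ACIDS, rng))
        for j in range(8)
    ]
    return SimulatedFamily(
        proteins,
        cds_list,
        MultipleAlignment(aln_rows, "protein"),
        phenotypes,
        manifest,
        MultipleAlignment(seed_rows, "protein"),
    )


LofKind = Literal["premature_stop", "frameshift"]


def inject_loss_of_function(
    record: SequenceRecord, kind: LofKind, position: int, seed: int = 0
) -> tuple[SequenceRecord, tuple[str, str], dict]:
    """Mutate a CDS with a premature stop or frameshift at a 1-based codon.

    Returns the mutated record, the pairwise reference/mutant nucleotide
    alignment (gaps mark the indel), and a manifest entry.  A premature
    stop substitutes a TAA codon; a frameshift deletes one base or inserts
    one or two bases at the codon start.
    """
    if record.alphabet != "dna":
        raise ValueError("inject_loss_of_function needs a CDS record")
    n_codons = len(record.residues) // 3
    if not 1 <= position <= n_codons:
        raise ValueError(f"codon position {position} outside 1..{n_codons}")
    rng = np.random.default_rng(seed)
    seq = record.residues
    off = 3 * (position - 1)
    if kind == "premature_stop":
        mutated = seq[:off] + "TAA" + seq[off + 3 :]
        pair = (seq, mutated)
    elif kind == "frameshift":
        if rng.random() < 0.5:
            mutated = seq[:off] + seq[off + 1 :]  # -1 deletion
            pair = (seq, seq[:off] + "-" + seq[off + 1 :])
        else:
            ins = _random_string("ACGT", int(rng.integers(1, 3)), rng)
            mutated = seq[:off] + ins + seq[off:]
            pair = (seq[:off] + "-" * len(ins) + seq[off:], mutated)
    else:
        raise ValueError(f"unknown defect kind {kind!r}")
    entry = {"kind": kind, "position": position}
    return SequenceRecord(record.id, mutated, "dna", record.description), pair, entry


def simulate_architecture_panel(
    n: int, seed: int, lof_fraction: float = 0.3
) -> tuple[list[SequenceRecord], list[SequenceRecord], dict[str, dict],
           MultipleAlignment, dict[str, tuple[str, str]]]:
    """Records cycling through {none, R3, R2R3, 3R} with seeded defects.

    Returns (proteins, cds, truth-by-id, seed alignment for the PSSM,
    pairwise reference alignments for frameshifted records).  Proteins are
    the translations of the (possibly mutated) CDS, as an annotation run
    would see them.
    """
    rng = np.random.default_rng(seed)
    consensus = _repeat_consensus(50)
    classes = ["none", "R3", "R2R3", "3R"]
    proteins, cds_list = [], []
    truth: dict[str, dict] = {}
    pairs: dict[str, tuple[str, str]] = {}
    for k in range(n):
        arch = classes[k % 4]
        n_rep = classes.index(arch)
        rid = f"REC{k:03d}"
        repeats = [_mutate(consensus, 0.02, AMINO_ACIDS, rng) for _ in range(n_rep)]
        nterm = LEADER + REPEAT_LINKER.join(repeats)
        protein = nterm + _random_string(DISORDER_ALPHABET, 120, rng)
        cds_rec = SequenceRecord(rid, reverse_translate(protein, rng), "dna")
        entry: dict = {"arch_class": arch, "defect": None, "functional": True}
        if n_rep and rng.random() < lof_fraction:
            kind: LofKind = (
                "premature_stop" if rng.random() < 0.5 else "frameshift"
            )
            domain_end = len(LEADER) + n_rep * 50 + (n_rep - 1) * len(REPEAT_LINKER)
            codon = int(rng.integers(len(LEADER) + 2, domain_end - 2)) + 1
            cds_rec, pair, defect = inject_loss_of_function(
                cds_rec, kind, codon, int(rng.integers(2**31))
            )
            entry.update(defect=defect, functional=False)
            if kind == "frameshift":
                pairs[rid] = pair
        # read-through conceptual translation, as an annotation scan sees it
        proteins.append(cds_rec.translate())
        cds_list.append(cds_rec)
        truth[rid] = entry
    seed_rows = [
        (f"seed{j}", _mutate(consensus, 0.02, AMINO_ACIDS, rng)) for j in range(8)
    ]
    return proteins, cds_list, truth, MultipleAlignment(seed_rows, "protein"), pairs


def write_family(family: SimulatedFamily, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA/TSV/JSON artefacts; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": out / "proteins.faa",
        "cds": out / "cds.fna",
        "alignment": out / "alignment.faa",
        "seed_alignment": out / "seed_alignment.faa",
        "phenotypes": out / "phenotypes.tsv",
        "manifest": out / "truth_manifest.json",
    }
    write_fasta(family.proteins, paths["proteins"])
    write_fasta(family.cds, paths["cds"])
    write_alignment(family.alignment, paths["alignment"])
    write_alignment(family.seed_alignment, paths["seed_alignment"])
    write_phenotype_tsv(family.phenotypes, paths["phenotypes"])
    paths["manifest"].write_text(family.manifest.to_json())
    return paths
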