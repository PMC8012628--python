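"""Sequence records and multiple alignments.

Thin, validated containers shared by every analysis stage.  FASTA input and
output goes through Biopython; the containers themselves stay plain so they
are cheap to construct inside simulators and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = set("ACGTN")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

Alphabet = Literal["protein", "dna"]


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein or CDS sequence with identifier.

    Residues are stored upper-case and validated against the declared
    alphabet ('protein' allows the 20 standard amino acids plus X and *,
    'dna' allows A/C/G/T/N).
    """

    id: str
    residues: str
    alphabet: Alphabet = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        upper = self.residues.upper()
        object.__setattr__(self, "residues", upper)
        if self.alphabet == "protein":
            allowed = PROTEIN_ALPHABET | {"X", "*"}
        elif self.alphabet == "dna":
            allowed = DNA_ALPHABET
        else:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        bad = set(upper) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} outside "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def translate(self) -> "SequenceRecord":
        """Translate a CDS record (frame 0, standard nuclear code)."""
        if self.alphabet != "dna":
            raise ValueError("translate requires a dna record")
        prot = str(Seq(self.residues[: len(self.residues) // 3 * 3]).translate())
        return SequenceRecord(self.id, prot, "protein", self.description)


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over a shared alphabet.

    ``alphabet`` is 'protein', 'dna' or 'codon'; codon alignments must have
    a column count divisible by 3 and gaps only as whole ``---`` triplets.
    """

    rows: list[tuple[str, str]]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        ids = [rid for rid, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate row ids in alignment")
        self.rows = [(rid, seq.upper()) for rid, seq in self.rows]
        if self.alphabet == "codon":
            n = self.n_columns
            if n % 3:
                raise ValueError("codon alignment length not divisible by 3")
            for rid, seq in self.rows:
                for i in range(0, n, 3):
                    cod = seq[i : i + 3]
                    if "-" in cod and cod != "---":
                        raise ValueError(
                            f"row {rid!r}: partial gap triplet {cod!r} at column {i}"
                        )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, record_id: str) -> str:
        for rid, seq in self.rows:
            if rid == record_id:
                return seq
        raise KeyError(record_id)

    def column(self, i: int) -> list[str]:
        return [seq[i] for _, seq in self.rows]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def ungap(seq: str) -> str:
    return seq.replace("-", "")


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[SequenceRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, str(rec.seq), alphabet, rec.description)
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_alignment(path: str | Path, alphabet: str = "protein") -> MultipleAlignment:
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append((rec.id, str(rec.seq)))
    return MultipleAlignment(rows, alphabet)


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.rows]
    SeqIO.write(seqs, str(path), "fasta")
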