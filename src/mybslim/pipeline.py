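"""End-to-end orchestration: annotate -> conserve -> MoRF -> SLiM screen.

Mirrors the analysis order of the study: repeat architecture and
functional calling first, then conservation-window discovery among
activators, then disorder/MoRF evidence, then screening candidate cores
against the bundled ELM-style motif set.  Every run is deterministic given
the config; the summary carries the config hash and seed so reruns are
auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import conservation, disorder_morf, family_annotation, slim_patterns
from .conservation import ConservedWindow
from .disorder_morf import MorfCandidate, MorfParams, PhenotypeLabel
from .records import (
    MultipleAlignment,
    SequenceRecord,
    read_alignment,
    read_fasta,
    ungap,
)
from .synthetic_data import TruthManifest


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat, YAML-round-trippable configuration for one pipeline run."""

    proteins: str = ""
    cds: str = ""
    alignment: str = ""
    seed_alignment: str = ""
    phenotypes: str = ""
    outdir: str = "out"
    seed: int = 0
    # annotation
    threshold_bits: float = family_annotation.DEFAULT_THRESHOLD_BITS
    tandem_gap_max: int = family_annotation.DEFAULT_TANDEM_GAP_MAX
    profile_pseudocount: float = 0.5
    # conservation windows
    region: str = "auto"  # or "START:END" in alignment columns
    min_len: int = 15
    max_len: int = 17
    margin: float = 0.10
    window_ignore_gaps: bool = False
    # disorder / MoRF
    disorder_window: int = 21
    flank: int = 25
    dip_margin: float = 0.05
    dip_fraction: float = 0.5
    alpha: float = 0.05
    bonferroni: bool = False

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class PipelineResult:
    calls: list[family_annotation.ArchitectureCall]
    windows: list[ConservedWindow]
    candidates: list[MorfCandidate]
    screen: list[tuple[str, str, str, str]]
    consensus_by_window: dict[str, str]
    divergence: list[disorder_morf.DivergenceReport]
    tree_newick: str
    summary: dict


def _auto_region(
    alignment: MultipleAlignment,
    calls: Sequence[family_annotation.ArchitectureCall],
) -> tuple[int, int]:
    """C-terminal region: columns after the last repeat hit of any row."""
    row_by_id = dict(alignment.rows)
    start = 0
    for call in calls:
        if call.record_id not in row_by_id or not call.hits:
            continue
        seq = row_by_id[call.record_id]
        residues = 0
        for col, ch in enumerate(seq):
            if ch != "-":
                residues += 1
            if residues == call.hits[-1].end:
                start = max(start, col + 1)
                break
    return start, alignment.n_columns


def run_pipeline_objects(
    proteins: list[SequenceRecord],
    cds: list[SequenceRecord],
    alignment: MultipleAlignment,
    seed_alignment: MultipleAlignment,
    phenotypes: dict[str, PhenotypeLabel],
    config: Optional[PipelineConfig] = None,
    reference_alignments: Optional[dict[str, tuple[str, str]]] = None,
) -> PipelineResult:
    """Run all stages on in-memory objects (the core of ``run_pipeline``)."""
    cfg = config or PipelineConfig()

    # --- stage: annotate ---------------------------------------------------
    try:
        profile = family_annotation.build_profile(
            seed_alignment, cfg.profile_pseudocount
        )
        cds_by_id = {r.id: r for r in cds}
        calls = family_annotation.annotate_family(
            proteins, profile, cds_by_id, cfg.threshold_bits, cfg.tandem_gap_max,
            reference_alignments,
        )
    except Exception as exc:  # pragma: no cover - error path
        raise StageError("annotate", str(exc)) from exc
    functional = {c.record_id for c in calls if c.functional}

    # --- stage: conserve ---------------------------------------------------
    try:
        activator_ids = [
            rid for rid, ph in sorted(phenotypes.items())
            if ph.activator and rid in functional and rid in dict(alignment.rows)
        ]
        if len(activator_ids) < 2:
            raise ValueError("need >= 2 functional activator rows")
        act_aln = MultipleAlignment(
            [(rid, dict(alignment.rows)[rid]) for rid in activator_ids], "protein"
        )
        stats = conservation.column_conservation(
            act_aln, ignore_gaps=cfg.window_ignore_gaps
        )
        if cfg.region == "auto":
            region = _auto_region(act_aln, calls)
        else:
            a, b = cfg.region.split(":")
            region = (int(a), int(b))
        windows = conservation.find_conserved_windows(
            stats, region, cfg.min_len, cfg.max_len, cfg.margin
        )
        dm = conservation.p_distance_matrix(alignment)
        tree = conservation.neighbor_joining(dm)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("conserve", str(exc)) from exc

    # --- stage: morf -------------------------------------------------------
    try:
        if not phenotypes:
            raise ValueError("phenotype table required for MoRF calling")
        profiles = {
            p.id: disorder_morf.disorder_profile(p, cfg.disorder_window)
            for p in proteins if p.id in dict(alignment.rows)
        }
        params = MorfParams(
            flank=cfg.flank,
            dip_margin=cfg.dip_margin,
            dip_fraction=cfg.dip_fraction,
            alpha=cfg.alpha,
            bonferroni=cfg.bonferroni,
        )
        candidates = disorder_morf.call_morf_candidates(
            windows, profiles, alignment, phenotypes, params
        )
        consensus_by_window = {
            w.label: disorder_morf.activator_consensus(alignment, w, phenotypes)
            for w in windows
        }
        divergence = []
        for w in windows:
            cons = consensus_by_window[w.label]
            for rid, seq in alignment.rows:
                if phenotypes.get(rid) and not phenotypes[rid].activator:
                    region_seq = seq[w.start_col : w.end_col]
                    divergence.append(
                        disorder_morf.divergence_to_consensus(
                            region_seq, cons, rid, w.label
                        )
                    )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("morf", str(exc)) from exc

    # --- stage: screen -----------------------------------------------------
    try:
        peptides: dict[tuple[str, str], str] = {}
        for cand in candidates:
            if not cand.called:
                continue
            for rid, (s, e) in sorted(cand.spans_by_record.items()):
                residues = ungap(dict(alignment.rows)[rid])[s:e]
                if residues:
                    peptides[(rid, cand.window.label)] = residues
        screen = slim_patterns.screen_candidates(peptides)
    except Exception as exc:
        raise StageError("screen", str(exc)) from exc

    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_records": len(proteins),
        "arch_classes": {
            c.record_id: c.arch_class for c in sorted(calls, key=lambda c: c.record_id)
        },
        "functional": sorted(functional),
        "windows": [
            {
                "label": w.label,
                "start_col": w.start_col,
                "end_col": w.end_col,
                "mean_identity": round(w.mean_identity, 6),
            }
            for w in windows
        ],
        "morf_calls": [
            {
                "label": c.window.label,
                "called": c.called,
                "order_dip": round(c.order_dip, 6),
                "enrichment_p": float(c.enrichment_p),
                "flags": sorted(c.flags),
            }
            for c in candidates
        ],
        "screen": [list(r) for r in screen],
    }
    return PipelineResult(
        calls, windows, candidates, screen, consensus_by_window, divergence,
        tree, summary,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load inputs from the configured paths, run all stages, write outputs."""
    for name in ("proteins", "cds", "alignment", "seed_alignment", "phenotypes"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            stage = "morf" if name == "phenotypes" else "annotate"
            raise StageError(stage, f"required input {name!r} missing: {path!r}")
    proteins = read_fasta(config.proteins, "protein")
    cds = read_fasta(config.cds, "dna")
    alignment = read_alignment(config.alignment, "protein")
    seed_aln = read_alignment(config.seed_alignment, "protein")
    phenotypes = disorder_morf.read_phenotype_tsv(config.phenotypes)

    result = run_pipeline_objects(
        proteins, cds, alignment, seed_aln, phenotypes, config
    )
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    family_annotation.write_annotation_tsv(result.calls, out / "annotation.tsv")
    (out / "tree.nwk").write_text(result.tree_newick + "\n")
    slim_patterns.write_screen_tsv(result.screen, out / "screen.tsv")
    (out / "summary.json").write_text(json.dumps(result.summary, indent=1))
    return result


@dataclass
class RecoveryReport:
    per_motif: dict[str, dict]
    sensitivity: float
    precision: float
    n_false_windows: int
    confusion: dict[str, dict[str, int]] = field(default_factory=dict)


def evaluate_recovery(
    candidates: Sequence[MorfCandidate],
    manifest: TruthManifest,
    overlap_min: float = 0.5,
) -> RecoveryReport:
    """Score called MoRF windows against the planted truth.

    A planted motif counts as detected when some *called* candidate's span
    overlaps at least ``overlap_min`` of the planted span in at least one
    record; a called candidate overlapping no planted span in any record
    is a false window.
    """
    called = [c for c in candidates if c.called]
    motif_labels: list[str] = []
    for entry in manifest.records.values():
        for label in entry.get("motif_spans", {}):
            if label not in motif_labels:
                motif_labels.append(label)

    per_motif: dict[str, dict] = {}
    used: set[int] = set()
    for label in motif_labels:
        best = 0.0
        best_idx = None
        for idx, cand in enumerate(called):
            for rid, (s, e) in cand.spans_by_record.items():
                entry = manifest.records.get(rid)
                if not entry or label not in entry.get("motif_spans", {}):
                    continue
                ts, te = entry["motif_spans"][label]
                ov = max(0, min(e, te) - max(s, ts)) / max(1, te - ts)
                if ov > best:
                    best, best_idx = ov, idx
        detected = best >= overlap_min
        if detected and best_idx is not None:
            used.add(best_idx)
        per_motif[label] = {"detected": detected, "overlap_fraction": round(best, 4)}

    # any called window overlapping any planted span at all is not "false"
    for idx, cand in enumerate(called):
        if idx in used:
            continue
        for rid, (s, e) in cand.spans_by_record.items():
            entry = manifest.records.get(rid)
            if not entry:
                continue
            for ts, te in entry.get("motif_spans", {}).values():
                if min(e, te) - max(s, ts) > 0:
                    used.add(idx)
                    break
            if idx in used:
                break

    n_false = len(called) - len(used & set(range(len(called))))
    detected_n = sum(1 for v in per_motif.values() if v["detected"])
    sensitivity = detected_n / len(motif_labels) if motif_labels else 1.0
    precision = (len(called) - n_false) / len(called) if called else 1.0
    return RecoveryReport(per_motif, sensitivity, precision, n_false)


def evaluate_annotation(
    calls: Sequence[family_annotation.ArchitectureCall],
    truth: dict[str, dict],
) -> dict[str, dict[str, int]]:
    """Confusion tables over architecture classes and functional status."""
    arch: dict[str, dict[str, int]] = {}
    func: dict[str, dict[str, int]] = {}
    for call in calls:
        t = truth.get(call.record_id)
        if t is None:
            raise KeyError(f"record {call.record_id!r} absent from truth")
        arch.setdefault(t["arch_class"], {}).setdefault(call.arch_class, 0)
        arch[t["arch_class"]][call.arch_class] += 1
        tkey = "functional" if t.get("functional", True) else "non_functional"
        pkey = "functional" if call.functional else "non_functional"
        func.setdefault(tkey, {}).setdefault(pkey, 0)
        func[tkey][pkey] += 1
    return {"arch": arch, "functional": func}
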