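"""Four-stage pipeline orchestration: quant -> precursor -> targets -> cleavage.

Each stage is runnable standalone given its inputs; ``run_all`` chains them
and writes a manifest with a checksum per output, so a rerun on identical
inputs is byte-identical.  Logging at INFO records every filtering decision
count (reads dropped, candidates excluded and why), keeping the analysis
funnel auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cleavage as cleavage_mod
from . import io as io_mod
from . import simulate as simulate_mod
from .hairpin import HairpinRules, find_precursors, to_dot_bracket
from .quantify import ReadLibrary, quantify_experiment
from .targets import Region, scan_transcriptome

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; every knob has the study default."""

    out_dir: str = "mirslice_out"
    control_library: str | None = None
    treated_library: str | None = None
    catalog: str | None = None
    contigs: str | None = None
    clones: str | None = None
    # quant thresholds: induced > upper fold, repressed < lower fold (strict)
    lower_fold: float = 0.8
    upper_fold: float = 1.2
    min_rpm: float = 1.0
    # precursor rules
    pairing_fraction: float = 0.60
    max_unpaired: int = 5
    min_loop: int = 3
    flank_nt: int = 150
    # target scoring
    max_penalty: float = 3.0
    max_gaps: int = 1
    both_strands: bool = False
    # reporting
    report_precision: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise io_mod.ConfigurationError(
                f"unknown config keys: {sorted(unknown)}"
            )
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def hairpin_rules(self) -> HairpinRules:
        return HairpinRules(
            pairing_fraction=self.pairing_fraction,
            max_unpaired=self.max_unpaired,
            min_loop=self.min_loop,
            flank_nt=self.flank_nt,
        )


def _require(stage: str, **paths: str | None) -> None:
    for name, value in paths.items():
        if value is None or not Path(value).exists():
            raise StageError(stage, f"missing input {name} ({value})")


def _read_library(path: str, name: str) -> ReadLibrary:
    if path.endswith((".fastq", ".fq")):
        reads = io_mod.read_fastq_collapsed(path)
    else:
        reads = io_mod.read_collapsed_fasta(path)
    return ReadLibrary(name=name, reads=reads)


def run_quant(config: PipelineConfig) -> Path:
    """Stage 1: quantify the catalog across the two libraries; write quant.tsv."""
    _require(
        "quant",
        control_library=config.control_library,
        treated_library=config.treated_library,
        catalog=config.catalog,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    control = _read_library(config.control_library, "control")
    treated = _read_library(config.treated_library, "treated")
    catalog = io_mod.read_mirna_catalog(config.catalog)
    records = quantify_experiment(
        control, treated, catalog,
        lower=config.lower_fold, upper=config.upper_fold, min_rpm=config.min_rpm,
    )
    by_class: dict[str, int] = {}
    for r in records:
        by_class[r.regulation_class.value] = by_class.get(r.regulation_class.value, 0) + 1
    logger.info(
        "quant: depths %d/%d, %d catalog entries detected (%s)",
        control.total_reads, treated.total_reads, len(records),
        ", ".join(f"{k}={v}" for k, v in sorted(by_class.items())) or "none",
    )
    if not records:
        logger.warning("quant: no catalog miRNA detected in either library")
    path = out_dir / "quant.tsv"
    io_mod.write_tsv_report(
        [
            {
                "mirna_id": r.mirna_id,
                "sequence": r.sequence,
                "rpm_control": r.rpm_control,
                "rpm_treated": r.rpm_treated,
                "ratio": float("nan") if r.ratio is None else r.ratio,
                "class": r.regulation_class.value,
            }
            for r in records
        ],
        path,
        float_precision=config.report_precision,
        columns=["mirna_id", "sequence", "rpm_control", "rpm_treated", "ratio", "class"],
    )
    return path


def run_precursor(config: PipelineConfig) -> Path:
    """Stage 2: hairpin search for every catalog miRNA; write precursors.tsv."""
    _require("precursor", contigs=config.contigs, catalog=config.catalog)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = io_mod.read_fasta(config.contigs)
    catalog = io_mod.read_mirna_catalog(config.catalog)
    rules = config.hairpin_rules()
    rows = []
    folds: list[str] = []
    n_accepted = 0
    for mature in catalog:
        for cand in find_precursors(mature, contigs, rules):
            if cand.verdict == "accepted":
                n_accepted += 1
            rows.append(
                {
                    "mirna_id": mature.id,
                    "contig_id": cand.contig_id,
                    "window_start": cand.window[0],
                    "window_end": cand.window[1],
                    "strand": cand.strand,
                    "arm": cand.arm or "",
                    "verdict": cand.verdict,
                    "reason": cand.rejection_reason,
                    "mature_paired_fraction": cand.mature_paired_fraction,
                    "predicted_star": cand.predicted_star or "",
                }
            )
            if cand.fold is not None:
                folds.append(
                    f">{mature.id}|{cand.contig_id}|{cand.window[0]}-{cand.window[1]}|{cand.strand}\n"
                    f"{cand.fold.sequence}\n{to_dot_bracket(cand.fold)}\n"
                )
    logger.info(
        "precursor: %d candidate loci, %d accepted", len(rows), n_accepted
    )
    path = out_dir / "precursors.tsv"
    io_mod.write_tsv_report(
        rows, path, float_precision=config.report_precision,
        columns=[
            "mirna_id", "contig_id", "window_start", "window_end", "strand",
            "arm", "verdict", "reason", "mature_paired_fraction", "predicted_star",
        ],
    )
    (out_dir / "folds.txt").write_text("".join(folds))
    return path


def _target_hits(config: PipelineConfig):
    contigs = io_mod.read_fasta(config.contigs)
    catalog = io_mod.read_mirna_catalog(config.catalog)
    for mature in catalog:
        for hit in scan_transcriptome(
            mature, contigs,
            max_penalty=config.max_penalty, max_gaps=config.max_gaps,
            both_strands=config.both_strands,
        ):
            yield mature, hit


def run_targets(config: PipelineConfig) -> Path:
    """Stage 3: penalty-score target scan; write targets.tsv with region columns."""
    _require("targets", contigs=config.contigs, catalog=config.catalog)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for mature, hit in _target_hits(config):
        rows.append(
            {
                "mirna_id": mature.id,
                "contig_id": hit.contig_id,
                "start": hit.start,
                "end": hit.end,
                "strand": hit.strand,
                "penalty": hit.score.penalty,
                "five_prime_gu_mm": hit.score.region_string(Region.FIVE_PRIME),
                "central_gu_mm": hit.score.region_string(Region.CENTRAL),
                "three_prime_gu_mm": hit.score.region_string(Region.THREE_PRIME),
                "gaps": hit.score.gap_count,
                "verdict": hit.score.verdict,
            }
        )
    logger.info("targets: %d candidate sites", len(rows))
    path = out_dir / "targets.tsv"
    io_mod.write_tsv_report(
        rows, path, float_precision=config.report_precision,
        columns=[
            "mirna_id", "contig_id", "start", "end", "strand", "penalty",
            "five_prime_gu_mm", "central_gu_mm", "three_prime_gu_mm",
            "gaps", "verdict",
        ],
    )
    return path


def run_cleavage(config: PipelineConfig) -> Path:
    """Stage 4: tally RACE clones on validated sites; write cleavage.tsv."""
    _require(
        "cleavage",
        clones=config.clones, contigs=config.contigs, catalog=config.catalog,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clones = cleavage_mod.read_clone_tsv(config.clones)
    by_target: dict[str, list] = {}
    for clone in clones:
        by_target.setdefault(clone.target_id, []).append(clone)
    hits = {}
    for _, hit in _target_hits(config):
        hits.setdefault(hit.contig_id, hit)
    rows = []
    for target_id, target_clones in sorted(by_target.items()):
        hit = hits.get(target_id)
        if hit is None:
            logger.warning(
                "cleavage: %d clones reference unknown target %r; skipped",
                sum(c.count for c in target_clones), target_id,
            )
            continue
        profile = cleavage_mod.tally_cleavage(target_clones, hit)
        for pos in sorted(profile.tallies):
            rows.append(
                {
                    "target_id": target_id,
                    "mirna_position": pos,
                    "clones": profile.tallies[pos],
                    "modal_position": profile.modal_position,
                    "total_clones": profile.total_clones,
                    "unmapped_clones": profile.unmapped_clones,
                }
            )
        logger.info(
            "cleavage: %s modal position %s (%d clones mapped, %d unmapped)",
            target_id, profile.modal_position,
            profile.total_clones, profile.unmapped_clones,
        )
    path = out_dir / "cleavage.tsv"
    io_mod.write_tsv_report(
        rows, path, float_precision=config.report_precision,
        columns=[
            "target_id", "mirna_position", "clones",
            "modal_position", "total_clones", "unmapped_clones",
        ],
    )
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> Path:
    """Stages 1-4 in order plus a checksum manifest; aborts naming the stage."""
    stages = [
        ("quant", run_quant),
        ("precursor", run_precursor),
        ("targets", run_targets),
        ("cleavage", run_cleavage),
    ]
    outputs: list[Path] = []
    for name, stage in stages:
        try:
            outputs.append(stage(config))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc
    out_dir = Path(config.out_dir)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("file\tsha256\n")
        for path in outputs:
            fh.write(f"{path.name}\t{_sha256(path)}\n")
    return out_dir


def write_simulated_inputs(
    spec: simulate_mod.SimulationSpec, out_dir: str | Path
) -> PipelineConfig:
    """Generate a full synthetic experiment on disk and a config pointing at it."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exp = simulate_mod.simulate_experiment(spec)
    io_mod.write_fasta(
        [io_mod.Sequence(id=m.id, residues=m.sequence) for m in exp.catalog],
        out_dir / "catalog.fasta",
    )
    io_mod.write_fasta(exp.contigs, out_dir / "contigs.fasta")
    io_mod.write_collapsed_fasta(exp.control.reads, out_dir / "control.fasta")
    io_mod.write_collapsed_fasta(exp.treated.reads, out_dir / "treated.fasta")
    all_clones = [c for clones in exp.clones.values() for c in clones]
    cleavage_mod.write_clone_tsv(all_clones, out_dir / "clones.tsv")
    config = PipelineConfig(
        out_dir=str(out_dir / "results"),
        control_library=str(out_dir / "control.fasta"),
        treated_library=str(out_dir / "treated.fasta"),
        catalog=str(out_dir / "catalog.fasta"),
        contigs=str(out_dir / "contigs.fasta"),
        clones=str(out_dir / "clones.tsv"),
        seed=spec.seed,
    )
    config.to_yaml(out_dir / "config.yaml")
    return config
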