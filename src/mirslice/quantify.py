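"""Library normalization, perfect-match catalog assignment, and wound-response classes.

A read is assigned to a catalog miRNA only when its sequence equals the mature
sequence exactly, full length — length variants and single-nucleotide variants
are distinct reads and are ignored here.  Abundance is expressed in reads per
million (RPM = count / library total * 1e6), and the treated/control RPM ratio
is classified with strict fold-change thresholds: induced above 1.2, repressed
below 0.8, unchanged in between (boundary values inclusive).  A ratio is
undefined when the control RPM is zero, and a class is not called when both
conditions sit below a minimum-abundance floor (default 1 RPM).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .io import ConfigurationError, CountedRead, MatureMiRNA


class RegulationClass(str, enum.Enum):
    INDUCED = "induced"
    REPRESSED = "repressed"
    UNCHANGED = "unchanged"
    UNDETERMINED = "undetermined"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class ReadLibrary:
    """A collapsed small-RNA library for one condition."""

    name: str
    reads: list[CountedRead]
    total_reads: int | None = None

    def __post_init__(self) -> None:
        observed = sum(r.count for r in self.reads)
        if self.total_reads is None:
            self.total_reads = observed
        elif self.total_reads != observed:
            raise ValueError(
                f"library {self.name}: total_reads={self.total_reads} but reads sum to {observed}"
            )
        if self.total_reads <= 0:
            raise ValueError(f"library {self.name} is empty")


@dataclass
class MiRNAQuantRecord:
    mirna_id: str
    sequence: str
    rpm_control: float
    rpm_treated: float
    ratio: float | None
    regulation_class: RegulationClass


def compute_rpm(count: int, total_reads: int) -> float:
    """Reads per million: count / total_reads * 1e6."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total_reads * 1e6


def assign_to_catalog(
    library: ReadLibrary, catalog: list[MatureMiRNA]
) -> dict[str, int]:
    """Sum read counts onto catalog entries by exact full-length sequence match.

    Only detected entries appear in the result.  Two catalog entries sharing a
    sequence under different ids would make assignment ambiguous and raise
    :class:`ConfigurationError`.
    """
    seq_to_id: dict[str, str] = {}
    for entry in catalog:
        if entry.sequence in seq_to_id and seq_to_id[entry.sequence] != entry.id:
            raise ConfigurationError(
                f"catalog entries {seq_to_id[entry.sequence]!r} and {entry.id!r} "
                "share the same mature sequence"
            )
        seq_to_id[entry.sequence] = entry.id
    counts: dict[str, int] = {}
    for read in library.reads:
        mirna_id = seq_to_id.get(read.residues)
        if mirna_id is not None:
            counts[mirna_id] = counts.get(mirna_id, 0) + read.count
    return counts


def compute_ratio(rpm_control: float, rpm_treated: float) -> float | None:
    """Treated/control RPM ratio; ``None`` (undefined) when the control is zero."""
    if rpm_control == 0:
        return None
    return rpm_treated / rpm_control


def classify_regulation(
    ratio: float | None,
    rpm_control: float = float("inf"),
    rpm_treated: float = float("inf"),
    lower: float = 0.8,
    upper: float = 1.2,
    min_rpm: float = 1.0,
) -> RegulationClass:
    """Classify a fold-change ratio against strict induction/repression thresholds.

    ``undetermined`` when the ratio is undefined or both condition RPMs fall
    below ``min_rpm``; otherwise exactly one of induced / repressed / unchanged.
    """
    if upper <= lower:
        raise ConfigurationError(
            f"upper threshold ({upper}) must exceed lower threshold ({lower})"
        )
    if ratio is None or (rpm_control < min_rpm and rpm_treated < min_rpm):
        return RegulationClass.UNDETERMINED
    if ratio > upper:
        return RegulationClass.INDUCED
    if ratio < lower:
        return RegulationClass.REPRESSED
    return RegulationClass.UNCHANGED


def quantify_experiment(
    control: ReadLibrary,
    treated: ReadLibrary,
    catalog: list[MatureMiRNA],
    lower: float = 0.8,
    upper: float = 1.2,
    min_rpm: float = 1.0,
) -> list[MiRNAQuantRecord]:
    """Quantify every catalog miRNA detected in either library.

    Records are sorted by ascending ratio (most repressed first); undefined
    ratios sort last.  Ratios are kept at full precision — two-decimal
    rendering happens only in report writers.
    """
    counts_control = assign_to_catalog(control, catalog)
    counts_treated = assign_to_catalog(treated, catalog)
    records: list[MiRNAQuantRecord] = []
    for entry in catalog:
        c = counts_control.get(entry.id, 0)
        t = counts_treated.get(entry.id, 0)
        if c == 0 and t == 0:
            continue
        rpm_c = compute_rpm(c, control.total_reads)
        rpm_t = compute_rpm(t, treated.total_reads)
        ratio = compute_ratio(rpm_c, rpm_t)
        cls = classify_regulation(ratio, rpm_c, rpm_t, lower, upper, min_rpm)
        records.append(
            MiRNAQuantRecord(
                mirna_id=entry.id,
                sequence=entry.sequence,
                rpm_control=rpm_c,
                rpm_treated=rpm_t,
                ratio=ratio,
                regulation_class=cls,
            )
        )
    records.sort(key=lambda r: (r.ratio is None, r.ratio if r.ratio is not None else 0.0))
    return records
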