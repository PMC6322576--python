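"""Sequence model and readers/writers shared by every analysis stage.

All comparisons in this package happen in RNA space: DNA input is upper-cased
and ``T`` is mapped to ``U`` on the way in.  Transcriptome contigs may retain
``N`` (which never pairs and never matches); small-RNA reads must be
unambiguous A/C/G/U and are otherwise dropped with a log message, as are reads
outside the configured small-RNA length window (default 18-26 nt, a 2-nt
margin around the canonical 20-24 nt mature-miRNA range).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence as SequenceLike

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_BASES = frozenset("ACGU")
_CONTIG_BASES = frozenset("ACGUN")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

#: default small-RNA read length bounds (nt), inclusive
DEFAULT_MIN_READ_LEN = 18
DEFAULT_MAX_READ_LEN = 26

_COLLAPSED_HEADER = re.compile(r"_x(\d+)$")


class ParseError(ValueError):
    """Malformed FASTA/FASTQ input."""


class ConfigurationError(ValueError):
    """Caller-supplied parameters are inconsistent."""


def normalize_rna(residues: str) -> str:
    """Upper-case, map T->U, and collapse non-N ambiguity codes to N."""
    s = residues.upper().replace("T", "U")
    if not set(s) <= _CONTIG_BASES:
        s = "".join(c if c in _CONTIG_BASES else "N" for c in s)
    return s


def reverse_complement(residues: str) -> str:
    """Reverse complement in RNA space (N maps to N)."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Sequence:
    """A named RNA sequence (contig, mature miRNA, probe...).

    ``residues`` are normalized RNA: only A/C/G/U/N after construction.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Sequence id must be non-empty")
        object.__setattr__(self, "residues", normalize_rna(self.residues))

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CountedRead:
    """A unique small-RNA sequence with the number of raw reads collapsing to it."""

    residues: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("read count must be >= 0")
        if not set(self.residues) <= RNA_BASES:
            raise ValueError(f"read contains non-ACGU residues: {self.residues!r}")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA (guide strand) with an optional star (passenger) strand."""

    id: str
    sequence: str
    star_sequence: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not 18 <= len(self.sequence) <= 26:
            raise ValueError(
                f"mature miRNA {self.id} length {len(self.sequence)} outside 18-26 nt"
            )
        if self.star_sequence is not None:
            star = normalize_rna(self.star_sequence)
            object.__setattr__(self, "star_sequence", star)
            if abs(len(star) - len(self.sequence)) > 2:
                raise ValueError(
                    f"star strand of {self.id} differs by more than 2 nt in length"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


def _header_line_number(path: Path, record_index: int) -> int:
    """1-based line number of the ``record_index``-th (0-based) FASTA header."""
    seen = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                seen += 1
                if seen == record_index:
                    return lineno
    return 0


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into normalized :class:`Sequence` records.

    Record order is preserved.  A header without any sequence raises
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    out: list[Sequence] = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        residues = normalize_rna(str(rec.seq))
        if not residues:
            lineno = _header_line_number(path, idx)
            raise ParseError(
                f"{path}: record {rec.id!r} at line {lineno} has a header but no sequence"
            )
        out.append(Sequence(id=rec.id, residues=residues))
    return out


def write_fasta(sequences: Iterable[Sequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def _collapse(
    raw: Iterable[tuple[str, int]],
    min_len: int,
    max_len: int,
    source: str,
) -> list[CountedRead]:
    counter: Counter[str] = Counter()
    dropped_ambiguous = 0
    dropped_length = 0
    for residues, count in raw:
        residues = normalize_rna(residues)
        if not set(residues) <= RNA_BASES:
            dropped_ambiguous += count
            continue
        if not min_len <= len(residues) <= max_len:
            dropped_length += count
            continue
        counter[residues] += count
    if dropped_ambiguous or dropped_length:
        logger.info(
            "%s: dropped %d reads with ambiguous bases and %d outside %d-%d nt",
            source, dropped_ambiguous, dropped_length, min_len, max_len,
        )
    return [
        CountedRead(residues=seq, count=n)
        for seq, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def read_fastq_collapsed(
    path: str | Path,
    min_len: int = DEFAULT_MIN_READ_LEN,
    max_len: int = DEFAULT_MAX_READ_LEN,
) -> list[CountedRead]:
    """Collapse a FASTQ file to unique reads with counts.

    Quality strings are required by the format but otherwise ignored.  Output
    is ordered by descending count, then lexicographically.
    """
    path = Path(path)
    try:
        raw = ((str(rec.seq), 1) for rec in SeqIO.parse(str(path), "fastq"))
        return _collapse(raw, min_len, max_len, str(path))
    except ValueError as exc:  # biopython signals seq/qual length mismatch etc.
        raise ParseError(f"{path}: {exc}") from exc


def read_collapsed_fasta(
    path: str | Path,
    min_len: int = DEFAULT_MIN_READ_LEN,
    max_len: int = DEFAULT_MAX_READ_LEN,
) -> list[CountedRead]:
    """Read a pre-collapsed FASTA library with ``_x<count>`` header suffixes.

    Headers without the suffix count as a single read.
    """
    raw = []
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        m = _COLLAPSED_HEADER.search(rec.id)
        raw.append((str(rec.seq), int(m.group(1)) if m else 1))
    return _collapse(raw, min_len, max_len, str(path))


def write_collapsed_fasta(reads: Iterable[CountedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f">r{i}_x{read.count}\n{read.residues}\n")


def write_fastq(reads: Iterable[CountedRead], path: str | Path) -> None:
    """Expand collapsed reads into a plain FASTQ (constant quality)."""
    with open(path, "w") as fh:
        serial = 0
        for read in reads:
            for _ in range(read.count):
                fh.write(f"@r{serial}\n{read.residues}\n+\n{'I' * len(read.residues)}\n")
                serial += 1


def write_tsv_report(
    records: SequenceLike[dict] | pd.DataFrame,
    path: str | Path,
    float_precision: int = 2,
    columns: SequenceLike[str] | None = None,
) -> None:
    """Write tabular results as TSV with a header row and fixed float precision.

    ``columns`` supplies the schema when ``records`` is an empty list.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(list(records), columns=columns)
    frame.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}f")


def read_mirna_catalog(path: str | Path) -> list[MatureMiRNA]:
    """Read a miRBase-style FASTA of mature miRNA sequences."""
    return [MatureMiRNA(id=s.id, sequence=s.residues) for s in read_fasta(path)]
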