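"""RACE clone tallying and modal cleavage-site calls.

Two RACE chemistries report the same scission from opposite fragments:
5'-RLM-RACE captures the 5'-most base of the 3' cleavage fragment, while
3'-PPM-RACE captures the 3'-most base of the 5' fragment.  Both are expressed
in miRNA coordinates through the validated target alignment.  Naming
convention: "cleaved at the k-th nucleotide" denotes the scission between the
target bases pairing miRNA positions k and k+1, reported as k — so an RLM5
endpoint maps directly to k, while a PPM3 endpoint (pairing k+1) is
normalized down by one.  Canonical AGO slicing falls at k = 10, which also
breaks ties in the modal call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .targets import DuplexAlignment, TargetHit

logger = logging.getLogger(__name__)

CANONICAL_SLICER_POSITION = 10

METHODS = ("RLM5", "PPM3")


@dataclass(frozen=True)
class RaceClone:
    """A sequenced RACE clone endpoint on a target transcript (0-based)."""

    target_id: str
    method: str  # "RLM5" or "PPM3"
    endpoint: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown RACE method {self.method!r}")
        if self.count < 1:
            raise ValueError("clone count must be >= 1")
        if self.endpoint < 0:
            raise ValueError("endpoint must be a 0-based transcript coordinate")


@dataclass
class CleavageProfile:
    target_id: str
    tallies: dict[int, int]  # miRNA position -> merged clone count
    modal_position: int | None
    total_clones: int
    unmapped_clones: int = 0


def pairing_map(hit: TargetHit) -> dict[int, int]:
    """Map each aligned target base (contig coordinate) to its miRNA position.

    Gap columns are omitted.  Only sense-strand sites are supported, matching
    the transcript-oriented scan.
    """
    if hit.strand != "+":
        raise ValueError("pairing_map requires a sense-strand target site")
    pmap: dict[int, int] = {}
    for col in hit.alignment.columns:
        if col.mirna_pos is not None and col.target_pos is not None:
            pmap[hit.start + col.target_pos] = col.mirna_pos
    return pmap


def clone_to_mirna_position(clone: RaceClone, pmap: dict[int, int]) -> int | None:
    """Normalized scission position of a clone, or ``None`` when unmapped."""
    mirna_pos = pmap.get(clone.endpoint)
    if mirna_pos is None:
        return None
    if clone.method == "RLM5":
        return mirna_pos
    # PPM3: the 5'-fragment's last base pairs k+1; the scission is reported as k.
    return mirna_pos - 1 if mirna_pos > 1 else None


def tally_cleavage(
    clones: list[RaceClone],
    hit: TargetHit,
    canonical: int = CANONICAL_SLICER_POSITION,
) -> CleavageProfile:
    """Accumulate clone counts by normalized miRNA position and call the mode.

    Ties break toward the canonical slicer position, then toward the smaller
    position.  Unmapped clones are counted separately and logged.
    """
    target_ids = {c.target_id for c in clones}
    if len(target_ids) > 1:
        raise ValueError(f"clones span multiple targets: {sorted(target_ids)}")
    pmap = pairing_map(hit)
    tallies: dict[int, int] = {}
    unmapped = 0
    total = 0
    for clone in clones:
        total += clone.count
        pos = clone_to_mirna_position(clone, pmap)
        if pos is None:
            unmapped += clone.count
        else:
            tallies[pos] = tallies.get(pos, 0) + clone.count
    if unmapped:
        logger.info(
            "%s: %d of %d clones fell outside the validated site",
            hit.contig_id, unmapped, total,
        )
    if tallies:
        best = max(tallies.values())
        tied = sorted(p for p, n in tallies.items() if n == best)
        modal = canonical if canonical in tied else tied[0]
    else:
        modal = None
        logger.warning("%s: no clones mapped; modal position undefined", hit.contig_id)
    return CleavageProfile(
        target_id=clones[0].target_id if clones else hit.contig_id,
        tallies=tallies,
        modal_position=modal,
        total_clones=total - unmapped,
        unmapped_clones=unmapped,
    )


def read_clone_tsv(path: str | Path) -> list[RaceClone]:
    """Read RACE clones from TSV columns target_id, method, endpoint, count."""
    frame = pd.read_csv(path, sep="\t")
    required = {"target_id", "method", "endpoint", "count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"clone table {path} lacks columns: {sorted(missing)}")
    return [
        RaceClone(
            target_id=str(row.target_id),
            method=str(row.method),
            endpoint=int(row.endpoint),
            count=int(row.count),
        )
        for row in frame.itertuples()
    ]


def write_clone_tsv(clones: list[RaceClone], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "target_id": c.target_id,
                "method": c.method,
                "endpoint": c.endpoint,
                "count": c.count,
            }
            for c in clones
        ],
        columns=["target_id", "method", "endpoint", "count"],
    )
    frame.to_csv(path, sep="\t", index=False)
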