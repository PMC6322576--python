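"""Penalty-score miRNA target prediction with region rules.

Plant miRNAs cleave targets through near-perfect complementarity, so a simple
additive penalty over the miRNA:site duplex is the field's classic statistic:
each mismatch costs 1 point, each G:U wobble 0.5, each gap 2.  Penalties are
partitioned along the miRNA into a 5' region (positions 1-8 from the miRNA 5'
end), the central region (9-11, where AGO-mediated scission occurs), and a 3'
region (12 to the end).  A site is a candidate only if its total penalty is at
most 3 points and the central region carries no mismatch; a central G:U adds
its 0.5 but is not by itself disqualifying.

Alignment is global, miRNA 5'->3' against the reverse-oriented site
(antiparallel pairing), with at most one gap by default: with gaps costing 2
against a cutoff of 3, a second gap can never yield a candidate, so the
search space is the ungapped register plus every single-gap placement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .io import MatureMiRNA, Sequence

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}

MISMATCH_PENALTY = 1.0
GU_PENALTY = 0.5
GAP_PENALTY = 2.0
DEFAULT_MAX_PENALTY = 3.0
DEFAULT_MAX_GAPS = 1

CENTRAL_START = 9  # 1-based miRNA positions 9-11 form the central region
CENTRAL_END = 11


class PairingState(str, enum.Enum):
    MATCH = "match"
    GU = "GU"
    MISMATCH = "mismatch"
    GAP_IN_TARGET = "gap_in_target"
    GAP_IN_MIRNA = "gap_in_mirna"


class Region(str, enum.Enum):
    FIVE_PRIME = "five_prime"
    CENTRAL = "central"
    THREE_PRIME = "three_prime"


_STATE_PENALTY = {
    PairingState.MATCH: 0.0,
    PairingState.GU: GU_PENALTY,
    PairingState.MISMATCH: MISMATCH_PENALTY,
    PairingState.GAP_IN_TARGET: GAP_PENALTY,
    PairingState.GAP_IN_MIRNA: GAP_PENALTY,
}


def region_of(mirna_position: int, mirna_length: int) -> Region:
    """Region of a 1-based miRNA position: 1-8 / 9-11 / 12-L."""
    if not 1 <= mirna_position <= mirna_length:
        raise ValueError(
            f"position {mirna_position} outside miRNA of length {mirna_length}"
        )
    if mirna_position < CENTRAL_START:
        return Region.FIVE_PRIME
    if mirna_position <= CENTRAL_END:
        return Region.CENTRAL
    return Region.THREE_PRIME


def classify_pair(mirna_base: str, target_base: str) -> PairingState:
    """Watson-Crick -> match; G:U or U:G -> GU wobble; anything else -> mismatch."""
    duo = (mirna_base, target_base)
    if duo in WC_PAIRS:
        return PairingState.MATCH
    if duo in GU_PAIRS:
        return PairingState.GU
    return PairingState.MISMATCH


@dataclass(frozen=True)
class AlignedColumn:
    """One duplex column: miRNA position (1-based) vs site position (0-based, 5'->3')."""

    mirna_pos: int | None
    target_pos: int | None
    state: PairingState
    region: Region


@dataclass
class DuplexAlignment:
    mirna: MatureMiRNA
    site_sequence: str
    columns: list[AlignedColumn]

    @property
    def gap_count(self) -> int:
        return sum(
            1
            for c in self.columns
            if c.state in (PairingState.GAP_IN_TARGET, PairingState.GAP_IN_MIRNA)
        )


@dataclass
class TargetScore:
    penalty: float
    region_counts: dict[Region, tuple[int, int]]  # region -> (GU count, mismatch count)
    gap_count: int
    verdict: str | None = None  # "candidate" or "excluded" once filtered
    exclusion_reason: str = ""

    def region_string(self, region: Region) -> str:
        gu, mm = self.region_counts[region]
        return f"{gu}/{mm}"


def _column_states(mirna_seq: str, rev_site: str, gap: tuple[str, int] | None):
    """Yield (mirna_pos, rev_site_index, state) columns for one gap placement.

    ``gap`` is ``None`` (ungapped), ``("target", g)`` meaning miRNA position g
    (1-based) faces a gap, or ``("mirna", g)`` meaning reversed-site index g
    (0-based) faces a gap.
    """
    L = len(mirna_seq)
    if gap is None:
        for i in range(L):
            yield (i + 1, i, classify_pair(mirna_seq[i], rev_site[i]))
    elif gap[0] == "target":
        g = gap[1]
        j = 0
        for i in range(1, L + 1):
            if i == g:
                yield (i, None, PairingState.GAP_IN_TARGET)
            else:
                yield (i, j, classify_pair(mirna_seq[i - 1], rev_site[j]))
                j += 1
    else:
        g = gap[1]
        i = 1
        for j in range(len(rev_site)):
            if j == g:
                yield (None, j, PairingState.GAP_IN_MIRNA)
            else:
                yield (i, j, classify_pair(mirna_seq[i - 1], rev_site[j]))
                i += 1


def _penalized_positions(columns) -> tuple[int, ...]:
    """1-based miRNA positions of penalized columns.

    A gap column with no miRNA base takes the position of its 5'-flanking
    miRNA column (position 1 for a leading gap).
    """
    out = []
    last = 1
    for mirna_pos, _, state in columns:
        if mirna_pos is not None:
            last = mirna_pos
        if _STATE_PENALTY[state] > 0:
            out.append(last)
    return tuple(sorted(out))


def align_site(
    mirna: MatureMiRNA,
    site_sequence: str,
    max_gaps: int = DEFAULT_MAX_GAPS,
) -> DuplexAlignment:
    """Minimum-penalty antiparallel alignment of a miRNA against a site.

    The site is given 5'->3' on the transcript and must be within one
    nucleotide of the miRNA length.  Ties prefer fewer gaps, then the
    alignment whose 5'-most penalized column sits closest to the miRNA 3' end.
    """
    L = mirna.length
    site = site_sequence.upper().replace("T", "U")
    delta = len(site) - L
    if abs(delta) > max_gaps:
        raise ValueError(
            f"site length {len(site)} outside allowed band for miRNA length {L}"
        )
    rev = site[::-1]
    if delta == 0:
        placements: list[tuple[str, int] | None] = [None]
    elif delta == -1:
        placements = [("target", g) for g in range(1, L + 1)]
    else:
        placements = [("mirna", g) for g in range(len(site))]

    best = None
    for gap in placements:
        cols = list(_column_states(mirna.sequence, rev, gap))
        penalty = sum(_STATE_PENALTY[state] for _, _, state in cols)
        gaps = 0 if gap is None else 1
        # Larger-position penalized columns (closer to the 3' end) win ties;
        # tuple comparison on sorted positions implements the recursion.
        key = (penalty, gaps, tuple(-p for p in _penalized_positions(cols)))
        if best is None or key < best[0]:
            best = (key, cols)
    _, cols = best
    columns = []
    last_pos = 1
    for mirna_pos, rev_idx, state in cols:
        if mirna_pos is not None:
            last_pos = mirna_pos
        region = region_of(last_pos, L)
        target_pos = None if rev_idx is None else len(site) - 1 - rev_idx
        columns.append(
            AlignedColumn(
                mirna_pos=mirna_pos, target_pos=target_pos, state=state, region=region
            )
        )
    return DuplexAlignment(mirna=mirna, site_sequence=site, columns=columns)


def score_alignment(alignment: DuplexAlignment) -> TargetScore:
    """Penalty and per-region GU/mismatch counts for a duplex alignment.

    Gap columns cost 2 points each and are attributed to the region of the
    5'-flanking miRNA position.
    """
    counts = {r: [0, 0] for r in Region}
    penalty = 0.0
    gaps = 0
    for col in alignment.columns:
        penalty += _STATE_PENALTY[col.state]
        if col.state is PairingState.GU:
            counts[col.region][0] += 1
        elif col.state is PairingState.MISMATCH:
            counts[col.region][1] += 1
        elif col.state in (PairingState.GAP_IN_TARGET, PairingState.GAP_IN_MIRNA):
            gaps += 1
    return TargetScore(
        penalty=penalty,
        region_counts={r: (gu, mm) for r, (gu, mm) in counts.items()},
        gap_count=gaps,
    )


def filter_candidate(
    score: TargetScore, max_penalty: float = DEFAULT_MAX_PENALTY
) -> TargetScore:
    """Apply the candidate filter: penalty <= cutoff and no central mismatch.

    Central G:U wobbles are allowed (they still count toward the penalty).
    The verdict and, when excluded, the reason(s) are written onto the score.
    """
    reasons = []
    if score.penalty > max_penalty:
        reasons.append(f"penalty {score.penalty:g} exceeds {max_penalty:g}")
    if score.region_counts[Region.CENTRAL][1] > 0:
        reasons.append("mismatch in the central region")
    score.verdict = "excluded" if reasons else "candidate"
    score.exclusion_reason = "; ".join(reasons)
    return score


@dataclass
class TargetHit:
    contig_id: str
    start: int  # 0-based half-open on the contig, sense strand
    end: int
    strand: str
    score: TargetScore
    alignment: DuplexAlignment


def _collapse_overlaps(hits: list[TargetHit]) -> list[TargetHit]:
    """Keep the best hit per overlapping locus (min penalty, longest, leftmost)."""
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    clusters: list[list[TargetHit]] = []
    cluster_end = -1
    for hit in hits:
        if clusters and hit.start < cluster_end:
            clusters[-1].append(hit)
            cluster_end = max(cluster_end, hit.end)
        else:
            clusters.append([hit])
            cluster_end = hit.end
    return [
        min(c, key=lambda h: (h.score.penalty, -(h.end - h.start), h.start))
        for c in clusters
    ]


def _quick_min_penalty(mirna_seq: str, rev_site: str) -> float:
    """Lower-bound-free minimum penalty of a window in O(L) (scan prefilter).

    For equal lengths this is the ungapped penalty; for off-by-one lengths the
    best single-gap placement via prefix/suffix cost sums.
    """
    L = len(mirna_seq)
    S = len(rev_site)
    cost = _STATE_PENALTY
    if S == L:
        return sum(
            cost[classify_pair(mirna_seq[i], rev_site[i])] for i in range(L)
        )
    if S == L - 1:
        # gap in target opposite miRNA position g (1-based)
        prefix = [0.0] * (L + 1)
        for i in range(L - 1):
            prefix[i + 1] = prefix[i] + cost[classify_pair(mirna_seq[i], rev_site[i])]
        suffix = [0.0] * (L + 1)
        for i in range(L - 1, 0, -1):
            suffix[i] = suffix[i + 1] + cost[classify_pair(mirna_seq[i], rev_site[i - 1])]
        return GAP_PENALTY + min(prefix[g - 1] + suffix[g] for g in range(1, L + 1))
    # S == L + 1: unaligned site base at reversed index g
    prefix = [0.0] * (S + 1)
    for j in range(L):
        prefix[j + 1] = prefix[j] + cost[classify_pair(mirna_seq[j], rev_site[j])]
    suffix = [0.0] * (S + 1)
    for j in range(S - 1, 0, -1):
        suffix[j] = suffix[j + 1] + cost[classify_pair(mirna_seq[j - 1], rev_site[j])]
    return GAP_PENALTY + min(prefix[g] + suffix[g + 1] for g in range(S))


def scan_transcriptome(
    mirna: MatureMiRNA,
    contigs: list[Sequence],
    max_penalty: float = DEFAULT_MAX_PENALTY,
    max_gaps: int = DEFAULT_MAX_GAPS,
    both_strands: bool = False,
) -> list[TargetHit]:
    """Scan contigs for candidate target sites of a miRNA.

    Every window of length L-1, L, L+1 on the sense strand is aligned and
    scored; only candidate verdicts are kept, overlapping candidates collapse
    to the best per locus, and output is sorted by ascending penalty then
    contig id.  Contigs are mRNA transcripts, so the reverse strand is only
    scanned on request (unoriented assemblies).
    """
    from .io import reverse_complement

    L = mirna.length
    all_hits: list[TargetHit] = []
    for contig in contigs:
        strands = [("+", contig.residues)]
        if both_strands:
            strands.append(("-", reverse_complement(contig.residues)))
        contig_hits: list[TargetHit] = []
        for strand, seq in strands:
            n = len(seq)
            for wlen in (L - 1, L, L + 1):
                if wlen > n or abs(wlen - L) > max_gaps:
                    continue
                for start in range(n - wlen + 1):
                    window = seq[start:start + wlen]
                    if "N" in window:
                        continue
                    if _quick_min_penalty(mirna.sequence, window[::-1]) > max_penalty:
                        continue
                    aln = align_site(mirna, window, max_gaps=max_gaps)
                    score = filter_candidate(score_alignment(aln), max_penalty)
                    if score.verdict != "candidate":
                        continue
                    if strand == "-":
                        fwd_start, fwd_end = n - (start + wlen), n - start
                    else:
                        fwd_start, fwd_end = start, start + wlen
                    contig_hits.append(
                        TargetHit(
                            contig_id=contig.id,
                            start=fwd_start,
                            end=fwd_end,
                            strand=strand,
                            score=score,
                            alignment=aln,
                        )
                    )
        all_hits.extend(_collapse_overlaps(contig_hits))
    all_hits.sort(key=lambda h: (h.score.penalty, h.contig_id, h.start))
    return all_hits
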