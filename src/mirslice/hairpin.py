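"""Pre-miRNA hairpin identification in transcriptome contigs.

A contig is a candidate precursor when it carries an exact full-length match
to the mature miRNA and the surrounding window folds into a stem-loop placing
the mature sequence in one arm, paired across the loop to a star strand — the
duplex that DCL1 excises.  Folding uses a weighted maximum-pairing dynamic
program (Nussinov-style): Watson-Crick pairs score 1.0, G:U wobbles 0.8, and a
hairpin loop must span at least 3 unpaired bases.  The fold serves only as a
binary gate plus star identification, so no thermodynamic parameters are
involved; a free-energy backend can be substituted behind the same
:class:`FoldResult` contract.

The predicted star strand follows standard DCL1 duplex geometry: the window
segment pairing the mature span, shifted to carry a 2-nt 3' overhang on each
strand of the duplex.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io import ConfigurationError, MatureMiRNA, Sequence, reverse_complement

__all__ = [
    "FoldResult",
    "HairpinRules",
    "HairpinCandidate",
    "MatureMiRNA",
    "find_exact_matches",
    "fold_window",
    "evaluate_hairpin",
    "find_precursors",
    "to_dot_bracket",
]

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

WC_WEIGHT = 1.0
GU_WEIGHT = 0.8
DEFAULT_MIN_LOOP = 3
DEFAULT_MAX_WINDOW = 400
DEFAULT_FLANK_NT = 150


def _pair_weights(gu_weight: float = GU_WEIGHT) -> np.ndarray:
    w = np.zeros((5, 5))
    w[_CODE["A"], _CODE["U"]] = w[_CODE["U"], _CODE["A"]] = WC_WEIGHT
    w[_CODE["G"], _CODE["C"]] = w[_CODE["C"], _CODE["G"]] = WC_WEIGHT
    w[_CODE["G"], _CODE["U"]] = w[_CODE["U"], _CODE["G"]] = gu_weight
    return w


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int64)


@njit(cache=True)
def _fill(codes, pairw, min_loop):  # pragma: no cover - exercised via fold_window
    n = codes.size
    W = np.zeros((n, n))
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                w = pairw[codes[i], codes[k]]
                if w > 0.0:
                    v = w
                    if k - 1 >= i + 1:
                        v += W[i + 1, k - 1]
                    if k + 1 <= j:
                        v += W[k + 1, j]
                    if v > best:
                        best = v
            W[i, j] = best
    return W


@njit(cache=True)
def _traceback(W, codes, pairw, min_loop):  # pragma: no cover - via fold_window
    n = codes.size
    partner = np.full(n, -1, dtype=np.int64)
    eps = 1e-7
    cap = n + 8
    si = np.empty(cap, dtype=np.int64)
    sj = np.empty(cap, dtype=np.int64)
    sh = np.empty(cap, dtype=np.int64)
    si[0], sj[0], sh[0] = 0, n - 1, n - 1
    top = 1
    while top > 0:
        top -= 1
        i, j, hint = si[top], sj[top], sh[top]
        while j - i > min_loop and W[i, j] > eps:
            target = W[i, j]
            best_k = -1
            best_d = 0
            for k in range(i + min_loop + 1, j + 1):
                w = pairw[codes[i], codes[k]]
                if w > 0.0:
                    v = w
                    if k - 1 >= i + 1:
                        v += W[i + 1, k - 1]
                    if k + 1 <= j:
                        v += W[k + 1, j]
                    if abs(v - target) < eps:
                        d = hint - k if hint >= k else k - hint
                        if best_k < 0 or d < best_d or (d == best_d and k > best_k):
                            best_d = d
                            best_k = k
            if best_k >= 0:
                partner[i] = best_k
                partner[best_k] = i
                if best_k + 1 <= j:
                    si[top], sj[top], sh[top] = best_k + 1, j, j
                    top += 1
                i, j, hint = i + 1, best_k - 1, best_k - 1
            else:
                i += 1
    return partner


@dataclass(frozen=True)
class FoldResult:
    """A nested (pseudoknot-free) pairing of a window, 0-based positions."""

    sequence: str
    pairs: tuple[tuple[int, int], ...]
    pair_kinds: tuple[str, ...]  # "WC" or "GU", parallel to pairs
    weight: float

    def partner_array(self) -> np.ndarray:
        partner = np.full(len(self.sequence), -1, dtype=np.int64)
        for a, b in self.pairs:
            partner[a] = b
            partner[b] = a
        return partner


def fold_window(
    window_sequence: str,
    min_loop: int = DEFAULT_MIN_LOOP,
    max_window: int = DEFAULT_MAX_WINDOW,
    gu_weight: float = GU_WEIGHT,
) -> FoldResult:
    """Maximum-weight nested pairing of a window by dynamic programming.

    Deterministic traceback: the 5'-most pairable position is paired whenever
    doing so preserves optimality; among equally optimal partners the one
    continuing the enclosing helix is preferred (ties toward the 3' side).
    """
    seq = window_sequence.upper().replace("T", "U")
    if len(seq) > max_window:
        raise ConfigurationError(
            f"window of {len(seq)} nt exceeds the configured maximum {max_window}"
        )
    if len(seq) < min_loop + 2:
        return FoldResult(sequence=seq, pairs=(), pair_kinds=(), weight=0.0)
    codes = _encode(seq)
    pairw = _pair_weights(gu_weight)
    W = _fill(codes, pairw, min_loop)
    partner = _traceback(W, codes, pairw, min_loop)
    pairs = []
    kinds = []
    weight = 0.0
    for i in range(len(seq)):
        j = int(partner[i])
        if j > i:
            w = pairw[codes[i], codes[j]]
            pairs.append((i, j))
            kinds.append("WC" if w == WC_WEIGHT else "GU")
            weight += w
    assert abs(weight - W[0, len(seq) - 1]) < 1e-6, "traceback lost optimality"
    return FoldResult(
        sequence=seq, pairs=tuple(pairs), pair_kinds=tuple(kinds), weight=weight
    )


def to_dot_bracket(fold: FoldResult) -> str:
    chars = ["."] * len(fold.sequence)
    for a, b in fold.pairs:
        chars[a] = "("
        chars[b] = ")"
    return "".join(chars)


@dataclass(frozen=True)
class HairpinRules:
    """Acceptance rules for a mature-bearing stem-loop."""

    pairing_fraction: float = 0.60  # minimum fraction of mature positions paired
    max_unpaired: int = 5  # maximum mature positions left unpaired
    min_loop: int = DEFAULT_MIN_LOOP
    flank_nt: int = DEFAULT_FLANK_NT  # window flank on each side of the match
    max_window: int = DEFAULT_MAX_WINDOW
    gu_weight: float = GU_WEIGHT


@dataclass
class HairpinCandidate:
    contig_id: str
    window: tuple[int, int]  # 0-based half-open, contig forward coordinates
    strand: str  # "+" or "-"
    mature_location: tuple[int, int]  # within the (oriented) window
    fold: FoldResult | None
    arm: str | None  # "5p" or "3p"
    predicted_star: str | None
    verdict: str  # "accepted" or "rejected"
    rejection_reason: str = ""
    mature_paired_fraction: float = 0.0
    duplex_pairs: tuple[tuple[int, int], ...] = ()  # (mature pos, star pos), window coords
    star_interval: tuple[int, int] | None = None  # 0-based half-open, window coords


def find_exact_matches(
    mature: MatureMiRNA, contigs: list[Sequence]
) -> list[tuple[str, tuple[int, int], str]]:
    """All exact full-length occurrences of the mature sequence on either strand.

    Intervals are 0-based half-open in contig forward coordinates.
    """
    queries = [(mature.sequence, "+")]
    rc = reverse_complement(mature.sequence)
    if rc != mature.sequence:
        queries.append((rc, "-"))
    hits = []
    for contig in contigs:
        for query, strand in queries:
            start = contig.residues.find(query)
            while start != -1:
                hits.append((contig.id, (start, start + len(query)), strand))
                start = contig.residues.find(query, start + 1)
    return hits


def _hairpin_loops(fold: FoldResult) -> list[tuple[int, int]]:
    """Closing pairs (a, b) that enclose no other pair — the hairpin loops."""
    loops = []
    for a, b in fold.pairs:
        if not any(a < x < y < b for x, y in fold.pairs if (x, y) != (a, b)):
            loops.append((a, b))
    return loops


_PAIRABLE = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


def evaluate_hairpin(
    window_sequence: str,
    mature_location: tuple[int, int],
    fold: FoldResult,
    rules: HairpinRules | None = None,
) -> HairpinCandidate:
    """Decide whether a folded window qualifies as a precursor and predict the star.

    The fold gates the topology; the decision is about the mature:star duplex.
    A maximum-weight pairing of a long window is highly degenerate — a base
    excluded from the true duplex can usually be paired somewhere in the
    flanks at equal weight, so the global fold cannot be trusted to keep the
    duplex intact.  The duplex is therefore assessed at the best register
    (position + partner is constant along an antiparallel duplex): every
    register placing a star segment on one arm, separated from the mature by
    at least a minimum loop, is scored by how many mature positions can pair
    (WC or GU) at that register, and the best one is kept (ties resolved
    toward the register the fold's own mature pairings vote for).  Acceptance
    requires: enough mature positions paired in the fold, no mature overlap
    with a terminal loop, no pairing of the mature within its own span, and
    enough duplex-pairable positions at the chosen register (fraction and
    absolute bounds).
    """
    rules = rules or HairpinRules()
    ms, me = mature_location
    n = len(window_sequence)
    if not (0 <= ms < me <= n):
        raise ValueError(f"mature location {mature_location} outside window of {n} nt")
    L = me - ms
    candidate = HairpinCandidate(
        contig_id="",
        window=(0, n),
        strand="+",
        mature_location=mature_location,
        fold=fold,
        arm=None,
        predicted_star=None,
        verdict="rejected",
    )
    partner = fold.partner_array()
    paired = [p for p in range(ms, me) if partner[p] >= 0]
    candidate.mature_paired_fraction = len(paired) / L

    if candidate.mature_paired_fraction < rules.pairing_fraction:
        candidate.rejection_reason = (
            f"insufficient mature pairing ({len(paired)}/{L} positions)"
        )
        return candidate
    for a, b in _hairpin_loops(fold):
        if any(a < p < b for p in range(ms, me)):
            candidate.rejection_reason = "overlaps terminal loop"
            return candidate
    if any(ms <= partner[p] < me for p in paired):
        candidate.rejection_reason = "mature pairs within its own span"
        return candidate

    votes = [p + int(partner[p]) for p in paired if not ms <= partner[p] < me]
    register0 = int(statistics.median_low(votes)) if votes else 2 * me + rules.min_loop

    def _duplex(reg: int) -> list[tuple[int, int]]:
        pairs = []
        for p in range(ms, me):
            q = reg - p
            if 0 <= q < n and not ms <= q < me:
                if (window_sequence[p], window_sequence[q]) in _PAIRABLE:
                    pairs.append((p, q))
        return pairs

    # Candidate registers place the star on one arm with a loop of at least
    # min_loop between the arms (innermost duplex pair spacing).
    lo_5p, hi_5p = 2 * me - 1 + rules.min_loop, me - 1 + n - 1
    lo_3p, hi_3p = ms, 2 * ms - 1 - rules.min_loop
    registers = [r for r in range(lo_5p, hi_5p + 1)] + [
        r for r in range(lo_3p, hi_3p + 1)
    ]
    if not registers:
        candidate.rejection_reason = "window leaves no room for a star arm"
        return candidate
    register, duplex = max(
        ((reg, _duplex(reg)) for reg in registers),
        key=lambda rd: (len(rd[1]), -abs(rd[0] - register0), -rd[0]),
    )
    candidate.duplex_pairs = tuple(duplex)
    duplex_fraction = len(duplex) / L
    candidate.mature_paired_fraction = min(
        candidate.mature_paired_fraction, duplex_fraction
    )
    if duplex_fraction < rules.pairing_fraction:
        candidate.rejection_reason = (
            f"insufficient duplex pairing at register ({len(duplex)}/{L} positions)"
        )
        return candidate
    if L - len(duplex) > rules.max_unpaired:
        candidate.rejection_reason = (
            f"too many unpaired duplex positions ({L - len(duplex)} > {rules.max_unpaired})"
        )
        return candidate
    star_start = register - me + 3
    star_end = register - ms + 3
    if not (star_end <= ms or star_start >= me):
        candidate.rejection_reason = "star span overlaps the mature span"
        return candidate
    candidate.arm = "5p" if star_start >= me else "3p"
    candidate.star_interval = (max(0, star_start), min(n, star_end))
    candidate.predicted_star = window_sequence[candidate.star_interval[0]:candidate.star_interval[1]]
    candidate.verdict = "accepted"
    return candidate


def find_precursors(
    mature: MatureMiRNA,
    contigs: list[Sequence],
    rules: HairpinRules | None = None,
) -> list[HairpinCandidate]:
    """Locate, fold, and evaluate every exact mature match in a contig set.

    Every candidate is returned with a verdict; accepted candidates come
    first, sorted by descending fraction of mature positions paired.
    """
    rules = rules or HairpinRules()
    by_id = {c.id: c for c in contigs}
    candidates: list[HairpinCandidate] = []
    for contig_id, (start, end), strand in find_exact_matches(mature, contigs):
        contig = by_id[contig_id]
        wstart = max(0, start - rules.flank_nt)
        wend = min(contig.length, end + rules.flank_nt)
        window_seq = contig.residues[wstart:wend]
        if strand == "-":
            window_seq = reverse_complement(window_seq)
            mature_loc = (wend - end, wend - start)
        else:
            mature_loc = (start - wstart, end - wstart)
        if len(window_seq) < 2 * mature.length + rules.min_loop:
            cand = HairpinCandidate(
                contig_id=contig_id,
                window=(wstart, wend),
                strand=strand,
                mature_location=mature_loc,
                fold=None,
                arm=None,
                predicted_star=None,
                verdict="rejected",
                rejection_reason="window too short to form a duplex",
            )
            candidates.append(cand)
            continue
        fold = fold_window(
            window_seq,
            min_loop=rules.min_loop,
            max_window=rules.max_window,
            gu_weight=rules.gu_weight,
        )
        cand = evaluate_hairpin(window_seq, mature_loc, fold, rules)
        cand.contig_id = contig_id
        cand.window = (wstart, wend)
        cand.strand = strand
        candidates.append(cand)
    candidates.sort(
        key=lambda c: (c.verdict != "accepted", -c.mature_paired_fraction)
    )
    return candidates
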