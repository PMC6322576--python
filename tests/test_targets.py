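"""Penalty scoring, region rules, and transcriptome scanning."""

from functools import lru_cache

import numpy as np
import pytest

from conftest import random_rna
from mirslice.io import MatureMiRNA, Sequence, reverse_complement
from mirslice.targets import (
    PairingState,
    Region,
    align_site,
    classify_pair,
    filter_candidate,
    region_of,
    scan_transcriptome,
    score_alignment,
)
from mirslice.simulate import build_site, make_target_contig

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def oracle_min_penalty(mirna_seq: str, site: str, max_gaps: int = 1) -> float:
    """Independent recursive minimum-penalty aligner (no shared code)."""
    rev = site[::-1]

    def cost(a: str, b: str) -> float:
        if (a, b) in _WC:
            return 0.0
        if (a, b) in _GU:
            return 0.5
        return 1.0

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, gaps: int) -> float:
        if i == len(mirna_seq) and j == len(rev):
            return 0.0
        best = float("inf")
        if i < len(mirna_seq) and j < len(rev):
            best = cost(mirna_seq[i], rev[j]) + rec(i + 1, j + 1, gaps)
        if gaps < max_gaps:
            if i < len(mirna_seq):
                best = min(best, 2.0 + rec(i + 1, j, gaps + 1))
            if j < len(rev):
                best = min(best, 2.0 + rec(i, j + 1, gaps + 1))
        return best

    return rec(0, 0, 0)


@pytest.mark.parametrize(
    "pos,expected",
    [
        (1, Region.FIVE_PRIME),
        (8, Region.FIVE_PRIME),
        (9, Region.CENTRAL),
        (11, Region.CENTRAL),
        (12, Region.THREE_PRIME),
        (21, Region.THREE_PRIME),
    ],
)
def test_region_partition(pos, expected):
    assert region_of(pos, 21) == expected


def test_region_out_of_range():
    with pytest.raises(ValueError):
        region_of(0, 21)
    with pytest.raises(ValueError):
        region_of(22, 21)


@pytest.mark.parametrize("a", "ACGU")
@pytest.mark.parametrize("b", "ACGU")
def test_classify_pair_exhaustive(a, b):
    state = classify_pair(a, b)
    if (a, b) in _WC:
        assert state is PairingState.MATCH
    elif (a, b) in _GU:
        assert state is PairingState.GU
    else:
        assert state is PairingState.MISMATCH


def test_align_perfect_complement(mir408):
    site = reverse_complement(mir408.sequence)
    aln = align_site(mir408, site)
    assert all(c.state is PairingState.MATCH for c in aln.columns)
    assert score_alignment(aln).penalty == 0.0
    # antiparallel: miRNA position 1 pairs the site's 3'-most base
    assert aln.columns[0].mirna_pos == 1
    assert aln.columns[0].target_pos == len(site) - 1
    positions = [c.target_pos for c in aln.columns]
    assert positions == sorted(positions, reverse=True)


def test_align_single_substitution_at_position_5(mir408):
    site = build_site(mir408, [("mismatch", 5)])
    aln = align_site(mir408, site)
    bad = [c for c in aln.columns if c.state is PairingState.MISMATCH]
    assert [c.mirna_pos for c in bad] == [5]
    assert score_alignment(aln).penalty == 1.0


def test_align_one_gap_is_minimum_over_placements(mir408):
    site = build_site(mir408, [("gap", 15)])
    aln = align_site(mir408, site)
    score = score_alignment(aln)
    assert score.gap_count == 1
    assert score.penalty >= 2.0
    assert score.penalty == oracle_min_penalty(mir408.sequence, site)


def test_align_rejects_out_of_band_sites(mir408):
    with pytest.raises(ValueError):
        align_site(mir408, "ACGU")


@pytest.mark.parametrize("seed", range(6))
def test_align_matches_recursive_oracle(mir408, seed):
    rng = np.random.default_rng(seed)
    for _ in range(40):
        wlen = mir408.length + int(rng.integers(-1, 2))
        site = random_rna(rng, wlen)
        penalty = score_alignment(align_site(mir408, site)).penalty
        assert penalty == pytest.approx(oracle_min_penalty(mir408.sequence, site))


# The three validated wound-response targets: per-region (GU, mismatch)
# patterns, their penalties, and retention under the candidate filter.
TABLE_PATTERNS = [
    ({"five_prime": (0, 1), "central": (0, 0), "three_prime": (0, 1)}, 2.0),
    ({"five_prime": (0, 0), "central": (0, 0), "three_prime": (1, 2)}, 2.5),
    ({"five_prime": (1, 1), "central": (0, 0), "three_prime": (1, 1)}, 3.0),
]


@pytest.mark.parametrize("pattern,expected_penalty", TABLE_PATTERNS)
def test_validated_target_patterns_score_and_pass(mir408, pattern, expected_penalty):
    planted = make_target_contig(mir408, pattern, seed=22)
    hits = scan_transcriptome(mir408, [planted.contig])
    assert len(hits) == 1
    score = hits[0].score
    assert score.penalty == expected_penalty
    assert score.verdict == "candidate"
    for key, (gu, mm) in pattern.items():
        assert score.region_counts[Region[key.upper()]] == (gu, mm)


@pytest.mark.parametrize(
    "penalty,central_mm,expected",
    [
        (3.0, 0, "candidate"),
        (2.0, 1, "excluded"),
        (3.5, 0, "excluded"),
        (0.0, 0, "candidate"),
    ],
)
def test_filter_rules(penalty, central_mm, expected):
    from mirslice.targets import TargetScore

    score = TargetScore(
        penalty=penalty,
        region_counts={
            Region.FIVE_PRIME: (0, 0),
            Region.CENTRAL: (0, central_mm),
            Region.THREE_PRIME: (0, 0),
        },
        gap_count=0,
    )
    assert filter_candidate(score).verdict == expected


def test_central_gu_does_not_exclude(mir408):
    """A central G:U wobble costs 0.5 but is not disqualifying on its own."""
    site = build_site(mir408, [("GU", 10)])
    score = filter_candidate(score_alignment(align_site(mir408, site)))
    assert score.penalty == 0.5
    assert score.verdict == "candidate"


def test_single_event_penalty_steps(mir408):
    """A GU raises the penalty by exactly 0.5, a mismatch by exactly 1."""
    for pos in range(1, mir408.length + 1):
        base = mir408.sequence[pos - 1]
        if base in "GU":
            site = build_site(mir408, [("GU", pos)])
            assert score_alignment(align_site(mir408, site)).penalty == 0.5
        site = build_site(mir408, [("mismatch", pos)])
        assert score_alignment(align_site(mir408, site)).penalty == 1.0


def test_antiparallel_role_symmetry(mir408, rng):
    """Swapping which strand is 'guide' leaves the minimum penalty unchanged."""
    for _ in range(20):
        site = random_rna(rng, 21)
        p1 = score_alignment(align_site(mir408, site)).penalty
        swapped = MatureMiRNA(id="site-as-guide", sequence=site)
        p2 = score_alignment(align_site(swapped, mir408.sequence)).penalty
        assert p1 == pytest.approx(p2)


def test_scan_finds_planted_site_uniquely(mir408):
    planted = make_target_contig(
        mir408,
        {"five_prime": (0, 1), "three_prime": (0, 1)},
        flank_length=80,
        seed=21,
    )
    hits = scan_transcriptome(mir408, [planted.contig])
    assert len(hits) == 1
    assert (hits[0].start, hits[0].end) == planted.site_interval
    assert hits[0].score.penalty == 2.0


def test_scan_reverse_complement_contig_scores_zero(mir408):
    contig = Sequence(id="rc", residues=reverse_complement(mir408.sequence))
    hits = scan_transcriptome(mir408, [contig])
    assert len(hits) == 1
    assert hits[0].score.penalty == 0.0


def test_scan_decoy_set_recovers_only_candidates(mir408):
    """5 planted candidates, 5 central-mismatch decoys, 40 background contigs."""
    rng = np.random.default_rng(22)
    contigs = []
    for i in range(5):
        contigs.append(
            make_target_contig(
                mir408, {"five_prime": (0, 1), "three_prime": (1, 0)},
                rng=rng, contig_id=f"cand_{i}",
            ).contig
        )
    for i in range(5):
        contigs.append(
            make_target_contig(
                mir408, {"central": (0, 1)}, rng=rng, contig_id=f"decoy_{i}"
            ).contig
        )
    for i in range(40):
        contigs.append(Sequence(id=f"bg_{i}", residues=random_rna(rng, 200)))
    hits = scan_transcriptome(mir408, contigs)
    assert sorted(h.contig_id for h in hits) == [f"cand_{i}" for i in range(5)]


def test_scan_emits_no_rule_violations(mir408):
    """Filter soundness: no emitted site breaks the penalty or central rule."""
    rng = np.random.default_rng(30)
    contigs = [
        Sequence(id=f"c{i}", residues=random_rna(rng, 150)) for i in range(10)
    ]
    contigs.append(
        make_target_contig(mir408, {"three_prime": (2, 1)}, rng=rng).contig
    )
    for hit in scan_transcriptome(mir408, contigs):
        assert hit.score.penalty <= 3.0
        assert hit.score.region_counts[Region.CENTRAL][1] == 0


def test_score_identity_invariant(mir408, rng):
    """penalty == 1*mismatches + 0.5*GU + 2*gaps for every alignment."""
    for _ in range(30):
        wlen = mir408.length + int(rng.integers(-1, 2))
        site = random_rna(rng, wlen)
        score = score_alignment(align_site(mir408, site))
        gu = sum(c[0] for c in score.region_counts.values())
        mm = sum(c[1] for c in score.region_counts.values())
        assert score.penalty == pytest.approx(mm + 0.5 * gu + 2 * score.gap_count)
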