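"""The synthetic-data generator: determinism and self-consistency."""

import numpy as np
import pytest

from mirslice.io import ConfigurationError, read_fastq_collapsed
from mirslice.quantify import quantify_experiment
from mirslice.simulate import (
    MIR408_RPM,
    MIR408_STAR_RPM,
    RpmPlan,
    SimulationSpec,
    dinucleotide_shuffle,
    make_libraries,
    make_mirnas,
    make_precursor_contig,
    make_race_clones,
    make_target_contig,
    simulate_experiment,
)
from mirslice.targets import Region, scan_transcriptome


def test_make_mirnas_deterministic_with_override(mir408):
    a = make_mirnas(10, seed=5, overrides=[mir408])
    b = make_mirnas(10, seed=5, overrides=[mir408])
    assert [m.sequence for m in a] == [m.sequence for m in b]
    assert a[0].sequence == mir408.sequence
    assert all(len(m.sequence) == 21 for m in a)
    assert len({m.sequence for m in a}) == 10


def test_make_libraries_realizes_printed_abundances(mir408):
    """At a depth where every planned RPM is an integer count, realization is exact."""
    catalog = make_mirnas(3, seed=1, overrides=[mir408])
    plans = [RpmPlan.from_rpms(mir408.id, *MIR408_RPM)]
    control, treated = make_libraries(plans, catalog, depth=100_000_000, seed=1)
    counts_c = {r.residues: r.count for r in control.reads}
    counts_t = {r.residues: r.count for r in treated.reads}
    assert counts_c[mir408.sequence] == 29095
    assert counts_t[mir408.sequence] == 19704
    assert control.total_reads == treated.total_reads == 100_000_000


def test_make_libraries_rounding_at_shallow_depth(mir408):
    catalog = make_mirnas(2, seed=1, overrides=[mir408])
    plans = [RpmPlan.from_rpms(mir408.id, *MIR408_RPM)]
    control, treated = make_libraries(plans, catalog, depth=1_000_000, seed=1)
    counts_c = {r.residues: r.count for r in control.reads}
    counts_t = {r.residues: r.count for r in treated.reads}
    assert counts_c[mir408.sequence] == 291
    assert counts_t[mir408.sequence] == 197
    realized = counts_t[mir408.sequence] / counts_c[mir408.sequence]
    assert abs(realized - plans[0].ratio) < 0.005


def test_make_libraries_infeasible_plan_errors(mir408):
    catalog = make_mirnas(2, seed=1, overrides=[mir408])
    plans = [RpmPlan(mir408.id, rpm_control=2e6, ratio=1.0)]
    with pytest.raises(ConfigurationError):
        make_libraries(plans, catalog, depth=1000, seed=1)


def test_quantify_recovers_every_planted_class(mir408):
    exp = simulate_experiment(SimulationSpec(seed=7))
    records = quantify_experiment(exp.control, exp.treated, exp.catalog)
    assert len(records) == len(exp.plans)
    planned = {p.mirna_id: p.expected_class() for p in exp.plans}
    for record in records:
        assert record.regulation_class == planned[record.mirna_id]


def test_generated_fastq_parses_with_zero_drops(mir408, tmp_path):
    catalog = make_mirnas(3, seed=2, overrides=[mir408])
    plans = [RpmPlan(mir408.id, rpm_control=5000.0, ratio=0.5)]
    control, _ = make_libraries(plans, catalog, depth=2000, seed=2)
    from mirslice.io import write_fastq

    path = tmp_path / "lib.fastq"
    write_fastq(control.reads, path)
    back = read_fastq_collapsed(path)
    assert sum(r.count for r in back) == 2000
    assert {r.residues: r.count for r in back} == {
        r.residues: r.count for r in control.reads
    }


def test_precursor_constructor_guards(mir408):
    with pytest.raises(ConfigurationError):
        make_precursor_contig(mir408, loop_length=2, seed=1)
    with pytest.raises(ConfigurationError):
        make_precursor_contig(mir408, stem_mismatches=16, seed=1)


def test_precursor_contig_layout(mir408):
    planted = make_precursor_contig(mir408, stem_mismatches=0, seed=3)
    ms, me = planted.mature_interval
    assert planted.contig.residues[ms:me] == mir408.sequence
    ss, se = planted.star_interval
    assert planted.contig.residues[ss:se] == planted.star
    assert len(planted.star) == mir408.length


def test_dinucleotide_shuffle_preserves_composition(rng):
    from conftest import random_rna
    from collections import Counter

    seq = random_rna(rng, 120)
    shuffled = dinucleotide_shuffle(seq, rng)
    assert shuffled != seq
    assert Counter(zip(seq, seq[1:])) == Counter(zip(shuffled, shuffled[1:]))
    assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


@pytest.mark.parametrize("trial", range(4))
def test_generator_and_scorer_agree_on_random_patterns(mir408, trial):
    """Self-consistency: the planted expected score always equals the scan's."""
    rng = np.random.default_rng(900 + trial)
    for _ in range(25):
        pattern = {
            "five_prime": (int(rng.integers(0, 2)), int(rng.integers(0, 2))),
            "central": (int(rng.integers(0, 2)), 0),
            "three_prime": (int(rng.integers(0, 2)), int(rng.integers(0, 2))),
        }
        planted = make_target_contig(mir408, pattern, rng=rng)
        if planted.expected.verdict != "candidate":
            continue
        hits = [
            h
            for h in scan_transcriptome(mir408, [planted.contig])
            if (h.start, h.end) == planted.site_interval
        ]
        assert len(hits) == 1
        assert hits[0].score.penalty == planted.expected.penalty
        assert hits[0].score.region_counts == planted.expected.region_counts


def test_infeasible_pattern_errors(mir408):
    # only three central positions exist
    with pytest.raises(ConfigurationError):
        make_target_contig(mir408, {"central": (0, 4)}, seed=1)


def test_race_clones_deterministic(mir408):
    from mirslice.io import reverse_complement, Sequence

    contig = Sequence(id="t", residues="A" * 50 + reverse_complement(mir408.sequence) + "A" * 50)
    (hit,) = scan_transcriptome(mir408, [contig])
    a = make_race_clones(hit, 10, 1.0, 30, seed=41)
    b = make_race_clones(hit, 10, 1.0, 30, seed=41)
    assert a == b
    assert len(a) == 30


def test_noise_free_clones_all_map_to_true_position(mir408):
    from mirslice.io import reverse_complement, Sequence
    from mirslice.cleavage import pairing_map, clone_to_mirna_position

    contig = Sequence(id="t", residues="A" * 50 + reverse_complement(mir408.sequence) + "A" * 50)
    (hit,) = scan_transcriptome(mir408, [contig])
    clones = make_race_clones(hit, 10, noise_sd=0.0, n=10, ppm_fraction=0.5, seed=2)
    pmap = pairing_map(hit)
    assert {clone_to_mirna_position(c, pmap) for c in clones} == {10}
    assert {c.method for c in clones} == {"RLM5", "PPM3"}


def test_simulated_experiment_reproducible():
    a = simulate_experiment(SimulationSpec(seed=7))
    b = simulate_experiment(SimulationSpec(seed=7))
    assert [c.residues for c in a.contigs] == [c.residues for c in b.contigs]
    assert a.clones == b.clones
    assert [(r.residues, r.count) for r in a.control.reads] == [
        (r.residues, r.count) for r in b.control.reads
    ]
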