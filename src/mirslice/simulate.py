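"""Seeded synthetic data with the statistical structure the analysis assumes.

Every generator is a pure function of its parameters and a seed, so complete
experiments — two-condition read libraries with planted per-miRNA RPM and
fold-change ratios, contigs carrying planted precursor hairpins and target
sites with specified per-region mismatch/GU/gap patterns, and RACE clone sets
with a planted modal scission plus positional noise — are reproducible
byte-for-byte without any sequencing download.

Planted read counts are hit by deterministic (banker's) rounding rather than
multinomial sampling, so planned RPM values are realized exactly whenever
``rpm * depth / 1e6`` is an integer; filler background reads absorb the
remaining library depth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    ConfigurationError,
    CountedRead,
    MatureMiRNA,
    Sequence,
    reverse_complement,
)
from .quantify import ReadLibrary, RegulationClass, classify_regulation
from .cleavage import RaceClone
from .targets import (
    PairingState,
    Region,
    TargetHit,
    TargetScore,
    classify_pair,
    filter_candidate,
    region_of,
)

_BASES = "ACGU"
_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: mature/star sequences and library abundances of sweet potato miR408, the
#: wound-repressed miRNA this pipeline was built around (RPM unwounded/wounded)
MIR408_MATURE = "UGCACUGCCUCUUCCCUGGCU"
MIR408_STAR = "ACGGGGACGAGGCGGAGCAUG"
MIR408_RPM = (290.95, 197.04)
MIR408_STAR_RPM = (2.7, 3.77)

#: per-region (GU, mismatch) patterns of the three validated miR408 targets,
#: with the miRNA-coordinate cleavage position each one's RACE clones peak at
VALIDATED_TARGET_PATTERNS = {
    "KCS_like": ({"five_prime": (0, 1), "central": (0, 0), "three_prime": (0, 1)}, 10),
    "PCL_like": ({"five_prime": (0, 0), "central": (0, 0), "three_prime": (1, 2)}, 10),
    "GAUT_like": ({"five_prime": (1, 1), "central": (0, 0), "three_prime": (1, 1)}, 11),
}


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


# ---------------------------------------------------------------------------
# miRNA catalogs and read libraries
# ---------------------------------------------------------------------------

def make_mirnas(
    n: int,
    length: int = 21,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    overrides: list[MatureMiRNA] | None = None,
) -> list[MatureMiRNA]:
    """A catalog of ``n`` mature miRNAs; ``overrides`` are injected verbatim first."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    catalog = list(overrides or [])
    seen = {m.sequence for m in catalog}
    i = 0
    while len(catalog) < n:
        seq = random_rna(rng, length)
        if seq in seen:
            continue
        catalog.append(MatureMiRNA(id=f"syn-miR-{i:03d}", sequence=seq))
        seen.add(seq)
        i += 1
    return catalog


@dataclass(frozen=True)
class RpmPlan:
    """Planned control abundance and treated/control ratio for one miRNA.

    The ratio is carried at full precision; two-decimal figures are renderings.
    """

    mirna_id: str
    rpm_control: float
    ratio: float

    @classmethod
    def from_rpms(cls, mirna_id: str, rpm_control: float, rpm_treated: float) -> "RpmPlan":
        return cls(mirna_id, rpm_control, rpm_treated / rpm_control)

    def expected_class(
        self, lower: float = 0.8, upper: float = 1.2, min_rpm: float = 1.0
    ) -> RegulationClass:
        return classify_regulation(
            self.ratio, self.rpm_control, self.rpm_control * self.ratio,
            lower, upper, min_rpm,
        )


def _filler_reads(
    rng: np.random.Generator,
    remainder: int,
    forbidden: set[str],
    n_fillers: int = 50,
    length: int = 25,
) -> list[CountedRead]:
    if remainder <= 0:
        return []
    n_fillers = min(n_fillers, remainder)
    seqs: list[str] = []
    while len(seqs) < n_fillers:
        s = random_rna(rng, length)
        if s not in forbidden and s not in seqs:
            seqs.append(s)
    base, extra = divmod(remainder, n_fillers)
    return [
        CountedRead(residues=s, count=base + (1 if i < extra else 0))
        for i, s in enumerate(seqs)
    ]


def make_libraries(
    plans: list[RpmPlan],
    catalog: list[MatureMiRNA],
    depth: int = 1_000_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    names: tuple[str, str] = ("unwounded", "wounded"),
) -> tuple[ReadLibrary, ReadLibrary]:
    """Two-condition libraries whose realized RPM matches the plan by rounding.

    Control counts are ``round(rpm * depth / 1e6)`` (half-even); treated
    counts apply the plan's full-precision ratio before rounding.  Distinct
    filler reads absorb the rest of the depth in both conditions.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    seq_of = {m.id: m.sequence for m in catalog}
    control_reads: list[CountedRead] = []
    treated_reads: list[CountedRead] = []
    for plan in plans:
        if plan.mirna_id not in seq_of:
            raise ConfigurationError(f"plan references unknown miRNA {plan.mirna_id!r}")
        c = round(plan.rpm_control * depth / 1e6)
        t = round(plan.rpm_control * plan.ratio * depth / 1e6)
        if c:
            control_reads.append(CountedRead(seq_of[plan.mirna_id], c))
        if t:
            treated_reads.append(CountedRead(seq_of[plan.mirna_id], t))
    forbidden = set(seq_of.values())
    for reads, name in ((control_reads, names[0]), (treated_reads, names[1])):
        planned = sum(r.count for r in reads)
        if planned > depth:
            raise ConfigurationError(
                f"{name}: planned reads ({planned}) exceed library depth ({depth})"
            )
        reads.extend(_filler_reads(rng, depth - planned, forbidden))
    return (
        ReadLibrary(name=names[0], reads=control_reads),
        ReadLibrary(name=names[1], reads=treated_reads),
    )


# ---------------------------------------------------------------------------
# precursor contigs
# ---------------------------------------------------------------------------

@dataclass
class PlantedPrecursor:
    contig: Sequence
    mature_interval: tuple[int, int]  # 0-based half-open on the contig
    star: str  # the planted star strand, 5'->3', 2-nt 3' overhang register
    star_interval: tuple[int, int]


def _non_pairing_base(rng: np.random.Generator, mirna_base: str) -> str:
    choices = [
        b for b in _BASES if classify_pair(mirna_base, b) is PairingState.MISMATCH
    ]
    return str(rng.choice(choices))


def make_precursor_contig(
    mature: MatureMiRNA,
    stem_mismatches: int = 0,
    loop_length: int = 8,
    flank_length: int = 150,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    contig_id: str = "planted_precursor",
) -> PlantedPrecursor:
    """A contig carrying mature + loop + (mutated) star inside random flanks.

    Substitutions are placed at stem positions outside the central region
    (miRNA positions 9-11) and away from the duplex ends, so the register and
    loop-adjacent pairing survive.  The planted star follows the 2-nt 3'
    overhang convention: the arm segment shifted two bases toward the loop.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = mature.length
    if loop_length < 3:
        raise ConfigurationError("loop_length must be at least 3 (minimum hairpin loop)")
    eligible = [p for p in range(3, L - 1) if not 9 <= p <= 11]  # 1-based positions
    if stem_mismatches > L - 6 or stem_mismatches > len(eligible):
        raise ConfigurationError(
            f"{stem_mismatches} stem mismatches cannot be placed on a {L}-nt duplex"
        )
    arm = list(reverse_complement(mature.sequence))  # arm[L - p] pairs position p
    for p in rng.choice(eligible, size=stem_mismatches, replace=False):
        arm[L - int(p)] = _non_pairing_base(rng, mature.sequence[int(p) - 1])
    arm_seq = "".join(arm)
    flank5 = random_rna(rng, flank_length)
    loop = random_rna(rng, loop_length)
    flank3 = random_rna(rng, flank_length)
    residues = flank5 + mature.sequence + loop + arm_seq + flank3
    ms = flank_length
    rs = ms + L + loop_length
    star = (arm_seq + flank3)[2 : L + 2]
    return PlantedPrecursor(
        contig=Sequence(id=contig_id, residues=residues),
        mature_interval=(ms, ms + L),
        star=star,
        star_interval=(rs + 2, rs + L + 2),
    )


def dinucleotide_shuffle(
    seq: str, rng: np.random.Generator, max_tries: int = 1000
) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Rejection-sampled Eulerian walk on the dinucleotide transition multigraph;
    the walk is accepted only when it consumes every transition.
    """
    if len(seq) < 4:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    n_edges = len(seq) - 1
    for _ in range(max_tries):
        pools = {v: [lst[i] for i in rng.permutation(len(lst))] for v, lst in edges.items()}
        walk = [seq[0]]
        cur = seq[0]
        for _ in range(n_edges):
            pool = pools.get(cur)
            if not pool:
                break
            cur = pool.pop()
            walk.append(cur)
        if len(walk) == len(seq):
            return "".join(walk)
    raise RuntimeError("dinucleotide shuffle did not converge")


def shuffle_flanks(
    planted: PlantedPrecursor, rng: np.random.Generator
) -> Sequence:
    """Dinucleotide-shuffle everything around the mature match (star included).

    The exact mature match survives, so the contig still enters the precursor
    pipeline, but a qualifying duplex should only arise by chance.
    """
    ms, me = planted.mature_interval
    residues = planted.contig.residues
    left = dinucleotide_shuffle(residues[:ms], rng)
    right = dinucleotide_shuffle(residues[me:], rng)
    return Sequence(
        id=planted.contig.id + "_shuffled",
        residues=left + residues[ms:me] + right,
    )


# ---------------------------------------------------------------------------
# target contigs
# ---------------------------------------------------------------------------

_REGION_KEYS = {
    "five_prime": Region.FIVE_PRIME,
    "central": Region.CENTRAL,
    "three_prime": Region.THREE_PRIME,
}


@dataclass
class PlantedTarget:
    contig: Sequence
    site_interval: tuple[int, int]
    site: str
    expected: TargetScore


def build_site(
    mature: MatureMiRNA,
    events: list[tuple[str, int]],
    rng: np.random.Generator | None = None,
) -> str:
    """The target site (5'->3') pairing a miRNA with the given planted events.

    Events are ("GU" | "mismatch" | "gap", 1-based miRNA position).  A GU
    wobble is only constructible where the miRNA base is G or U (the pair is
    made by a pairing-preserving swap); a gap deletes the target base opposite
    the position.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    paired: list[str | None] = [_WC_PARTNER[b] for b in mature.sequence]
    used: set[int] = set()
    gaps = 0
    for kind, pos in events:
        if pos in used:
            raise ConfigurationError(f"two events at miRNA position {pos}")
        used.add(pos)
        m = mature.sequence[pos - 1]
        if kind == "GU":
            if m == "G":
                paired[pos - 1] = "U"
            elif m == "U":
                paired[pos - 1] = "G"
            else:
                raise ConfigurationError(
                    f"cannot plant a GU wobble opposite {m} at position {pos}"
                )
        elif kind == "mismatch":
            paired[pos - 1] = _non_pairing_base(rng, m)
        elif kind == "gap":
            gaps += 1
            if gaps > 1:
                raise ConfigurationError("at most one gap per planted site")
            paired[pos - 1] = None
        else:
            raise ConfigurationError(f"unknown event kind {kind!r}")
    return "".join(reversed([b for b in paired if b is not None]))


def _pattern_events(
    mature: MatureMiRNA,
    region_pattern: dict[str, tuple],
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    L = mature.length
    pools = {
        Region.FIVE_PRIME: list(range(1, 9)),
        Region.CENTRAL: list(range(9, 12)),
        Region.THREE_PRIME: list(range(12, L + 1)),
    }
    events: list[tuple[str, int]] = []
    for key, spec in region_pattern.items():
        region = _REGION_KEYS[key] if isinstance(key, str) else key
        gu, mm, *rest = spec
        gap = rest[0] if rest else 0
        pool = pools[region]
        gu_pool = [p for p in pool if mature.sequence[p - 1] in "GU"]
        if gu > len(gu_pool):
            raise ConfigurationError(
                f"cannot place {gu} GU wobbles in {region.value} of {mature.id}"
            )
        chosen_gu = [int(p) for p in rng.choice(gu_pool, size=gu, replace=False)]
        remaining = [p for p in pool if p not in chosen_gu]
        if mm + gap > len(remaining):
            raise ConfigurationError(
                f"pattern does not fit in {region.value} of {mature.id}"
            )
        chosen = [int(p) for p in rng.choice(remaining, size=mm + gap, replace=False)]
        events.extend(("GU", p) for p in chosen_gu)
        events.extend(("mismatch", p) for p in chosen[:mm])
        events.extend(("gap", p) for p in chosen[mm:])
    return events


def expected_score(
    mature: MatureMiRNA,
    events: list[tuple[str, int]],
    max_penalty: float = 3.0,
) -> TargetScore:
    """The score the penalty formula assigns to a planted event list."""
    counts = {r: [0, 0] for r in Region}
    penalty = 0.0
    gaps = 0
    for kind, pos in events:
        region = region_of(pos, mature.length)
        if kind == "GU":
            counts[region][0] += 1
            penalty += 0.5
        elif kind == "mismatch":
            counts[region][1] += 1
            penalty += 1.0
        else:
            gaps += 1
            penalty += 2.0
    score = TargetScore(
        penalty=penalty,
        region_counts={r: (gu, mm) for r, (gu, mm) in counts.items()},
        gap_count=gaps,
    )
    return filter_candidate(score, max_penalty)


def make_target_contig(
    mature: MatureMiRNA,
    region_pattern: dict[str, tuple],
    flank_length: int = 60,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    contig_id: str = "planted_target",
) -> PlantedTarget:
    """A contig with one planted target site realizing a per-region pattern.

    ``region_pattern`` maps region name to (GU count, mismatch count[, gaps]).
    The returned expected score is computed from the penalty formula, not from
    the scanner, so generator and scorer can be checked against each other.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    events = _pattern_events(mature, region_pattern, rng)
    site = build_site(mature, events, rng)
    flank5 = random_rna(rng, flank_length)
    flank3 = random_rna(rng, flank_length)
    return PlantedTarget(
        contig=Sequence(id=contig_id, residues=flank5 + site + flank3),
        site_interval=(flank_length, flank_length + len(site)),
        site=site,
        expected=expected_score(mature, events),
    )


# ---------------------------------------------------------------------------
# RACE clones
# ---------------------------------------------------------------------------

def make_race_clones(
    hit: TargetHit,
    true_position: int,
    noise_sd: float,
    n: int,
    ppm_fraction: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[RaceClone]:
    """``n`` RACE clones around a planted scission at a validated site.

    Each clone's scission is ``round(normal(true_position, noise_sd))``
    clipped to the duplex; endpoints follow the chemistry conventions (the
    RLM5 endpoint pairs position p, the PPM3 endpoint pairs p + 1).
    """
    L = hit.alignment.mirna.length
    if not 1 <= true_position < L:
        raise ValueError(f"true_position must lie in [1, {L - 1}]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    inv = {
        col.mirna_pos: hit.start + col.target_pos
        for col in hit.alignment.columns
        if col.mirna_pos is not None and col.target_pos is not None
    }
    valid = sorted(p for p in inv if p + 1 in inv and p >= 1)
    if not valid:
        raise ConfigurationError("site has no mappable scission positions")
    scissions = np.rint(rng.normal(true_position, noise_sd, size=n)).astype(int)
    is_ppm = rng.random(size=n) < ppm_fraction
    clones = []
    for s, ppm in zip(scissions, is_ppm):
        s = min(valid, key=lambda v: (abs(v - int(s)), v))  # clip to the site
        endpoint = inv[s + 1] if ppm else inv[s]
        clones.append(
            RaceClone(
                target_id=hit.contig_id,
                method="PPM3" if ppm else "RLM5",
                endpoint=endpoint,
                count=1,
            )
        )
    return clones


# ---------------------------------------------------------------------------
# whole experiments
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Parameters of a full synthetic wounding experiment.

    Defaults mirror the study conditions: a 20-entry catalog headed by the
    printed miR408 mature/star pair at their printed abundances, a library
    depth at which every printed RPM is an exact read count, one planted
    precursor contig, the three validated per-region target patterns, decoy
    and background contigs, and 50-clone RACE sets with unit positional noise.
    """

    seed: int = 0
    n_mirnas: int = 20
    mirna_length: int = 21
    library_depth: int = 100_000_000
    flank_length: int = 60
    n_central_decoys: int = 5
    n_high_penalty_decoys: int = 5
    n_background_contigs: int = 5
    background_length: int = 300
    precursor_stem_mismatches: int = 4
    precursor_loop: int = 8
    precursor_flank: int = 150
    race_n: int = 50
    race_sd: float = 1.0
    race_ppm_fraction: float = 0.5


@dataclass
class SimulatedExperiment:
    catalog: list[MatureMiRNA]
    plans: list[RpmPlan]
    control: ReadLibrary
    treated: ReadLibrary
    contigs: list[Sequence]
    planted_precursor: PlantedPrecursor
    planted_targets: dict[str, PlantedTarget]
    clones: dict[str, list[RaceClone]]
    race_true_positions: dict[str, int]


_CLASS_RATIO_RANGES = {
    RegulationClass.REPRESSED: (0.2, 0.65),
    RegulationClass.UNCHANGED: (0.95, 1.05),
    RegulationClass.INDUCED: (1.35, 2.5),
}


def default_plans(
    catalog: list[MatureMiRNA], rng: np.random.Generator
) -> list[RpmPlan]:
    """Printed abundances for the leading mature/star pair, spread classes for the rest."""
    plans = [
        RpmPlan.from_rpms(catalog[0].id, *MIR408_RPM),
        RpmPlan.from_rpms(catalog[1].id, *MIR408_STAR_RPM),
    ]
    classes = [
        RegulationClass.REPRESSED,
        RegulationClass.UNCHANGED,
        RegulationClass.INDUCED,
    ]
    for i, entry in enumerate(catalog[2:]):
        lo, hi = _CLASS_RATIO_RANGES[classes[i % 3]]
        plans.append(
            RpmPlan(
                mirna_id=entry.id,
                rpm_control=float(rng.integers(5, 500)),
                ratio=float(rng.uniform(lo, hi)),
            )
        )
    return plans


def simulate_experiment(spec: SimulationSpec) -> SimulatedExperiment:
    """Generate a complete synthetic experiment driving all four stages."""
    from .targets import scan_transcriptome

    rng = np.random.default_rng(spec.seed)
    overrides = [
        MatureMiRNA(id="Ib-miR408", sequence=MIR408_MATURE, star_sequence=MIR408_STAR),
        MatureMiRNA(id="Ib-miR408*", sequence=MIR408_STAR),
    ]
    catalog = make_mirnas(
        spec.n_mirnas, spec.mirna_length, rng=rng, overrides=overrides
    )
    plans = default_plans(catalog, rng)
    control, treated = make_libraries(
        plans, catalog, depth=spec.library_depth, rng=rng
    )
    mature = catalog[0]

    planted_precursor = make_precursor_contig(
        mature,
        stem_mismatches=spec.precursor_stem_mismatches,
        loop_length=spec.precursor_loop,
        flank_length=spec.precursor_flank,
        rng=rng,
    )
    contigs = [planted_precursor.contig]

    planted_targets: dict[str, PlantedTarget] = {}
    race_true_positions: dict[str, int] = {}
    for name, (pattern, true_pos) in VALIDATED_TARGET_PATTERNS.items():
        planted = make_target_contig(
            mature, pattern, flank_length=spec.flank_length, rng=rng, contig_id=name
        )
        planted_targets[name] = planted
        race_true_positions[name] = true_pos
        contigs.append(planted.contig)
    for i in range(spec.n_central_decoys):
        contigs.append(
            make_target_contig(
                mature,
                {"central": (0, 1), "three_prime": (0, 1)},
                flank_length=spec.flank_length,
                rng=rng,
                contig_id=f"decoy_central_{i}",
            ).contig
        )
    for i in range(spec.n_high_penalty_decoys):
        contigs.append(
            make_target_contig(
                mature,
                {"five_prime": (1, 1), "three_prime": (0, 2, 0)},
                flank_length=spec.flank_length,
                rng=rng,
                contig_id=f"decoy_weak_{i}",
            ).contig
        )  # penalty 3.5: just past the exclusion boundary
    for i in range(spec.n_background_contigs):
        contigs.append(
            Sequence(
                id=f"background_{i}",
                residues=random_rna(rng, spec.background_length),
            )
        )

    hits = {
        h.contig_id: h
        for h in scan_transcriptome(mature, contigs)
        if h.contig_id in planted_targets
    }
    clones = {
        name: make_race_clones(
            hits[name],
            race_true_positions[name],
            spec.race_sd,
            spec.race_n,
            spec.race_ppm_fraction,
            rng=rng,
        )
        for name in planted_targets
    }
    return SimulatedExperiment(
        catalog=catalog,
        plans=plans,
        control=control,
        treated=treated,
        contigs=contigs,
        planted_precursor=planted_precursor,
        planted_targets=planted_targets,
        clones=clones,
        race_true_positions=race_true_positions,
    )
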