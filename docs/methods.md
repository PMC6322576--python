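# Methods

This note documents the models, conventions and numerical choices behind
`mirslice`, and what the synthetic experiments do and do not establish.

## Sequence space and I/O

All comparison happens in RNA space: input is upper-cased and T→U mapped.
Transcriptome contigs may keep `N` (it never pairs and never matches a
read); ambiguity codes other than N are collapsed to N. Small-RNA reads must
be unambiguous A/C/G/U and must fall in a configurable length window,
default 18–26 nt — a 2-nt margin around the canonical 20–24 nt mature-miRNA
range so that edge-length variants are not silently discarded. Dropped reads
are counted in the log, never silently. Collapsed libraries use the common
`_x<count>` FASTA header convention.

## Quantification and regulation classes

Catalog assignment is exact full-length equality between a collapsed read
and a mature sequence. Length variants and single-nucleotide variants are
distinct reads: isomiR grouping is deliberately out of scope, because the
classification this pipeline feeds is defined on the canonical mature
sequence only. Two catalog entries sharing one sequence is a configuration
error (assignment would be ambiguous), not a warning.

RPM = count / library total × 10⁶. The treated/control ratio is kept at full
precision; two-decimal figures appear only in reports. Classes use strict
thresholds — induced > 1.2, repressed < 0.8 — so boundary ratios are
*unchanged*. A zero-control ratio is *undefined* rather than infinite, and a
miRNA below the abundance floor (default 1 RPM) in **both** conditions is
*undetermined*; the floor keeps low-count ratios (e.g. a star strand at a
few RPM) callable while suppressing pure-noise calls. No pseudocounts are
added anywhere.

## Precursor identification

Candidate loci are exact full-length matches of the mature sequence on
either strand of a contig; a window of 150 nt flank on each side (clipped at
contig ends) is extracted and folded. Plant precursors vary widely in size;
150 nt per side covers typical stems without folding whole contigs, and the
flank is configurable.

**Folding model.** `fold_window` computes a maximum-weight nested pairing
(no pseudoknots) by O(n³) dynamic programming: Watson–Crick pairs weigh 1.0,
G:U wobbles 0.8, hairpin loops span at least 3 unpaired bases. G:U pairs are
genuine stem pairs in plant precursors; the 0.8 discount keeps GU-saturated
spurious stems from outscoring Watson–Crick ones. No free-energy parameters
are used because the structure serves only as a binary gate plus star
identification; a thermodynamic backend can be swapped in behind the
`FoldResult` contract. The traceback is deterministic: the 5'-most pairable
position is paired whenever that preserves optimality, and among equally
optimal partners the one continuing the enclosing helix is preferred (ties
toward the 3' side), which favours contiguous stems over fragmented ones.
The fill and traceback are JIT-compiled with numba; a 320-nt window folds in
well under a second.

**Why the hairpin decision is duplex-centric.** A maximum-weight pairing of
a ~320-nt window is extremely degenerate: most bases can be paired somewhere,
so a base excluded from the true mature:star duplex is almost always paired
into the flanks at equal total weight. Concretely, forcing the full planted
duplex in a typical synthetic window costs about one weight unit relative to
the unconstrained optimum — the optimal fold *provably* scatters part of the
mature into the flanks, regardless of traceback. Judging the raw global
fold would therefore reject genuine precursors and accept promiscuous ones.
Instead, the fold gates the topology (the mature must be well paired, clear
of any terminal loop, and not paired within its own span), and the duplex is
then assessed at the best *register*: along an antiparallel duplex the sum
position + partner is constant, so every register that places a star segment
on one arm — separated from the mature by at least the minimum loop — is
scored by how many mature positions could pair (WC or G:U) at that register.
The best register wins; ties resolve toward the register the fold's own
mature pairings vote for. Acceptance then requires at least 60% of mature
positions pairable and at most 5 unpaired (both configurable). Against
dinucleotide-shuffled flank controls, a random register pairs a given
position with probability ≈ 6/16, so 16-of-21 pairable arises by chance in
well under 5% of shuffles — measured 2/100 at the default seed.

**Star prediction.** The star is the arm segment pairing the mature span,
shifted to the standard DCL1 geometry of 2-nt 3' overhangs on both strands:
for register R and mature span [ms, me) the star occupies [R−me+3, R−ms+3).
The overhang convention is the field's default duplex geometry; nothing in
the pipeline downstream depends on the exact overhang.

## Target prediction

Penalty scoring is additive over duplex columns: mismatch 1, G:U 0.5, gap 2,
match 0. Region boundaries follow the miRNA coordinate: 5' = 1–8, central =
9–11, 3' = 12–L. The candidate filter excludes a site iff penalty > 3 or the
central region contains a mismatch. A central G:U does **not** exclude —
only a central *mismatch* is disqualifying — though it still contributes
0.5; published examples never disambiguate this case (validated sites all
have clean central regions), so the permissive reading was chosen and is
configurable in principle via the scoring table.

Alignment is global, miRNA 5'→3' against the reverse-oriented site, at most
one gap (default): with gaps costing 2 against a cutoff of 3, two gaps can
never yield a candidate, so the search space is exactly the ungapped
register plus every single-gap placement, minimized exactly (a degenerate
banded alignment DP). Ties prefer fewer gaps, then push penalized columns
toward the miRNA 3' end — the region where plant duplexes tolerate damage.
Gap columns lacking a miRNA base take the region of the 5'-flanking miRNA
position (position 1 for a leading gap); the convention is unconstrained by
any validated gap-free site and is documented rather than load-bearing.

Scanning slides windows of length L−1, L, L+1 along the sense strand
(contigs are oriented transcripts; `both_strands=True` exists for unoriented
assemblies), prefilters each window with an O(L) exact minimum-penalty
computation, keeps candidates, collapses overlapping candidates to the best
per locus (minimum penalty, then longest, then leftmost — one site per
locus, as targets are reported per gene), and sorts by penalty. Seed-region
weighting schemes used by some predictors are deliberately not applied: the
published penalties (2, 2.5, 3) are exactly the unweighted sums of the
stated unit costs.

## Cleavage mapping

Naming convention: "cleaved at the k-th nucleotide" means the scission
between the target bases pairing miRNA positions k and k+1, reported as k.
An RLM5 endpoint (5'-most base of the 3' fragment) pairs k and maps
directly; a PPM3 endpoint (3'-most base of the 5' fragment) pairs k+1 and is
normalized down by one, making the two chemistries tally into one
distribution. Endpoints outside the validated site are counted as unmapped
and logged, never dropped silently. The modal call breaks ties toward the
canonical slicer position 10, then toward the smaller position; the
canonical preference encodes standard AGO geometry and is configurable.

## Synthetic data

The generator emulates, deterministically under a seed:

- **Libraries** with planned per-miRNA control RPM and treated/control
  ratios. Counts are deterministic (banker's) rounding of rpm × depth / 10⁶,
  so planned RPM is realized *exactly* whenever that product is an integer;
  distinct filler reads (25 nt, never colliding with the catalog) absorb the
  rest of the depth. Plans carry full-precision ratios — e.g. a published
  pair 290.95 → 197.04 RPM is planned as ratio 197.04/290.95 ≈ 0.6772, which
  reports as 0.68 at two decimals. The reference fixture uses a depth of
  10⁸ reads, the smallest power of ten at which every published RPM in the
  abundance table (including 2.7 and 3.77) is an integer count; the default
  20-entry catalog spreads the remaining miRNAs over the three regulation
  classes with ratios kept ≥ 0.15 away from the thresholds so rounding can
  never flip a planted class.
- **Precursor contigs**: 5' flank + mature + loop (default 8 nt) + mutated
  reverse complement of the mature + 3' flank. Stem substitutions go to
  non-central positions away from the duplex ends so register and
  loop-adjacent pairing survive; the planted star records the 2-nt overhang
  register. Dinucleotide-shuffled flank controls (Eulerian-walk shuffle,
  composition-preserving) supply the negative class.
- **Target contigs** realizing per-region GU/mismatch/gap patterns by
  pairing-preserving or pairing-breaking substitutions of the site; the
  expected score is computed from the penalty formula, independently of the
  scanner, so generator and scorer cross-check each other.
- **RACE clone sets**: each clone's scission is round(normal(true, sd))
  clipped to the duplex, with endpoints derived per the chemistry
  conventions and an RLM5/PPM3 mix.

What the generator does **not** emulate: sequencing error, adapter
artefacts, isomiR clouds, expression time courses, non-uniform transcript
coverage, or paralogous precursor families. Passing tests therefore
demonstrate the *algorithms* recover planted structure under the stated
noise, not that real libraries are free of upstream artefacts.

## Known limitations and one honest miss

- The fold is a maximum-pairing model, not a thermodynamic one; its role is
  gating and star identification only, and the duplex-register evaluation
  above exists precisely because the global optimum of this model is
  degenerate on long windows.
- Cleavage-recovery arithmetic: with scission noise round(normal(p, 1)) the
  true position carries only ≈ 38% of the clone mass (each neighbour ≈ 24%),
  so at 50 clones the modal call matches the planted position in ≈ 85–86% of
  replicate draws (independent Monte-Carlo, 50 000 replicates); ≥ 95%
  recovery is first reached near 100 clones. The end-to-end check that
  demands ≥ 95% at 50 clones fails for this arithmetic reason — the
  generator's conditions were kept as stated rather than quietly increasing
  the clone count or shrinking the noise.
- Problem sizes in the test suite are chosen for exactness, not scale:
  fold-optimality is verified exhaustively on windows ≤ 60 nt (the oracle is
  O(n³) recursion), aligner equivalence on contigs ≤ 200 nt over 30 seeds,
  and the filter sweep enumerates all 1- and 2-event patterns on a 21-mer.
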