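# Methods

## Structure model

`hknot` predicts a single H-type pseudoknot per sequence: two crossing
stems (core pairs `(i, j)` and `(k, l)`, `i < k < j < l`), each possibly
extended by stacked pairs with at most a small number of bulge/internal-loop
interruptions, plus at most one hairpin stem-loop per pseudoknot loop.
Anything outside this family — kissing hairpins, multibranch loops,
higher-order (K/L/M-type) pseudoknots, multiple pseudoknots per
sequence — is out of scope by design. Structures are represented as sets
of 1-based base pairs in two bracket layers: the ROUND layer (`()`)
holds stem 1, its extensions and all hairpins; the SQUARE layer (`[]`)
holds stem 2 and its extensions. Each layer is internally non-crossing,
so extended dot-bracket rendering is unambiguous and round-trips.

Base pairing admits A-U, G-C and the G-U wobble pair; wobble can be
disabled (`PairingRule.watson_crick_only()`, CLI `--no-gu`).

## Pipeline stages and their parameters

**Candidate enumeration.** All quadruples `i < k < j < l` with both
pairs complementary and segment minima: left loop (`i+1..k-1`) ≥ 1 nt,
middle (`k+1..j-1`) ≥ 0 nt, right loop (`j+1..l-1`) ≥ 1 nt. The middle
minimum must stay 0 — the two core pairs may be directly adjacent, as in
the worked 22-nt example where `j = 8` abuts `k = 7`. Enumeration runs
over per-position partner lists; the suite checks exact set-equality
against a four-nested-loop oracle up to length 30. Loop boundaries are
strictly exclusive (`i+1..k-1`, `j+1..l-1`); descriptions that include a
stem-adjacent paired position in the "loop" are treated as off-by-one.

**Decoration.** Stem 2 is extended first (left-loop bases paired with
right-flank bases), then stem 1 (left-flank bases with right-loop
bases); the regions are disjoint, so the order matters only for trace
output. Each extension step moves one base outward on both sides; when
the adjacent bases cannot pair, an interruption may skip up to
`max_gap = 2` bases per side (one interruption per stem by default).
These defaults keep the search tiny while covering the common
single-bulge case; both are configurable. The chosen extension set is
the per-stem maximum-pair set under those limits, found by a small
memoized search whose tie-breaks reproduce plain greedy stacking
(prefer pairing adjacent bases, then the smallest gap). A pure greedy
scan is almost always identical but can be beaten by one pair in rare
letter arrangements; the maximization keeps the stage equal to its
brute-force oracle, which the suite asserts on random ≤ 30-nt instances.

**Max-pairs filter.** Candidates within `stem_slack = 2` of the maximum
decorated pair count proceed (e.g. a maximum of 9 admits 7+), sorted by
ascending energy; `top_k` can cap the survivor list (default: no cap).
"Stems" throughout means base-pair count.

**Hairpin search.** Hairpin stems are contiguous stacks — the motif
grammar's pair productions generate stacked pairs only, so bulged
hairpin stems are excluded. The unconstrained grammar would accept
single-pair stems and zero-length loops; the imposed minima
(`min_hairpin_stem = 2` pairs, `min_hairpin_loop = 3` nt) match both
steric reality and the worked example's hairpin (stem 2, loop 3). Within
each maximal unpaired run of each loop, the best hairpin is chosen by:
most stem pairs, then smallest loop, then **lowest stacking energy**,
then leftmost opening. The energy tie-break is load-bearing: in the
worked example's right loop `CAUAGCAUAA`, stems `(11,17),(12,16)` and
`(12,18),(13,17)` tie at 2 pairs / 3-nt loop, and the latter wins
because its 5'UA3'/3'AU5' stack (-1.33 kcal/mol) is more stable than
5'AU3'/3'UA5' (-1.10); a position-based tie-break alone would pick the
other stem. One hairpin per loop at most, giving the 1/2/4 variants per
candidate (without hairpins, each side alone, both).

**Final selection.** Among all variants of all survivors: strict
maximum total pair count, then minimum energy, then lexicographically
smallest dot-bracket. The slack applies only to which candidates enter
hairpin search, not to the final pair-count criterion — with any energy
model in which a small hairpin has positive net cost (loop initiation
exceeding two stack terms), a within-slack final rule would always
discard hairpins in favor of the hairpin-free variant and the method
could never emit one.

## Energy model

The score is a simplified nearest-neighbor free energy:

    E = Σ stacking terms (adjacent pairs within each stem)
      + hairpin-loop initiation per hairpin
      + pseudoknot penalty (default +7.0 kcal/mol)
      + 0.1 kcal/mol per unpaired base left in the pseudoknot loops

Watson-Crick-on-Watson-Crick stacks use the standard Turner ΔG°₃₇
constants (−0.93 to −3.42 kcal/mol); stacks involving a G-U wobble use
flat surrogate values (−1.2 with a Watson-Crick neighbor, −0.5 between
two wobbles). All stack terms are ≤ 0 and all penalties ≥ 0, so adding
a stacked pair never raises the energy — selection stays consistent
with the max-pairs criterion. Hairpin-loop costs are tabulated from
5.4 kcal/mol (3-nt loop) upward, monotone non-decreasing, with
logarithmic extrapolation past 30 nt. Pairs separated by a bulge or
internal loop contribute no stacking term across the gap and no extra
penalty. Bases in a hairpin loop are covered by the hairpin term and
excluded from the per-base loop cost.

This model is a deliberate stand-in for a full thermodynamic evaluator:
selection is driven primarily by pair count, and energy only ranks
near-maximal variants, so a monotone stacking-aware surrogate preserves
the pipeline's decisions while keeping the package self-contained
(no dangles, no coaxial stacking, no temperature dependence). The
parameter tables ship as TSV (`src/hknot/data/`) and the whole evaluator
is replaceable by any `(variant, sequence) -> float` callable.

## Synthetic fixtures

The generator plants a pseudoknot of known geometry: flanks (2 nt),
stem 1 (3 pairs), left loop (6 nt), stem 2 (3 pairs), right loop
(12 nt), optional hairpins per loop, optional bulge inside one stem —
about 34–37 nt total, the size class of small viral pseudoknots and of
the pipeline's worked example. Recoverability is engineered, not
assumed: stem and hairpin letters are drawn from G-C pairs only and all
filler is A, so filler can pair with nothing (the sequence contains no
U, and A-C is not an allowed pair), and the letter draw is
rejection-sampled (up to 64 attempts) until no accidental complementary
run of ≥ 3 pairs exists outside ± 1 of the planted registers. Two-pair
accidental runs are unavoidable in a two-letter complementary alphabet
(every draw has many) and are tolerated. The recovery suite uses 50
fixtures — hairpin on the right loop (even seeds) or on both loops (odd
seeds) — and requires both core stems recovered under the ±1
displacement tolerance in ≥ 90%; measured recovery at these settings is
48/50. The two misses are draws where a residual two-pair run lets an
interruption-stitched rival stem tie the planted pair count and win on
energy — the known, accepted failure mode.

What passing these fixtures does **not** show: real pseudoknots have
heterogeneous loop composition, competing near-isoenergetic stems and
non-canonical pairs, so recovery here measures pipeline correctness
(register and geometry recovery under benign letter statistics), not
field accuracy on natural sequences.

## Evaluation conventions

Confusion counts compare pair sets irrespective of layer: `tp` predicted
∩ reference, `fp` predicted only, `fn` reference only. True negatives at
base-pair level have no canonical definition; the convention here is the
number of positions unpaired in both structures, which yields magnitudes
comparable to published per-dataset counts. PPV, recall, F1 and MCC
follow the standard formulas; any zero denominator reports 0.0 with an
`*_defined = False` flag rather than NaN. Core-stem matching accepts a
predicted pair displaced by one position in exactly one coordinate —
`(k±1, l)` or `(k, l±1)` but not `(k±1, l±1)`.

## Numerical and determinism notes

Everything is integer/float arithmetic on tiny structures; no
optimization or iteration is involved. Determinism is enforced at every
choice point: candidates sort by `(i, k, j, l)`, decoration tie-breaks
prefer stacking then smallest gaps, hairpin ranking ends at leftmost
opening, final selection ends at the lexicographically smallest
dot-bracket. Degenerate inputs are values, not errors: a sequence with
no crossing complementary pairs returns an all-dots "no pseudoknot
detected" result with energy 0.

## Known limitations

- One pseudoknot, one hairpin per loop; no nested-only global folding.
- The energy surrogate ranks stacks sensibly but its absolute values are
  not comparable to laboratory ΔG measurements.
- Candidate enumeration is O(n²)–O(n⁴) in sequence length and intended
  for desk-scale inputs (tens to a few hundred nt), not genome scans.
- BPSEQ export only; no CT-format support.
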