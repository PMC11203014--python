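"""Stage 4 — hairpin stem-loops inside the pseudoknot loops.

A hairpin is a contiguous stack of complementary pairs enclosing a loop
of unpaired bases, the structure generated by the motif grammar

    S -> L P R        P -> 'x' P 'y'   (x-y one of a-u, u-a, g-c, c-g, g-u, u-g)
    P -> M            L, R, M -> K     K -> base K | epsilon

restricted by two minima the bare grammar lacks: at least
``min_hairpin_stem`` stacked pairs and at least ``min_hairpin_loop``
unpaired loop bases (the unconstrained productions would accept
degenerate single-pair or zero-loop "hairpins").

Among admissible hairpins in a span, the best is the one with the
longest stem, then the smallest loop, then the lowest stacking energy,
then the leftmost opening.  The energy tie-break matters: on the worked
decoration example two stems of equal length and loop size compete in
the right loop, and the lower-energy stack is the one the method keeps.
For each decorated candidate, up to one hairpin per pseudoknot loop is
considered, giving 1, 2 or 4 structure variants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .decoration import DecoratedCandidate
from .energy import StackTable, stack_energy
from .params import PairingRule, TuningParams
from .sequence_io import Layer, RnaSequence, SecondaryStructure

__all__ = ["Side", "HairpinMatch", "StructureVariant", "find_hairpin", "make_variants"]

Pair = Tuple[int, int]


class Side(enum.Enum):
    LEFT_LOOP = "left"
    RIGHT_LOOP = "right"


@dataclass(frozen=True)
class HairpinMatch:
    """A stacked hairpin stem and its loop, inside one pseudoknot loop.

    ``stem_pairs`` is ordered outermost-first: (a, b), (a+1, b-1), ...
    ``flank_left`` / ``flank_right`` are the unpaired parts of the search
    span outside the stem (the L and R sides of the motif).
    """

    stem_pairs: Tuple[Pair, ...]
    loop_span: range
    flank_left: range
    flank_right: range
    side: Optional[Side] = None

    @property
    def n_pairs(self) -> int:
        return len(self.stem_pairs)


@dataclass
class StructureVariant:
    """A decorated candidate with an optional hairpin per loop."""

    base: DecoratedCandidate
    left_hairpin: Optional[HairpinMatch] = None
    right_hairpin: Optional[HairpinMatch] = None
    energy: Optional[float] = None

    @property
    def total_pairs(self) -> int:
        n = self.base.pair_count
        for h in (self.left_hairpin, self.right_hairpin):
            if h is not None:
                n += h.n_pairs
        return n

    def all_pairs(self) -> List[Pair]:
        pairs = self.base.all_pairs()
        for h in (self.left_hairpin, self.right_hairpin):
            if h is not None:
                pairs.extend(h.stem_pairs)
        return pairs

    def hairpin_pairs(self) -> List[Pair]:
        pairs: List[Pair] = []
        for h in (self.left_hairpin, self.right_hairpin):
            if h is not None:
                pairs.extend(h.stem_pairs)
        return sorted(pairs)

    def to_structure(self, length: int) -> SecondaryStructure:
        """Render as a two-layer structure: stem 1 + hairpins ROUND, stem 2 SQUARE."""
        pairs = {p: Layer.ROUND for p in self.base.stem1_pairs}
        pairs.update({p: Layer.SQUARE for p in self.base.stem2_pairs})
        for h in (self.left_hairpin, self.right_hairpin):
            if h is not None:
                for p in h.stem_pairs:
                    pairs[p] = Layer.ROUND
        return SecondaryStructure(length=length, pairs=pairs)


def find_hairpin(
    span: range,
    seq: RnaSequence,
    rule: PairingRule | None = None,
    params: TuningParams | None = None,
    stack_table: StackTable | None = None,
    side: Optional[Side] = None,
) -> Optional[HairpinMatch]:
    """Best hairpin whose bases all lie within ``span``, or None.

    ``span`` must be a contiguous run of currently unpaired positions.
    Ranking: most stem pairs, then smallest loop, then lowest stacking
    energy, then leftmost opening.
    """
    params = params or TuningParams()
    rule = rule or params.rule
    min_loop, min_stem = params.min_hairpin_loop, params.min_hairpin_stem
    if len(span) < 2 * min_stem + min_loop:
        return None
    lo, hi = span[0], span[-1]
    best: tuple | None = None
    best_match: Optional[HairpinMatch] = None
    for a in range(lo, hi + 1):
        for b in range(a + 2 * min_stem + min_loop - 1, hi + 1):
            depth = 0
            while (
                rule.pairs(seq.base(a + depth), seq.base(b - depth))
                and (b - depth) - (a + depth) - 1 >= min_loop
            ):
                depth += 1
            if depth < min_stem:
                continue
            stem = tuple((a + t, b - t) for t in range(depth))
            loop_len = (b - depth) - (a + depth) + 1
            energy = stack_energy(stem, seq, stack_table)
            key = (-depth, loop_len, energy, a)
            if best is None or key < best:
                best = key
                best_match = HairpinMatch(
                    stem_pairs=stem,
                    loop_span=range(a + depth, b - depth + 1),
                    flank_left=range(lo, a),
                    flank_right=range(b + 1, hi + 1),
                    side=side,
                )
    return best_match


def _best_hairpin_in_loop(
    loop: range,
    paired: set,
    seq: RnaSequence,
    rule: PairingRule,
    params: TuningParams,
    stack_table: StackTable | None,
    side: Side,
) -> Optional[HairpinMatch]:
    """Best hairpin over the maximal unpaired runs of one pseudoknot loop."""
    runs: List[range] = []
    start = None
    for pos in loop:
        if pos not in paired:
            if start is None:
                start = pos
        elif start is not None:
            runs.append(range(start, pos))
            start = None
    if start is not None:
        runs.append(range(start, loop[-1] + 1))

    best: Optional[HairpinMatch] = None
    best_key: tuple | None = None
    for run in runs:
        match = find_hairpin(run, seq, rule, params, stack_table, side)
        if match is None:
            continue
        key = (
            -match.n_pairs,
            len(match.loop_span),
            stack_energy(match.stem_pairs, seq, stack_table),
            match.stem_pairs[0][0],
        )
        if best_key is None or key < best_key:
            best, best_key = match, key
    return best


def make_variants(
    decorated: DecoratedCandidate,
    seq: RnaSequence,
    rule: PairingRule | None = None,
    params: TuningParams | None = None,
    stack_table: StackTable | None = None,
) -> List[StructureVariant]:
    """The 1, 2 or 4 variants of a candidate: each loop with/without its hairpin.

    The hairpin-free variant is always present; a side contributes only
    if its loop admits a hairpin.  Hairpin pairs nest inside the loops
    and never cross the candidate's pairs (asserted).
    """
    params = params or TuningParams()
    rule = rule or params.rule
    core = decorated.core
    paired = {x for p in decorated.all_pairs() for x in p}

    left = _best_hairpin_in_loop(
        core.left_loop(), paired, seq, rule, params, stack_table, Side.LEFT_LOOP
    )
    right = _best_hairpin_in_loop(
        core.right_loop(), paired, seq, rule, params, stack_table, Side.RIGHT_LOOP
    )

    for match in (left, right):
        if match is None:
            continue
        for a, b in match.stem_pairs:
            for i, j in decorated.all_pairs():
                assert not (i < a < j < b or a < i < b < j), (
                    f"hairpin pair ({a},{b}) crosses candidate pair ({i},{j})"
                )

    variants = [StructureVariant(base=decorated)]
    if right is not None:
        variants.append(StructureVariant(base=decorated, right_hairpin=right))
    if left is not None:
        variants.append(StructureVariant(base=decorated, left_hairpin=left))
    if left is not None and right is not None:
        variants.append(
            StructureVariant(base=decorated, left_hairpin=left, right_hairpin=right)
        )
    return variants
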