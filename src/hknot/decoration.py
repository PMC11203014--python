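"""Stage 2 — decorate core stems with outward stacked extensions.

Each core pair is extended outward one step at a time: stem 1 pairs
flank-left bases (positions < i) with right-loop bases, stem 2 pairs
left-loop bases with flank-right bases (positions > l), mirroring the
directionality of the worked decoration example.  When stacking fails,
an interruption may skip up to ``max_gap`` unpaired bases on either or
both sides (a bulge if one side, an internal loop if both), at most
``max_interruptions`` times per stem, after which extension resumes.

The per-stem extension set chosen is the one that maximizes the number
of added pairs under those gap limits.  The search is a small memoized
recursion whose tie-breaks reproduce plain greedy stacking: at equal
pair count it prefers pairing the adjacent bases over skipping, then the
smallest total gap, then the smallest gap on the opening side.  Stem 2
is extended before stem 1; their index regions are disjoint, so the
order only fixes the reporting/trace order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .core_stems import CoreStemCandidate
from .params import PairingRule, TuningParams
from .sequence_io import RnaSequence

__all__ = ["DecoratedCandidate", "decorate"]

Pair = Tuple[int, int]


@dataclass(frozen=True)
class DecoratedCandidate:
    """A core candidate plus its outward stem extensions.

    ``stem1_pairs`` / ``stem2_pairs`` are ordered core-first (outward);
    ``interruptions`` maps stem number (1 or 2) to the (open-side gap,
    close-side gap) of each interruption taken, in extension order.
    """

    core: CoreStemCandidate
    stem1_pairs: Tuple[Pair, ...]
    stem2_pairs: Tuple[Pair, ...]
    interruptions: Dict[int, Tuple[Tuple[int, int], ...]] = field(default_factory=dict)

    @property
    def pair_count(self) -> int:
        return len(self.stem1_pairs) + len(self.stem2_pairs)

    def all_pairs(self) -> List[Pair]:
        return list(self.stem1_pairs) + list(self.stem2_pairs)


def _extend_stem(
    seq: str,
    start_open: int,
    start_close: int,
    open_min: int,
    close_max: int,
    rule: PairingRule,
    max_gap: int,
    max_interruptions: int,
) -> Tuple[List[Pair], List[Tuple[int, int]]]:
    """Maximal outward extension from (start_open, start_close) exclusive.

    Opens walk down to ``open_min``, closes walk up to ``close_max``.
    Returns the added pairs (outward order) and the gaps taken.
    """
    # gap options in greedy preference order: stack first, then smallest gaps
    gap_options = sorted(
        ((go, gc) for go in range(max_gap + 1) for gc in range(max_gap + 1)
         if (go, gc) != (0, 0)),
        key=lambda g: (g[0] + g[1], g[0]),
    )
    memo: Dict[Tuple[int, int, int], Tuple[int, Tuple[int, int] | None]] = {}

    def best(o: int, c: int, ints: int) -> int:
        """Max pairs addable with next open candidate o, close candidate c."""
        key = (o, c, ints)
        if key in memo:
            return memo[key][0]
        best_count, best_choice = 0, None
        choices = [(0, 0)] + (gap_options if ints > 0 else [])
        for go, gc in choices:
            oo, cc = o - go, c + gc
            if oo < open_min or cc > close_max:
                continue
            if not rule.pairs(seq[oo - 1], seq[cc - 1]):
                continue
            cnt = 1 + best(oo - 1, cc + 1, ints - (1 if (go, gc) != (0, 0) else 0))
            if cnt > best_count:
                best_count, best_choice = cnt, (go, gc)
        memo[key] = (best_count, best_choice)
        return best_count

    pairs: List[Pair] = []
    gaps: List[Tuple[int, int]] = []
    o, c, ints = start_open - 1, start_close + 1, max_interruptions
    best(o, c, ints)
    while True:
        _, choice = memo[(o, c, ints)]
        if choice is None:
            break
        go, gc = choice
        oo, cc = o - go, c + gc
        pairs.append((oo, cc))
        if (go, gc) != (0, 0):
            gaps.append((go, gc))
            ints -= 1
        o, c = oo - 1, cc + 1
    return pairs, gaps


def decorate(
    core: CoreStemCandidate,
    seq: RnaSequence,
    rule: PairingRule | None = None,
    params: TuningParams | None = None,
) -> DecoratedCandidate:
    """Extend both core stems outward; never removes core pairs.

    A core whose flanks cannot pair decorates to itself (pair_count 2).
    """
    params = params or TuningParams()
    rule = rule or params.rule
    s = seq.residues
    n = len(s)
    i, k, j, l = core.i, core.k, core.j, core.l

    # stem 2 first: opens in the left loop (> i), closes in the right flank (<= n)
    ext2, gaps2 = _extend_stem(
        s, k, l, open_min=i + 1, close_max=n,
        rule=rule, max_gap=params.max_gap, max_interruptions=params.max_interruptions,
    )
    # stem 1: opens in the left flank (>= 1), closes in the right loop (< l)
    ext1, gaps1 = _extend_stem(
        s, i, j, open_min=1, close_max=l - 1,
        rule=rule, max_gap=params.max_gap, max_interruptions=params.max_interruptions,
    )

    interruptions: Dict[int, Tuple[Tuple[int, int], ...]] = {}
    if gaps1:
        interruptions[1] = tuple(gaps1)
    if gaps2:
        interruptions[2] = tuple(gaps2)
    return DecoratedCandidate(
        core=core,
        stem1_pairs=((i, j),) + tuple(ext1),
        stem2_pairs=((k, l),) + tuple(ext2),
        interruptions=interruptions,
    )
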