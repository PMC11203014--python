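"""Stage 1 — enumerate candidate core-stem skeletons of an H-type pseudoknot.

An H-type pseudoknot is defined by two crossing base pairs, the *core
stems*: pair 1 ``(i, j)`` and pair 2 ``(k, l)`` with ``i < k < j < l``.
Pair 1 is rendered in the ROUND layer, pair 2 in the SQUARE layer.  The
candidate set contains every quadruple satisfying the crossing condition,
the pairing rule at both pairs, and the configurable minimum lengths of
the three skeleton segments (left loop, middle, right loop).

Enumeration over partner lists is the normative backend; its output is
exactly the set a four-nested-loop scan produces, which the test suite
checks against an independent brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

from .params import PairingRule, TuningParams
from .sequence_io import RnaSequence

__all__ = ["CoreStemCandidate", "enumerate_core_candidates", "count_candidates"]


@dataclass(frozen=True, order=True)
class CoreStemCandidate:
    """The two crossing core base pairs (i,j) and (k,l) with i < k < j < l."""

    i: int
    k: int
    j: int
    l: int

    def __post_init__(self) -> None:
        if not (self.i < self.k < self.j < self.l):
            raise ValueError(
                f"core pairs ({self.i},{self.j}) and ({self.k},{self.l}) do not cross"
            )

    @property
    def pair1(self) -> Tuple[int, int]:
        """Core stem 1 (ROUND layer)."""
        return (self.i, self.j)

    @property
    def pair2(self) -> Tuple[int, int]:
        """Core stem 2 (SQUARE layer)."""
        return (self.k, self.l)

    def left_loop(self) -> range:
        """Positions strictly between the two stem openings: (i+1 .. k-1)."""
        return range(self.i + 1, self.k)

    def right_loop(self) -> range:
        """Positions strictly between the two closings: (j+1 .. l-1)."""
        return range(self.j + 1, self.l)

    def middle(self) -> range:
        """Positions strictly between k and j (may be empty)."""
        return range(self.k + 1, self.j)


def enumerate_core_candidates(
    seq: RnaSequence,
    rule: PairingRule | None = None,
    params: TuningParams | None = None,
) -> List[CoreStemCandidate]:
    """All core-stem candidates for ``seq``, sorted by (i, k, j, l).

    A candidate requires ``i < k < j < l``, both pairs allowed by ``rule``,
    and segment minima ``len(i+1..k-1) >= min_left_loop``,
    ``len(k+1..j-1) >= min_middle``, ``len(j+1..l-1) >= min_right_loop``.
    Sequences too short to host any candidate yield an empty list.
    """
    params = params or TuningParams()
    rule = rule or params.rule
    s = seq.residues
    n = len(s)
    # partner[x] = sorted positions y > x with (s[x], s[y]) allowed (1-based)
    partner: List[List[int]] = [[] for _ in range(n + 1)]
    for x in range(1, n + 1):
        bx = s[x - 1]
        partner[x] = [y for y in range(x + 1, n + 1) if rule.pairs(bx, s[y - 1])]

    min_l, min_m, min_r = params.min_left_loop, params.min_middle, params.min_right_loop
    out: List[CoreStemCandidate] = []
    for i in range(1, n + 1):
        for j in partner[i]:
            # k ranges over (i + min_l + 1 .. j - min_m - 1), l over (j + min_r + 1 .. n)
            k_lo, k_hi = i + min_l + 1, j - min_m - 1
            if k_hi < k_lo:
                continue
            for k in range(k_lo, k_hi + 1):
                for l in partner[k]:
                    if l > j + min_r:
                        out.append(CoreStemCandidate(i=i, k=k, j=j, l=l))
    out.sort()
    return out


def count_candidates(
    seq: RnaSequence,
    rule: PairingRule | None = None,
    params: TuningParams | None = None,
) -> int:
    """Number of core-stem candidates (diagnostics)."""
    return len(enumerate_core_candidates(seq, rule, params))
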