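"""Planted-pseudoknot fixture generator.

Builds a sequence with a known H-type pseudoknot — two crossing stems of
configurable length, loops of configurable length, optional hairpins in
either loop and an optional bulge interrupting one stem — together with
its ground-truth structure.  This emulates the shape class of curated
pseudoknot benchmarks in which hairpins sit on one or both sides of the
core stems.

Recoverability by construction is best-effort: by default, stem and
hairpin letters are drawn from G-C pairs only and loop/flank filler is
all A, so filler can pair with nothing (no U in the sequence means A has
no partner, and A-C is not an allowed pair); accidental complementary
runs can then only arise between stem letters of different units, and
the generator redraws letters (up to a fixed number of attempts) until
no such competing run of stem length remains, keeping the draw with the
fewest competitors otherwise.  Set ``stem_pairs`` to all four
Watson-Crick pairs and ``filler_alphabet`` to the full alphabet for
adversarial fixtures without these guarantees.  Generation is
deterministic for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .core_stems import CoreStemCandidate
from .sequence_io import Layer, RnaSequence, SecondaryStructure

__all__ = ["FixtureSpec", "generate", "planted_core"]

WC_PAIRS = (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"))
GC_PAIRS = (("G", "C"), ("C", "G"))

_ALLOWED = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_REDRAW_ATTEMPTS = 64


@dataclass(frozen=True)
class FixtureSpec:
    """Blueprint of a planted pseudoknot.

    ``hairpin_left`` / ``hairpin_right`` are (stem pairs, loop nt) tuples;
    a hairpin requires its loop to satisfy
    ``loop_len >= 2*stem + loop + 2`` (one unpaired flank base on each
    side).  ``bulge`` = (stem number 1|2, gap nt) inserts ``gap`` filler
    bases after the outermost opening base of that stem.
    """

    seed: int
    stem1_len: int = 3
    stem2_len: int = 3
    left_loop_len: int = 6
    right_loop_len: int = 12
    hairpin_left: Optional[Tuple[int, int]] = None
    hairpin_right: Optional[Tuple[int, int]] = None
    bulge: Optional[Tuple[int, int]] = None
    flank_len: int = 2
    filler_alphabet: str = "A"
    stem_pairs: Tuple[Tuple[str, str], ...] = GC_PAIRS

    def __post_init__(self) -> None:
        if min(self.stem1_len, self.stem2_len) < 1:
            raise ValueError("stems need at least one pair")
        if min(self.left_loop_len, self.right_loop_len, self.flank_len) < 0:
            raise ValueError("negative segment length")
        for hp, loop_len, name in (
            (self.hairpin_left, self.left_loop_len, "left"),
            (self.hairpin_right, self.right_loop_len, "right"),
        ):
            if hp is not None:
                hs, hl = hp
                if hs < 1 or hl < 0:
                    raise ValueError(f"bad {name} hairpin spec {hp}")
                if loop_len < 2 * hs + hl + 2:
                    raise ValueError(
                        f"{name} loop of {loop_len} nt cannot host hairpin {hp}"
                    )
        if self.bulge is not None:
            stem, gap = self.bulge
            if stem not in (1, 2) or gap < 1:
                raise ValueError(f"bad bulge spec {self.bulge}")


def _loop_segment(
    length: int,
    hairpin: Optional[Tuple[int, int]],
    start: int,
    rng: random.Random,
    filler: str,
    stem_pairs: Tuple[Tuple[str, str], ...],
) -> Tuple[List[str], List[Tuple[int, int]]]:
    """Bases of one pseudoknot loop (1-based global start), plus hairpin pairs."""
    if hairpin is None:
        return [rng.choice(filler) for _ in range(length)], []
    hs, hl = hairpin
    extra = length - (2 * hs + hl)
    pre = (extra + 1) // 2
    post = extra - pre
    letters = [rng.choice(stem_pairs) for _ in range(hs)]
    bases = (
        [rng.choice(filler) for _ in range(pre)]
        + [x for x, _ in letters]
        + [rng.choice(filler) for _ in range(hl)]
        + [y for _, y in reversed(letters)]
        + [rng.choice(filler) for _ in range(post)]
    )
    a0 = start + pre
    b0 = start + pre + hs + hl + hs - 1
    pairs = [(a0 + t, b0 - t) for t in range(hs)]
    return bases, pairs


def _competing_runs(seq: RnaSequence, truth: SecondaryStructure, min_run: int) -> int:
    """Complementary diagonal runs of >= min_run pairs that are not within
    one position (in one coordinate) of a planted pair anywhere along the run."""
    s = seq.residues
    n = len(s)
    planted = truth.pair_set

    def planted_ish(x: int, y: int) -> bool:
        return any(
            (abs(x - i) <= 1 and y == j) or (x == i and abs(y - j) <= 1)
            for (i, j) in planted
        )

    runs = 0
    for x in range(1, n + 1):
        for y in range(x + 2, n + 1):
            if x > 1 and y < n and (s[x - 2], s[y]) in _ALLOWED:
                continue  # not the start of a diagonal run
            length = 0
            while x + length < y - length and (
                (s[x + length - 1], s[y - length - 1]) in _ALLOWED
            ):
                length += 1
            if length >= min_run and any(
                not planted_ish(x + t, y - t) for t in range(length)
            ):
                runs += 1
    return runs


def generate(spec: FixtureSpec) -> Tuple[RnaSequence, SecondaryStructure]:
    """Build the fixture sequence and its ground-truth structure.

    Letter draws are rejection-sampled: the first draw with no competing
    complementary run at least as long as the shortest planted stem is
    kept (best attempt otherwise).
    """
    rng = random.Random(spec.seed)
    # suppressing 2-runs is infeasible in a two-letter complementary
    # alphabet (every draw has many), so 3 is the best-effort floor
    min_run = min(
        [spec.stem1_len, spec.stem2_len]
        + [hp[0] for hp in (spec.hairpin_left, spec.hairpin_right) if hp is not None]
    )
    min_run = max(min_run, 3)
    best: Tuple[int, Tuple[RnaSequence, SecondaryStructure]] | None = None
    for _ in range(_REDRAW_ATTEMPTS):
        seq, truth = _build(spec, rng)
        score = _competing_runs(seq, truth, min_run)
        if best is None or score < best[0]:
            best = (score, (seq, truth))
        if score == 0:
            break
    return best[1]


def _build(
    spec: FixtureSpec, rng: random.Random
) -> Tuple[RnaSequence, SecondaryStructure]:
    filler = spec.filler_alphabet

    stem1 = [rng.choice(spec.stem_pairs) for _ in range(spec.stem1_len)]
    stem2 = [rng.choice(spec.stem_pairs) for _ in range(spec.stem2_len)]
    bulge_stem, bulge_gap = spec.bulge if spec.bulge is not None else (0, 0)

    chars: List[str] = []
    pos = 0

    def emit(bases: List[str]) -> int:
        """Append bases; return 1-based position of the first one."""
        nonlocal pos
        start = pos + 1
        chars.extend(bases)
        pos += len(bases)
        return start

    emit([rng.choice(filler) for _ in range(spec.flank_len)])

    # stem 1 openings, outermost first; optional bulge after the outermost base
    open1: List[int] = []
    for t, (x, _) in enumerate(stem1):
        open1.append(emit([x]))
        if bulge_stem == 1 and t == 0:
            emit([rng.choice(filler) for _ in range(bulge_gap)])

    left_start = pos + 1
    left_bases, left_hp_pairs = _loop_segment(
        spec.left_loop_len, spec.hairpin_left, left_start, rng, filler, spec.stem_pairs
    )
    emit(left_bases)

    open2: List[int] = []
    for t, (x, _) in enumerate(stem2):
        open2.append(emit([x]))
        if bulge_stem == 2 and t == 0:
            emit([rng.choice(filler) for _ in range(bulge_gap)])

    # stem 1 closings: ascending position pairs with descending opening
    close1 = [emit([y]) for _, y in reversed(stem1)]
    stem1_pairs = list(zip(open1, reversed(close1)))

    right_start = pos + 1
    right_bases, right_hp_pairs = _loop_segment(
        spec.right_loop_len, spec.hairpin_right, right_start, rng, filler, spec.stem_pairs
    )
    emit(right_bases)

    close2 = [emit([y]) for _, y in reversed(stem2)]
    stem2_pairs = list(zip(open2, reversed(close2)))

    emit([rng.choice(filler) for _ in range(spec.flank_len)])

    pairs = {p: Layer.ROUND for p in stem1_pairs}
    pairs.update({p: Layer.ROUND for p in left_hp_pairs + right_hp_pairs})
    pairs.update({p: Layer.SQUARE for p in stem2_pairs})
    seq = RnaSequence("".join(chars))
    return seq, SecondaryStructure(length=seq.length, pairs=pairs)


def planted_core(truth: SecondaryStructure) -> CoreStemCandidate:
    """Recover the two core pairs of a planted structure.

    The core of each stem is its innermost pair: among ROUND pairs that
    cross some SQUARE pair (hairpin pairs cross nothing), the one with
    the largest opening index, and likewise for the SQUARE stem.
    """
    square = truth.layer_pairs(Layer.SQUARE)
    crossing_round = [
        (i, j)
        for (i, j) in truth.layer_pairs(Layer.ROUND)
        if any(i < k < j < l for (k, l) in square)
    ]
    if not crossing_round or not square:
        raise ValueError("structure contains no crossing stems")
    i, j = max(crossing_round)
    k, l = max(square)
    return CoreStemCandidate(i=i, k=k, j=j, l=l)
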