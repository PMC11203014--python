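"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results by exhaustive enumeration or by
direct grammar derivation, sharing no code path with the package.
"""

from __future__ import annotations

from typing import List, Set, Tuple

Pair = Tuple[int, int]


def allowed(x: str, y: str, wobble: bool = True) -> bool:
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    if wobble:
        pairs |= {("G", "U"), ("U", "G")}
    return (x, y) in pairs


def brute_force_candidates(
    seq: str,
    min_left: int = 1,
    min_middle: int = 0,
    min_right: int = 1,
    wobble: bool = True,
) -> List[Tuple[int, int, int, int]]:
    """All (i, k, j, l) with i<k<j<l, both pairs allowed, segment minima met.

    Four nested loops, 1-based, no pruning.
    """
    n = len(seq)
    out = []
    for i in range(1, n + 1):
        for k in range(1, n + 1):
            for j in range(1, n + 1):
                for l in range(1, n + 1):
                    if not (i < k < j < l):
                        continue
                    if (k - 1) - (i + 1) + 1 < min_left:
                        continue
                    if (j - 1) - (k + 1) + 1 < min_middle:
                        continue
                    if (l - 1) - (j + 1) + 1 < min_right:
                        continue
                    if allowed(seq[i - 1], seq[j - 1], wobble) and allowed(
                        seq[k - 1], seq[l - 1], wobble
                    ):
                        out.append((i, k, j, l))
    return sorted(out)


def max_stem_extension(
    seq: str,
    start_open: int,
    start_close: int,
    open_min: int,
    close_max: int,
    max_gap: int,
    max_interruptions: int,
    wobble: bool = True,
) -> int:
    """Maximum pairs addable outward from (start_open, start_close), by
    enumerating every legal extension set recursively (no memoization)."""

    def rec(o: int, c: int, ints: int) -> int:
        best = 0
        for go in range(max_gap + 1):
            for gc in range(max_gap + 1):
                cost = 1 if (go, gc) != (0, 0) else 0
                if cost > ints:
                    continue
                oo, cc = o - go, c + gc
                if oo < open_min or cc > close_max:
                    continue
                if allowed(seq[oo - 1], seq[cc - 1], wobble):
                    best = max(best, 1 + rec(oo - 1, cc + 1, ints - cost))
        return best

    return rec(start_open - 1, start_close + 1, max_interruptions)


def max_decoration_pairs(
    seq: str,
    i: int,
    k: int,
    j: int,
    l: int,
    max_gap: int = 2,
    max_interruptions: int = 1,
    wobble: bool = True,
) -> int:
    """Maximum decorated pair count of core ((i,j),(k,l)): 2 core pairs plus
    the best extension of each stem within its regions."""
    n = len(seq)
    ext2 = max_stem_extension(seq, k, l, i + 1, n, max_gap, max_interruptions, wobble)
    ext1 = max_stem_extension(seq, i, j, 1, l - 1, max_gap, max_interruptions, wobble)
    return 2 + ext1 + ext2


def hairpin_grammar_accepts(
    span: str, min_stem: int = 2, min_loop: int = 3, wobble: bool = True
) -> bool:
    """Recognizer for the hairpin motif grammar restricted by the minima.

    Follows the productions directly: S -> L P R with L and R consuming
    arbitrary (possibly empty) flanks, P -> 'x' P 'y' for the six allowed
    pairs, bottoming out in P -> M with M consuming the loop.
    """

    def derives_P(sub: str, depth: int) -> bool:
        # P -> M (M -> K derives any string): stop if minima already met
        if depth >= min_stem and len(sub) >= min_loop:
            return True
        # P -> 'x' P 'y'
        if len(sub) >= 2 and allowed(sub[0].upper(), sub[-1].upper(), wobble):
            return derives_P(sub[1:-1], depth + 1)
        return False

    n = len(span)
    for a in range(n):  # L -> K consumes span[:a]
        for b in range(a, n):  # R -> K consumes span[b+1:]
            if derives_P(span[a : b + 1], 0):
                return True
    return False


def best_hairpin_pairs(
    span_text: str, min_stem: int = 2, min_loop: int = 3, wobble: bool = True
) -> int:
    """Maximum stacked-stem depth of any admissible hairpin in the span."""
    n = len(span_text)
    best = 0
    for a in range(n):
        for b in range(a + 1, n):
            depth = 0
            while (
                a + depth < b - depth
                and allowed(span_text[a + depth], span_text[b - depth], wobble)
                and (b - depth) - (a + depth) - 1 >= min_loop
            ):
                depth += 1
            if depth >= min_stem:
                best = max(best, depth)
    return best
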