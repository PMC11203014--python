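"""Shared parameter objects: the base-pairing rule and the pipeline tuning knobs.

All coordinates spoken by public interfaces are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Tuple

#: Watson-Crick pairs plus the G-U wobble pair.
DEFAULT_ALLOWED_PAIRS: FrozenSet[Tuple[str, str]] = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


@dataclass(frozen=True)
class PairingRule:
    """Which unordered residue pairs may form a base pair.

    The default allows A-U and G-C Watson-Crick pairs and the G-U wobble
    pair.  The set is kept symmetric: X-Y allowed iff Y-X allowed.
    """

    allowed: FrozenSet[Tuple[str, str]] = DEFAULT_ALLOWED_PAIRS

    def __post_init__(self) -> None:
        for x, y in self.allowed:
            if (y, x) not in self.allowed:
                raise ValueError(f"pairing rule not symmetric: {x}-{y}")

    def pairs(self, x: str, y: str) -> bool:
        return (x, y) in self.allowed

    @classmethod
    def watson_crick_only(cls) -> "PairingRule":
        """A-U / G-C only, no wobble."""
        return cls(frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}))


@dataclass(frozen=True)
class TuningParams:
    """Tuning knobs for the prediction pipeline.

    Attributes
    ----------
    stem_slack:
        Candidates whose decorated pair count is within ``stem_slack`` of the
        maximum proceed to hairpin search (e.g. a maximum of 9 pairs with
        slack 2 admits candidates with 7 or more).
    max_gap:
        Largest number of unpaired bases that one interruption (bulge or
        internal loop) may skip on each side of a stem during decoration.
    max_interruptions:
        Maximum number of interruptions per stem during decoration.
    min_hairpin_loop:
        Minimum number of unpaired bases in a hairpin loop.
    min_hairpin_stem:
        Minimum number of stacked pairs in a hairpin stem.
    min_left_loop / min_middle / min_right_loop:
        Minimum lengths (nt) of the three segments of the pseudoknot
        skeleton: between the two stem openings, between the second opening
        and the first closing, and between the two closings.  The middle
        minimum must stay 0 (the two core pairs may be adjacent).
    top_k:
        Optional cap on how many max-pair survivors enter hairpin search
        (after the ascending-energy sort); ``None`` means all survivors.
    """

    stem_slack: int = 2
    max_gap: int = 2
    max_interruptions: int = 1
    min_hairpin_loop: int = 3
    min_hairpin_stem: int = 2
    min_left_loop: int = 1
    min_middle: int = 0
    min_right_loop: int = 1
    top_k: int | None = None
    rule: PairingRule = field(default_factory=PairingRule)

    def __post_init__(self) -> None:
        for name in (
            "stem_slack",
            "max_gap",
            "max_interruptions",
            "min_hairpin_loop",
            "min_hairpin_stem",
            "min_left_loop",
            "min_middle",
            "min_right_loop",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be positive or None")
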