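"""A simplified nearest-neighbor free-energy model for scoring variants.

The score of a structure variant is

    E = sum of stacking terms over adjacent stacked pairs within each stem
        (core stems with their extensions, and hairpin stems)
      + hairpin-loop initiation cost per included hairpin
      + a flat pseudoknot penalty
      + a small per-base cost for unpaired bases left inside the
        pseudoknot loops.

Stacking constants for Watson-Crick-on-Watson-Crick steps follow the
standard Turner nearest-neighbor values at 37 °C; steps involving the
G-U wobble pair use flat surrogate values.  All stacking terms are <= 0
and all penalty terms >= 0, so adding a stacked complementary pair to a
stem never increases the energy.  Parameters are loaded from the TSV
tables shipped with the package (``data/stacking.tsv`` and
``data/hairpin_loops.tsv``) and can be replaced wholesale: any callable
``(variant, seq) -> float`` serves as an energy model, which is the
plug-in point for more elaborate evaluators.

A variant with no pairs scores 0.0 by convention.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Dict, Sequence, Tuple

from .sequence_io import RnaSequence

__all__ = [
    "EnergyParams",
    "EnergyModel",
    "load_stack_table",
    "load_hairpin_loop_table",
    "default_energy_params",
    "stack_energy",
    "hairpin_loop_cost",
    "evaluate_energy",
    "make_energy_model",
]

Pair = Tuple[int, int]
StackTable = Dict[Tuple[Tuple[str, str], Tuple[str, str]], float]

#: Extrapolation slope beyond the tabulated hairpin loop lengths
#: (Jacobson-Stockmayer form, ~1.75 * RT at 37 degC).
_LOOP_EXTRAPOLATION = 1.75 * 0.001987 * 310.15


def load_stack_table(path=None) -> StackTable:
    """Load stacking constants: ((outer5, outer3), (inner5, inner3)) -> kcal/mol."""
    if path is None:
        path = resources.files("hknot").joinpath("data/stacking.tsv")
    table: StackTable = {}
    with path.open() if hasattr(path, "open") else open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = ((row["outer5"], row["outer3"]), (row["inner5"], row["inner3"]))
            table[key] = float(row["dG"])
    return table


def load_hairpin_loop_table(path=None) -> Dict[int, float]:
    """Load hairpin-loop initiation costs: loop length (nt) -> kcal/mol."""
    if path is None:
        path = resources.files("hknot").joinpath("data/hairpin_loops.tsv")
    table: Dict[int, float] = {}
    with path.open() if hasattr(path, "open") else open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[int(row["length"])] = float(row["dG"])
    return table


@dataclass(frozen=True)
class EnergyParams:
    stack_table: StackTable
    hairpin_loop_table: Dict[int, float]
    pseudoknot_penalty: float = 7.0
    unpaired_pk_loop_cost: float = 0.1

    def __post_init__(self) -> None:
        if any(v > 0 for v in self.stack_table.values()):
            raise ValueError("stacking terms must be <= 0")
        if self.pseudoknot_penalty < 0 or self.unpaired_pk_loop_cost < 0:
            raise ValueError("penalty terms must be >= 0")


_DEFAULT_PARAMS: EnergyParams | None = None


def default_energy_params() -> EnergyParams:
    """The shipped parameter set (loaded once)."""
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = EnergyParams(
            stack_table=load_stack_table(),
            hairpin_loop_table=load_hairpin_loop_table(),
        )
    return _DEFAULT_PARAMS


def stack_energy(pairs: Sequence[Pair], seq: RnaSequence, table: StackTable | None = None) -> float:
    """Sum of stacking terms over adjacent pairs of one stem.

    Pairs (a, b) and (a+1, b-1) stack; pairs separated by a bulge or
    internal loop contribute no stacking term across the gap.
    """
    if table is None:
        table = default_energy_params().stack_table
    ordered = sorted(pairs)
    total = 0.0
    for (a, b), (c, d) in zip(ordered, ordered[1:]):
        if c == a + 1 and d == b - 1:
            key = ((seq.base(a), seq.base(b)), (seq.base(c), seq.base(d)))
            term = table.get(key)
            if term is None:
                raise KeyError(f"no stacking entry for {key}")
            total += term
    return total


def hairpin_loop_cost(loop_len: int, table: Dict[int, float] | None = None) -> float:
    """Hairpin-loop initiation cost; extrapolated logarithmically past the table."""
    if table is None:
        table = default_energy_params().hairpin_loop_table
    if loop_len < min(table):
        raise ValueError(f"hairpin loop of length {loop_len} below tabulated minimum")
    if loop_len in table:
        return table[loop_len]
    longest = max(table)
    return table[longest] + _LOOP_EXTRAPOLATION * math.log(loop_len / longest)


def evaluate_energy(variant, seq: RnaSequence, params: EnergyParams | None = None) -> float:
    """Free-energy score (kcal/mol) of a :class:`~hknot.hairpins.StructureVariant`."""
    if params is None:
        params = default_energy_params()
    base = variant.base
    hairpins = [h for h in (variant.left_hairpin, variant.right_hairpin) if h is not None]
    if not base.stem1_pairs and not base.stem2_pairs and not hairpins:
        return 0.0

    total = params.pseudoknot_penalty
    total += stack_energy(base.stem1_pairs, seq, params.stack_table)
    total += stack_energy(base.stem2_pairs, seq, params.stack_table)
    for h in hairpins:
        total += stack_energy(h.stem_pairs, seq, params.stack_table)
        total += hairpin_loop_cost(len(h.loop_span), params.hairpin_loop_table)

    core = base.core
    paired = {x for p in base.all_pairs() for x in p}
    for h in hairpins:
        paired.update(x for p in h.stem_pairs for x in p)
    hairpin_loop_positions = {x for h in hairpins for x in h.loop_span}
    loop_positions = (
        set(core.left_loop()) | set(core.middle()) | set(core.right_loop())
    )
    n_unpaired = len(loop_positions - paired - hairpin_loop_positions)
    total += params.unpaired_pk_loop_cost * n_unpaired
    return total


EnergyModel = Callable[[object, RnaSequence], float]


def make_energy_model(params: EnergyParams | None = None) -> EnergyModel:
    """Bind :func:`evaluate_energy` to a parameter set."""
    if params is None:
        params = default_energy_params()

    def model(variant, seq: RnaSequence) -> float:
        return evaluate_energy(variant, seq, params)

    return model
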