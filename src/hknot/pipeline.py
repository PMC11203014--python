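"""End-to-end prediction: candidate enumeration through final selection.

The five stages, in order:

1. enumerate crossing core-stem candidates;
2. decorate each candidate's stems outward (stacked pairs, bulges,
   internal loops);
3. keep candidates whose pair count is within ``stem_slack`` of the
   maximum, sort them by ascending energy (optionally capped at
   ``top_k`` survivors);
4. search each survivor's pseudoknot loops for hairpins and emit the
   with/without-hairpin variants;
5. among all variants, keep those with the maximum total pair count and
   return the one with minimum free energy (ties broken by the
   lexicographically smallest dot-bracket string).

A sequence with no core candidate yields an explicit "no pseudoknot
detected" result (all-dots structure, energy 0) rather than an error.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .core_stems import enumerate_core_candidates
from .decoration import DecoratedCandidate, decorate
from .energy import EnergyModel, make_energy_model
from .hairpins import StructureVariant, make_variants
from .params import TuningParams
from .sequence_io import (
    Layer,
    RnaSequence,
    SecondaryStructure,
    render_dotbracket,
)

__all__ = ["PredictionResult", "predict", "trace"]

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    """Predicted structure R, its energy E (kcal/mol) and wall time D (s)."""

    structure: SecondaryStructure
    energy: float
    elapsed: float
    n_candidates: int
    n_survivors: int
    variant: Optional[StructureVariant] = None

    @property
    def pseudoknot_found(self) -> bool:
        return bool(self.structure.pairs)

    @property
    def dotbracket(self) -> str:
        return render_dotbracket(self.structure)


def _empty_result(length: int, n_candidates: int, t0: float) -> PredictionResult:
    return PredictionResult(
        structure=SecondaryStructure(length=length),
        energy=0.0,
        elapsed=time.perf_counter() - t0,
        n_candidates=n_candidates,
        n_survivors=0,
    )


def _survivors(
    seq: RnaSequence, params: TuningParams, model: EnergyModel
) -> Tuple[int, List[DecoratedCandidate]]:
    """Stages 1-3: candidate count and energy-sorted max-pair survivors."""
    candidates = enumerate_core_candidates(seq, params.rule, params)
    if not candidates:
        return 0, []
    decorated = [decorate(c, seq, params.rule, params) for c in candidates]
    max_pairs = max(d.pair_count for d in decorated)
    kept = [d for d in decorated if d.pair_count >= max_pairs - params.stem_slack]
    kept.sort(key=lambda d: (model(StructureVariant(base=d), seq), d.core))
    if params.top_k is not None:
        kept = kept[: params.top_k]
    return len(candidates), kept


def predict(
    seq: RnaSequence,
    params: TuningParams | None = None,
    model: EnergyModel | None = None,
) -> PredictionResult:
    """Run all five stages on ``seq`` and return the selected structure.

    Deterministic for fixed inputs: ties at equal pair count and equal
    energy fall back to the lexicographically smallest dot-bracket.
    """
    params = params or TuningParams()
    model = model or make_energy_model()
    t0 = time.perf_counter()

    n_candidates, survivors = _survivors(seq, params, model)
    logger.info("stage 1-3: %d candidates, %d survivors", n_candidates, len(survivors))
    if not survivors:
        logger.info("no pseudoknot detected")
        return _empty_result(seq.length, n_candidates, t0)

    variants: List[StructureVariant] = []
    for d in survivors:
        variants.extend(make_variants(d, seq, params.rule, params))
    for v in variants:
        v.energy = model(v, seq)
    logger.info("stage 4: %d variants", len(variants))

    max_total = max(v.total_pairs for v in variants)
    finalists = [v for v in variants if v.total_pairs == max_total]
    winner = min(
        finalists,
        key=lambda v: (v.energy, render_dotbracket(v.to_structure(seq.length))),
    )
    result = PredictionResult(
        structure=winner.to_structure(seq.length),
        energy=winner.energy,
        elapsed=time.perf_counter() - t0,
        n_candidates=n_candidates,
        n_survivors=len(survivors),
        variant=winner,
    )
    logger.info(
        "stage 5: %s (E=%.2f kcal/mol, %.3f s)",
        result.dotbracket,
        result.energy,
        result.elapsed,
    )
    return result


def trace(
    seq: RnaSequence,
    params: TuningParams | None = None,
    model: EnergyModel | None = None,
) -> List[Tuple[str, str]]:
    """Per-stage dot-bracket rows for the winning candidate.

    Returns (stage label, dot-bracket row) tuples: the bare core pairs
    (stage 1), one row per decoration pair added in extension order
    (stage 2: stem 2 first, then stem 1), and the final selection with
    hairpins (stage 4).  An input with no candidate yields a single
    all-dots row.
    """
    params = params or TuningParams()
    result = predict(seq, params, model)
    if result.variant is None:
        return [("stage1", "." * seq.length)]

    base = result.variant.base
    core = base.core
    rows: List[Tuple[str, str]] = []

    def row(pairs_round, pairs_square) -> str:
        pairs = {p: Layer.ROUND for p in pairs_round}
        pairs.update({p: Layer.SQUARE for p in pairs_square})
        return render_dotbracket(SecondaryStructure(length=seq.length, pairs=pairs))

    rows.append(("stage1", row([core.pair1], [core.pair2])))
    stem2 = list(base.stem2_pairs)
    stem1 = list(base.stem1_pairs)
    for t in range(2, len(stem2) + 1):
        rows.append(("stage2", row([core.pair1], stem2[:t])))
    for t in range(2, len(stem1) + 1):
        rows.append(("stage2", row(stem1[:t], stem2)))
    rows.append(("stage4", result.dotbracket))
    return rows
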