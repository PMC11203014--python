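import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hknot import (
    CoreStemCandidate,
    RnaSequence,
    Side,
    TuningParams,
    decorate,
    find_hairpin,
    make_variants,
)

from oracles import best_hairpin_pairs, hairpin_grammar_accepts

WORKED_CORE = CoreStemCandidate(i=2, k=7, j=8, l=20)


class TestFindHairpin:
    def test_worked_example_right_loop(self, worked_seq):
        match = find_hairpin(range(10, 20), worked_seq, side=Side.RIGHT_LOOP)
        assert match is not None
        assert match.stem_pairs == ((12, 18), (13, 17))
        assert list(match.loop_span) == [14, 15, 16]
        assert match.side is Side.RIGHT_LOOP
        # the L/R flanks are the rest of the span
        assert list(match.flank_left) == [10, 11]
        assert list(match.flank_right) == [19]

    def test_all_a_span_has_no_hairpin(self):
        seq = RnaSequence("A" * 15)
        assert find_hairpin(range(2, 14), seq) is None

    def test_ggg_aaa_ccc_span(self):
        seq = RnaSequence("GGGAAACCC")
        match = find_hairpin(range(1, 10), seq)
        assert match.stem_pairs == ((1, 9), (2, 8), (3, 7))
        assert list(match.loop_span) == [4, 5, 6]

    def test_min_loop_truncates_stack_depth(self):
        # a fourth pair would shrink the loop below the minimum
        seq = RnaSequence("GGGGAAACCCC")
        match = find_hairpin(range(1, 12), seq)
        assert match.n_pairs == 4
        match = find_hairpin(
            range(1, 12), seq, params=TuningParams(min_hairpin_loop=5)
        )
        assert match.n_pairs == 3

    def test_span_too_short_returns_none(self):
        seq = RnaSequence("GGGAAACCC")
        assert find_hairpin(range(1, 6), seq) is None


class TestMakeVariants:
    def test_worked_candidate_gives_two_variants(self, worked_seq):
        d = decorate(WORKED_CORE, worked_seq)
        variants = make_variants(d, worked_seq)
        assert len(variants) == 2
        plain, with_hp = variants
        assert plain.left_hairpin is None and plain.right_hairpin is None
        assert with_hp.right_hairpin is not None and with_hp.left_hairpin is None
        # 5 decoration pairs + 2 hairpin pairs
        assert with_hp.total_pairs == 7

    def test_no_admissible_loop_gives_single_variant(self):
        seq = RnaSequence("GAACAUAA")
        d = decorate(CoreStemCandidate(i=1, k=3, j=4, l=6), seq)
        variants = make_variants(d, seq)
        assert len(variants) == 1
        assert variants[0].total_pairs == d.pair_count

    def test_hairpins_on_both_sides_give_four_variants(self):
        # left loop GGAAACC hosts a 2-pair hairpin, right loop GGGAAACCC a 3-pair one
        #            i  left-loop   k     j  right-loop     l
        seq_str = "G" + "AGGAAACCA" + "A" + "C" + "AGGGAAACCCA" + "U" + "A"
        seq = RnaSequence(seq_str)
        core = CoreStemCandidate(i=1, k=11, j=12, l=24)
        d = decorate(core, seq)
        assert d.pair_count == 2  # A/C flanks cannot extend either stem
        variants = make_variants(d, seq)
        assert len(variants) == 4
        kinds = {
            (v.left_hairpin is not None, v.right_hairpin is not None) for v in variants
        }
        assert kinds == {(False, False), (False, True), (True, False), (True, True)}
        both = max(variants, key=lambda v: v.total_pairs)
        assert both.total_pairs == 2 + 2 + 3
        # independent enumeration oracle confirms the per-side stem depths
        assert best_hairpin_pairs(seq_str[1:10]) == 2
        assert best_hairpin_pairs(seq_str[12:23]) == 3

    def test_variant_structure_renders_with_hairpins_in_round_layer(self, worked_seq):
        d = decorate(WORKED_CORE, worked_seq)
        v = [x for x in make_variants(d, worked_seq) if x.right_hairpin][0]
        from conftest import WORKED_FINAL

        assert v.to_structure(worked_seq.length).length == 22
        from hknot import render_dotbracket

        assert render_dotbracket(v.to_structure(22)) == WORKED_FINAL


@settings(deadline=None, max_examples=80, derandomize=True)
@given(seed=st.integers(0, 10**6), n=st.integers(4, 26))
def test_grammar_recognizer_agreement(seed, n):
    """find_hairpin is non-absent exactly when the motif grammar (with the
    stem/loop minima) accepts the span, and every emitted stem is a valid
    derivation: stacked, complementary, loop long enough."""
    rng = random.Random(seed)
    span_str = "".join(rng.choice("ACGU") for _ in range(n))
    seq = RnaSequence(span_str)
    params = TuningParams()
    match = find_hairpin(range(1, n + 1), seq, params=params)
    accepted = hairpin_grammar_accepts(
        span_str, params.min_hairpin_stem, params.min_hairpin_loop
    )
    assert (match is not None) == accepted
    if match is not None:
        stem = match.stem_pairs
        assert len(stem) >= params.min_hairpin_stem
        for t, (a, b) in enumerate(stem):
            assert (a, b) == (stem[0][0] + t, stem[0][1] - t)
            assert params.rule.pairs(seq.base(a), seq.base(b))
        assert len(match.loop_span) >= params.min_hairpin_loop
        assert len(stem) == best_hairpin_pairs(
            span_str, params.min_hairpin_stem, params.min_hairpin_loop
        )
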