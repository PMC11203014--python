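import pytest

from hknot import (
    CoreStemCandidate,
    DecoratedCandidate,
    RnaSequence,
    StructureVariant,
    decorate,
    default_energy_params,
    evaluate_energy,
    find_hairpin,
    make_variants,
    hairpin_loop_cost,
    make_energy_model,
    stack_energy,
)


@pytest.fixture(scope="module")
def params():
    return default_energy_params()


class TestShippedTables:
    def test_all_stacking_terms_are_stabilizing(self, params):
        assert params.stack_table
        assert all(v <= 0 for v in params.stack_table.values())

    def test_stack_table_covers_all_allowed_pair_combinations(self, params):
        pairs = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
        for outer in pairs:
            for inner in pairs:
                assert (outer, inner) in params.stack_table

    def test_stack_table_duplex_rotation_symmetry(self, params):
        for ((x, y), (w, z)), v in params.stack_table.items():
            assert params.stack_table[((z, w), (y, x))] == pytest.approx(v)

    def test_hairpin_loop_costs_monotone_nondecreasing(self, params):
        lengths = sorted(params.hairpin_loop_table)
        assert lengths[0] == 3
        costs = [params.hairpin_loop_table[n] for n in lengths]
        assert all(a <= b for a, b in zip(costs, costs[1:]))
        # logarithmic extrapolation stays monotone past the table
        beyond = max(lengths)
        assert hairpin_loop_cost(beyond + 5) >= hairpin_loop_cost(beyond)


class TestEvaluate:
    def test_zero_pairs_scores_zero(self):
        seq = RnaSequence("GAACAUAA")
        core = CoreStemCandidate(i=1, k=3, j=4, l=6)
        empty = DecoratedCandidate(core=core, stem1_pairs=(), stem2_pairs=())
        assert evaluate_energy(StructureVariant(base=empty), seq) == 0.0

    def test_extra_stacked_gc_pair_strictly_lowers_energy(self):
        seq = RnaSequence("AGGGGUAAACCCC")
        core = CoreStemCandidate(i=1, k=5, j=6, l=10)
        full = decorate(core, seq)
        shorter = DecoratedCandidate(
            core=core,
            stem1_pairs=full.stem1_pairs,
            stem2_pairs=full.stem2_pairs[:-1],
        )
        e_full = evaluate_energy(StructureVariant(base=full), seq)
        e_short = evaluate_energy(StructureVariant(base=shorter), seq)
        assert e_full < e_short

    def test_three_stack_hairpin_matches_hand_sum(self, params):
        # GGG...CCC: two GC-on-GC stacking terms plus the 3-nt loop cost
        seq = RnaSequence("GGGAAACCC")
        match = find_hairpin(range(1, 10), seq)
        hand_sum = 2 * params.stack_table[(("G", "C"), ("G", "C"))] + (
            params.hairpin_loop_table[3]
        )
        assert stack_energy(match.stem_pairs, seq) + hairpin_loop_cost(
            len(match.loop_span)
        ) == pytest.approx(hand_sum)

    def test_bulge_breaks_the_stacking_chain(self):
        seq = RnaSequence("AGAGGUAAACCC")
        # (5,10),(4,11) stack; (2,12) sits beyond a bulge, so only one term
        contiguous = stack_energy([(5, 10), (4, 11)], seq)
        with_bulge = stack_energy([(5, 10), (4, 11), (2, 12)], seq)
        assert with_bulge == pytest.approx(contiguous)

    def test_energy_is_a_pure_function(self, worked_seq):
        from hknot import enumerate_core_candidates

        model = make_energy_model()
        core = enumerate_core_candidates(worked_seq)[0]
        v = StructureVariant(base=decorate(core, worked_seq))
        assert model(v, worked_seq) == model(v, worked_seq)

    def test_worked_example_components(self, worked_seq, params):
        """Energy decomposition of the final worked-example variant."""
        core = CoreStemCandidate(i=2, k=7, j=8, l=20)
        d = decorate(core, worked_seq)
        variants = [v for v in make_variants(d, worked_seq) if v.right_hairpin]
        v = variants[0]
        e = evaluate_energy(v, worked_seq)
        expected = (
            params.pseudoknot_penalty
            + stack_energy(d.stem1_pairs, worked_seq)
            + stack_energy(d.stem2_pairs, worked_seq)
            + stack_energy(v.right_hairpin.stem_pairs, worked_seq)
            + params.hairpin_loop_table[3]
            # unpaired loop bases: 3,4 (left) and 10,11,19 (right flanks)
            + params.unpaired_pk_loop_cost * 5
        )
        assert e == pytest.approx(expected)
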