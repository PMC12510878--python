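import math

import numpy as np
import pytest

from motiffold.alignments import point_mass_alignment
from motiffold.fold import cyk, inside
from motiffold.grammar import (
    RBG_RULES,
    Grammar,
    ParamSet,
    build_r3d_grammar,
    build_rbgj3j4,
    default_params,
    parse_dotbracket,
    sample_parse,
    split_loop_probability,
    train_by_counting,
)
from motiffold.motifs import expand_variants, parse_descriptor_text


class TestSplitLoopProbability:
    def test_trained_hairpin_worked_example(self):
        kept, per = split_loop_probability(0.3475, 0.4, 15)
        assert kept == pytest.approx(0.2085, abs=1e-12)
        assert round(per, 4) == 0.0093
        assert kept + 15 * per == pytest.approx(0.3475, abs=1e-12)

    def test_zero_fraction_keeps_everything(self):
        assert split_loop_probability(0.7, 0.0, 5) == (0.7, 0.0)

    def test_no_motifs_returns_mass_to_generic(self):
        assert split_loop_probability(0.7, 0.4, 0) == (0.7, 0.0)

    def test_even_split(self):
        assert split_loop_probability(0.5, 0.5, 2) == (0.25, 0.125)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_loop_probability(0.5, 1.5, 2)


class TestParamSet:
    def test_default_validates(self, params):
        params.validate()

    def test_default_multiloop_split_anchored(self, params):
        assert params.multiloop_split == pytest.approx((0.51, 0.32, 0.17))

    def test_json_round_trip_bit_exact(self, params, tmp_path):
        p = tmp_path / "params.json"
        params.to_json(p)
        back = ParamSet.from_json(p)
        assert back.to_dict() == params.to_dict()
        assert back.transitions == params.transitions

    def test_unnormalized_rejected(self, params):
        bad = params.copy()
        bad.transitions["P"]["hp"] += 0.1
        with pytest.raises(ValueError):
            build_rbgj3j4(bad)


class TestGrammarConstruction:
    def test_rule_probabilities_normalized(self, params):
        for nt, rules in params.transitions.items():
            assert sum(rules.values()) == pytest.approx(1.0, abs=1e-9)

    def test_nonterminal_count(self, rbg, motif_grammar):
        assert rbg.nonterminal_count == len(RBG_RULES) == 11
        assert motif_grammar.nonterminal_count == 11 + len(motif_grammar.variants)

    def test_split_conserves_loop_rule_mass(self, params, motif_grammar):
        # hairpin rule: generic kept + all HL motif alternatives
        total = math.exp(motif_grammar.log_t[("P", "hp")]) + sum(
            math.exp(mr.log_prob) for mr in motif_grammar.motif_rules["HL"])
        assert total == pytest.approx(params.transitions["P"]["hp"], abs=1e-12)

    def test_empty_library_identical_to_base(self, rbg, rng):
        empty = build_r3d_grammar(rbg, [])
        for _ in range(20):
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, int(rng.integers(5, 15))))
            pa, _ = point_mass_alignment(seq)
            assert cyk(pa, empty).log_prob == pytest.approx(
                cyk(pa, rbg).log_prob, abs=1e-12)

    def test_vanishing_motif_mass_converges_to_base(self, params, rbg):
        tiny = params.copy()
        tiny.f_class = {k: 1e-6 for k in tiny.f_class}
        variants = expand_variants(parse_descriptor_text(
            "HL GNRA L1=G Loop=N R1=RA"))
        near = build_r3d_grammar(Grammar("RBGJ3J4", tiny), variants)
        seq = "GGGCGAAAGCCC"
        pa, _ = point_mass_alignment(seq)
        assert inside(pa, near) == pytest.approx(inside(pa, rbg), abs=1e-4)


class TestTrainByCounting:
    def test_counting_arithmetic_single_parse(self):
        # two lone-pair hairpins: F0 -> aPa used twice, aF5a never:
        # p = (2 + 1) / (2 + 1 + 0 + 1)
        ps = train_by_counting([("GAAACGAAAC", "(...)(...)")])
        assert ps.transitions["F0"]["aPa"] == pytest.approx(0.75)
        assert ps.transitions["F0"]["aF5a"] == pytest.approx(0.25)

    def test_no_multiloops_pseudocount_floor(self):
        ps = train_by_counting([("GGGAAACCC", "(((...)))")])
        used = 1  # hp rule used once
        floor = 1 / (used + len(RBG_RULES["P"]))
        assert ps.transitions["P"]["J3"] == pytest.approx(floor)
        assert ps.transitions["P"]["J4"] == pytest.approx(floor)

    def test_empty_training_set_uniform_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            ps = train_by_counting([])
        assert "empty training set" in caplog.text
        for nt, rules in ps.transitions.items():
            assert all(p == pytest.approx(1 / len(rules)) for p in rules.values())

    def test_emissions_reflect_observed_pairs(self):
        ps = train_by_counting([("GGGAAACCC", "(((...)))")])
        # G:C pairs observed; A:A never
        assert ps.emis_pair[2, 1] > ps.emis_pair[0, 0]

    def test_parameter_recovery_small(self, rng):
        # moderate-scale recovery; tolerance loose at n=2000
        gen = default_params()
        seqs = []
        while len(seqs) < 2000:
            try:
                seq, pairs, _ = sample_parse(gen, rng, max_len=600)
            except RuntimeError:
                continue
            seqs.append((seq, pairs))
        ps = train_by_counting(seqs)
        for nt in ("S", "F0", "F5", "P"):
            for rule, p in gen.transitions[nt].items():
                assert ps.transitions[nt][rule] == pytest.approx(p, abs=0.05)

    def test_zero_j4_mass_never_samples_four_way(self, rng):
        ps = default_params()
        p = ps.transitions["P"]
        p["J3"] += p["J4"]
        p["J4"] = 0.0
        ps.validate()
        n_j4 = 0
        for _ in range(10_000):
            try:
                _seq, pairs, used = sample_parse(ps, rng, max_len=400)
            except RuntimeError:
                continue
            n_j4 += used.get(("P", "J4"), 0)
        assert n_j4 == 0

    def test_crossing_structure_rejected(self):
        with pytest.raises(ValueError, match="crossing"):
            train_by_counting([("GGGGAAAACCCC", [(0, 5), (2, 8)])])


class TestDotBracket:
    def test_basic(self):
        assert parse_dotbracket("((..))") == {(0, 5), (1, 4)}
        assert parse_dotbracket("<...>") == {(0, 4)}

    def test_unbalanced(self):
        with pytest.raises(ValueError):
            parse_dotbracket("((.)")
        with pytest.raises(ValueError):
            parse_dotbracket(".))")


def test_sampler_deterministic():
    a = sample_parse(default_params(), np.random.default_rng(5))
    b = sample_parse(default_params(), np.random.default_rng(5))
    assert a[0] == b[0] and a[1] == b[1]
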