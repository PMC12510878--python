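import itertools
import time

import numpy as np
import pytest

from motiffold.alignments import MSA, build_probabilistic_alignment, point_mass_alignment
from motiffold.fold import (
    Constraints,
    InfeasibleError,
    cyk,
    enumerate_derivations,
    fold_sequence,
    inside,
    parse_key,
    score_structure,
)
from motiffold.grammar import build_r3d_grammar
from motiffold.motifs import expand_variants, parse_descriptor_text


def oracle_stats(pa, grammar, constraints=None):
    ders = enumerate_derivations(pa, grammar, constraints)
    logps = np.array([d.log_prob for d in ders])
    keys = [(d.pairs, d.annots) for d in ders]
    return logps.max(), np.logaddexp.reduce(logps), keys


class TestOracleEquivalence:
    @pytest.mark.parametrize("grammar_fixture", ["rbg", "motif_grammar", "layer_grammar"])
    def test_cyk_and_inside_match_enumeration(self, grammar_fixture, request, rng):
        grammar = request.getfixturevalue(grammar_fixture)
        for _ in range(30):
            L = int(rng.integers(3, 8))
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, L))
            pa, _ = point_mass_alignment(seq)
            mx, tot, keys = oracle_stats(pa, grammar)
            assert cyk(pa, grammar).log_prob == pytest.approx(mx, abs=1e-9)
            assert inside(pa, grammar) == pytest.approx(tot, abs=1e-9)
            assert len(keys) == len(set(keys)), f"ambiguous derivations for {seq}"

    def test_oracle_on_probabilistic_columns(self, motif_grammar, rng):
        # the equivalence also holds for genuine alignment columns
        rows = ["".join("ACGU"[k] for k in rng.integers(0, 4, 6)) for _ in range(4)]
        pa, _ = build_probabilistic_alignment(MSA(["a", "b", "c", "d"], rows))
        mx, tot, _ = oracle_stats(pa, motif_grammar)
        assert cyk(pa, motif_grammar).log_prob == pytest.approx(mx, abs=1e-9)
        assert inside(pa, motif_grammar) == pytest.approx(tot, abs=1e-9)

    def test_inside_at_least_cyk(self, rbg, rng):
        for _ in range(50):
            L = int(rng.integers(4, 14))
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, L))
            pa, _ = point_mass_alignment(seq)
            assert inside(pa, rbg) >= cyk(pa, rbg).log_prob - 1e-12


class TestConstraints:
    def test_forced_pairs_present(self, rbg):
        pa, _ = point_mass_alignment("GGGAAACCC")
        res = cyk(pa, rbg, Constraints(forced_pairs={(0, 8), (1, 7), (2, 6)}))
        assert {(0, 8), (1, 7), (2, 6)} <= set(res.pairs)

    def test_forbidden_pair_absent(self, rbg):
        pa, _ = point_mass_alignment("GGGAAACCC")
        res = cyk(pa, rbg, Constraints(forbidden_pairs={(0, 8)}))
        assert (0, 8) not in set(res.pairs)

    def test_adjacent_forced_pair_infeasible(self, rbg):
        pa, _ = point_mass_alignment("GGGAAACCC")
        with pytest.raises(InfeasibleError):
            cyk(pa, rbg, Constraints(forced_pairs={(0, 1)}))

    def test_unpairable_positions(self, rbg):
        pa, _ = point_mass_alignment("GGGAAACCC")
        res = cyk(pa, rbg, Constraints(unpairable=frozenset(range(9))))
        assert res.pairs == []

    def test_crossing_forced_pairs_rejected(self):
        with pytest.raises(ValueError, match="cross"):
            Constraints(forced_pairs={(0, 5), (3, 8)})

    def test_forced_and_forbidden_conflict(self):
        with pytest.raises(InfeasibleError):
            Constraints(forced_pairs={(0, 5)}, forbidden_pairs={(0, 5)})

    def test_oracle_equivalence_under_constraints(self, motif_grammar, rng):
        for _ in range(10):
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 7))
            pa, _ = point_mass_alignment(seq)
            cons = Constraints(forced_pairs={(0, 6)})
            try:
                mx, tot, _ = oracle_stats(pa, motif_grammar, cons)
            except ValueError:
                continue
            if not np.isfinite(mx):
                with pytest.raises(InfeasibleError):
                    cyk(pa, motif_grammar, cons)
                continue
            assert cyk(pa, motif_grammar, cons).log_prob == pytest.approx(mx, abs=1e-9)
            assert inside(pa, motif_grammar, cons) == pytest.approx(tot, abs=1e-9)


class TestTraceback:
    def test_rescore_round_trip(self, motif_grammar, rng):
        for _ in range(25):
            L = int(rng.integers(6, 30))
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, L))
            pa, _ = point_mass_alignment(seq)
            res = cyk(pa, motif_grammar)
            assert score_structure(pa, motif_grammar, res) == pytest.approx(
                res.log_prob, abs=1e-9)

    def test_traceback_is_an_enumerated_derivation(self, motif_grammar, rng):
        for _ in range(15):
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 7))
            pa, _ = point_mass_alignment(seq)
            res = cyk(pa, motif_grammar)
            ders = enumerate_derivations(pa, motif_grammar)
            keys = {(d.pairs, d.annots): d.log_prob for d in ders}
            pk = parse_key(res)
            assert pk in keys
            assert keys[pk] == pytest.approx(res.log_prob, abs=1e-9)

    def test_layer1_pairs_nested(self, rbg, rng):
        for _ in range(10):
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 25))
            pairs = sorted(cyk(point_mass_alignment(seq)[0], rbg).pairs)
            for a, b in pairs:
                for c, d in pairs:
                    assert not (a < c < b < d)

    def test_coordinate_mapping(self, rbg):
        msa = MSA(["a", "b"], ["GGG-AAACCC", "GGGUAAACCC"])
        pa, colmap = build_probabilistic_alignment(msa, gap_max=0.4)
        res = cyk(pa, rbg).mapped(colmap)
        assert res.one_based
        for i, j in res.pairs:
            assert 1 <= i < j <= msa.length


class TestMotifDetection:
    def test_planted_gnra_called_with_exact_ends(self, motif_grammar):
        res = fold_sequence("AAGGGCGAAAGCCCAA", motif_grammar)
        gnra = [c for c in res.motif_calls if c.name == "GNRA"]
        assert len(gnra) == 1
        assert gnra[0].span == (6, 9)

    def test_planted_kturn_called_with_exact_ends(self, motif_grammar):
        # outer stem, GA, inner stem + loop, GA + RNN bulge
        seq = "GGGGC" + "GA" + "GCGAC" + "UUCG" + "GUCGC" + "GAGAA" + "GCCCC"
        res = fold_sequence(seq, motif_grammar)
        kturn = [c for c in res.motif_calls if c.name == "K-turn"]
        assert len(kturn) == 1
        assert kturn[0].span == (5, 25)

    def test_motif_mass_helps_on_consensus_instance(self, rbg, motif_grammar):
        # a sequence containing the exact GNRA consensus scores at least as
        # high under the motif grammar as under the base grammar
        pa, _ = point_mass_alignment("AAGGGCGAAAGCCCAA")
        assert cyk(pa, motif_grammar).log_prob >= cyk(pa, rbg).log_prob - 1e-9

    def test_single_row_alignment_equals_sequence_fold(self, motif_grammar):
        seq = "AAGGGCGAAAGCCCAA"
        msa = MSA(["only"], [seq])
        pa, _ = build_probabilistic_alignment(msa)
        res_a = cyk(pa, motif_grammar)
        res_s = fold_sequence(seq, motif_grammar)
        assert res_a.log_prob == pytest.approx(res_s.log_prob, abs=1e-12)
        assert parse_key(res_a) == parse_key(res_s)


def test_runtime_grows_subcubically(motif_grammar, rng):
    """Runtime trend across doubling lengths stays below cubic growth
    (with slack for constant overhead) -- a smoke test, not a benchmark."""
    times = {}
    for L in (40, 80, 160):
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, L))
        pa, _ = point_mass_alignment(seq)
        t0 = time.perf_counter()
        cyk(pa, motif_grammar)
        times[L] = time.perf_counter() - t0
    assert times[160] / max(times[80], 1e-9) < 12.0
    assert times[80] / max(times[40], 1e-9) < 12.0
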