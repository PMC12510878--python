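import itertools

import numpy as np
import pytest

from motiffold.alignments import ColumnMap, MSA, build_probabilistic_alignment, shuffle_columns
from motiffold.covariation import (
    PairSet,
    annotate_support,
    covariation_standin,
    decompose_layers,
    fdr_report,
    find_helices,
    fold_multilayer,
    max_nested_subset,
    read_pairs,
)
from motiffold.fold import InfeasibleError, MotifCall, ParseResult
from motiffold.synth import PlantSpec, PlantedHelix, generate


def brute_force_max_nested(pairs):
    best = 0
    for r in range(len(pairs), 0, -1):
        for sub in itertools.combinations(pairs, r):
            ok = True
            for (a, b), (c, d) in itertools.combinations(sub, 2):
                crossing = a < c < b < d or c < a < d < b
                shared = len({a, b} & {c, d}) > 0
                if crossing or shared:
                    ok = False
                    break
            if ok:
                return r
    return best


class TestPairIO:
    def test_three_row_tsv(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("1\t9\t0.001\tpositive\n2\t8\t0.02\tpositive\n3\t5\t1.0\tnegative\n")
        ps = read_pairs(p, ColumnMap(np.arange(10)))
        assert len(ps.positive) == 2
        assert ps.negative == [(2, 4)]

    def test_pair_on_dropped_column_warned_and_dropped(self, tmp_path, caplog):
        p = tmp_path / "pairs.tsv"
        p.write_text("1\t5\t0.001\tpositive\n2\t6\t0.001\tpositive\n")
        colmap = ColumnMap(np.array([1, 2, 3, 5]))  # original column 1 dropped
        with caplog.at_level("WARNING"):
            ps = read_pairs(p, colmap)
        assert len(ps.positive) == 1
        assert "dropped" in caplog.text

    def test_duplicate_pair_error(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("1\t9\t0.001\tpositive\n1\t9\t0.002\tpositive\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_pairs(p, ColumnMap(np.arange(10)))

    def test_malformed_row_error(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("1\tx\t0.001\tpositive\n")
        with pytest.raises(ValueError):
            read_pairs(p, ColumnMap(np.arange(10)))

    def test_bad_class_token(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("1\t9\t0.001\tmaybe\n")
        with pytest.raises(ValueError, match="class"):
            read_pairs(p, ColumnMap(np.arange(10)))


class TestStandinCovariation:
    def test_planted_covarying_pairs_recovered(self):
        spec = PlantSpec(n_seq=50, length=26, seed=3, helices=[
            PlantedHelix(0, 25, 10, comp_rate=0.7)])
        msa, truth = generate(spec)
        pa, _ = build_probabilistic_alignment(msa)
        ps = covariation_standin(pa, msa, n_shuffles=100, seed=11)
        assert truth.pairs <= ps.positive_pairs
        assert all(e <= 0.05 for _, _, e in ps.positive)

    def test_fully_conserved_alignment_no_positives(self):
        msa = MSA([f"s{i}" for i in range(20)], ["GGGAAACCCUU"] * 20)
        pa, _ = build_probabilistic_alignment(msa)
        ps = covariation_standin(pa, msa, n_shuffles=50, seed=1)
        assert ps.positive == []

    def test_null_calibration(self):
        # on covariation-free input the positive fraction stays below the
        # threshold plus three binomial standard errors
        spec = PlantSpec(n_seq=40, length=30, seed=9)
        msa, _ = generate(spec)
        null = shuffle_columns(msa, 4)
        pa, _ = build_probabilistic_alignment(null)
        ps = covariation_standin(pa, null, n_shuffles=80, seed=2)
        n_tests = 30 * 29 / 2
        frac = len(ps.positive) / n_tests
        se = np.sqrt(0.05 * 0.95 / n_tests)
        assert frac <= 0.05 + 3 * se


class TestLayerDecomposition:
    def test_nested_set_single_layer(self):
        ps = PairSet(positive=[(1, 10, 0.01), (2, 9, 0.01), (3, 8, 0.01)])
        assert decompose_layers(ps) == [[(1, 10), (2, 9), (3, 8)]]

    def test_crossing_tie_break(self):
        ps = PairSet(positive=[(1, 5, 0.01), (3, 8, 0.01)])
        layers = decompose_layers(ps)
        assert layers == [[(1, 5)], [(3, 8)]]

    def test_union_and_disjointness(self, rng):
        pos = set()
        while len(pos) < 10:
            i, j = sorted(rng.integers(0, 30, 2))
            if i < j:
                pos.add((int(i), int(j)))
        ps = PairSet(positive=[(i, j, 0.01) for i, j in pos])
        layers = decompose_layers(ps)
        flat = [p for layer in layers for p in layer]
        assert sorted(flat) == sorted(pos)
        for layer in layers:
            for (a, b), (c, d) in itertools.combinations(layer, 2):
                assert not (a < c < b < d or c < a < d < b)

    def test_layer1_matches_exhaustive_maximum(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 11))
            pairs = set()
            while len(pairs) < n:
                i, j = sorted(rng.integers(0, 16, 2))
                if i < j:
                    pairs.add((int(i), int(j)))
            layer1 = max_nested_subset(sorted(pairs))
            assert len(layer1) == brute_force_max_nested(sorted(pairs))


class TestMultilayerFolding:
    def test_crossing_pairs_give_two_layers(self, motif_grammar, layer_grammar):
        # nested stem plus one crossing pair: a pseudoknot needs layer 2
        spec = PlantSpec(n_seq=30, length=40, seed=5, helices=[
            PlantedHelix(2, 21, 4, comp_rate=0.0),
            PlantedHelix(12, 30, 2, comp_rate=0.0)])
        msa, _ = generate(spec)
        pa, _ = build_probabilistic_alignment(msa)
        nested = [(2, 21), (3, 20), (4, 19), (5, 18)]
        crossing = [(12, 30), (13, 29)]
        layers = decompose_layers(PairSet(
            positive=[(i, j, 0.01) for i, j in nested + crossing]))
        assert len(layers) == 2
        res = fold_multilayer(pa, motif_grammar, layer_grammar, layers)
        assert len(res.layers) == 2
        assert set(nested) <= set(res.layers[0])
        assert set(crossing) <= set(res.layers[1])

    def test_no_positive_pairs_single_layer(self, motif_grammar, layer_grammar):
        spec = PlantSpec(n_seq=5, length=20, seed=2)
        msa, _ = generate(spec)
        pa, _ = build_probabilistic_alignment(msa)
        res = fold_multilayer(pa, motif_grammar, layer_grammar, [])
        assert len(res.layers) == 1

    def test_forced_pair_in_negatives_infeasible(self, motif_grammar, layer_grammar):
        spec = PlantSpec(n_seq=5, length=20, seed=2)
        msa, _ = generate(spec)
        pa, _ = build_probabilistic_alignment(msa)
        with pytest.raises((InfeasibleError, ValueError)):
            fold_multilayer(pa, motif_grammar, layer_grammar,
                            [[(2, 15)]], negatives=[(2, 15)])

    def test_no_negative_pair_in_any_layer(self, motif_grammar, layer_grammar):
        spec = PlantSpec(n_seq=20, length=30, seed=8, helices=[
            PlantedHelix(1, 20, 4, comp_rate=0.0)])
        msa, _ = generate(spec)
        pa, _ = build_probabilistic_alignment(msa)
        negatives = [(7, 12), (8, 11)]
        res = fold_multilayer(pa, motif_grammar, layer_grammar,
                              [[(1, 20), (2, 19)]], negatives=negatives)
        assert (1, 20) in res.layers[0]
        for layer in res.layers:
            assert not (set(negatives) & set(layer))


def _call(name, cls, span, segments=()):
    return MotifCall(name, name, cls, cls, span, tuple(segments), -1.0)


class TestSupportAnnotation:
    def test_closing_helix_positive_supports(self):
        pairs = [(2, 12), (3, 11), (4, 10)]
        parse = ParseResult([pairs], [_call("GNRA", "HL", (5, 9))], -1.0)
        out = annotate_support(parse, PairSet(positive=[(3, 11, 0.01)]))
        assert out.motif_calls[0].supported is True

    def test_empty_positive_set_unsupported(self):
        pairs = [(2, 12), (3, 11), (4, 10)]
        parse = ParseResult([pairs], [_call("GNRA", "HL", (5, 9))], -1.0)
        out = annotate_support(parse, PairSet())
        assert out.motif_calls[0].supported is False

    def test_j3_supported_by_enclosed_helix(self):
        # J3 junction spanning (5, 24); covariation only in the second
        # enclosed helix
        pairs = [(4, 25), (6, 12), (7, 11), (15, 22), (16, 21)]
        parse = ParseResult([pairs], [_call("hammerhead", "J3", (5, 24))], -1.0)
        out = annotate_support(parse, PairSet(positive=[(16, 21, 0.01)]))
        assert out.motif_calls[0].supported is True

    def test_distant_helix_does_not_support(self):
        pairs = [(2, 12), (3, 11), (4, 10), (20, 30), (21, 29)]
        parse = ParseResult([pairs], [_call("GNRA", "HL", (5, 9))], -1.0)
        out = annotate_support(parse, PairSet(positive=[(20, 30, 0.01)]))
        assert out.motif_calls[0].supported is False

    def test_bs_flanking_helices(self):
        # branch segment between two helices of a junction
        pairs = [(0, 30), (2, 10), (3, 9), (14, 25), (15, 24)]
        parse = ParseResult([pairs], [_call("CsrA", "BS", (11, 13))], -1.0)
        out = annotate_support(parse, PairSet(positive=[(2, 10, 0.01)]))
        assert out.motif_calls[0].supported is True


class TestHelices:
    def test_maximal_stacks(self):
        helices = find_helices([(0, 10), (1, 9), (5, 20), (3, 7)])
        assert sorted(map(len, helices)) == [1, 1, 2]

    def test_lone_pair_is_a_helix(self):
        assert find_helices([(4, 9)]) == [[(4, 9)]]


class TestFdrReport:
    def test_supported_fdr_from_printed_counts(self):
        rep = fdr_report(1460, 2124, 121, 290)
        assert rep["fdr_supported_pct"] == pytest.approx(100 * 121 / 1460, abs=1e-9)
        assert round(rep["fdr_supported_pct"], 1) == 8.3

    def test_unsupported_fdr_from_printed_counts(self):
        rep = fdr_report(1460, 2124, 121, 290)
        assert rep["n_real_unsupported"] == 664
        assert rep["n_ctrl_unsupported"] == 169
        assert rep["fdr_unsupported_pct"] == pytest.approx(100 * 169 / 664, abs=1e-9)

    def test_expected_null_helices(self):
        rep = fdr_report(1, 1, 0, 0, evalue_threshold=0.05, n_ctrl_helices=14146)
        assert rep["expected_null_helices"] == pytest.approx(707.3)

    def test_zero_denominators_undefined(self):
        rep = fdr_report(0, 0, 0, 0)
        assert rep["fdr_supported_pct"] is None
        assert rep["fdr_unsupported_pct"] is None

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            fdr_report(5, 4, 0, 0)
        with pytest.raises(ValueError):
            fdr_report(-1, 4, 0, 0)
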