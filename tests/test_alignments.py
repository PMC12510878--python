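import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motiffold.alignments import (
    MSA,
    AlignmentFormatError,
    build_probabilistic_alignment,
    point_mass_alignment,
    read_fasta,
    read_stockholm,
    shuffle_columns,
    write_stockholm,
)


class TestStockholmIO:
    def test_read_toy(self, toy_stockholm):
        msa = read_stockholm(toy_stockholm)
        assert msa.n_seq == 2
        assert msa.length == 10
        assert msa.ss_cons == "<<<...>>>."

    def test_round_trip(self, toy_stockholm, tmp_path):
        msa = read_stockholm(toy_stockholm)
        out = tmp_path / "out.sto"
        write_stockholm(msa, out)
        assert read_stockholm(out) == msa

    def test_t_normalized_to_u(self, tmp_path):
        p = tmp_path / "t.sto"
        p.write_text("# STOCKHOLM 1.0\nseq1 GGTTAACC\n//\n")
        assert "T" not in read_stockholm(p).rows[0]
        assert "U" in read_stockholm(p).rows[0]

    def test_ragged_rows_error(self):
        with pytest.raises(AlignmentFormatError, match="ragged"):
            MSA(sequence_ids=["a", "b"], rows=["ACGU", "ACG"])

    def test_empty_file_error(self, tmp_path):
        p = tmp_path / "empty.sto"
        p.write_text("")
        with pytest.raises(AlignmentFormatError):
            read_stockholm(p)

    def test_fasta_single_sequence(self, tmp_path):
        p = tmp_path / "s.fa"
        p.write_text(">x\nGGGAAACCC\n")
        msa = read_fasta(p)
        assert msa.n_seq == 1


class TestProbabilisticAlignment:
    def test_point_mass_column(self):
        msa = MSA(["a", "b", "c", "d"], ["A"] * 4)
        pa, _ = build_probabilistic_alignment(msa)
        assert np.allclose(pa.single[0], [1, 0, 0, 0])

    def test_half_half_column(self):
        msa = MSA(["a", "b", "c", "d"], ["A", "A", "G", "G"])
        pa, _ = build_probabilistic_alignment(msa)
        assert np.allclose(pa.single[0], [0.5, 0, 0.5, 0])

    def test_gap_threshold_drops_column(self):
        # 8 gaps out of 10 (80% > 75% default) in column 2
        rows = [("A" + ("-" if s < 8 else "G")) for s in range(10)]
        msa = MSA([f"s{i}" for i in range(10)], rows)
        pa, colmap = build_probabilistic_alignment(msa)
        assert list(colmap.kept) == [0]
        assert pa.L == 1

    def test_gaps_excluded_and_renormalized(self):
        msa = MSA(["a", "b", "c", "d"], ["A", "A", "-", "G"])
        pa, _ = build_probabilistic_alignment(msa)
        assert np.allclose(pa.single[0], [2 / 3, 0, 1 / 3, 0])

    def test_ambiguity_split_uniformly(self):
        msa = MSA(["a", "b"], ["R", "A"])
        pa, _ = build_probabilistic_alignment(msa)
        assert np.allclose(pa.single[0], [0.75, 0, 0.25, 0])

    def test_pair_freq_direct_count(self):
        msa = MSA(["a", "b", "c"], ["AU", "AU", "GC"])
        pa, _ = build_probabilistic_alignment(msa)
        joint = pa.pair_freq(0, 1)
        assert joint[0, 3] == pytest.approx(2 / 3)
        assert joint[2, 1] == pytest.approx(1 / 3)

    def test_pair_freq_excludes_half_gapped_sequences(self):
        msa = MSA(["a", "b", "c"], ["AU", "A-", "GC"])
        pa, _ = build_probabilistic_alignment(msa)
        joint = pa.pair_freq(0, 1)
        assert joint[0, 3] == pytest.approx(0.5)
        assert joint[2, 1] == pytest.approx(0.5)

    def test_marginal_consistency(self, rng):
        rows = ["".join("ACGU"[k] for k in rng.integers(0, 4, 12)) for _ in range(8)]
        msa = MSA([f"s{i}" for i in range(8)], rows)
        pa, _ = build_probabilistic_alignment(msa)
        for i, j in [(0, 5), (2, 11), (3, 4)]:
            joint = pa.pair_freq(i, j)
            assert np.allclose(joint.sum(), 1.0, atol=1e-9)
            assert np.allclose(joint.sum(axis=1), pa.single[i], atol=1e-9)
            assert np.allclose(joint.sum(axis=0), pa.single[j], atol=1e-9)

    def test_distributions_normalized(self, rng):
        rows = ["".join(rng.choice(list("ACGU-N")) for _ in range(9)) for _ in range(6)]
        msa = MSA([f"s{i}" for i in range(6)], rows)
        pa, _ = build_probabilistic_alignment(msa)
        assert np.allclose(pa.single.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pa.single >= 0)

    def test_single_sequence_point_mass(self):
        pa, _ = point_mass_alignment("GACU")
        assert np.allclose(pa.single, np.eye(4)[[2, 0, 1, 3]])

    def test_bad_weights(self):
        msa = MSA(["a"], ["ACGU"])
        with pytest.raises(ValueError):
            build_probabilistic_alignment(msa, weights=np.array([-1.0]))


class TestShuffleColumns:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_column_composition_conserved(self, seed):
        rng = np.random.default_rng(seed % 1000)
        rows = ["".join("ACGU-"[k] for k in rng.integers(0, 5, 7)) for _ in range(5)]
        msa = MSA([f"s{i}" for i in range(5)], rows)
        shuf = shuffle_columns(msa, seed)
        for j in range(msa.length):
            assert sorted(msa.column(j)) == sorted(shuf.column(j))

    def test_determinism(self):
        msa = MSA(["a", "b", "c"], ["ACG", "GCA", "UUU"])
        assert shuffle_columns(msa, 7) == shuffle_columns(msa, 7)

    def test_shuffling_destroys_covariation(self):
        # plant a perfectly covarying pair; after shuffling the joint
        # frequency approaches the product of the marginals
        rng = np.random.default_rng(0)
        pairs = [("A", "U"), ("G", "C"), ("C", "G"), ("U", "A")]
        rows = []
        for _ in range(200):
            a, b = pairs[rng.integers(4)]
            rows.append(a + b)
        msa = MSA([f"s{i}" for i in range(200)], rows)
        pa0, _ = build_probabilistic_alignment(msa)
        assert pa0.pair_freq(0, 1)[0, 3] == pytest.approx(
            pa0.single[0][0], abs=1e-9)  # perfectly coupled
        shuf = shuffle_columns(msa, 3)
        pa1, _ = build_probabilistic_alignment(shuf)
        expected = np.outer(pa1.single[0], pa1.single[1])
        assert np.abs(pa1.pair_freq(0, 1) - expected).max() < 0.1
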