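import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppistack._tables import AA_INDEX, AMINO_ACIDS, hyin_table, phychem_table, pseaa_property_table
from ppistack.features import (
    FFMOD_DIMS,
    EncoderSpec,
    ResidueFeatureSet,
    build_context_matrix,
    build_targeted_feature,
    encode_entropy_density,
    encode_hyin,
    encode_kpseaa,
    encode_one_hot,
    encode_phychem,
    encode_pssm_row,
    featurize_record,
)
from ppistack.io import ProteinRecord

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=60)


class TestOneHot:
    def test_orthonormal_over_alphabet(self):
        mat = np.stack([encode_one_hot(aa) for aa in AMINO_ACIDS])
        assert np.array_equal(mat, np.eye(20))

    def test_x_is_zero(self):
        assert not encode_one_hot("X").any()

    def test_outside_alphabet_rejected(self):
        with pytest.raises(ValueError):
            encode_one_hot("B")


class TestEntropyDensity:
    def test_homopolymer_is_zero(self):
        assert not encode_entropy_density("AAAA").any()

    def test_uniform_composition_closed_form(self):
        vec = encode_entropy_density(AMINO_ACIDS)
        expected = (1 / 20) * np.log2(20)
        assert np.allclose(vec, expected)

    def test_against_count_formula_oracle(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=200))
        vec = encode_entropy_density(seq)
        for u, aa in enumerate(AMINO_ACIDS):
            p = seq.count(aa) / len(seq)
            expected = -p * np.log2(p) if p > 0 else 0.0
            assert vec[u] == pytest.approx(expected, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            encode_entropy_density("")


class TestLookupEncoders:
    def test_pure_lookup(self):
        assert np.array_equal(encode_phychem("W"), encode_phychem("W"))
        assert np.array_equal(encode_hyin("K"), encode_hyin("K"))

    def test_x_zero_of_declared_dimension(self):
        assert encode_phychem("X").shape == (21,) and not encode_phychem("X").any()
        assert encode_hyin("X").shape == (2,) and not encode_hyin("X").any()

    @pytest.mark.parametrize(
        "table,shape",
        [(phychem_table, (20, 21)), (hyin_table, (20, 2)), (pseaa_property_table, (20, 3))],
    )
    def test_tables_structurally_valid(self, table, shape):
        arr = table()
        assert arr.shape == shape
        assert np.isfinite(arr).all()


class TestPssmRow:
    def test_zero_score_maps_to_half(self):
        assert encode_pssm_row(np.zeros((3, 20)), 1) == pytest.approx(np.full(20, 0.5))

    def test_range_and_oracle(self):
        rng = np.random.default_rng(3)
        pssm = rng.normal(scale=5, size=(10, 20))
        row = encode_pssm_row(pssm, 4)
        assert ((row > 0) & (row < 1)).all()
        assert np.allclose(row, 1 / (1 + np.exp(-pssm[4])), atol=1e-12)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            encode_pssm_row(np.zeros((3, 20)), 3)


def _kpseaa_oracle(sub: str, lam: int, w: float) -> np.ndarray:
    """Direct summation of the pseudo amino acid composition definition."""
    props = pseaa_property_table()
    idx = [AA_INDEX[c] for c in sub]
    L = len(idx)
    thetas = []
    for j in range(1, lam + 1):
        if j >= L:
            thetas.append(0.0)
            continue
        total = 0.0
        for t in range(L - j):
            a, b = props[idx[t]], props[idx[t + j]]
            total += sum((b[k] - a[k]) ** 2 for k in range(3)) / 3.0
        thetas.append(total / (L - j))
    freqs = np.array([idx.count(u) / L for u in range(20)])
    denom = 1.0 + w * sum(thetas)
    return np.concatenate([freqs / denom, w * np.array(thetas) / denom])


class TestKPseAA:
    def test_homopolymer_degenerate(self):
        vec = encode_kpseaa("A" * 25, 12)
        assert vec[AA_INDEX["A"]] == pytest.approx(1.0)
        assert np.count_nonzero(vec) == 1

    def test_dimension_is_20_plus_lambda(self):
        assert encode_kpseaa("ACDEFGHIKLMNPQRSTVWYA", 10, lam=10).shape == (30,)
        assert encode_kpseaa("ACDEFGHIKLMNPQRSTVWYA", 10, lam=4).shape == (24,)

    def test_against_direct_summation_oracle(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=21))
        vec = encode_kpseaa(seq, 10, K=10, lam=10, w=0.05)
        assert np.allclose(vec, _kpseaa_oracle(seq, 10, 0.05), atol=1e-10)

    @given(seq=seq_strategy, i=st.integers(0, 59))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_components_sum_to_one(self, seq, i):
        if i >= len(seq):
            i = i % len(seq)
        vec = encode_kpseaa(seq, i)
        assert (vec >= 0).all()
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_edge_clamp_short_subsequence(self):
        # position 0 with K=2: subsequence length 3, theta_j = 0 for j >= 3
        vec = encode_kpseaa("ACDEFGH", 0, K=2, lam=10)
        assert not vec[20 + 3 :].any()

    def test_out_of_range_position(self):
        with pytest.raises(IndexError):
            encode_kpseaa("ACD", 3)


class TestFFModCombination:
    @pytest.mark.parametrize("ffmod,dim", [(0, 40), (1, 23), (2, 50)])
    def test_pair_dimensions(self, tiny_record, ffmod, dim):
        assert build_targeted_feature(tiny_record, 3, ffmod).shape == (dim,)

    def test_unknown_ffmod(self, tiny_record):
        with pytest.raises(ValueError):
            build_targeted_feature(tiny_record, 0, 3)

    def test_ffmod2_requires_pssm(self, tiny_record):
        tiny_record.pssm = None
        with pytest.raises(ValueError, match="PSSM"):
            build_targeted_feature(tiny_record, 0, 2)

    def test_encoder_spec_dimension_checks(self):
        EncoderSpec("K-PseAA", 30, {"lambda": 10})
        with pytest.raises(ValueError):
            EncoderSpec("K-PseAA", 25, {"lambda": 10})
        with pytest.raises(ValueError):
            EncoderSpec("Seq", 19)


class TestContextMatrix:
    def test_left_edge_padding(self, tiny_record):
        ctx, mask = build_context_matrix(tiny_record, 0, 8, 0)
        assert mask[:8].all() and not mask[8:].any()
        assert not ctx[:8].any()

    def test_interior_no_padding_middle_row_is_ftr(self, tiny_record):
        W, i = 5, 10
        ctx, mask = build_context_matrix(tiny_record, i, W, 1)
        assert not mask.any()
        assert np.array_equal(ctx[W], build_targeted_feature(tiny_record, i, 1))

    @pytest.mark.parametrize("ffmod", [0, 1, 2])
    def test_against_slice_and_pad_oracle(self, tiny_record, ffmod):
        W = 4
        L = len(tiny_record)
        feats = np.stack([build_targeted_feature(tiny_record, j, ffmod) for j in range(L)])
        for i in [0, 3, L // 2, L - 1]:
            ctx, mask = build_context_matrix(tiny_record, i, W, ffmod)
            for off in range(-W, W + 1):
                j = i + off
                if 0 <= j < L:
                    assert np.allclose(ctx[off + W], feats[j])
                    assert not mask[off + W]
                else:
                    assert not ctx[off + W].any()
                    assert mask[off + W]

    def test_padded_row_count_formula(self, tiny_record):
        L, W = len(tiny_record), 7
        for i in range(L):
            _, mask = build_context_matrix(tiny_record, i, W, 0)
            assert mask.sum() == max(0, W - i) + max(0, i + W - L + 1)

    def test_featurize_record_matches_per_position(self, tiny_record):
        W = 3
        tr, ctx, mask = featurize_record(tiny_record, W, 0)
        for i in [0, 1, 12, len(tiny_record) - 1]:
            c, m = build_context_matrix(tiny_record, i, W, 0)
            assert np.allclose(ctx[i], c)
            assert np.array_equal(mask[i], m)
            assert np.allclose(tr[i], build_targeted_feature(tiny_record, i, 0))

    def test_feature_set_invariant_enforced(self, tiny_record):
        ctx, mask = build_context_matrix(tiny_record, 5, 3, 0)
        f_tr = build_targeted_feature(tiny_record, 5, 0)
        ResidueFeatureSet(0, f_tr, ctx, mask, 3)
        with pytest.raises(ValueError):
            ResidueFeatureSet(0, f_tr + 1.0, ctx, mask, 3)


def test_ffmod_dims_constant():
    assert FFMOD_DIMS == {0: 40, 1: 23, 2: 50}
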