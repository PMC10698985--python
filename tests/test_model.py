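import numpy as np
import pytest

from ppistack._nn import sigmoid
from ppistack.model import PPINetConfig, SiteNet


@pytest.fixture(scope="module")
def default_net():
    return SiteNet(PPINetConfig(ffmod=0, window=8, seed=3))


@pytest.fixture(scope="module")
def batch():
    rng = np.random.default_rng(0)
    B, L, d = 6, 17, 40
    ctx = rng.normal(size=(B, L, d))
    mask = np.zeros((B, L), dtype=bool)
    mask[0, :3] = True
    mask[2, -2:] = True
    tr = rng.normal(size=(B, d))
    return ctx, mask, tr


class TestConvBlock:
    def test_length_and_channels_preserved(self, default_net, batch):
        ctx, _, _ = batch
        Z = default_net.conv_block_forward(ctx)
        assert Z.shape == (6, 17, 8)

    def test_zero_input_zero_bias_gives_zero(self, default_net):
        out = default_net.conv_block_forward(np.zeros((2, 17, 40)))
        assert np.allclose(out, 0.0)  # biases are zero-initialized

    def test_single_layer_against_sliding_dot_product_oracle(self):
        cfg = PPINetConfig(ffmod=0, window=8, conv_layers=1, kernel_size=3,
                           n_kernels=2, pool_size=3, seed=1)
        net = SiteNet(cfg)
        conv, _, _ = net.conv_stages[0]
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 1))  # length-6, 1-channel input
        W = conv.params["W"] = rng.normal(size=(3, 1, 2))
        conv.params["b"] = np.zeros(2)
        out = net.conv_block_forward(x[None])[0]
        # oracle: zero-pad, slide dot product, relu, windowed max (same pad)
        xp = np.concatenate([[0.0], x[:, 0], [0.0]])
        pre = np.stack(
            [[np.dot(xp[i : i + 3], W[:, 0, o]) for o in range(2)] for i in range(6)]
        )
        act = np.maximum(pre, 0.0)
        padded = np.vstack([np.full((1, 2), -np.inf), act, np.full((1, 2), -np.inf)])
        pooled = np.stack([padded[i : i + 3].max(axis=0) for i in range(6)])
        assert np.allclose(out, pooled, atol=1e-12)

    def test_empty_sequence_rejected(self, default_net):
        with pytest.raises(ValueError):
            default_net.conv_block_forward(np.zeros((1, 0, 40)))


class TestMaskedAttention:
    def test_identical_values_convexity(self, default_net):
        # constant input rows -> constant V rows -> weighted mean returns them
        z = np.tile(np.random.default_rng(1).normal(size=(1, 1, 8)), (1, 17, 1))
        mask = np.zeros((1, 17), dtype=bool)
        A = default_net.masked_multihead_attention(z, mask)
        att = default_net.attention
        v = np.einsum("hmd,d->hm", att.params["Wv"], z[0, 0]).reshape(-1)
        assert np.allclose(A[0], v[None, :], atol=1e-9)

    def test_padded_position_gets_negligible_weight(self, default_net):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(1, 17, 8))
        mask = np.zeros((1, 17), dtype=bool)
        mask[0, 5] = True
        default_net.masked_multihead_attention(z, mask)
        weights = default_net.attention.last_weights  # (B, H, key, query)
        assert (weights[0, :, 5, :] < 1e-6).all()

    def test_weight_columns_sum_to_one(self, default_net, batch):
        ctx, mask, _ = batch
        Z = default_net.conv_block_forward(ctx)
        default_net.masked_multihead_attention(Z, mask)
        weights = default_net.attention.last_weights
        assert np.allclose(weights.sum(axis=2), 1.0, atol=1e-9)

    def test_hand_unrolled_oracle(self):
        """L=3, d_m=2, one head against a dense loop over the definition."""
        cfg = PPINetConfig(ffmod=0, window=1, n_heads=1, head_dim=2, seed=0)
        net = SiteNet(cfg)
        att = net.attention
        rng = np.random.default_rng(9)
        Wq = att.params["Wq"][0] = rng.normal(size=(2, 8))
        Wk = att.params["Wk"][0] = rng.normal(size=(2, 8))
        Wv = att.params["Wv"][0] = rng.normal(size=(2, 8))
        z = rng.normal(size=(3, 8))
        mask = np.array([False, False, True])
        A = net.masked_multihead_attention(z, mask)
        # dense unrolled computation
        q = [Wq @ z[i] for i in range(3)]
        k = [Wk @ z[i] for i in range(3)]
        v = [Wv @ z[i] for i in range(3)]
        E = np.array([[k[i] @ q[j] / np.sqrt(2) for j in range(3)] for i in range(3)])
        E[2, :] -= 1e9
        w = np.exp(E) / np.exp(E).sum(axis=0, keepdims=True)
        H = np.stack([sum(w[i, j] * v[i] for i in range(3)) for j in range(3)])
        assert np.allclose(A, H, atol=1e-10)

    def test_all_padded_rejected(self, default_net):
        z = np.zeros((1, 4, 8))
        with pytest.raises(ValueError):
            default_net.masked_multihead_attention(z, np.ones((1, 4), dtype=bool))


class TestAggregate:
    def test_row_dimension_with_defaults(self, default_net, batch):
        ctx, mask, _ = batch
        Z = default_net.conv_block_forward(ctx)
        A = default_net.masked_multihead_attention(Z, mask)
        f_agg = default_net.aggregate(Z, A, mask)
        assert f_agg.shape == (6, 72)  # 8 kernels + 4 heads x 16 dims

    def test_constant_rows_mean_identity(self):
        S_row = np.arange(72, dtype=float)
        Z = np.tile(S_row[:8], (1, 5, 1))
        A = np.tile(S_row[8:], (1, 5, 1))
        mask = np.zeros((1, 5), dtype=bool)
        assert np.allclose(SiteNet.aggregate(Z, A, mask)[0], S_row)

    def test_masked_mean_oracle(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(1, 10, 8))
        A = rng.normal(size=(1, 10, 64))
        mask = np.zeros((1, 10), dtype=bool)
        mask[0, [0, 4, 9]] = True
        f_agg = SiteNet.aggregate(Z, A, mask)[0]
        S = np.concatenate([Z, A], axis=2)[0]
        expected = S[~mask[0]].mean(axis=0)
        assert np.allclose(f_agg, expected, atol=1e-12)

    def test_no_valid_rows_rejected(self):
        with pytest.raises(ValueError):
            SiteNet.aggregate(np.zeros((1, 3, 8)), np.zeros((1, 3, 64)),
                              np.ones((1, 3), dtype=bool))


class TestPredictor:
    def test_zeroed_final_layer_gives_half(self, batch):
        net = SiteNet(PPINetConfig(ffmod=0, window=8, seed=2))
        net.fc[-1]["linear"].params["W"][:] = 0.0
        net.fc[-1]["linear"].params["b"][:] = 0.0
        x = np.random.default_rng(0).normal(size=(4, net.config.predictor_input_dim))
        assert np.allclose(net.predictor_forward(x), 0.5)

    def test_output_in_open_unit_interval(self, default_net):
        rng = np.random.default_rng(1)
        x = rng.normal(scale=50, size=(8, default_net.config.predictor_input_dim))
        p = default_net.predictor_forward(x)
        assert ((p > 0) & (p < 1)).all()

    def test_eval_mode_deterministic(self, default_net, batch):
        ctx, mask, tr = batch
        a = default_net.forward(ctx, mask, tr)
        b = default_net.forward(ctx, mask, tr)
        assert np.array_equal(a, b)

    def test_dimension_mismatch_rejected(self, default_net):
        with pytest.raises(ValueError):
            default_net.predictor_forward(np.zeros((2, 50)))


class TestFullForward:
    @pytest.mark.parametrize("ffmod,dim", [(0, 112), (1, 95), (2, 122)])
    def test_predictor_input_dimension(self, ffmod, dim):
        cfg = PPINetConfig(ffmod=ffmod, window=8)
        assert cfg.predictor_input_dim == dim

    def test_invariant_to_padded_row_content(self, default_net, batch):
        ctx, mask, tr = batch
        base = default_net.forward(ctx, mask, tr)
        perturbed = ctx.copy()
        perturbed[mask] = np.random.default_rng(3).normal(size=(mask.sum(), 40)) * 100
        assert np.allclose(default_net.forward(perturbed, mask, tr), base, atol=1e-9)

    def test_no_attention_ablation_matches_conv_only_oracle(self, batch):
        ctx, mask, tr = batch
        cfg = PPINetConfig(ffmod=0, window=8, use_attention=False, seed=5)
        net = SiteNet(cfg)
        assert cfg.agg_dim == 8
        p = net.forward(ctx, mask, tr)
        # oracle: run the reduced graph by hand
        Z = net.conv_block_forward(ctx * ~mask[:, :, None])
        f_agg = SiteNet.aggregate(Z, None, mask)
        oracle = net.predictor_forward(np.concatenate([f_agg, tr], axis=1))
        assert np.allclose(p, oracle, atol=1e-12)

    def test_single_head_matches_multihead_with_one_head(self, batch):
        """A 1-head model is single-head attention exactly: its concatenated
        output equals the lone head's output."""
        ctx, mask, _ = batch
        cfg = PPINetConfig(ffmod=0, window=8, n_heads=1, seed=6)
        net = SiteNet(cfg)
        Z = net.conv_block_forward(ctx)
        A = net.masked_multihead_attention(Z, mask)
        assert A.shape == (6, 17, 16)
        W = net.attention.last_weights
        H = np.einsum("bij,bim->bjm", W[:, 0], np.einsum(
            "md,bld->blm", net.attention.params["Wv"][0], Z))
        assert np.allclose(A, H, atol=1e-12)

    def test_mismatched_ftr_dim_rejected(self, default_net, batch):
        ctx, mask, _ = batch
        with pytest.raises(ValueError, match="ffmod"):
            default_net.forward(ctx, mask, np.zeros((6, 23)))

    def test_checkpoint_round_trip(self, tmp_path, default_net, batch):
        ctx, mask, tr = batch
        path = tmp_path / "net.npz"
        default_net.save(path)
        loaded = SiteNet.load(path)
        assert np.allclose(loaded.forward(ctx, mask, tr),
                           default_net.forward(ctx, mask, tr), atol=1e-15)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Central finite differences on a small network; rare mismatches at
        ReLU/max-pool kinks are tolerated, the bulk must agree tightly."""
        cfg = PPINetConfig(ffmod=0, window=2, conv_layers=2, kernel_size=3,
                           n_kernels=3, pool_size=3, n_heads=2, head_dim=2,
                           fc_sizes=(7, 5, 1), dropout_rate=0.0, seed=0)
        net = SiteNet(cfg)
        rng = np.random.default_rng(1)
        B, L, d = 6, 5, cfg.input_dim
        ctx = rng.normal(size=(B, L, d))
        mask = np.zeros((B, L), dtype=bool)
        mask[0, :2] = True
        tr = rng.normal(size=(B, d))
        y = rng.integers(0, 2, B).astype(float)

        def loss():
            logit = net.forward(ctx, mask, tr, training=True, return_logit=True)
            p = np.clip(sigmoid(logit), 1e-7, 1 - 1e-7)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        for ly in net.layers():
            ly.zero_grad()
        net.loss_and_grads(ctx, mask, tr, y, rng=None)
        errors = []
        pick = np.random.default_rng(0)
        for ly in net.layers():
            for k, P in ly.params.items():
                flat_idx = pick.choice(P.size, min(6, P.size), replace=False)
                for fi in flat_idx:
                    ix = np.unravel_index(fi, P.shape)
                    eps, old = 1e-6, P[ix]
                    P[ix] = old + eps
                    lp = loss()
                    P[ix] = old - eps
                    lm = loss()
                    P[ix] = old
                    num = (lp - lm) / (2 * eps)
                    g = ly.grads[k][ix]
                    errors.append(abs(num - g) / max(1e-8, abs(num) + abs(g)))
        errors = np.array(errors)
        assert np.median(errors) < 1e-7
        assert (errors < 1e-5).mean() > 0.95


def test_config_defaults_match_reference_tables():
    """Snapshot of the architecture and training defaults."""
    cfg = PPINetConfig()
    assert (cfg.conv_layers, cfg.kernel_size, cfg.n_kernels, cfg.pool_size) == (3, 5, 8, 3)
    assert (cfg.n_heads, cfg.head_dim) == (4, 16)
    assert cfg.fc_sizes == (1024, 256, 1)
    assert cfg.dropout_rate == 0.5
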