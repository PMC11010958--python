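"""Swin-Unet segmenter: windows, masked attention, merging/expanding, PUTS."""

import dataclasses

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad

from endovit import nn, stn, swin
from endovit.nn import ValidationError


def plain_softmax_attention(Q, K, V, bias=None, mask=None):
    """Scalar-loop evaluation of softmax(Q K^T / sqrt(d) + B + mask) V."""
    nq, dk = Q.shape
    out = np.zeros((nq, V.shape[1]))
    for i in range(nq):
        scores = np.array(
            [Q[i] @ K[j] / np.sqrt(dk) for j in range(K.shape[0])])
        if bias is not None:
            scores = scores + bias[i]
        if mask is not None:
            scores = scores + mask[i]
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        out[i] = w @ V
    return out


class TestWindows:
    @pytest.mark.parametrize("h,w,M", [(4, 4, 2), (8, 8, 4), (8, 12, 2),
                                       (6, 6, 3), (16, 16, 4)])
    def test_partition_reverse_round_trip(self, rng, h, w, M):
        fm = rng.normal(size=(2, h, w, 5))
        back = np.asarray(swin.window_reverse(
            swin.window_partition(fm, M), h, w, M))
        np.testing.assert_array_equal(back, fm)

    def test_window_contents_row_major(self):
        fm = np.arange(16, dtype=float).reshape(1, 4, 4, 1)
        wins = np.asarray(swin.window_partition(fm, 2))[..., 0]
        np.testing.assert_array_equal(wins[0], [0, 1, 4, 5])
        np.testing.assert_array_equal(wins[1], [2, 3, 6, 7])
        np.testing.assert_array_equal(wins[2], [8, 9, 12, 13])

    def test_indivisible_map_rejected(self, rng):
        with pytest.raises(ValidationError):
            swin.window_partition(rng.normal(size=(1, 5, 4, 3)), 2)

    def test_window_count(self, rng):
        wins = swin.window_partition(rng.normal(size=(3, 8, 8, 4)), 4)
        assert np.asarray(wins).shape == (3 * 4, 16, 4)


class TestRelativePositionBias:
    def test_index_range_and_center(self):
        M = 3
        idx = swin.relative_position_index(M)
        assert idx.shape == (9, 9)
        assert idx.min() >= 0 and idx.max() < (2 * M - 1) ** 2
        # zero offset (query == key) always maps to the same table entry
        diag = np.diag(idx)
        assert (diag == diag[0]).all()

    def test_equal_offsets_share_entries(self):
        """Pairs with the same spatial offset read the same table entry."""
        M = 3
        idx = swin.relative_position_index(M)
        coords = [(i, j) for i in range(M) for j in range(M)]
        for a in range(M * M):
            for b in range(M * M):
                for c in range(M * M):
                    for d in range(M * M):
                        da = (coords[a][0] - coords[b][0],
                              coords[a][1] - coords[b][1])
                        db = (coords[c][0] - coords[d][0],
                              coords[c][1] - coords[d][1])
                        if da == db:
                            assert idx[a, b] == idx[c, d]

    def test_bias_gather_matches_loop(self, rng):
        M, H = 2, 3
        table = rng.normal(size=((2 * M - 1) ** 2, H))
        idx = swin.relative_position_index(M)
        bias = np.asarray(swin.relative_position_bias(table, M))
        assert bias.shape == (H, M * M, M * M)
        for h in range(H):
            for i in range(M * M):
                for j in range(M * M):
                    assert bias[h, i, j] == table[idx[i, j], h]


class TestWindowAttention:
    def _attn_params(self, rng, dim, heads, M):
        p = nn.init_multi_head_attention(rng, dim, heads)
        p["bias_table"] = rng.normal(0.0, 0.02, size=((2 * M - 1) ** 2, heads))
        return p

    def test_no_information_crosses_windows(self, rng):
        """Perturbing one window leaves every other window's output intact."""
        M, dim, heads = 2, 4, 2
        p = self._attn_params(rng, dim, heads, M)
        fm = rng.normal(size=(1, 4, 4, dim))
        base = np.asarray(swin.w_msa(fm, p, M, heads))
        fm2 = fm.copy()
        fm2[0, 0, 0] += 10.0  # inside the top-left window only
        out2 = np.asarray(swin.w_msa(fm2, p, M, heads))
        np.testing.assert_array_equal(base[0, :2, 2:], out2[0, :2, 2:])
        np.testing.assert_array_equal(base[0, 2:, :], out2[0, 2:, :])
        assert np.abs(base[0, :2, :2] - out2[0, :2, :2]).max() > 0

    def test_gradient_zero_across_windows(self, rng):
        M, dim, heads = 2, 4, 2
        p = self._attn_params(rng, dim, heads, M)
        fm = rng.normal(size=(1, 4, 4, dim))

        def loss(x):  # depends only on the top-left window's output
            out = swin.w_msa(x, p, M, heads)
            return anp.sum(out[0, :2, :2] ** 2)

        g = grad(loss)(fm)
        assert np.abs(g[0, :2, :2]).sum() > 0
        np.testing.assert_array_equal(g[0, 2:, :], 0.0)
        np.testing.assert_array_equal(g[0, :2, 2:], 0.0)

    def test_single_window_matches_biased_attention_oracle(self, rng):
        """One window, one head: full scalar re-derivation of
        softmax(QK^T/sqrt(d) + B)V including the qkv/out projections."""
        M, dim, heads = 2, 4, 1
        p = self._attn_params(rng, dim, heads, M)
        fm = rng.normal(size=(1, M, M, dim))
        got = np.asarray(swin.w_msa(fm, p, M, heads))

        tokens = fm.reshape(M * M, dim)
        qkv = tokens @ p["qkv"]["W"] + p["qkv"]["b"]
        Q, K, V = qkv[:, :dim], qkv[:, dim:2 * dim], qkv[:, 2 * dim:]
        bias = np.asarray(swin.relative_position_bias(p["bias_table"], M))[0]
        att = plain_softmax_attention(Q, K, V, bias=bias)
        expected = (att @ p["proj"]["W"] + p["proj"]["b"]).reshape(1, M, M, dim)
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_zero_bias_table_reduces_to_plain_attention(self, rng):
        M, dim, heads = 2, 6, 2
        p = self._attn_params(rng, dim, heads, M)
        p["bias_table"] *= 0.0
        fm = rng.normal(size=(1, M, M, dim))
        got = np.asarray(swin.w_msa(fm, p, M, heads))
        tokens = fm.reshape(1, M * M, dim)
        expected = np.asarray(nn.multi_head_attention(tokens, p, heads))
        np.testing.assert_allclose(got.reshape(1, M * M, dim), expected,
                                   atol=1e-10)


class TestShiftedWindows:
    def test_cyclic_shift_matches_roll(self, rng):
        fm = rng.normal(size=(2, 6, 6, 3))
        for s in (-2, -1, 1, 2, 3):
            got = np.asarray(swin.cyclic_shift(fm, s))
            np.testing.assert_array_equal(got, np.roll(fm, (s, s),
                                                       axis=(1, 2)))

    def test_shift_round_trip(self, rng):
        fm = rng.normal(size=(1, 4, 4, 2))
        back = np.asarray(swin.cyclic_shift(swin.cyclic_shift(fm, -1), 1))
        np.testing.assert_array_equal(back, fm)

    def test_mask_blocks_exactly_cross_region_pairs(self):
        """Enumerate region labels directly and compare pair-by-pair."""
        h = w = 8
        M = 4
        s = M // 2
        mask = swin.sw_msa_mask(h, w, M)
        assert mask.shape == ((h // M) * (w // M), M * M, M * M)

        # region labels on the shifted map, derived independently: the shift
        # introduces two cut lines per axis, at h-M and h-s, splitting the map
        # into bands that were contiguous before the shift
        def region(i, j):
            rb = 0 if i < h - M else (1 if i < h - s else 2)
            cb = 0 if j < w - M else (1 if j < w - s else 2)
            return rb * 3 + cb

        labels = np.array([[region(i, j) for j in range(w)]
                           for i in range(h)], dtype=float)
        win = np.asarray(swin.window_partition(
            labels[None, :, :, None], M))[:, :, 0]
        for n in range(mask.shape[0]):
            for a in range(M * M):
                for b in range(M * M):
                    if win[n, a] == win[n, b]:
                        assert mask[n, a, b] == 0.0
                    else:
                        assert mask[n, a, b] <= swin.MASK_NEG

    def test_first_window_unmasked(self):
        mask = swin.sw_msa_mask(8, 8, 4)
        np.testing.assert_array_equal(mask[0], 0.0)

    def test_sw_msa_equals_manual_shift_mask_unshift(self, rng):
        M, dim, heads = 2, 4, 2
        p = nn.init_multi_head_attention(rng, dim, heads)
        p["bias_table"] = rng.normal(size=((2 * M - 1) ** 2, heads))
        fm = rng.normal(size=(1, 4, 4, dim))
        got = np.asarray(swin.sw_msa(fm, p, M, heads))
        shifted = np.roll(fm, (-1, -1), axis=(1, 2))
        mid = np.asarray(swin.w_msa(shifted, p, M, heads,
                                    mask=swin.sw_msa_mask(4, 4, M)))
        expected = np.roll(mid, (1, 1), axis=(1, 2))
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestBlocks:
    def test_fresh_block_pair_is_identity(self, rng):
        """Zero-initialized residual outputs make a new pair a no-op."""
        p = [swin.init_swin_block(rng, 8, 2, 2) for _ in range(2)]
        fm = rng.normal(size=(2, 4, 4, 8))
        out = np.asarray(swin.swin_block_pair(fm, p, 2, 2))
        np.testing.assert_allclose(out, fm, atol=1e-12)

    def test_block_matches_composed_steps(self, rng):
        dim, heads, M = 4, 1, 2
        p = swin.init_swin_block(rng, dim, heads, M)
        p["attn"]["proj"]["W"] = rng.normal(size=(dim, dim))
        p["mlp"]["fc2"]["W"] = rng.normal(size=(4 * dim, dim))
        fm = rng.normal(size=(1, 2, 2, dim))
        got = np.asarray(swin.swin_block(fm, p, M, heads, shifted=False))
        h1 = np.asarray(nn.layer_norm(fm, p["ln1"]["gain"], p["ln1"]["bias"]))
        y = fm + np.asarray(swin.w_msa(h1, p["attn"], M, heads))
        h2 = np.asarray(nn.layer_norm(y, p["ln2"]["gain"], p["ln2"]["bias"]))
        expected = y + np.asarray(nn.mlp(h2, p["mlp"]))
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_block_preserves_shape(self, rng):
        p = swin.init_swin_block(rng, 8, 2, 2)
        fm = rng.normal(size=(2, 4, 4, 8))
        for shifted in (False, True):
            assert np.asarray(swin.swin_block(fm, p, 2, 2,
                                              shifted)).shape == fm.shape


class TestMergingExpanding:
    def test_merging_halves_resolution_doubles_dim(self, rng):
        p = swin.init_patch_merging(rng, 6)
        fm = rng.normal(size=(2, 8, 8, 6))
        assert np.asarray(swin.patch_merging(fm, p)).shape == (2, 4, 4, 12)

    def test_merging_gathers_the_right_pixels(self, rng):
        """With identity LN and a projection that copies coordinate 0 of each
        of the four concatenated neighbours, the output reproduces the 2x2
        neighbourhood of channel-0 values exactly."""
        d = 3
        p = swin.init_patch_merging(rng, d)
        p["ln"]["gain"] = np.ones(4 * d)
        p["ln"]["bias"] = np.zeros(4 * d)
        W = np.zeros((4 * d, 2 * d))
        for k in range(4):
            W[k * d, k] = 1.0
        p["reduce"]["W"] = W
        p["reduce"]["b"] = np.zeros(2 * d)
        fm = rng.normal(size=(1, 4, 4, d))
        out = np.asarray(swin.patch_merging(fm, p))
        # reproduce the pre-projection layer norm on the concatenated vector
        for i in range(2):
            for j in range(2):
                cat = np.concatenate([fm[0, 2 * i, 2 * j],
                                      fm[0, 2 * i + 1, 2 * j],
                                      fm[0, 2 * i, 2 * j + 1],
                                      fm[0, 2 * i + 1, 2 * j + 1]])
                ln = (cat - cat.mean()) / np.sqrt(cat.var() + 1e-6)
                np.testing.assert_allclose(out[0, i, j, :4],
                                           ln[[0, d, 2 * d, 3 * d]],
                                           atol=1e-8)
                np.testing.assert_array_equal(out[0, i, j, 4:], 0.0)

    def test_merging_odd_size_rejected(self, rng):
        p = swin.init_patch_merging(rng, 4)
        with pytest.raises(ValidationError):
            swin.patch_merging(rng.normal(size=(1, 5, 4, 4)), p)

    @pytest.mark.parametrize("factor,out_shape",
                             [(2, (1, 8, 8, 4)), (4, (1, 16, 16, 8))])
    def test_expanding_shapes(self, rng, factor, out_shape):
        p = swin.init_patch_expanding(rng, 8, factor)
        fm = rng.normal(size=(1, 4, 4, 8))
        assert np.asarray(swin.patch_expanding(fm, p, factor)).shape == \
            out_shape

    def test_pixel_shuffle_scalar_oracle(self, rng):
        x = rng.normal(size=(1, 2, 2, 8))
        out = np.asarray(swin._pixel_shuffle(x, 2))
        assert out.shape == (1, 4, 4, 2)
        for i in range(4):
            for j in range(4):
                src = x[0, i // 2, j // 2].reshape(2, 2, 2)
                np.testing.assert_array_equal(out[0, i, j],
                                              src[i % 2, j % 2])

    def test_expand_then_merge_inverse_of_shuffle(self, rng):
        """pixel-shuffle by 2 followed by the 2x2 regather used in merging
        recovers the original spatial arrangement."""
        x = rng.normal(size=(1, 3, 3, 8))
        up = np.asarray(swin._pixel_shuffle(x, 2))
        regather = np.concatenate([up[:, 0::2, 0::2], up[:, 1::2, 0::2],
                                   up[:, 0::2, 1::2], up[:, 1::2, 1::2]],
                                  axis=-1)
        # regather order (x0,x1,x2,x3) = rows-then-cols; shuffle wrote
        # row-major (i%2, j%2) -> channel blocks, so permute accordingly
        perm = np.concatenate([x[..., 0:2], x[..., 4:6],
                               x[..., 2:4], x[..., 6:8]], axis=-1)
        np.testing.assert_array_equal(regather, perm)

    def test_invalid_factor_rejected(self, rng):
        with pytest.raises(ValidationError):
            swin.init_patch_expanding(rng, 8, 3)


class TestPuts:
    def test_forward_shape_and_distribution(self, rng, tiny_swin_cfg,
                                            tiny_swin_params):
        u = rng.random((2, 16, 16, 3))
        soft = np.asarray(swin.puts_forward(u, tiny_swin_cfg,
                                            tiny_swin_params))
        assert soft.shape == (2, 16, 16, 2)
        assert (soft >= 0).all()
        np.testing.assert_allclose(soft.sum(axis=-1), 1.0, atol=1e-6)

    def test_fresh_model_predicts_uniform(self, rng, tiny_swin_cfg,
                                          tiny_swin_params):
        """Zero-initialized head gives exactly 0.5/0.5 everywhere."""
        u = rng.random((1, 16, 16, 3))
        soft = np.asarray(swin.puts_forward(u, tiny_swin_cfg,
                                            tiny_swin_params))
        np.testing.assert_allclose(soft, 0.5, atol=1e-12)

    def test_identity_theta_equals_plain_swin_unet(self, rng, tiny_swin_cfg,
                                                   tiny_swin_params):
        """Forcing the affine transform to identity reproduces a conventional
        Swin-Unet with the same weights (the STN ablation axis)."""
        # randomize the head so both outputs are nontrivial
        params = {k: v for k, v in tiny_swin_params.items()}
        params["head"] = nn.init_dense(rng, tiny_swin_cfg.embed_dim, 2)
        u = rng.random((2, 16, 16, 3))
        with_stn = np.asarray(swin.puts_forward(
            u, tiny_swin_cfg, params, theta_override=stn.IDENTITY_THETA))
        plain_cfg = dataclasses.replace(tiny_swin_cfg, use_stn=False)
        plain_params = {k: v for k, v in params.items() if k != "stn"}
        plain = np.asarray(swin.puts_forward(u, plain_cfg, plain_params))
        assert np.abs(with_stn - plain).max() <= 1e-6

    def test_differentiable_end_to_end(self, rng, tiny_swin_cfg,
                                       tiny_swin_params):
        u = rng.random((1, 16, 16, 3))
        truth = (rng.random((1, 16, 16)) > 0.5).astype(int)

        def loss(p):
            return swin.seg_loss_from_logits(
                swin.puts_logits(u, tiny_swin_cfg, p), truth)

        g = grad(loss)(tiny_swin_params)
        flat = nn.count_params(g)
        assert flat == nn.count_params(tiny_swin_params)
        assert np.abs(g["head"]["b"]).sum() > 0


class TestSegLoss:
    def test_uniform_prediction_gives_ln2(self, rng):
        pred = np.full((2, 4, 4, 2), 0.5)
        truth = (rng.random((2, 4, 4)) > 0.5).astype(int)
        assert float(swin.seg_loss(pred, truth)) == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_prediction_near_zero(self):
        truth = np.zeros((1, 2, 2), dtype=int)
        truth[0, 0, 0] = 1
        pred = np.eye(2)[truth] * 0.999998 + 1e-6
        assert float(swin.seg_loss(pred, truth)) < 1e-5

    def test_matches_scalar_pixel_loop(self, rng):
        pred = rng.random((1, 3, 3, 2))
        pred = pred / pred.sum(axis=-1, keepdims=True)
        truth = (rng.random((1, 3, 3)) > 0.5).astype(int)
        expected = np.mean([-np.log(pred[0, i, j, truth[0, i, j]])
                            for i in range(3) for j in range(3)])
        assert float(swin.seg_loss(pred, truth)) == \
            pytest.approx(expected, abs=1e-9)

    def test_logits_form_agrees_with_soft_form(self, rng):
        logits = rng.normal(size=(1, 4, 4, 2))
        truth = (rng.random((1, 4, 4)) > 0.5).astype(int)
        soft = np.asarray(nn.softmax(logits, axis=-1))
        a = float(swin.seg_loss(soft, truth))
        b = float(swin.seg_loss_from_logits(logits, truth))
        assert a == pytest.approx(b, abs=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            swin.seg_loss(rng.random((1, 4, 4, 2)), np.zeros((1, 3, 4)))

    def test_hard_mask_is_argmax(self, rng):
        soft = rng.random((1, 4, 4, 2))
        soft = soft / soft.sum(axis=-1, keepdims=True)
        hm = swin.hard_mask(soft)
        assert hm.dtype == np.uint8
        np.testing.assert_array_equal(hm, (soft[..., 1] >= soft[..., 0]) * 1)


class TestConfigValidation:
    def test_odd_depth_rejected(self):
        with pytest.raises(ValidationError, match="even"):
            swin.SwinConfig(image_size=16, patch_size=4, embed_dim=8,
                            depths=(3, 2), heads=(2, 2), window_size=2)

    def test_window_not_dividing_resolution_rejected(self):
        with pytest.raises(ValidationError):
            swin.SwinConfig(image_size=16, patch_size=4, embed_dim=8,
                            depths=(2, 2), heads=(2, 2), window_size=3)

    def test_heads_depths_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            swin.SwinConfig(image_size=16, patch_size=4, embed_dim=8,
                            depths=(2, 2), heads=(2,), window_size=2)
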