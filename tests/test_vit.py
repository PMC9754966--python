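"""Transformer segmenter: patch handling, encoder algebra, decoder, schedule,
gradient correctness and small-scale training behaviour."""

import numpy as np
import pytest

import octdls.autodiff as ad
from octdls.vit import (
    SegModel,
    TrainConfig,
    ViTConfig,
    bilinear_matrix,
    interpolate_pos_embed,
    patchify,
    poly_lr,
    train,
    unpatchify,
)

TOY = ViTConfig(patch_size=8, embed_dim=16, n_layers=2, n_heads=2, input_size_px=32)


def bilinear_oracle(grid: np.ndarray, out_side: int, align_corners: bool) -> np.ndarray:
    """Direct per-pixel bilinear interpolation, independent of the matrix path."""
    n = grid.shape[0]
    out = np.zeros((out_side, out_side) + grid.shape[2:])
    for i in range(out_side):
        for j in range(out_side):
            if align_corners:
                y = i * (n - 1) / (out_side - 1) if out_side > 1 else 0.0
                x = j * (n - 1) / (out_side - 1) if out_side > 1 else 0.0
            else:
                y = np.clip((i + 0.5) * n / out_side - 0.5, 0, n - 1)
                x = np.clip((j + 0.5) * n / out_side - 0.5, 0, n - 1)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, n - 1), min(x0 + 1, n - 1)
            fy, fx = y - y0, x - x0
            out[i, j] = (
                grid[y0, x0] * (1 - fy) * (1 - fx)
                + grid[y0, x1] * (1 - fy) * fx
                + grid[y1, x0] * fy * (1 - fx)
                + grid[y1, x1] * fy * fx
            )
    return out


class TestPatchify:
    def test_patch_counts_and_lengths(self):
        img = np.zeros((512, 512, 3))
        p = patchify(img, 16)
        assert p.shape == (1024, 768)
        assert patchify(np.zeros((128, 128, 3)), 16).shape == (64, 768)

    def test_round_trip_reconstruction(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64, 3))
        assert np.array_equal(unpatchify(patchify(img, 16), 16, 64), img)

    def test_row_major_order(self):
        img = np.zeros((32, 32, 3))
        img[0:16, 16:32] = 1.0  # second patch in row-major order
        p = patchify(img, 16)
        assert p[1].sum() == 16 * 16 * 3 and p[0].sum() == 0

    def test_non_divisible_side_rejected(self):
        with pytest.raises(ValueError):
            patchify(np.zeros((100, 100, 3)), 16)


class TestEncoder:
    def test_zero_layer_encoder_is_tokens_plus_pos(self):
        cfg = ViTConfig(patch_size=8, embed_dim=16, n_layers=0, n_heads=2, input_size_px=32)
        model = SegModel(cfg, seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        img = rng.random((1, 32, 32, 3))
        x = model.embed(img)
        out = model.encode(x)
        tokens = patchify(img, 8)
        expected = tokens @ model.params["patch_w"].data + model.params["patch_b"].data
        expected = expected + model.params["pos"].data
        assert np.allclose(out.data, expected)

    def test_permutation_equivariance(self):
        """Permuting patches together with position embeddings permutes outputs."""
        model = SegModel(TOY, seed=3, dtype=np.float64)
        rng = np.random.default_rng(2)
        img = rng.random((1, 32, 32, 3))
        out1 = model.encode(model.embed(img)).data[0]
        perm = rng.permutation(TOY.n_patches)
        tokens = patchify(img, TOY.patch_size)[0]
        proj = tokens @ model.params["patch_w"].data + model.params["patch_b"].data
        x_perm = (proj + model.params["pos"].data)[perm][None]
        out2 = model.encode(ad.constant(x_perm)).data[0]
        assert np.allclose(out2, out1[perm], atol=1e-10)

    def test_output_finite_for_random_input(self):
        model = SegModel(TOY, seed=5)
        img = np.random.default_rng(3).random((2, 32, 32, 3))
        out = model.encode(model.embed(img))
        assert np.isfinite(out.data).all()

    def test_token_count_mismatch_rejected(self):
        model = SegModel(TOY, seed=0)
        with pytest.raises(ValueError):
            model.encode(ad.constant(np.zeros((1, 7, TOY.embed_dim))))


class TestDecoder:
    def test_pixel_probabilities_sum_to_one(self):
        model = SegModel(TOY, seed=1)
        img = np.random.default_rng(4).random((32, 32, 3))
        probs = model.predict_proba(img)
        assert probs.shape == (32, 32, 3)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_constant_logits_give_uniform_probabilities(self):
        p = ad.softmax(ad.constant(np.zeros((4, 4, 3))))
        assert np.allclose(p.data, 1 / 3)

    def test_patch_constant_logits_upsample_matches_bilinear_oracle(self):
        model = SegModel(TOY, seed=2, dtype=np.float64)
        rng = np.random.default_rng(5)
        g = TOY.grid_side
        logits_grid = rng.random((g, g, 3))
        # push the patch logits through the decoder's upsampling path
        grid_t = ad.constant(logits_grid.transpose(2, 0, 1)[None])
        interp = bilinear_matrix(g, 32, align_corners=False)
        up = ad.matmul(ad.matmul(ad.constant(interp), grid_t), ad.constant(interp.T))
        oracle = bilinear_oracle(logits_grid, 32, align_corners=False)
        assert np.allclose(up.data[0].transpose(1, 2, 0), oracle, atol=1e-12)

    def test_predict_mask_tie_breaks_to_lowest_class(self):
        probs = np.full((4, 4, 3), 1 / 3)
        assert (np.argmax(probs, axis=-1) == 0).all()
        model = SegModel(TOY, seed=7)
        img = np.zeros((32, 32, 3))
        mask = model.predict_mask(img)
        assert mask.shape == (32, 32)
        assert set(np.unique(mask)) <= {0, 1, 2}


class TestPolySchedule:
    def test_base_and_final_rates_exact(self):
        cfg = TrainConfig()
        assert poly_lr(0, 100, cfg) == 1e-3
        assert poly_lr(100, 100, cfg) == 0.0

    def test_midpoint_closed_form(self):
        cfg = TrainConfig()
        assert poly_lr(50, 100, cfg) == pytest.approx(1e-3 * 0.5**0.9)

    def test_zero_total_steps_rejected(self):
        with pytest.raises(ValueError):
            poly_lr(0, 0, TrainConfig())


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Central finite differences agree with backprop to 1e-4 relative."""
        cfg = ViTConfig(patch_size=8, embed_dim=8, n_layers=2, n_heads=2, input_size_px=16)
        model = SegModel(cfg, seed=9, dtype=np.float64)
        rng = np.random.default_rng(10)
        img = rng.random((1, 16, 16, 3))
        mask = rng.integers(0, 3, size=(1, 16, 16))

        loss = model.loss(img, mask)
        loss.backward()
        eps = 1e-6
        checked = 0
        for name in ("patch_w", "pos", "l0.wq", "l1.mlp_w1", "dec_w", "l0.ln1_g"):
            p = model.params[name]
            flat_idx = rng.integers(0, p.data.size, size=3)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.data.shape)
                orig = p.data[idx]
                p.data[idx] = orig + eps
                up = float(model.loss(img, mask).data)
                p.data[idx] = orig - eps
                down = float(model.loss(img, mask).data)
                p.data[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = p.grad[idx]
                # relative check, with an absolute floor where the gradient
                # itself is below finite-difference resolution
                denom = max(abs(numeric), abs(analytic), 1e-6)
                assert abs(numeric - analytic) / denom < 1e-4
                checked += 1
        assert checked == 18


class TestTraining:
    def test_initial_loss_near_ln3_on_balanced_labels(self):
        rng = np.random.default_rng(11)
        img = rng.random((32, 32, 3))
        mask = rng.integers(0, 3, size=(32, 32)).astype(np.uint8)
        model = SegModel(TOY, seed=12)
        loss = model.loss(img[None], mask[None])
        assert float(loss.data) == pytest.approx(np.log(3), rel=0.05)

    def test_memorizes_single_image(self):
        rng = np.random.default_rng(13)
        img = rng.random((32, 32, 3)) * 2 - 1
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[:16] = 1
        mask[16:, :16] = 2
        tcfg = TrainConfig(base_lr=0.1, epochs=60, batch_size=1, seed=0)
        model, log = train([(img, mask)], TOY, tcfg)
        early = np.mean([e["loss"] for e in log[:5]])
        late = np.mean([e["loss"] for e in log[-5:]])
        assert late < early
        acc = (model.predict_mask(img) == mask).mean()
        assert acc > 0.99

    def test_training_deterministic_given_seed(self):
        rng = np.random.default_rng(14)
        data = [
            (rng.random((32, 32, 3)), rng.integers(0, 3, size=(32, 32)).astype(np.uint8))
            for _ in range(3)
        ]
        tcfg = TrainConfig(base_lr=0.01, epochs=3, batch_size=2, seed=5)
        _, log1 = train(data, TOY, tcfg)
        _, log2 = train(data, TOY, tcfg)
        assert log1 == log2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TOY, TrainConfig())

    def test_bad_mask_label_rejected(self):
        img = np.zeros((32, 32, 3))
        mask = np.full((32, 32), 7, dtype=np.uint8)
        with pytest.raises(ValueError):
            train([(img, mask)], TOY, TrainConfig())


class TestPosEmbedTransfer:
    def test_same_size_is_identity(self):
        model = SegModel(TOY, seed=20)
        out = interpolate_pos_embed(model, TOY.input_size_px)
        assert np.array_equal(out.params["pos"].data, model.params["pos"].data)

    def test_constant_grid_stays_constant(self):
        model = SegModel(TOY, seed=21, dtype=np.float64)
        model.params["pos"].data[:] = 3.14
        out = interpolate_pos_embed(model, 64)
        assert np.allclose(out.params["pos"].data, 3.14)

    def test_linear_ramp_matches_bilinear_oracle_on_doubling(self):
        model = SegModel(TOY, seed=22, dtype=np.float64)
        g = TOY.grid_side
        ramp = np.linspace(0, 1, g)[:, None] * np.ones((g, g))
        model.params["pos"].data[:] = np.repeat(
            ramp.reshape(-1)[:, None], TOY.embed_dim, axis=1
        )
        out = interpolate_pos_embed(model, TOY.input_size_px * 2)
        got = out.params["pos"].data[:, 0].reshape(2 * g, 2 * g)
        oracle = bilinear_oracle(ramp[..., None], 2 * g, align_corners=True)[..., 0]
        assert np.allclose(got, oracle, atol=1e-12)

    def test_round_trip_approximates_smooth_grid(self):
        model = SegModel(TOY, seed=23, dtype=np.float64)
        g = TOY.grid_side
        yy, xx = np.meshgrid(np.linspace(0, np.pi, g), np.linspace(0, np.pi, g))
        smooth = np.sin(yy) * np.cos(xx)
        model.params["pos"].data[:] = np.repeat(
            smooth.reshape(-1)[:, None], TOY.embed_dim, axis=1
        )
        up = interpolate_pos_embed(model, TOY.input_size_px * 4)
        back = interpolate_pos_embed(up, TOY.input_size_px)
        err = np.abs(back.params["pos"].data - model.params["pos"].data).max()
        assert err < 0.05

    def test_other_parameters_untouched(self):
        model = SegModel(TOY, seed=24)
        out = interpolate_pos_embed(model, 64)
        assert np.array_equal(out.params["dec_w"].data, model.params["dec_w"].data)

    def test_non_divisible_size_rejected(self):
        model = SegModel(TOY, seed=25)
        with pytest.raises(ValueError):
            interpolate_pos_embed(model, 30)


class TestConfigValidation:
    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            ViTConfig(patch_size=16, input_size_px=100)

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ViTConfig(embed_dim=100, n_heads=3)
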