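"""Tiling, masking, reconstruction loss and MAE training/embedding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emmae.errors import ContractViolationError
from emmae.io_formats import MicrographImage
from emmae.representation import (
    MAEModel,
    MaskPattern,
    TileBatch,
    embed_micrograph,
    reconstruction_loss,
    sample_mask,
    tile_micrograph,
    train_mae,
    untile,
)


class TestTiling:
    def test_1024_gives_256_tiles(self):
        batch = tile_micrograph(np.zeros((1024, 1024)), 64)
        assert len(batch) == 256

    def test_grid_indices_row_major(self):
        batch = tile_micrograph(np.zeros((128, 128)), 64)
        assert len(batch) == 4
        assert [tuple(i) for i in batch.grid_index] == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_untile_is_exact_inverse(self, rng):
        pixels = rng.normal(size=(256, 256))
        np.testing.assert_array_equal(untile(tile_micrograph(pixels, 64)), pixels)

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ContractViolationError):
            tile_micrograph(np.zeros((100, 100)), 64)


class TestMasking:
    def test_exact_count(self):
        m = sample_mask(64, 0.5, 0)
        assert m.masked.sum() == 32

    @pytest.mark.parametrize("count,ratio", [(64, 0.5), (64, 0.75), (16, 0.3)])
    def test_count_rule_general(self, count, ratio):
        m = sample_mask(count, ratio, 5)
        assert m.masked.sum() == int(np.rint(ratio * count))

    def test_uniformity_over_many_draws(self):
        rng = np.random.default_rng(9)
        freq = np.zeros(64)
        n = 10_000
        for _ in range(n):
            freq += sample_mask(64, 0.5, rng).masked
        freq /= n
        assert freq.min() >= 0.47 and freq.max() <= 0.53

    def test_same_seed_identical(self):
        a = sample_mask(64, 0.5, 1234)
        b = sample_mask(64, 0.5, 1234)
        np.testing.assert_array_equal(a.masked, b.masked)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(count=st.integers(2, 256), ratio=st.floats(0.05, 0.95), seed=st.integers(0, 10**6))
    def test_exact_count_for_any_ratio(self, count, ratio, seed):
        m = sample_mask(count, ratio, seed)
        assert m.masked.sum() == int(np.rint(ratio * count))


class TestReconstructionLoss:
    def test_identity_is_zero(self, rng):
        Y = rng.normal(size=(16, 64))
        m = sample_mask(16, 0.5, rng)
        assert reconstruction_loss(Y, Y, m) == 0.0

    def test_constant_offset(self, rng):
        Y = rng.normal(size=(16, 64))
        mask = np.zeros(16, dtype=bool)
        mask[3] = True
        m = MaskPattern(masked=mask, ratio=1 / 16)
        assert reconstruction_loss(Y, Y + 2.0, m) == pytest.approx(4.0)

    def test_matches_loop_oracle(self, rng):
        Y = rng.normal(size=(16, 64))
        Yhat = rng.normal(size=(16, 64))
        m = sample_mask(16, 0.5, rng)
        total, n = 0.0, 0
        for i in range(16):
            if m.masked[i]:
                for j in range(64):
                    total += (Y[i, j] - Yhat[i, j]) ** 2
                    n += 1
        assert reconstruction_loss(Y, Yhat, m) == pytest.approx(total / n, abs=1e-10)

    def test_empty_mask_rejected(self, rng):
        Y = rng.normal(size=(4, 16))
        m = MaskPattern(masked=np.zeros(4, dtype=bool), ratio=0.5)
        with pytest.raises(ContractViolationError):
            reconstruction_loss(Y, Y, m)


class TestTraining:
    def _tiny_batch(self, cfg, rng, n_tiles=4):
        """Smooth random fields: structured content a tiny model can learn
        to inpaint (iid noise tiles would have no learnable structure)."""
        from scipy.ndimage import gaussian_filter

        raw = rng.normal(size=(n_tiles, cfg.tile_size, cfg.tile_size))
        tiles = np.stack([gaussian_filter(t, 3.0) for t in raw])
        tiles = (tiles - tiles.mean()) / tiles.std()
        idx = np.array([[i // 8, i % 8] for i in range(n_tiles)])
        return TileBatch(tiles=tiles, grid_index=idx, source_id="toy")

    def test_overfit_smoke(self, tiny_config, rng):
        """On four fixed tiles, 20 epochs at least halve the training loss."""
        cfg = tiny_config
        cfg.epochs = 20
        cfg.batch_size = 4
        cfg.learning_rate = 5e-3
        _, history = train_mae([self._tiny_batch(cfg, rng)], cfg)
        assert history[-1]["train_loss"] < 0.5 * history[0]["train_loss"]

    def test_validation_loss_mostly_non_increasing(self, tiny_config, rng):
        """The held-out loss (fixed tiles, frozen masks) decreases in at
        least 80% of epochs; the training loss itself is an average over
        freshly sampled masks, so it is the wrong monotonicity probe."""
        cfg = tiny_config
        cfg.epochs = 20
        cfg.batch_size = 32
        cfg.learning_rate = 5e-3
        _, history = train_mae([self._tiny_batch(cfg, rng, n_tiles=32)], cfg)
        losses = [h["val_loss"] for h in history]
        drops = sum(b <= a for a, b in zip(losses, losses[1:]))
        assert drops >= 0.8 * (len(losses) - 1)

    def test_deterministic_given_seeds(self, tiny_config, rng):
        cfg = tiny_config
        cfg.epochs = 5
        batch = self._tiny_batch(cfg, rng, n_tiles=8)
        _, h1 = train_mae([batch], cfg)
        _, h2 = train_mae([batch], cfg)
        assert h1[-1]["val_loss"] == h2[-1]["val_loss"]


class TestEmbedding:
    def test_grid_geometry(self, tiny_config, rng):
        model = MAEModel(tiny_config)
        img = MicrographImage(rng.normal(size=(64, 64)))
        emb = embed_micrograph(model, img)
        side = tiny_config.grid_size
        assert emb.grid.shape == (side, side, tiny_config.embed_dim)
        assert emb.stride_px == tiny_config.token_size
        assert np.all(np.isfinite(emb.grid))

    def test_deterministic(self, tiny_config, rng):
        model = MAEModel(tiny_config)
        pixels = rng.normal(size=(64, 64))
        a = embed_micrograph(model, MicrographImage(pixels))
        b = embed_micrograph(model, MicrographImage(pixels.copy()))
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_tiles_embed_independently(self, tiny_config, rng):
        """Swapping the content of two tiles swaps the corresponding grid
        blocks and leaves every other block unchanged."""
        cfg = tiny_config
        model = MAEModel(cfg)
        pixels = rng.normal(size=(64, 64))
        t = cfg.tile_size
        swapped = pixels.copy()
        swapped[0:t, 0:t], swapped[0:t, t : 2 * t] = (
            pixels[0:t, t : 2 * t].copy(),
            pixels[0:t, 0:t].copy(),
        )
        a = embed_micrograph(model, MicrographImage(pixels)).grid
        b = embed_micrograph(model, MicrographImage(swapped)).grid
        s = cfg.tokens_per_tile_side
        np.testing.assert_allclose(a[:s, :s], b[:s, s : 2 * s], atol=1e-10)
        np.testing.assert_allclose(a[:s, s : 2 * s], b[:s, :s], atol=1e-10)
        np.testing.assert_allclose(a[s:], b[s:], atol=1e-10)

    def test_wrong_resolution_rejected(self, tiny_config, rng):
        model = MAEModel(tiny_config)
        with pytest.raises(ContractViolationError):
            embed_micrograph(model, MicrographImage(rng.normal(size=(128, 128))))
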