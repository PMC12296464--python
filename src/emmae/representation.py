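"""Masked-autoencoder representation learning for micrograph tiles.

Working-resolution micrographs (1024x1024 by default) are cut into
non-overlapping 64x64 tiles — 256 per micrograph — so the model attends to
local context only, which suits micrographs' lack of long-range spatial
correlation.  Each tile is further split into 8x8-pixel tokens.  During
training, 50% of the tokens of every tile are hidden (independent uniform
draws per tile, exact count); the ViT encoder sees only the visible tokens
and a shallow decoder reconstructs the hidden pixels, trained with MSE over
the masked tokens.  No labels are involved at any point.

At inference no masking is applied: every token is encoded, and the 192-d
encoder outputs are arranged on a spatial grid (one cell per token, stride
= token size in working-frame pixels).  That grid is the clustering space
for segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .errors import ContractViolationError, TrainingError
from .io_formats import MicrographImage
from . import nn

__all__ = [
    "TileBatch",
    "MaskPattern",
    "MAEModel",
    "EmbeddingMap",
    "tile_micrograph",
    "untile",
    "sample_mask",
    "reconstruction_loss",
    "train_mae",
    "embed_micrograph",
]


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


@dataclass
class TileBatch:
    """All tiles of one micrograph, row-major, with their grid indices."""

    tiles: np.ndarray  # (n_tiles, tile, tile)
    grid_index: np.ndarray  # (n_tiles, 2) -> (row, col) in the tiling grid
    source_id: str = ""

    def __len__(self) -> int:
        return self.tiles.shape[0]


def tile_micrograph(X: MicrographImage | np.ndarray, tile_size: int) -> TileBatch:
    """Partition a working-resolution image into non-overlapping tiles."""
    pixels = X.pixels if isinstance(X, MicrographImage) else np.asarray(X, float)
    source = X.id if isinstance(X, MicrographImage) else ""
    rows, cols = pixels.shape
    if rows % tile_size or cols % tile_size:
        raise ContractViolationError(
            f"image shape {pixels.shape} not divisible by tile size {tile_size}"
        )
    gr, gc = rows // tile_size, cols // tile_size
    tiles = (
        pixels.reshape(gr, tile_size, gc, tile_size)
        .transpose(0, 2, 1, 3)
        .reshape(gr * gc, tile_size, tile_size)
    )
    idx = np.stack(np.meshgrid(np.arange(gr), np.arange(gc), indexing="ij"), axis=-1)
    return TileBatch(tiles=tiles.copy(), grid_index=idx.reshape(-1, 2), source_id=source)


def untile(batch: TileBatch) -> np.ndarray:
    """Exact inverse of :func:`tile_micrograph`."""
    n, t, _ = batch.tiles.shape
    gr = int(batch.grid_index[:, 0].max()) + 1
    gc = int(batch.grid_index[:, 1].max()) + 1
    out = np.empty((gr * t, gc * t))
    for tile, (r, c) in zip(batch.tiles, batch.grid_index):
        out[r * t : (r + 1) * t, c * t : (c + 1) * t] = tile
    return out


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------


@dataclass
class MaskPattern:
    """Boolean token mask within one tile; True = hidden from the encoder."""

    masked: np.ndarray
    ratio: float


def sample_mask(
    token_count: int, ratio: float, rng: np.random.Generator | int
) -> MaskPattern:
    """Mask exactly round(ratio * token_count) tokens, uniformly at random."""
    if not 0.0 < ratio < 1.0:
        raise ContractViolationError("mask ratio must lie in (0, 1)")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n_masked = int(np.rint(ratio * token_count))
    chosen = rng.choice(token_count, size=n_masked, replace=False)
    masked = np.zeros(token_count, dtype=bool)
    masked[chosen] = True
    return MaskPattern(masked=masked, ratio=ratio)


def reconstruction_loss(
    Y: np.ndarray, Yhat: np.ndarray, m: MaskPattern
) -> float:
    """MSE over the pixels of the masked tokens only.

    ``Y`` and ``Yhat`` have shape (token_count, pixels_per_token).
    """
    Y = np.asarray(Y, float)
    Yhat = np.asarray(Yhat, float)
    if Y.shape != Yhat.shape:
        raise ContractViolationError("shape mismatch between target and output")
    if not m.masked.any():
        raise ContractViolationError("empty mask: loss is undefined")
    diff = Y[m.masked] - Yhat[m.masked]
    return float(np.mean(diff**2))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


def standardize_tiles(tiles: np.ndarray) -> np.ndarray:
    """Zero-mean / unit-std standardization over one micrograph's tiles.

    The enhanced image lives in [0, 1] with low contrast; standardizing per
    micrograph puts the model input (and hence the latent geometry) on a
    common O(1) scale across micrographs.
    """
    mu = tiles.mean()
    sd = tiles.std()
    return (tiles - mu) / (sd if sd > 0 else 1.0)


def _tokenize(tiles: np.ndarray, token_size: int) -> np.ndarray:
    """(B, T, T) tiles -> (B, n_tok, token_size**2) row-major tokens."""
    B, T, _ = tiles.shape
    s = T // token_size
    return (
        tiles.reshape(B, s, token_size, s, token_size)
        .transpose(0, 1, 3, 2, 4)
        .reshape(B, s * s, token_size**2)
    )


class MAEModel:
    """Masked autoencoder: ViT encoder (width 192) + shallow ViT decoder."""

    def __init__(self, cfg: RunConfig, init_seed: int | None = None):
        self.cfg = cfg
        rng = np.random.default_rng(
            cfg.training_seed if init_seed is None else init_seed
        )
        p = cfg.token_size**2
        d, dd = cfg.embed_dim, cfg.decoder_dim
        side = cfg.tokens_per_tile_side

        # learned positional embeddings, small init (ViT convention); keeping
        # them small at the start stops token position from dominating the
        # latent geometry that downstream clustering relies on
        self.patch_embed = nn.Linear(rng, p, d)
        self.enc_pos = nn.Parameter(rng.normal(0.0, 0.02, size=(side * side, d)))
        self.enc_blocks = [
            nn.TransformerBlock(rng, d, cfg.encoder_heads, cfg.mlp_ratio)
            for _ in range(cfg.encoder_depth)
        ]
        self.enc_norm = nn.LayerNorm(d)

        self.dec_embed = nn.Linear(rng, d, dd)
        self.mask_token = nn.Parameter(rng.normal(0.0, 0.02, size=dd))
        self.dec_pos = nn.Parameter(rng.normal(0.0, 0.02, size=(side * side, dd)))
        self.dec_blocks = [
            nn.TransformerBlock(rng, dd, cfg.decoder_heads, cfg.mlp_ratio)
            for _ in range(cfg.decoder_depth)
        ]
        self.dec_norm = nn.LayerNorm(dd)
        self.head = nn.Linear(rng, dd, p)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[nn.Parameter]:
        params = self.patch_embed.parameters()
        params.append(self.enc_pos)
        for blk in self.enc_blocks:
            params += blk.parameters()
        params += self.enc_norm.parameters()
        params += self.dec_embed.parameters()
        params.append(self.mask_token)
        params.append(self.dec_pos)
        for blk in self.dec_blocks:
            params += blk.parameters()
        params += self.dec_norm.parameters()
        params += self.head.parameters()
        return params

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value[...] = v

    # -- forward / backward -------------------------------------------------

    def encode_tokens(
        self, tokens: np.ndarray, vis_idx: np.ndarray | None = None
    ) -> np.ndarray:
        """Encoder forward.  ``tokens``: (B, n_tok, p); ``vis_idx``: (B, n_vis)
        restricts the encoder to visible tokens (training); None encodes all
        tokens (inference)."""
        B = tokens.shape[0]
        if vis_idx is not None:
            rows = np.arange(B)[:, None]
            x_in = tokens[rows, vis_idx]
            pos = self.enc_pos.value[vis_idx]
        else:
            x_in = tokens
            pos = self.enc_pos.value[None, :, :]
        self._enc_vis_idx = vis_idx
        x = self.patch_embed.forward(x_in) + pos
        for blk in self.enc_blocks:
            x = blk.forward(x)
        return self.enc_norm.forward(x)

    def _encode_backward(self, g: np.ndarray) -> None:
        g = self.enc_norm.backward(g)
        for blk in reversed(self.enc_blocks):
            g = blk.backward(g)
        vis_idx = self._enc_vis_idx
        if vis_idx is not None:
            np.add.at(self.enc_pos.grad, vis_idx.reshape(-1), g.reshape(-1, g.shape[-1]))
        else:
            self.enc_pos.grad += g.sum(axis=0)
        self.patch_embed.backward(g)

    def forward_loss(
        self, tiles: np.ndarray, masks: np.ndarray, compute_grad: bool = True
    ) -> float:
        """Masked-reconstruction MSE for a batch of tiles.

        ``tiles``: (B, T, T); ``masks``: (B, n_tok) bool, identical masked
        counts per tile.  Accumulates parameter gradients when requested.
        """
        cfg = self.cfg
        tokens = _tokenize(tiles, cfg.token_size)
        B, n_tok, p = tokens.shape
        n_vis = n_tok - int(masks[0].sum())
        rows = np.arange(B)[:, None]
        # identical per-tile counts let visible tokens batch as a dense array
        vis_idx = np.stack([np.flatnonzero(~m)[:n_vis] for m in masks])

        latents = self.encode_tokens(tokens, vis_idx)  # (B, n_vis, d)

        y_vis = self.dec_embed.forward(latents)  # (B, n_vis, dd)
        dd = y_vis.shape[-1]
        full = np.broadcast_to(self.mask_token.value, (B, n_tok, dd)).copy()
        full[rows, vis_idx] = y_vis
        full = full + self.dec_pos.value[None, :, :]
        x = full
        for blk in self.dec_blocks:
            x = blk.forward(x)
        x = self.dec_norm.forward(x)
        recon = self.head.forward(x)  # (B, n_tok, p)

        diff = (recon - tokens) * masks[:, :, None]
        n_loss_pix = int(masks.sum()) * p
        loss = float((diff**2).sum() / n_loss_pix)

        if compute_grad:
            g = (2.0 / n_loss_pix) * diff
            g = self.head.backward(g)
            g = self.dec_norm.backward(g)
            for blk in reversed(self.dec_blocks):
                g = blk.backward(g)
            self.dec_pos.grad += g.sum(axis=0)
            # split the full-sequence gradient into visible / masked parts
            g_vis = g[rows, vis_idx]
            mask_grad = g.copy()
            mask_grad[rows, vis_idx] = 0.0
            self.mask_token.grad += mask_grad.reshape(-1, dd).sum(axis=0)
            g_lat = self.dec_embed.backward(g_vis)
            self._encode_backward(g_lat)
        return loss

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": v for i, v in enumerate(self.state())}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.cfg.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MAEModel":
        path = Path(path)
        cfg = RunConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state([data[f"p{i}"] for i in range(len(data.files))])
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _lr_schedule(step: int, total: int, base_lr: float, warmup_fraction: float) -> float:
    warmup = max(int(round(warmup_fraction * total)), 1)
    if step < warmup:
        return base_lr * (step + 1) / warmup
    prog = (step - warmup) / max(total - warmup, 1)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * prog))


def train_mae(
    tile_batches: list[TileBatch],
    cfg: RunConfig,
    log_path: str | Path | None = None,
) -> tuple[MAEModel, list[dict]]:
    """Train the MAE on tiles pooled from the given micrographs.

    20% of the tiles (seeded shuffle) are held out; the checkpoint with the
    lowest held-out reconstruction loss is returned, together with the
    per-epoch history.  Validation masks are drawn once and frozen so the
    selection criterion is deterministic.
    """
    if not tile_batches:
        raise ContractViolationError("need at least one micrograph of tiles")
    tiles = np.concatenate(
        [standardize_tiles(b.tiles) for b in tile_batches], axis=0
    )
    n_total = tiles.shape[0]
    n_tok = cfg.tokens_per_tile

    rng = np.random.default_rng(cfg.training_seed)
    mask_rng = np.random.default_rng(cfg.masking_seed)
    order = rng.permutation(n_total)
    n_val = max(int(round(cfg.val_fraction * n_total)), 1) if n_total > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:  # tiny corpora: train on everything
        train_idx = order
    val_tiles = tiles[val_idx]
    val_masks = np.stack(
        [sample_mask(n_tok, cfg.mask_ratio, mask_rng).masked for _ in range(n_val)]
    ) if n_val else None

    model = MAEModel(cfg)
    opt = nn.AdamW(
        model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay
    )
    n_train = train_idx.size
    batch = min(cfg.batch_size, n_train)
    steps_per_epoch = int(np.ceil(n_train / batch))
    total_steps = steps_per_epoch * cfg.epochs

    best_val = np.inf
    best_state = model.state()
    history: list[dict] = []
    step = 0
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, batch):
            idx = train_idx[perm[start : start + batch]]
            bt = tiles[idx]
            masks = np.stack(
                [sample_mask(n_tok, cfg.mask_ratio, mask_rng).masked for _ in idx]
            )
            opt.zero_grad()
            loss = model.forward_loss(bt, masks, compute_grad=True)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            opt.step(_lr_schedule(step, total_steps, cfg.learning_rate, cfg.warmup_fraction))
            epoch_loss += loss * len(idx)
            step += 1
        epoch_loss /= n_train

        if n_val:
            val_loss = model.forward_loss(val_tiles, val_masks, compute_grad=False)
        else:
            val_loss = epoch_loss
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        history.append({"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()

    model.load_state(best_state)
    if log_path is not None:
        lines = ["epoch,train_loss,val_loss"] + [
            f"{h['epoch']},{h['train_loss']:.8g},{h['val_loss']:.8g}" for h in history
        ]
        Path(log_path).write_text("\n".join(lines) + "\n")
    return model, history


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingMap:
    """Spatial grid of latent vectors for one micrograph.

    ``grid`` has shape (H_e, W_e, embed_dim); cell (i, j) covers the
    ``stride_px``-pixel square starting at working-frame pixel
    (i * stride_px, j * stride_px).
    """

    grid: np.ndarray
    stride_px: int
    source_id: str = ""

    @property
    def n_cells(self) -> int:
        return self.grid.shape[0] * self.grid.shape[1]

    def vectors(self) -> np.ndarray:
        """Row-major (n_cells, embed_dim) view of the grid."""
        return self.grid.reshape(-1, self.grid.shape[-1])


def embed_micrograph(model: MAEModel, X: MicrographImage | np.ndarray) -> EmbeddingMap:
    """Encode every token of every tile; no masking at inference."""
    cfg = model.cfg
    pixels = X.pixels if isinstance(X, MicrographImage) else np.asarray(X, float)
    if pixels.shape != (cfg.working_size, cfg.working_size):
        raise ContractViolationError(
            f"expected working-resolution input {cfg.working_size}, got {pixels.shape}"
        )
    batch = tile_micrograph(X, cfg.tile_size)
    tokens = _tokenize(standardize_tiles(batch.tiles), cfg.token_size)
    latents = model.encode_tokens(tokens, vis_idx=None)  # (n_tiles, n_tok, d)

    side = cfg.tokens_per_tile_side
    g = cfg.grid_size
    grid = np.empty((g, g, cfg.embed_dim))
    lat_tiles = latents.reshape(len(batch), side, side, cfg.embed_dim)
    for lt, (r, c) in zip(lat_tiles, batch.grid_index):
        grid[r * side : (r + 1) * side, c * side : (c + 1) * side] = lt
    return EmbeddingMap(grid=grid, stride_px=cfg.token_size, source_id=batch.source_id)
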