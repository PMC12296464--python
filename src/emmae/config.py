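"""Run configuration for the picking pipeline.

A single :class:`RunConfig` carries every tunable of the pipeline: the
working resolution and tiling geometry, the masked-autoencoder architecture
and optimizer settings, the clustering parameters and the post-processing
thresholds.  Defaults correspond to the full-scale operating point
(1024x1024 working images, 64x64 tiles, 192-d latents, 50% masking,
400 epochs); :func:`RunConfig.desk` returns a scaled-down profile suitable
for single-CPU runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ContractViolationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # geometry
    working_size: int = 1024
    tile_size: int = 64
    token_size: int = 8

    # masked autoencoder
    mask_ratio: float = 0.5
    embed_dim: int = 192
    encoder_depth: int = 6
    encoder_heads: int = 3
    decoder_dim: int = 96
    decoder_depth: int = 2
    decoder_heads: int = 3
    mlp_ratio: float = 4.0

    # optimisation
    epochs: int = 400
    batch_size: int = 64
    learning_rate: float = 1.5e-4
    weight_decay: float = 0.01
    warmup_fraction: float = 0.05
    val_fraction: float = 0.2

    # preprocessing
    wiener_window: int = 5
    clahe_clip_limit: float = 2.0
    clahe_tiles: int = 8
    guided_eps: float = 1e-2

    # clustering
    n_reference_clusters: int = 4
    max_iters: int = 5
    kmeans_restarts: int = 10
    kmeans_tol: float = 1e-6
    max_train_latents: int = 200_000

    # post-processing
    target_fraction: float = 0.04
    radius_factor: float = 1.5
    n_thresholds: int = 101

    # seeds
    seed: int = 0
    training_seed: int | None = None
    clustering_seed: int | None = None
    masking_seed: int | None = None

    def __post_init__(self) -> None:
        if self.working_size % self.tile_size != 0:
            raise ContractViolationError(
                f"working_size {self.working_size} not divisible by "
                f"tile_size {self.tile_size}"
            )
        if self.tile_size % self.token_size != 0:
            raise ContractViolationError(
                f"tile_size {self.tile_size} not divisible by "
                f"token_size {self.token_size}"
            )
        if not 0.0 < self.mask_ratio < 1.0:
            raise ContractViolationError("mask_ratio must lie in (0, 1)")
        if not 0.0 < self.target_fraction < 1.0:
            raise ContractViolationError("target_fraction must lie in (0, 1)")
        if self.max_iters < 3:
            raise ContractViolationError("max_iters must be >= 3")
        if self.training_seed is None:
            self.training_seed = self.seed + 1
        if self.clustering_seed is None:
            self.clustering_seed = self.seed + 2
        if self.masking_seed is None:
            self.masking_seed = self.seed + 3

    # -- derived geometry ---------------------------------------------------

    @property
    def tiles_per_side(self) -> int:
        return self.working_size // self.tile_size

    @property
    def tiles_per_micrograph(self) -> int:
        return self.tiles_per_side**2

    @property
    def tokens_per_tile_side(self) -> int:
        return self.tile_size // self.token_size

    @property
    def tokens_per_tile(self) -> int:
        return self.tokens_per_tile_side**2

    @property
    def grid_size(self) -> int:
        """Side length of the per-micrograph embedding grid."""
        return self.working_size // self.token_size

    # -- profiles -----------------------------------------------------------

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Scaled-down profile for single-CPU runs.

        256x256 working images tiled into 32x32 tiles (64 per micrograph),
        a 2-block encoder and 30 training epochs.  The latent width stays
        at 192 so downstream clustering behaves identically.
        """
        base = dict(
            working_size=256,
            tile_size=32,
            token_size=8,
            encoder_depth=2,
            decoder_depth=1,
            epochs=30,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ContractViolationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
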