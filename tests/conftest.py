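"""Shared fixtures.

``desk_benchmark`` is the expensive session fixture: it generates the
synthetic benchmark (10 micrographs at the generator defaults), trains the
scaled-down picker on the first five and exposes the held-out five for
evaluation.  Tests that only need geometry use ``tiny_config`` instead,
which instantiates in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from emmae.config import RunConfig
from emmae.pipeline import PickerArtifacts, train_picker
from emmae.synthetic import SyntheticSpec, SyntheticSample, generate_dataset


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config() -> RunConfig:
    """Smallest legal geometry: 64 px working frame, 16 px tiles, 4 px tokens."""
    return RunConfig(
        working_size=64,
        tile_size=16,
        token_size=4,
        embed_dim=8,
        encoder_depth=1,
        encoder_heads=2,
        decoder_dim=8,
        decoder_depth=1,
        decoder_heads=2,
        mlp_ratio=2.0,
        epochs=5,
        seed=7,
    )


@dataclass
class DeskBenchmark:
    spec: SyntheticSpec
    cfg: RunConfig
    artifacts: PickerArtifacts
    train_samples: list[SyntheticSample]
    test_samples: list[SyntheticSample]


@pytest.fixture(scope="session")
def desk_benchmark() -> DeskBenchmark:
    """Train the desk-profile picker once per session on the benchmark data."""
    spec = SyntheticSpec()  # generator defaults are the benchmark conditions
    samples = generate_dataset(spec, 10, base_seed=123)
    train, test = samples[:5], samples[5:]
    cfg = RunConfig.desk(seed=1)
    artifacts = train_picker(
        [s.micrograph for s in train], spec.diameter_px, train[0].mask, cfg
    )
    return DeskBenchmark(
        spec=spec, cfg=cfg, artifacts=artifacts, train_samples=train, test_samples=test
    )
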