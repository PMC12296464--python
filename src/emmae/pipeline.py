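"""End-to-end orchestration: train a picker, pick micrographs, evaluate.

Functions here wire the stage modules together and own the on-disk artifact
layout (model weights, reference cluster model, run manifest, coordinate
files).  The command-line interface in :mod:`emmae.cli` is a thin wrapper
over these functions; library users can call them directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .config import RunConfig
from .errors import ContractViolationError
from .evaluation import Metrics, aggregate, match_and_score
from .io_formats import MicrographImage, ParticleSet, write_coords
from .postprocess import FilterParams, postprocess_mask
from .preprocess import preprocess_micrograph
from .representation import MAEModel, embed_micrograph, tile_micrograph, train_mae
from .segmentation import (
    ReferenceClusterModel,
    assign_initial,
    fit_reference_clusters,
    hierarchical_refine,
)

__all__ = ["PickerArtifacts", "train_picker", "pick_micrograph", "evaluate_picks"]

logger = logging.getLogger(__name__)


@dataclass
class PickerArtifacts:
    """Everything needed to pick: MAE weights, cluster model, config."""

    model: MAEModel
    clusters: ReferenceClusterModel
    cfg: RunConfig
    manifest: dict

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.model.save(out_dir / "model")
        self.clusters.save(out_dir / "clusters.npz")
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path) -> "PickerArtifacts":
        out_dir = Path(out_dir)
        model = MAEModel.load(out_dir / "model")
        clusters = ReferenceClusterModel.load(out_dir / "clusters.npz")
        manifest = json.loads((out_dir / "manifest.json").read_text())
        return cls(model=model, clusters=clusters, cfg=model.cfg, manifest=manifest)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def train_picker(
    micrographs: list[MicrographImage],
    diameter_px: float,
    ref_mask: np.ndarray,
    cfg: RunConfig,
    out_dir: str | Path | None = None,
) -> PickerArtifacts:
    """Preprocess, train the MAE, and fit the train-set cluster model.

    ``ref_mask`` is the binary particle mask of the *first* micrograph, in
    that micrograph's original frame; it identifies the particle cluster.
    ``diameter_px`` is the particle diameter in original-frame pixels,
    shared across the training micrographs.
    """
    if not micrographs:
        raise ContractViolationError("need at least one training micrograph")
    if ref_mask is None:
        raise ContractViolationError("a reference particle mask is required")
    if ref_mask.shape != micrographs[0].shape:
        raise ContractViolationError(
            "reference mask shape must match the first micrograph"
        )

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    working: list[MicrographImage] = []
    for mi in micrographs:
        w, _, _, _ = preprocess_micrograph(mi, diameter_px, cfg)
        working.append(w)
    timings["preprocess_s"] = time.perf_counter() - t0

    batches = [tile_micrograph(w, cfg.tile_size) for w in working]
    n_tiles = sum(len(b) for b in batches)

    t0 = time.perf_counter()
    log_path = Path(out_dir) / "training_log.csv" if out_dir else None
    if log_path:
        log_path.parent.mkdir(parents=True, exist_ok=True)
    model, history = train_mae(batches, cfg, log_path=log_path)
    timings["train_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    embeddings = [embed_micrograph(model, w) for w in working]
    pooled = np.concatenate([e.vectors() for e in embeddings], axis=0)

    if ref_mask.shape != (cfg.working_size, cfg.working_size):
        ref_mask_working = (
            _sk_resize(
                ref_mask.astype(np.float64),
                (cfg.working_size, cfg.working_size),
                order=0,
                anti_aliasing=False,
                preserve_range=True,
            )
            >= 0.5
        )
    else:
        ref_mask_working = ref_mask.astype(bool)
    clusters = fit_reference_clusters(
        pooled, embeddings[0], ref_mask_working, seed=cfg.clustering_seed, cfg=cfg
    )
    timings["cluster_s"] = time.perf_counter() - t0

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "n_micrographs": len(micrographs),
        "n_training_tiles": n_tiles,
        "diameter_px": diameter_px,
        "final_val_loss": history[-1]["val_loss"] if history else None,
        "best_val_loss": min(h["val_loss"] for h in history) if history else None,
        "particle_cluster": clusters.particle_id,
        "timings": timings,
    }
    artifacts = PickerArtifacts(model=model, clusters=clusters, cfg=cfg, manifest=manifest)
    if out_dir is not None:
        artifacts.save(out_dir)
    return artifacts


def pick_micrograph(
    artifacts: PickerArtifacts,
    micrograph: MicrographImage,
    diameter_px: float,
    max_iters: int | None = None,
    clustering_seed: int | None = None,
) -> ParticleSet:
    """Pick particles in one micrograph; returns original-frame coordinates."""
    cfg = artifacts.cfg
    max_iters = cfg.max_iters if max_iters is None else max_iters
    seed = cfg.clustering_seed if clustering_seed is None else clustering_seed

    work, sx, sy, diam_working = preprocess_micrograph(micrograph, diameter_px, cfg)
    emb = embed_micrograph(artifacts.model, work)
    state = assign_initial(emb, artifacts.clusters)
    grid_mask = hierarchical_refine(emb, state, seed=seed, max_iters=max_iters, cfg=cfg)

    fp = FilterParams(
        diameter_px=diam_working,
        radius_factor=cfg.radius_factor,
        target_fraction=cfg.target_fraction,
        n_thresholds=cfg.n_thresholds,
    )
    ps = postprocess_mask(grid_mask, fp, cfg.working_size, stride_px=cfg.token_size)
    from .postprocess import map_to_original

    return map_to_original(ps, sx, sy)


def pick_and_write(
    artifacts: PickerArtifacts,
    micrographs: list[MicrographImage],
    diameter_px: float,
    out_dir: str | Path,
    fmt: str = "star",
) -> dict[str, ParticleSet]:
    """Pick a batch and write one coordinate file per micrograph.

    Per-micrograph failures are logged and skipped; raises only if every
    micrograph fails.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, ParticleSet] = {}
    failures: list[str] = []
    for mi in micrographs:
        try:
            ps = pick_micrograph(artifacts, mi, diameter_px)
            suffix = ".star" if fmt == "star" else ".box"
            write_coords(ps, out_dir / f"{mi.id}{suffix}", fmt=fmt)
            results[mi.id] = ps
        except Exception:  # pragma: no cover - defensive batch behaviour
            logger.exception("picking failed for micrograph %s", mi.id)
            failures.append(mi.id)
    if failures and not results:
        raise ContractViolationError(f"picking failed for all micrographs: {failures}")
    return results


def evaluate_picks(
    preds: dict[str, ParticleSet],
    gts: dict[str, ParticleSet],
    diameter_px: float,
    tp_iou: float = 0.6,
) -> tuple[dict[str, Metrics], Metrics, list[str]]:
    """Per-micrograph and aggregate metrics over ids present on both sides."""
    shared = sorted(set(preds) & set(gts))
    unmatched = sorted(set(preds) ^ set(gts))
    if unmatched:
        logger.warning("ids without a counterpart were excluded: %s", unmatched)
    if not shared:
        raise ContractViolationError("no micrograph ids shared between pred and gt")
    per = {}
    for mid in shared:
        _, metrics = match_and_score(preds[mid], gts[mid], diameter_px, tp_iou=tp_iou)
        per[mid] = metrics
    return per, aggregate(list(per.values())), unmatched
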