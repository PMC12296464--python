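"""Latent-space segmentation of particles from background.

Two stages, both operating on the per-micrograph grid of 192-d latent
vectors:

1. **Train-set clustering** — k-means with 4 clusters on latents pooled
   from all training micrographs.  A reference micrograph with a binary
   particle mask identifies which of the 4 clusters is the particle
   cluster: the mask is downsampled to the embedding grid (a cell counts
   as particle if at least half of its pixels are), and the cluster with
   the highest fraction of its cells falling on particle cells wins.

2. **Micrograph-specific hierarchical refinement** — for a new micrograph,
   cells are first assigned to the 4 train-set centers, seeding the
   particle cell set.  Then k-means with k = 3, 4, 5 is run on that
   micrograph's own latents; at each level the cluster with the greatest
   overlap (intersection count) with the previous particle set becomes the
   new particle set, progressively stripping micrograph-specific noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .config import RunConfig
from .errors import ContractViolationError
from .representation import EmbeddingMap

__all__ = [
    "ReferenceClusterModel",
    "HierarchicalState",
    "downsample_mask",
    "fit_reference_clusters",
    "assign_initial",
    "hierarchical_refine",
]

logger = logging.getLogger(__name__)


@dataclass
class ReferenceClusterModel:
    """k=4 train-set cluster centers plus the particle-cluster index."""

    centers: np.ndarray  # (4, embed_dim), sorted lexicographically
    particle_id: int
    fit_seed: int

    def save(self, path) -> None:
        np.savez(path, centers=self.centers, particle_id=self.particle_id,
                 fit_seed=self.fit_seed)

    @classmethod
    def load(cls, path) -> "ReferenceClusterModel":
        with np.load(path) as d:
            return cls(
                centers=d["centers"],
                particle_id=int(d["particle_id"]),
                fit_seed=int(d["fit_seed"]),
            )


@dataclass
class HierarchicalState:
    """Per-micrograph refinement state: current level and particle cells."""

    level: int
    particle_cells: np.ndarray  # boolean over row-major grid cells
    grid_shape: tuple[int, int]
    max_iters: int = 5


def _sorted_kmeans(
    vectors: np.ndarray, k: int, seed: int, cfg: RunConfig
) -> tuple[np.ndarray, np.ndarray]:
    """k-means (k-means++, restarts, fixed seed) with lexicographically
    sorted centers and nearest-center assignments (lower index on ties)."""
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=cfg.kmeans_restarts,
        tol=cfg.kmeans_tol,
        random_state=seed,
        algorithm="lloyd",
    ).fit(vectors)
    centers = km.cluster_centers_.astype(np.float64)
    order = np.lexsort(centers.T[::-1])  # sort rows lexicographically
    centers = centers[order]
    labels = np.argmin(cdist(vectors, centers), axis=1)
    return centers, labels


def downsample_mask(mask: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Reduce a working-frame binary mask to the embedding grid.

    A grid cell is particle if >= 50% of the pixels it covers are particle.
    """
    mask = np.asarray(mask).astype(bool)
    gh, gw = grid_shape
    H, W = mask.shape
    if H % gh or W % gw:
        raise ContractViolationError("mask shape not divisible by grid shape")
    sh, sw = H // gh, W // gw
    frac = mask.reshape(gh, sh, gw, sw).mean(axis=(1, 3))
    return frac >= 0.5


def fit_reference_clusters(
    train_latents: np.ndarray,
    ref_emb: EmbeddingMap,
    ref_mask: np.ndarray,
    seed: int,
    cfg: RunConfig | None = None,
) -> ReferenceClusterModel:
    """Cluster pooled training latents (k=4) and identify the particle cluster.

    ``ref_mask`` is a working-frame binary mask of the reference micrograph;
    ``ref_emb`` its embedding map.  The particle cluster is the one
    maximizing |cells in cluster on particle cells| / |cells in cluster|;
    ties break toward the larger intersection count, then the lower index
    of the lexicographically sorted centers.
    """
    cfg = cfg or RunConfig()
    k = cfg.n_reference_clusters
    train_latents = np.asarray(train_latents, float)
    if train_latents.ndim != 2:
        raise ContractViolationError("train latents must be (n, dim)")
    if np.unique(train_latents, axis=0).shape[0] < k:
        raise ContractViolationError(f"need at least {k} distinct latent vectors")
    if train_latents.shape[0] > cfg.max_train_latents:
        sub = np.random.default_rng(seed).choice(
            train_latents.shape[0], size=cfg.max_train_latents, replace=False
        )
        train_latents = train_latents[sub]

    gh, gw = ref_emb.grid.shape[:2]
    cell_is_particle = (
        ref_mask.reshape(-1)
        if ref_mask.shape == (gh, gw)
        else downsample_mask(ref_mask, (gh, gw)).reshape(-1)
    )
    if cell_is_particle.all() or not cell_is_particle.any():
        raise ContractViolationError(
            "reference mask must contain both particle and background cells"
        )

    centers, _ = _sorted_kmeans(train_latents, k, seed, cfg)
    ref_labels = np.argmin(cdist(ref_emb.vectors(), centers), axis=1)

    best = None
    for c in range(k):
        in_cluster = ref_labels == c
        n_c = int(in_cluster.sum())
        inter = int((in_cluster & cell_is_particle).sum())
        ratio = inter / n_c if n_c else 0.0
        key = (ratio, inter, -c)  # precision, then count, then lower index
        if best is None or key > best[0]:
            best = (key, c)
    return ReferenceClusterModel(centers=centers, particle_id=best[1], fit_seed=seed)


def assign_initial(emb: EmbeddingMap, model: ReferenceClusterModel) -> HierarchicalState:
    """Assign each grid cell to its nearest train-set center; the cells of
    the particle cluster seed the hierarchical refinement at level 3."""
    if emb.grid.shape[-1] != model.centers.shape[1]:
        raise ContractViolationError("latent width does not match cluster centers")
    labels = np.argmin(cdist(emb.vectors(), model.centers), axis=1)
    return HierarchicalState(
        level=3,
        particle_cells=labels == model.particle_id,
        grid_shape=emb.grid.shape[:2],
    )


def hierarchical_refine(
    emb: EmbeddingMap,
    state: HierarchicalState,
    seed: int,
    max_iters: int = 5,
    cfg: RunConfig | None = None,
) -> np.ndarray:
    """Refine the particle cell set with k-means at k = 3 .. ``max_iters``.

    At each level the cluster with the greatest overlap with the previous
    particle set is kept, where overlap is scored as the enrichment
    fraction |C intersect prev| / |C|: the raw intersection count would
    systematically favour large background clusters whenever the previous
    set is only partially enriched in particle cells.  Ties break toward
    the larger intersection, then the lower sorted-center index.  Returns
    the final binary particle mask on the embedding grid.
    """
    cfg = cfg or RunConfig()
    if state.level != 3:
        raise ContractViolationError("refinement must start from level 3")
    if max_iters < 3:
        raise ContractViolationError("max_iters must be >= 3")
    current = state.particle_cells.copy()
    if not current.any():
        logger.warning(
            "empty initial particle set for %s; returning empty mask", emb.source_id
        )
        return np.zeros(state.grid_shape, dtype=bool)

    vectors = emb.vectors()
    for k in range(3, max_iters + 1):
        centers, labels = _sorted_kmeans(vectors, k, seed + k, cfg)
        best = None
        for c in range(k):
            in_cluster = labels == c
            inter = int((in_cluster & current).sum())
            size = int(in_cluster.sum())
            frac = inter / size if size else 0.0
            key = (frac, inter, -c)  # enrichment, then count, then lower index
            if best is None or key > best[0]:
                best = (key, in_cluster)
        current = best[1]
    return current.reshape(state.grid_shape)
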