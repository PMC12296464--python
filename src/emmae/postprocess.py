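"""From grid-level particle masks to particle coordinates.

The binary mask produced by segmentation lives on the coarse embedding
grid.  It is smoothed with a uniform 3x3 kernel (filling single-cell
holes), bilinearly upsampled to the working resolution, and binarized with
an adaptive threshold chosen so the foreground occupies approximately the
particle area fraction observed in training data (~4% of the micrograph by
default).  Connected components then become particle candidates (centroid,
equivalent radius, mean map value as score), filtered by three rules:
radius outliers, border proximity, and non-maximum suppression at the
particle diameter.  Finally coordinates are mapped back to the original
micrograph frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import ContractViolationError
from .io_formats import ParticleSet

__all__ = [
    "PredictionMap",
    "FilterParams",
    "smooth",
    "upsample",
    "select_threshold",
    "extract_particles",
    "filter_particles",
    "map_to_original",
    "postprocess_mask",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictionMap:
    """Real-valued particle-evidence map in [0, 1], grid or working frame."""

    values: np.ndarray
    frame: str  # "grid" | "working"
    stride_px: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ContractViolationError("prediction map contains non-finite values")


@dataclass
class FilterParams:
    """Working-frame post-processing parameters."""

    diameter_px: float
    radius_factor: float = 1.5
    border_margin_px: float | None = None
    target_fraction: float = 0.04
    n_thresholds: int = 101

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ContractViolationError("diameter must be positive")
        if self.radius_factor <= 1:
            raise ContractViolationError("radius_factor must exceed 1")
        if self.border_margin_px is None:
            self.border_margin_px = self.diameter_px / 2.0

    @property
    def thresholds(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_thresholds)


def smooth(mask: np.ndarray, stride_px: float = 1.0) -> PredictionMap:
    """Uniform 3x3 mean filter with zero padding at the borders."""
    mask = np.asarray(mask, dtype=np.float64)
    out = ndimage.uniform_filter(mask, size=3, mode="constant", cval=0.0)
    return PredictionMap(values=np.clip(out, 0.0, 1.0), frame="grid", stride_px=stride_px)


def upsample(pm: PredictionMap, working_size: int) -> PredictionMap:
    """Bilinear interpolation of a grid-frame map to the working resolution."""
    if pm.frame != "grid":
        raise ContractViolationError("upsample expects a grid-frame map")
    out = _sk_resize(
        pm.values,
        (working_size, working_size),
        order=1,
        mode="edge",  # clamp at borders; reflection would create phantom extrema
        anti_aliasing=False,
        preserve_range=True,
    )
    return PredictionMap(values=np.clip(out, 0.0, 1.0), frame="working", stride_px=1.0)


def select_threshold(pm: PredictionMap, fp: FilterParams) -> float:
    """Pick the threshold whose foreground fraction is closest to the target.

    Every threshold on the uniform grid over [0, 1] is evaluated; ties
    resolve toward the larger (stricter) threshold.
    """
    if pm.frame != "working":
        raise ContractViolationError("threshold selection expects a working-frame map")
    values = pm.values
    if not values.any():
        logger.warning("all-zero prediction map; returning the strictest threshold")
    thresholds = fp.thresholds
    best_t = thresholds[-1]
    best_err = np.inf
    for t in thresholds:
        frac = float((values >= t).mean())
        err = abs(frac - fp.target_fraction)
        if err < best_err or (err == best_err):  # later (larger) t wins ties
            best_err = err
            best_t = float(t)
    return best_t


def extract_particles(
    binary: np.ndarray, fp: FilterParams, score_map: np.ndarray | None = None
) -> ParticleSet:
    """8-connected components -> centroids, equivalent radii and scores."""
    binary = np.asarray(binary).astype(bool)
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return ParticleSet(
            centers=np.empty((0, 2)),
            radius_px=fp.diameter_px / 2.0,
            frame="working",
            scores=np.empty(0),
            radii_px=np.empty(0),
        )
    ids = np.arange(1, n + 1)
    centroids = ndimage.center_of_mass(binary, labels, ids)  # (row, col)
    areas = ndimage.sum_labels(binary, labels, ids)
    if score_map is not None:
        scores = ndimage.mean(np.asarray(score_map, float), labels, ids)
    else:
        scores = np.ones(n)
    centers = np.array([[c, r] for r, c in centroids])  # -> (x, y)
    radii = np.sqrt(np.asarray(areas, float) / np.pi)
    return ParticleSet(
        centers=centers,
        radius_px=fp.diameter_px / 2.0,
        frame="working",
        scores=np.asarray(scores, float),
        radii_px=radii,
    )


def filter_particles(
    ps: ParticleSet, fp: FilterParams, image_size: int
) -> ParticleSet:
    """Apply the three filtering rules, in order: radius, border, NMS.

    (ii) drop components whose equivalent radius exceeds
    ``radius_factor * diameter/2``; (iii) drop centers strictly closer than
    ``border_margin_px`` to any image edge; (i) greedy non-maximum
    suppression in descending score, dropping any center within one
    particle diameter of an already-kept center.
    """
    if ps.frame != "working":
        raise ContractViolationError("filtering expects working-frame particles")
    centers = ps.centers
    scores = ps.scores if ps.scores is not None else np.ones(len(ps))
    radii = ps.radii_px if ps.radii_px is not None else np.full(len(ps), ps.radius_px)

    keep = radii <= fp.radius_factor * (fp.diameter_px / 2.0)

    m = fp.border_margin_px
    lo = np.minimum(centers[:, 0], centers[:, 1])
    hi = np.minimum(image_size - 1 - centers[:, 0], image_size - 1 - centers[:, 1])
    keep &= (lo >= m) & (hi >= m)

    idx = np.flatnonzero(keep)
    order = idx[np.lexsort((idx, -scores[idx]))]  # descending score, stable
    kept: list[int] = []
    for i in order:
        c = centers[i]
        if all(np.hypot(*(c - centers[j])) >= fp.diameter_px for j in kept):
            kept.append(i)
    kept_arr = np.array(sorted(kept), dtype=int)
    return ParticleSet(
        centers=centers[kept_arr] if kept_arr.size else np.empty((0, 2)),
        radius_px=ps.radius_px,
        frame="working",
        scores=scores[kept_arr] if kept_arr.size else np.empty(0),
        radii_px=radii[kept_arr] if kept_arr.size else np.empty(0),
    )


def map_to_original(ps: ParticleSet, scale_x: float, scale_y: float) -> ParticleSet:
    """Rescale working-frame centers back to original-micrograph pixels."""
    if ps.frame != "working":
        raise ContractViolationError("particles already in the original frame")
    if not (scale_x > 0 and scale_y > 0):
        raise ContractViolationError("missing or invalid resize scale factors")
    centers = ps.centers / np.array([scale_x, scale_y])
    return ParticleSet(
        centers=centers,
        radius_px=ps.radius_px / ((scale_x + scale_y) / 2.0),
        frame="original",
        scores=ps.scores,
        radii_px=ps.radii_px / ((scale_x + scale_y) / 2.0)
        if ps.radii_px is not None
        else None,
    )


def postprocess_mask(
    grid_mask: np.ndarray,
    fp: FilterParams,
    working_size: int,
    stride_px: float,
) -> ParticleSet:
    """Full chain: smooth -> upsample -> threshold -> extract -> filter."""
    pm = smooth(grid_mask, stride_px=stride_px)
    up = upsample(pm, working_size)
    t = select_threshold(up, fp)
    binary = up.values >= t
    ps = extract_particles(binary, fp, score_map=up.values)
    return filter_particles(ps, fp, image_size=working_size)
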