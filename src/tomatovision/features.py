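"""Surface features of a segmented fruit: color balance, texture, area, clusters.

Four families of features summarize a fruit's surface:

* **Color fractions** — the percentage of total masked intensity carried by
  each RGB channel. Ripening shifts mass from green to red, so these track
  maturity directly.
* **Local entropy** — Shannon entropy (bits) of the gray-level histogram in a
  sliding window. Smooth skin has near-zero entropy; lesions, specks and
  mold raise it. The texture quality coefficient is the mean of the entropy
  extrema over the fruit.
* **Pattern-weighted area** — a sub-pixel area estimate of a binary object
  obtained by scoring every 2×2 neighborhood with one of six fixed weights.
* **k-means clusters in L*a*b*** — chromaticity clustering (default k=4 on
  the a*b* plane, so shading does not split one color) that isolates lesion
  colors from the base fruit color.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage.filters import rank as skrank
from skimage.morphology import footprint_rectangle

from .exceptions import EmptyRegionError, ParameterError
from .imaging import SegmentedSample

__all__ = [
    "ColorFractions",
    "TextureResult",
    "AreaEstimate",
    "ClusterDescriptor",
    "ClusterSet",
    "extract_color_fractions",
    "texture_entropy",
    "estimate_area",
    "rgb_to_lab",
    "to_grayscale",
    "extract_clusters",
    "shading_trajectory_distance",
    "cluster_shading_distances",
    "lesion_descriptors",
    "DISEASE_FEATURE_NAMES",
]


@dataclass(frozen=True)
class ColorFractions:
    """Percentage of total foreground intensity per RGB channel; sums to 100."""

    red_pct: float
    green_pct: float
    blue_pct: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.red_pct, self.green_pct, self.blue_pct)


@dataclass(frozen=True)
class TextureResult:
    """Local-entropy texture summary over the fruit region.

    ``texture_quality_coefficient`` is the arithmetic mean of the minimum and
    maximum local entropy observed inside the mask.
    """

    entropy_map: np.ndarray  # (H, W) float, bits; zero outside the mask
    min_entropy: float
    max_entropy: float

    @property
    def texture_quality_coefficient(self) -> float:
        return (self.min_entropy + self.max_entropy) / 2.0


@dataclass(frozen=True)
class AreaEstimate:
    """Sub-pixel area of a binary object, in pixel-area units."""

    area: float


@dataclass(frozen=True)
class ClusterDescriptor:
    """Per-cluster summary used by the health/disease decision layer."""

    count: int
    mean_lab: tuple[float, float, float]
    mean_rgb: tuple[float, float, float]
    area: float
    bbox: tuple[int, int, int, int]  # (row_min, row_max, col_min, col_max), inclusive
    contrast: float  # a*b* distance from the overall foreground chromaticity


@dataclass(frozen=True)
class ClusterSet:
    """Result of chromaticity k-means over the foreground pixels.

    ``label_map`` assigns every foreground pixel a cluster index in [0, k);
    background pixels carry -1. ``means`` are full L*a*b* centroids of the
    members at convergence. ``inertia_history`` records the within-cluster
    sum of squared distances after each full-data Lloyd iteration.
    """

    k: int
    label_map: np.ndarray
    means: np.ndarray  # (k, 3) L*a*b*
    descriptors: tuple[ClusterDescriptor, ...]
    inertia_history: tuple[float, ...] = field(default=())


def extract_color_fractions(sample: SegmentedSample) -> ColorFractions:
    """Channel intensity mass over the foreground, as percentages of the total."""
    fg = sample.mask.pixels
    if not fg.any():
        raise EmptyRegionError("cannot extract color fractions from an empty mask")
    px = sample.image[fg].astype(np.float64)  # (N, 3)
    channel_sums = px.sum(axis=0)
    total = channel_sums.sum()
    if total <= 0:
        raise EmptyRegionError("foreground has zero total intensity")
    r, g, b = 100.0 * channel_sums / total
    return ColorFractions(red_pct=float(r), green_pct=float(g), blue_pct=float(b))


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luma grayscale conversion of an RGB raster to uint8."""
    if image.ndim == 2:
        return image
    return np.round(skcolor.rgb2gray(image) * 255.0).astype(np.uint8)


def texture_entropy(
    sample: SegmentedSample, window: int = 9, levels: int = 256
) -> TextureResult:
    """Per-pixel local Shannon entropy (bits) of the masked grayscale image.

    The histogram in each ``window``×``window`` neighborhood counts only
    pixels inside the foreground mask, so the zeroed background does not
    inject an artificial gray level. Extrema are taken over foreground
    pixels. ``levels`` re-quantizes the gray axis before counting.
    """
    if window % 2 == 0 or window < 1:
        raise ParameterError(f"window must be odd and positive, got {window}")
    if levels < 2:
        raise ParameterError(f"levels must be >= 2, got {levels}")
    fg = sample.mask.pixels
    if not fg.any():
        raise EmptyRegionError("cannot compute texture entropy of an empty mask")

    gray = to_grayscale(sample.image)
    if levels < 256:
        gray = (gray.astype(np.uint16) * levels // 256).astype(np.uint8)

    # restrict the windowed pass to the mask's bounding box (plus a margin of
    # window//2 so every neighborhood of a foreground pixel is covered);
    # exact because out-of-mask pixels never enter any histogram.
    rows, cols = np.nonzero(fg)
    m = window // 2
    r0, r1 = max(rows.min() - m, 0), min(rows.max() + m + 1, fg.shape[0])
    c0, c1 = max(cols.min() - m, 0), min(cols.max() + m + 1, fg.shape[1])
    ent_crop = skrank.entropy(
        gray[r0:r1, c0:c1],
        footprint_rectangle((window, window)),
        mask=fg[r0:r1, c0:c1].astype(np.uint8),
    )
    entropy_map = np.zeros(fg.shape, dtype=np.float64)
    entropy_map[r0:r1, c0:c1] = np.where(fg[r0:r1, c0:c1], ent_crop, 0.0)
    vals = entropy_map[fg]
    return TextureResult(
        entropy_map=entropy_map,
        min_entropy=float(vals.min()),
        max_entropy=float(vals.max()),
    )


# 2x2 pattern weights keyed by on-pixel count; count == 2 splits into
# adjacent (1/2) vs diagonal (3/4) configurations.
_AREA_WEIGHT_BY_COUNT = np.array([0.0, 0.25, 0.5, 0.875, 1.0])
_DIAGONAL_BONUS = 0.25


def estimate_area(image: np.ndarray) -> AreaEstimate:
    """Pattern-weighted sub-pixel area of a binary image.

    The image is zero-padded by one pixel on each side so that every pixel
    participates in exactly four 2×2 windows; each window contributes a fixed
    weight — 0 (no on pixels), 1/4 (one), 1/2 (two adjacent), 3/4 (two
    diagonal), 7/8 (three), 1 (four). A single isolated on pixel thus scores
    4 × 1/4 = 1.
    """
    b = np.pad(image.astype(bool), 1)
    tl, tr = b[:-1, :-1], b[:-1, 1:]
    bl, br = b[1:, :-1], b[1:, 1:]
    counts = (
        tl.astype(np.int8) + tr.astype(np.int8) + bl.astype(np.int8) + br.astype(np.int8)
    )
    area = _AREA_WEIGHT_BY_COUNT[counts].sum()
    diagonal = ((tl & br) | (tr & bl)) & (counts == 2)
    area += _DIAGONAL_BONUS * diagonal.sum()
    return AreaEstimate(area=float(area))


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster (or (N, 3) pixel list) to CIE L*a*b*.

    Assumes sRGB primaries and D65 white; L* lies in [0, 100].
    """
    return skcolor.rgb2lab(image.astype(np.float64) / 255.0)


def _assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # argmin over squared Euclidean distance; ties go to the lowest index
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _lloyd(
    points: np.ndarray,
    centers: np.ndarray,
    max_iter: int,
    tol: float,
    track_inertia: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd iterations until the assignment is stable (a true fixed point).

    Stopping on a stable assignment guarantees the returned centers are
    exactly the centroids of their members; ``tol`` additionally accepts
    convergence when the centroid shift is negligible and the assignment no
    longer changes the objective (a guard against tie oscillation). Empty
    clusters are re-seeded at the point farthest from its assigned centroid,
    which strictly decreases the objective.
    """
    k = centers.shape[0]
    history: list[float] = []
    labels = _assign(points, centers)
    last_inertia = np.inf
    for _ in range(max_iter):
        new_centers = centers.copy()
        for j in range(k):
            members = points[labels == j]
            if members.shape[0] == 0:
                resid = ((points - centers[labels]) ** 2).sum(axis=1)
                far = int(resid.argmax())
                new_centers[j] = points[far]
            else:
                new_centers[j] = members.mean(axis=0)
        shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        centers = new_centers
        new_labels = _assign(points, centers)
        inertia = float(((points - centers[new_labels]) ** 2).sum())
        if track_inertia:
            history.append(inertia)
        stable = np.array_equal(new_labels, labels)
        labels = new_labels
        if stable or (shift < tol and inertia >= last_inertia - tol):
            break
        last_inertia = inertia
    return labels, centers, history


def extract_clusters(
    sample: SegmentedSample,
    k: int = 4,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
    channels: str = "ab",
    warm_start_pixels: int = 20000,
) -> ClusterSet:
    """k-means clustering of the foreground pixels in L*a*b* chromaticity.

    By default clustering runs on the (a*, b*) plane only, so illumination
    shading (which mostly moves L*) does not split one surface color into
    several clusters; ``channels='lab'`` switches to full L*a*b*.
    Initialization picks ``k`` distinct foreground pixels uniformly at random
    from ``seed``; with more than ``warm_start_pixels`` foreground pixels a
    subsample is clustered first and the result refines on the full data, so
    the returned means are exact centroids of their members either way.
    Deterministic for a fixed seed.
    """
    if channels not in ("ab", "lab"):
        raise ParameterError(f"channels must be 'ab' or 'lab', got {channels!r}")
    fg = sample.mask.pixels
    n_fg = int(fg.sum())
    if n_fg < k:
        raise ParameterError(f"need at least k={k} foreground pixels, got {n_fg}")

    lab = rgb_to_lab(sample.image[fg])  # (N, 3)
    points = lab[:, 1:] if channels == "ab" else lab

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(n_fg, size=k, replace=False)
    centers = points[init_idx].astype(np.float64)

    if n_fg > warm_start_pixels:
        sub = rng.choice(n_fg, size=warm_start_pixels, replace=False)
        _, centers, _ = _lloyd(points[sub], centers, max_iter, tol)
    labels, centers, history = _lloyd(
        points, centers, max_iter, tol, track_inertia=True
    )

    label_map = np.full(fg.shape, -1, dtype=np.int32)
    label_map[fg] = labels

    overall_ab = lab[:, 1:].mean(axis=0)
    means = np.empty((k, 3))
    descriptors = []
    rows, cols = np.nonzero(fg)
    rgb_px = sample.image[fg].astype(np.float64)
    for j in range(k):
        member = labels == j
        if member.any():
            means[j] = lab[member].mean(axis=0)
            jr, jc = rows[member], cols[member]
            bbox = (int(jr.min()), int(jr.max()), int(jc.min()), int(jc.max()))
            mean_rgb = tuple(float(v) for v in rgb_px[member].mean(axis=0))
            area = estimate_area(label_map == j).area
        else:  # possible only if repair never triggered, kept for safety
            means[j] = np.nan
            bbox = (0, -1, 0, -1)
            mean_rgb = (0.0, 0.0, 0.0)
            area = 0.0
        contrast = float(np.sqrt(((means[j, 1:] - overall_ab) ** 2).sum()))
        descriptors.append(
            ClusterDescriptor(
                count=int(member.sum()),
                mean_lab=tuple(float(v) for v in means[j]),
                mean_rgb=mean_rgb,
                area=float(area),
                bbox=bbox,
                contrast=contrast,
            )
        )
    return ClusterSet(
        k=k,
        label_map=label_map,
        means=means,
        descriptors=tuple(descriptors),
        inertia_history=tuple(history),
    )


DISEASE_FEATURE_NAMES = (
    "lesion_rel_area",
    "lesion_mean_l",
    "lesion_mean_a",
    "lesion_mean_b",
    "lesion_chroma",
    "lesion_l_spread",
    "log_n_components",
    "log_median_component_px",
    "ring_score",
)


def shading_trajectory_distance(
    cluster_lab: np.ndarray, base_rgb: np.ndarray
) -> float:
    """Distance in L*a*b* from a cluster mean to the base color's shading arc.

    Under the multiplicative illumination model a shaded patch of the base
    color appears as s·rgb_base for some gain s; a cluster only signals a
    lesion if it is far from every such appearance. Plain a*b* distance
    would not do: chroma is not invariant to intensity scaling, so the shaded
    rim of a saturated fruit looks "contrasting" in a*b* alone. The gain grid
    spans the full shading-ratio range of a convex fruit under frontal light
    (rim-to-center gain about 0.55): relative to the base-cluster mean —
    which may itself be any shading band — plausible gains lie in
    [0.55, 1/0.55]. Gains outside that range would let dark lesions
    masquerade as deep shadow or vice versa.
    """
    gains = np.linspace(0.55, 1.85, 27)
    arc_rgb = np.clip(gains[:, None] * base_rgb[None, :], 0, 255)
    arc_lab = rgb_to_lab(arc_rgb)
    return float(np.sqrt(((arc_lab - cluster_lab[None, :]) ** 2).sum(axis=1)).min())


def cluster_shading_distances(clusters: ClusterSet) -> np.ndarray:
    """Per-cluster shading-robust contrast against the largest (base) cluster.

    The base cluster scores 0; empty clusters score 0.
    """
    counts = np.array([d.count for d in clusters.descriptors])
    base = int(counts.argmax())
    base_rgb = np.asarray(clusters.descriptors[base].mean_rgb)
    out = np.zeros(clusters.k)
    for j, d in enumerate(clusters.descriptors):
        if j != base and d.count > 0:
            out[j] = shading_trajectory_distance(np.asarray(d.mean_lab), base_rgb)
    return out


def lesion_descriptors(
    clusters: ClusterSet, sample: SegmentedSample, lab_delta: float = 12.0
) -> np.ndarray:
    """Morphological/chromatic descriptors of the lesion-candidate region.

    The largest cluster is taken as the base fruit color; clusters whose
    L*a*b* mean lies more than ``lab_delta`` away from the base color's
    shading trajectory (see :func:`_shading_trajectory_distance`) are lesion
    candidates. Descriptors (see :data:`DISEASE_FEATURE_NAMES`) capture the
    surface signatures that distinguish disease archetypes: relative lesion
    coverage and color, chroma (gray mold is nearly achromatic), lightness
    spread (white halos around dark centers), connected-component count and
    size (many tiny specks vs few large blotches), and a ring score — the
    hole fraction of the largest lesion component, high for concentric-ring
    lesions.
    """
    distances = cluster_shading_distances(clusters)
    lesion_ids = [j for j in range(clusters.k) if distances[j] > lab_delta]
    out = np.zeros(len(DISEASE_FEATURE_NAMES))
    if not lesion_ids:
        return out

    lesion_mask = np.isin(clusters.label_map, lesion_ids)
    fg_count = int((clusters.label_map >= 0).sum())
    lab_px = rgb_to_lab(sample.image[lesion_mask])
    mean_lab = lab_px.mean(axis=0)

    structure = np.ones((3, 3), dtype=int)
    comp_labels, n_comp = ndimage.label(lesion_mask, structure=structure)
    comp_sizes = ndimage.sum_labels(
        np.ones_like(comp_labels), comp_labels, index=range(1, n_comp + 1)
    )
    # drop 1-2 px fragments (noise-pixel misassignments) before counting
    solid = comp_sizes >= 3
    if solid.any():
        solid_labels = np.flatnonzero(solid) + 1
        largest_label = int(solid_labels[comp_sizes[solid].argmax()])
        comp_sizes = comp_sizes[solid]
        n_comp = int(solid.sum())
    else:
        largest_label = int(comp_sizes.argmax()) + 1 if n_comp else 0
    largest = comp_labels == largest_label
    filled = ndimage.binary_fill_holes(largest)
    filled_px = int(filled.sum())
    ring_score = 1.0 - largest.sum() / filled_px if filled_px else 0.0

    out[:] = (
        lesion_mask.sum() / fg_count,
        mean_lab[0],
        mean_lab[1],
        mean_lab[2],
        float(np.sqrt(lab_px[:, 1] ** 2 + lab_px[:, 2] ** 2).mean()),
        float(lab_px[:, 0].std()),
        np.log1p(n_comp),
        np.log1p(float(np.median(comp_sizes))),
        ring_score,
    )
    return out
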