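"""Synthetic tomato image generator with ground-truth annotations.

Every sample is a pair of frames mimicking a controlled acquisition chamber:
an empty dark background frame and a frame with a shaded ellipsoidal fruit.
The fruit's base chromaticity interpolates a green-to-red ramp with maturity,
and five disease archetypes render their characteristic surface morphology:

* early blight — dark concentric annuli around a sunken center,
* late blight — irregular brown blotches (unions of overlapping disks),
* bacterial canker — small dark-centered spots ringed by pale halos,
* gray mold — low-saturation gray patches,
* bacterial speck — many tiny (radius ≤ 3 px) dark dots.

Impulse (salt-and-pepper) noise and Gaussian blur are applied to the sample
frame only. A fixed seed reproduces every pixel and annotation bit-exactly;
dataset-level seeds derive one independent stream per sample index, so a
dataset is stable under partial regeneration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .classify import DiseaseLabel, ExtendedStage, HealthLabel, MaturityLabel
from .exceptions import ImageIOError, ParameterError
from .features import ColorFractions, extract_color_fractions
from .imaging import ForegroundMask, SegmentedSample, write_image

__all__ = [
    "SampleSpec",
    "GroundTruth",
    "generate_sample",
    "plan_dataset",
    "generate_dataset",
    "BACKGROUND_COLOR",
    "UNRIPE_COLOR",
    "RIPE_COLOR",
]

BACKGROUND_COLOR = np.array([6.0, 6.0, 8.0])
UNRIPE_COLOR = np.array([60.0, 140.0, 50.0])
TURNING_COLOR = np.array([210.0, 140.0, 45.0])  # yellow-orange "turning" stage
RIPE_COLOR = np.array([180.0, 30.0, 25.0])
_TURNING_POINT = 0.55

_LESION_COLORS = {
    DiseaseLabel.EARLY_BLIGHT: (np.array([50.0, 35.0, 22.0]), np.array([30.0, 22.0, 16.0])),
    DiseaseLabel.LATE_BLIGHT: (np.array([110.0, 70.0, 40.0]),),
    DiseaseLabel.BACTERIAL_CANKER: (np.array([45.0, 30.0, 25.0]), np.array([225.0, 218.0, 200.0])),
    DiseaseLabel.GRAY_MOLD: (np.array([150.0, 147.0, 143.0]),),
    DiseaseLabel.BACTERIAL_SPECK: (np.array([35.0, 28.0, 22.0]),),
}

RENDERED_ARCHETYPES = tuple(_LESION_COLORS)


@dataclass(frozen=True)
class SampleSpec:
    """Full description of one synthetic sample; the seed fixes every pixel."""

    maturity: float = 0.5
    disease: DiseaseLabel = DiseaseLabel.NONE
    lesion_fraction: float = 0.1
    fruit_axes: tuple[int, int] = (150, 180)  # (semi-axis rows, semi-axis cols)
    impulse_prob: float = 0.002
    blur_sigma: float = 0.6
    seed: int = 0
    canvas: tuple[int, int] = (480, 640)

    def __post_init__(self) -> None:
        if not 0.0 <= self.maturity <= 1.0:
            raise ParameterError(f"maturity must be in [0, 1], got {self.maturity}")
        if not 0.0 <= self.lesion_fraction <= 0.4:
            raise ParameterError(
                f"lesion_fraction must be in [0, 0.4], got {self.lesion_fraction}"
            )
        ay, ax = self.fruit_axes
        h, w = self.canvas
        if ay <= 0 or ax <= 0 or 2 * ay >= h or 2 * ax >= w:
            raise ParameterError(
                f"fruit axes {self.fruit_axes} do not fit canvas {self.canvas}"
            )
        if not 0.0 <= self.impulse_prob <= 1.0:
            raise ParameterError("impulse_prob must be in [0, 1]")
        if self.blur_sigma < 0:
            raise ParameterError("blur_sigma must be >= 0")
        if self.disease not in DiseaseLabel:
            raise ParameterError(f"unknown disease {self.disease!r}")
        if (
            self.disease not in (DiseaseLabel.NONE,)
            and self.disease not in RENDERED_ARCHETYPES
        ):
            raise ParameterError(f"archetype {self.disease} is not rendered in v1")


@dataclass(frozen=True)
class GroundTruth:
    """Per-sample annotations of the noiseless render."""

    fruit_mask: np.ndarray   # (H, W) bool
    lesion_mask: np.ndarray  # (H, W) bool, subset of fruit_mask
    maturity: float
    maturity_label: MaturityLabel
    extended_stage: ExtendedStage
    health_label: HealthLabel
    disease_label: DiseaseLabel
    true_color_fractions: ColorFractions
    lesion_fraction: float = 0.0


def _ripeness_color(maturity: float) -> np.ndarray:
    """Base surface color along the ripening trajectory.

    Real fruit turn green -> yellow-orange -> red; interpolating through a
    "turning" waypoint avoids the desaturated gray-brown a straight
    green-to-red RGB blend would pass through.
    """
    if maturity <= _TURNING_POINT:
        t = maturity / _TURNING_POINT
        return (1.0 - t) * UNRIPE_COLOR + t * TURNING_COLOR
    t = (maturity - _TURNING_POINT) / (1.0 - _TURNING_POINT)
    return (1.0 - t) * TURNING_COLOR + t * RIPE_COLOR


def maturity_label_of(maturity: float) -> MaturityLabel:
    if maturity < 1.0 / 3.0:
        return MaturityLabel.UNRIPE
    if maturity < 2.0 / 3.0:
        return MaturityLabel.MEDIUM
    return MaturityLabel.RIPE


def extended_stage_of(maturity: float) -> ExtendedStage:
    if maturity < 0.25:
        return ExtendedStage.UNRIPE
    if maturity < 0.5:
        return ExtendedStage.RIPEN
    if maturity < 0.75:
        return ExtendedStage.FULLY_RIPEN
    return ExtendedStage.ROTTEN


def spec_to_yaml(spec: SampleSpec, path: str | Path) -> None:
    """Serialize a SampleSpec to a YAML file (round-trips exactly)."""
    import yaml

    payload = {
        "maturity": spec.maturity,
        "disease": spec.disease.value,
        "lesion_fraction": spec.lesion_fraction,
        "fruit_axes": list(spec.fruit_axes),
        "impulse_prob": spec.impulse_prob,
        "blur_sigma": spec.blur_sigma,
        "seed": spec.seed,
        "canvas": list(spec.canvas),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def spec_from_yaml(path: str | Path) -> SampleSpec:
    """Load a SampleSpec from a YAML file written by :func:`spec_to_yaml`."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    return SampleSpec(
        maturity=float(data["maturity"]),
        disease=DiseaseLabel(data["disease"]),
        lesion_fraction=float(data["lesion_fraction"]),
        fruit_axes=tuple(data["fruit_axes"]),
        impulse_prob=float(data["impulse_prob"]),
        blur_sigma=float(data["blur_sigma"]),
        seed=int(data["seed"]),
        canvas=tuple(data["canvas"]),
    )


def _disk(mask: np.ndarray, cy: float, cx: float, r: float) -> None:
    """Set a filled disk in-place, clipped to the canvas (local-window draw)."""
    h, w = mask.shape
    r0, r1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    c0, c1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.ogrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _annulus(mask: np.ndarray, cy: float, cx: float, r_in: float, r_out: float) -> None:
    h, w = mask.shape
    r0, r1 = max(int(cy - r_out) - 1, 0), min(int(cy + r_out) + 2, h)
    c0, c1 = max(int(cx - r_out) - 1, 0), min(int(cx + r_out) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.ogrid[r0:r1, c0:c1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    mask[r0:r1, c0:c1] |= (d2 <= r_out * r_out) & (d2 >= r_in * r_in)


def _lesion_site_center(
    rng: np.random.Generator, cy: float, cx: float, ay: float, ax: float
) -> tuple[float, float]:
    # rejection-sample a center with normalized radius < 0.7 so whole
    # lesion elements stay inside the fruit
    while True:
        ty, tx = rng.uniform(-0.7, 0.7, size=2)
        if ty * ty + tx * tx < 0.49:
            return cy + ty * ay, cx + tx * ax


def _render_lesions(
    spec: SampleSpec,
    rng: np.random.Generator,
    fruit_mask: np.ndarray,
    cy: float,
    cx: float,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw lesion elements until the target coverage of the fruit is met.

    Returns a list of (mask, color) layers; masks are already clipped to the
    fruit.
    """
    ay, ax = spec.fruit_axes
    fruit_area = int(fruit_mask.sum())
    target = spec.lesion_fraction * fruit_area
    if target <= 0 or spec.disease == DiseaseLabel.NONE:
        return []
    colors = _LESION_COLORS[spec.disease]
    layers = [
        (np.zeros(spec.canvas, dtype=bool), color + rng.normal(0, 3, 3))
        for color in colors
    ]
    if spec.disease == DiseaseLabel.BACTERIAL_SPECK:
        # specks are tiny, so draw the expected number in one pass
        mean_dot_area = np.pi * 3.1  # E[r^2] for r ~ U(1, 2.5)
        n_dots = min(int(np.ceil(target / mean_dot_area)), 500)
        for _ in range(n_dots):
            sy, sx = _lesion_site_center(rng, cy, cx, ay, ax)
            _disk(layers[0][0], sy, sx, rng.uniform(1.0, 2.5))
        np.logical_and(layers[0][0], fruit_mask, out=layers[0][0])
        return layers

    covered = np.zeros(spec.canvas, dtype=bool)
    for _ in range(600):
        if covered.sum() >= target:
            break
        sy, sx = _lesion_site_center(rng, cy, cx, ay, ax)
        if spec.disease == DiseaseLabel.EARLY_BLIGHT:
            # sunken dark center plus concentric velvety annuli
            scale = rng.uniform(0.85, 1.2)
            _disk(layers[1][0], sy, sx, 5 * scale)
            for i, r_mid in enumerate((12, 19, 26)):
                width = rng.uniform(3.0, 4.0)
                layer = layers[i % 2][0]
                _annulus(layer, sy, sx, (r_mid - width / 2) * scale, (r_mid + width / 2) * scale)
        elif spec.disease == DiseaseLabel.LATE_BLIGHT:
            # irregular blotch: a clump of overlapping disks
            for _ in range(rng.integers(4, 9)):
                dy, dx = rng.normal(0, 7, size=2)
                _disk(layers[0][0], sy + dy, sx + dx, rng.uniform(5, 11))
        elif spec.disease == DiseaseLabel.BACTERIAL_CANKER:
            # bird's-eye spot: dark raised center with a white halo
            r_center = rng.uniform(2.0, 4.0)
            _disk(layers[0][0], sy, sx, r_center)
            _annulus(layers[1][0], sy, sx, r_center, r_center + rng.uniform(2.0, 3.0))
        elif spec.disease == DiseaseLabel.GRAY_MOLD:
            for _ in range(rng.integers(3, 7)):
                dy, dx = rng.normal(0, 6, size=2)
                _disk(layers[0][0], sy + dy, sx + dx, rng.uniform(4, 10))
        covered = np.zeros(spec.canvas, dtype=bool)
        for layer_mask, _ in layers:
            np.logical_and(layer_mask, fruit_mask, out=layer_mask)
            covered |= layer_mask
    return layers


def generate_sample(
    spec: SampleSpec,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render one (background frame, sample frame, ground truth) triple.

    The background frame is the uniform empty chamber; the sample frame adds
    the fruit, lesions, surface texture jitter, then blur and impulse noise.
    Ground-truth color fractions are measured on the noiseless render with
    the true fruit mask, so they agree with the feature extractor by
    construction.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    ay, ax = spec.fruit_axes
    background = np.broadcast_to(
        BACKGROUND_COLOR.astype(np.uint8), (h, w, 3)
    ).copy()

    cy = h / 2.0 + rng.uniform(-10, 10)
    cx = w / 2.0 + rng.uniform(-15, 15)
    yy, xx = np.mgrid[0:h, 0:w]
    rho2 = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    fruit_mask = rho2 <= 1.0

    base = _ripeness_color(spec.maturity)
    shade = 1.0 - 0.45 * rho2  # radial shading, in [0.55, 1] inside the fruit

    img = background.astype(np.float64).copy()
    img[fruit_mask] = base[None, :] * shade[fruit_mask, None]

    layers = _render_lesions(spec, rng, fruit_mask, cy, cx)
    lesion_mask = np.zeros((h, w), dtype=bool)
    for layer_mask, color in layers:
        img[layer_mask] = color
        lesion_mask |= layer_mask

    # deterministic surface texture so entropy features are non-degenerate;
    # bounded so every fruit pixel stays well above the background
    jitter = np.clip(rng.normal(0.0, 2.5, size=(int(fruit_mask.sum()), 3)), -7, 7)
    img[fruit_mask] = np.clip(img[fruit_mask] + jitter, 0, 255)
    noiseless = np.round(img).astype(np.uint8)

    truth_fractions = extract_color_fractions(
        SegmentedSample(
            image=np.where(fruit_mask[..., None], noiseless, 0),
            mask=ForegroundMask(pixels=fruit_mask, threshold=0.0),
        )
    )

    noisy = noiseless.astype(np.float64)
    if spec.blur_sigma > 0:
        noisy = ndimage.gaussian_filter(noisy, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    if spec.impulse_prob > 0:
        impulse = rng.random((h, w)) < spec.impulse_prob
        salt = rng.random((h, w)) < 0.5
        noisy[impulse & salt] = 255.0
        noisy[impulse & ~salt] = 0.0
    sample = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    fruit_area = int(fruit_mask.sum())
    truth = GroundTruth(
        fruit_mask=fruit_mask,
        lesion_mask=lesion_mask,
        maturity=spec.maturity,
        maturity_label=maturity_label_of(spec.maturity),
        extended_stage=extended_stage_of(spec.maturity),
        health_label=HealthLabel.RISKY if lesion_mask.any() else HealthLabel.HEALTHY,
        disease_label=spec.disease if lesion_mask.any() else DiseaseLabel.NONE,
        true_color_fractions=truth_fractions,
        lesion_fraction=float(lesion_mask.sum()) / fruit_area if fruit_area else 0.0,
    )
    return background, sample, truth


def _sample_seed(dataset_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=dataset_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0]) % (2**31)


_DEFAULT_STAGE_MIX = {"u": 1 / 3, "m": 1 / 3, "r": 1 / 3}
_STAGE_BANDS = {
    "u": (0.02, 0.31),
    "m": (0.35, 0.64),
    "r": (0.68, 1.0),
}


def plan_dataset(
    n_healthy: int,
    n_infected: int,
    stage_mix: dict[str, float] | None = None,
    disease_mix: dict[DiseaseLabel, float] | None = None,
    seed: int = 7,
) -> list[SampleSpec]:
    """Deterministic list of sample specs for a dataset.

    Healthy samples come first. Maturity stages are drawn from ``stage_mix``
    (uniform over u/m/r by default) with the maturity value uniform inside
    the stage's band; infected samples draw an archetype from ``disease_mix``
    (uniform over the five rendered archetypes by default). Specks cover a
    smaller area than the other lesions, matching their tiny physical size.
    """
    if n_healthy < 0 or n_infected < 0:
        raise ParameterError("sample counts must be >= 0")
    stage_mix = stage_mix or _DEFAULT_STAGE_MIX
    stages = list(stage_mix)
    stage_p = np.array([stage_mix[s] for s in stages], dtype=float)
    stage_p = stage_p / stage_p.sum()
    disease_mix = disease_mix or {d: 1 / len(RENDERED_ARCHETYPES) for d in RENDERED_ARCHETYPES}
    archetypes = list(disease_mix)
    disease_p = np.array([disease_mix[d] for d in disease_mix], dtype=float)
    disease_p = disease_p / disease_p.sum()

    specs = []
    for i in range(n_healthy + n_infected):
        rng = np.random.default_rng(_sample_seed(seed, i))
        stage = stages[rng.choice(len(stages), p=stage_p)]
        maturity = float(rng.uniform(*_STAGE_BANDS[stage]))
        axes = (int(rng.integers(130, 165)), int(rng.integers(155, 195)))
        if i < n_healthy:
            disease, fraction = DiseaseLabel.NONE, 0.0
        else:
            disease = archetypes[rng.choice(len(archetypes), p=disease_p)]
            if disease == DiseaseLabel.BACTERIAL_SPECK:
                fraction = float(rng.uniform(0.02, 0.05))
            else:
                fraction = float(rng.uniform(0.06, 0.18))
        specs.append(
            SampleSpec(
                maturity=maturity,
                disease=disease,
                lesion_fraction=fraction,
                fruit_axes=axes,
                seed=_sample_seed(seed, i),
            )
        )
    return specs


def generate_dataset(
    n_healthy: int,
    n_infected: int,
    stage_mix: dict[str, float] | None = None,
    disease_mix: dict[DiseaseLabel, float] | None = None,
    seed: int = 7,
    out_dir: str | Path = ".",
    write_masks: bool = False,
) -> pd.DataFrame:
    """Render a dataset to ``out_dir`` and return its manifest.

    Writes one background/sample PNG pair per sample plus ``manifest.csv``
    with paths, labels, and ground-truth color fractions. Byte-identical for
    identical arguments.
    """
    out_dir = Path(out_dir)
    if not out_dir.parent.exists():
        raise ImageIOError(f"cannot create dataset under missing {out_dir.parent}")
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = plan_dataset(n_healthy, n_infected, stage_mix, disease_mix, seed)
    rows = []
    for i, spec in enumerate(specs):
        background, sample, truth = generate_sample(spec)
        sid = f"sample_{i:04d}"
        bg_path = out_dir / f"{sid}_bg.png"
        img_path = out_dir / f"{sid}_img.png"
        write_image(background, bg_path)
        write_image(sample, img_path)
        if write_masks:
            write_image(truth.fruit_mask, out_dir / f"{sid}_fruit_mask.png")
            write_image(truth.lesion_mask, out_dir / f"{sid}_lesion_mask.png")
        rows.append(
            {
                "sample_id": sid,
                "background_path": bg_path.name,
                "sample_path": img_path.name,
                "seed": spec.seed,
                "maturity": round(spec.maturity, 6),
                "maturity_label": truth.maturity_label.value,
                "extended_stage": truth.extended_stage.value,
                "health_label": truth.health_label.value,
                "disease_label": truth.disease_label.value,
                "lesion_fraction": round(truth.lesion_fraction, 6),
                "true_red_pct": round(truth.true_color_fractions.red_pct, 6),
                "true_green_pct": round(truth.true_color_fractions.green_pct, 6),
                "true_blue_pct": round(truth.true_color_fractions.blue_pct, 6),
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "background_path", "sample_path", "seed", "maturity",
            "maturity_label", "extended_stage", "health_label", "disease_label",
            "lesion_fraction", "true_red_pct", "true_green_pct", "true_blue_pct",
        ],
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
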