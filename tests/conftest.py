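"""Shared fixtures: deterministic RNGs and a small pre-extracted dataset.

Synthetic fixtures use a quarter-size canvas (240x320) so the suite stays
fast; full-size frames are exercised by the acceptance tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from tomatovision import pipeline, synthgen
from tomatovision.imaging import ForegroundMask, SegmentedSample

SMALL_CANVAS = (240, 320)


def small_spec(spec: synthgen.SampleSpec) -> synthgen.SampleSpec:
    return replace(
        spec,
        canvas=SMALL_CANVAS,
        fruit_axes=(spec.fruit_axes[0] // 2, spec.fruit_axes[1] // 2),
    )


def make_segmented(image: np.ndarray, mask: np.ndarray) -> SegmentedSample:
    """Wrap an RGB array + bool mask into a SegmentedSample, zeroing outside."""
    return SegmentedSample(
        image=np.where(mask[..., None], image, 0).astype(np.uint8),
        mask=ForegroundMask(pixels=mask, threshold=0.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240903)


@pytest.fixture(scope="session")
def small_dataset():
    """60 quarter-size samples (30 healthy / 30 infected) with ground truth."""
    specs = [small_spec(s) for s in synthgen.plan_dataset(30, 30, seed=11)]
    samples = [synthgen.generate_sample(s) for s in specs]
    return specs, samples


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    """Feature matrix + labels for the small dataset, extracted once."""
    specs, samples = small_dataset
    rows, maturity, health, disease = [], [], [], []
    for i, (bg, img, truth) in enumerate(samples):
        fv, _, _ = pipeline.extract_sample_features(bg, img, sample_id=f"s{i:03d}")
        rows.append(fv.values)
        maturity.append(truth.maturity_label.value)
        health.append(truth.health_label.value)
        disease.append(truth.disease_label.value)
    return {
        "X": np.vstack(rows),
        "maturity": np.array(maturity),
        "health": np.array(health),
        "disease": np.array(disease),
    }
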