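"""Shared synthetic fixtures.

Everything is generated at test time from seeded specs; the expensive
scene-based fixtures are session-scoped so segmentation and background
subtraction run once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import gutquant as gq
from gutquant import classify as cl
from gutquant import morphometry as mo
from gutquant.imgproc import LabelVolume


@pytest.fixture(scope="session")
def default_scene():
    """The default 50-cell scene with moderate noise, seed 7."""
    spec = gq.SceneSpec(seed=7)
    grid, truth = gq.generate_gut_stack(spec)
    return spec, grid, truth


@pytest.fixture(scope="session")
def default_scene_labels(default_scene):
    """Watershed segmentation of the default scene's nuclear channel."""
    _, grid, _ = default_scene
    filtered = gq.median_filter_stack(grid, "nuclear", 3)
    return gq.segment_nuclei(filtered, "nuclear")


@pytest.fixture(scope="session")
def measured_scene():
    """400-cell scene measured on its ground-truth label volume.

    Isolates morphometry/classification from segmentation error: records
    carry ring and nuclear intensities (background subtracted) merged with
    the generator's true flags.
    """
    spec = gq.SceneSpec(
        seed=7, n_cells=400, shape_vox=(16, 256, 256), frac_small=0.75
    )
    grid, truth = gq.generate_gut_stack(spec)
    labels = LabelVolume(truth.labels)
    records = mo.measure_nuclei(labels, grid.voxel_spacing_um)
    rings = mo.build_ring_masks(labels, expand_px=2)
    bg = grid
    for ch in ("gfp", "ph3", "pros"):
        bg = mo.subtract_background(bg, ch, 20)
    records = records.merge(
        mo.quantify_ring_intensities(bg, rings, ["gfp"], raw_grid=grid), on="label"
    )
    records = records.merge(
        mo.quantify_nuclear_intensities(bg, labels, ["ph3", "pros"]), on="label"
    )
    merged = records.merge(
        truth.cells.rename(columns={"id": "label"}),
        on="label",
        suffixes=("", "_true"),
    )
    return spec, grid, truth, merged


@pytest.fixture(scope="session")
def measured_scene_model(measured_scene):
    """Threshold model for the measured scene.

    Size threshold from the scene's own bimodal length distribution;
    marker cutoffs from the internal control group = the cells known to
    be negative for each marker.
    """
    _, _, _, merged = measured_scene
    size = cl.derive_size_threshold(merged)
    cutoffs, norms = {}, {}
    cols = {"gfp": "gfp_ring_mean", "ph3": "ph3_nuc_mean", "pros": "pros_nuc_mean"}
    for ch, col in cols.items():
        cut = cl.derive_intensity_cutoff(merged.loc[merged[ch] == 0, col], factor=1.5)
        cutoffs[ch] = cut.cutoff
        norms[ch] = cut.normalization
    return cl.ThresholdModel(
        size_threshold_px=size.threshold_px,
        size_method=size.method,
        intensity_cutoffs=cutoffs,
        normalization=norms,
        marker_columns=cols,
        control_reference="ground-truth negatives",
        n_control=size.n_control,
    )
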