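"""End-to-end convenience pipelines built from the core modules.

These helpers wire phantom generation, seeded segmentation, feature
extraction and tracking together the way an analysis script would, so
examples, the CLI and validation runs share one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imaging import CHANNEL_CYTOPLASM, TimeSeriesStack
from .errors import SegmentationFailure
from .morphometry import compute_features
from .phantom import GroundTruth, PhantomSpec, generate_phantom, seed_polygons
from .segmentation import LevelSetParams, MuscleROI, evolve_levelset, manual_roi


def segment_frame(
    stack: TimeSeriesStack,
    gt: GroundTruth,
    frame_idx: int,
    params: LevelSetParams | None = None,
    margin_px: float = 10.0,
) -> dict[int, MuscleROI]:
    """Segment every fiber of one frame from seed boxes around the true
    geometry (the scripted stand-in for the user's hand-drawn polygons).
    Falls back to a manual ROI from the seed polygon if the contour
    vanishes.  Returns {ground-truth label: ROI}."""
    image = stack.channel(frame_idx, CHANNEL_CYTOPLASM)
    out: dict[int, MuscleROI] = {}
    for label, seed in seed_polygons(gt, frame_idx, margin_px=margin_px).items():
        try:
            roi = evolve_levelset(image, seed, params, stack_name=stack.metadata.stack_name)
        except SegmentationFailure:
            roi = manual_roi(seed, image.shape[-2:], stack_name=stack.metadata.stack_name)
        out[label] = roi
    return out


def measure_phantom(
    spec: PhantomSpec,
    frames: list[int] | None = None,
    params: LevelSetParams | None = None,
) -> tuple[pd.DataFrame, dict[tuple[int, int], MuscleROI], GroundTruth]:
    """Generate a phantom, segment the requested frames and measure features.

    Returns (feature table, {(frame, label): ROI}, ground truth).  The
    table carries stack/genotype/time columns alongside the ten features,
    matching the layout of ``Store.query_features``.
    """
    stack, gt = generate_phantom(spec)
    if frames is None:
        frames = sorted({f for f, _ in gt.masks})
    rows = []
    rois: dict[tuple[int, int], MuscleROI] = {}
    for f in frames:
        for label, roi in segment_frame(stack, gt, f, params=params).items():
            rois[(f, label)] = roi
            fv = compute_features(roi, spec.pixel_size_um)
            truth = gt.table[(gt.table["frame"] == f) & (gt.table["label"] == label)].iloc[0]
            rows.append(
                {
                    "stack_name": spec.stack_name,
                    "genotype": spec.genotype,
                    "frame_idx": f,
                    "label": label,
                    "hours_ahe": truth["hours_ahe"],
                    "cell_type": truth["cell_type"],
                    "segment": truth["segment"],
                    "lateral": truth["lateral"],
                    **{k: v for k, v in fv.as_dict().items()},
                }
            )
    return pd.DataFrame(rows), rois, gt


def atrophy_cohort_features(
    effects: list[str],
    n_animals: int,
    grid_h: np.ndarray,
    seed: int = 0,
    noise_sd: float = 3.0,
    n_diom_segments: int = 1,
) -> pd.DataFrame:
    """Full pipeline over synthetic cohorts: per genotype effect, render
    ``n_animals`` phantom animals sampled on ``grid_h`` (hours AHE), segment
    and measure every fiber.  Animal-level seeds derive from ``seed``.  One
    abdominal segment (two hemisegment fibers) per animal keeps cohorts of
    10 animals at 20 muscles per genotype and time point."""
    from .phantom import default_atrophy_scenario

    grid_h = np.asarray(grid_h, float)
    tables = []
    for gi, effect in enumerate(effects):
        for a in range(n_animals):
            spec = default_atrophy_scenario(
                effect,
                seed=(seed + 7919 * gi + 104729 * a) % (2**31 - 1),
                hours_ahe=grid_h,
                noise_sd=noise_sd,
                n_diom_segments=n_diom_segments,
            )
            spec.stack_name = f"{effect}-animal{a}"
            table, _, _ = measure_phantom(spec)
            tables.append(table)
    return pd.concat(tables, ignore_index=True)
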