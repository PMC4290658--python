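"""Tracking of muscle ROIs across frames and anatomical annotation.

Correspondences between adjacent time points are established by a nearest-
neighbour search on ROI centroids, constrained by a maximum displacement D
(estimated from the largest fiber movement observed over one frame
interval).  Candidate pairs are matched greedily in ascending centroid
distance, which is deterministic and near-optimal at typical fiber
densities; ties are broken by lower ROI id.  Splits and merges are not
modelled — pupal muscles neither divide nor fuse in this window.

Annotations follow a four-criterion nomenclature (cell type, body part,
abdominal segment, lateral side) and are propagated along tracks; the
lateral side is inferred from the registered midline (anterior at left,
y down: the animal's left appears at smaller y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .segmentation import MuscleROI


@dataclass
class TrackingParams:
    """Maximum allowed centroid displacement D between adjacent frames, px."""

    max_distance_px: float

    def __post_init__(self) -> None:
        if not self.max_distance_px > 0:
            raise ValueError("max_distance_px must be positive")


@dataclass(frozen=True)
class CellAnnotation:
    """Four-criterion muscle nomenclature."""

    cell_type: str  # DEOM | DIOM | other
    body_part: str  # thorax | abdomen
    segment: int
    lateral: str  # left | right

    def __post_init__(self) -> None:
        if self.cell_type not in ("DEOM", "DIOM", "other"):
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.body_part not in ("thorax", "abdomen"):
            raise ValueError(f"unknown body_part {self.body_part!r}")
        if self.body_part == "abdomen" and not 1 <= self.segment <= 8:
            raise ValueError("abdominal segment must be in [1, 8]")
        if self.lateral not in ("left", "right"):
            raise ValueError(f"lateral must be 'left' or 'right'")


@dataclass
class Track:
    """An ordered chain of ROI identities for one anatomical muscle."""

    track_id: int
    frames: list[int]  # frame index per element
    roi_ids: list[int]  # one ROI per listed frame
    annotation: Optional[CellAnnotation] = None

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.roi_ids):
            raise ValueError("frames and roi_ids must align")
        if len(set(self.frames)) != len(self.frames):
            raise ValueError("at most one ROI per frame per track")


def link_frames(
    rois_a: Sequence[MuscleROI],
    rois_b: Sequence[MuscleROI],
    params: TrackingParams,
) -> list[tuple[int, int]]:
    """One-to-one matches between two frames' ROIs as (index_a, index_b).

    Candidate pairs are sorted by ascending centroid distance (ties by the
    lower roi_id pair) and accepted greedily; pairs beyond D are skipped.
    """
    if not rois_a or not rois_b:
        return []
    ca = np.array([r.centroid for r in rois_a], float)
    cb = np.array([r.centroid for r in rois_b], float)
    dists = np.hypot(*(ca[:, None, :] - cb[None, :, :]).transpose(2, 0, 1))
    pairs = [
        (dists[i, j], rois_a[i].roi_id, rois_b[j].roi_id, i, j)
        for i in range(len(rois_a))
        for j in range(len(rois_b))
        if dists[i, j] <= params.max_distance_px
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    return matches


def build_tracks(
    frames: Sequence[Sequence[MuscleROI]], params: TrackingParams
) -> list[Track]:
    """Chain pairwise links into tracks; a broken link starts a new track."""
    tracks: list[Track] = []
    open_by_index: dict[int, Track] = {}  # ROI index in previous frame -> track
    next_id = 1
    prev: Sequence[MuscleROI] = []
    for f_idx, rois in enumerate(frames):
        matches = dict()
        if prev:
            matches = {j: i for i, j in link_frames(prev, rois, params)}
        new_open: dict[int, Track] = {}
        for j, roi in enumerate(rois):
            if j in matches and matches[j] in open_by_index:
                tr = open_by_index[matches[j]]
                tr.frames.append(f_idx)
                tr.roi_ids.append(roi.roi_id)
            else:
                tr = Track(track_id=next_id, frames=[f_idx], roi_ids=[roi.roi_id])
                next_id += 1
                tracks.append(tr)
            new_open[j] = tr
        open_by_index = new_open
        prev = rois
    return tracks


@dataclass
class AnnotationConflict:
    roi_id: int
    existing: CellAnnotation
    proposed: CellAnnotation


def propagate_annotation(
    track: Track,
    annotation: CellAnnotation,
    rois_by_id: dict[int, MuscleROI],
) -> list[AnnotationConflict]:
    """Attach an annotation to every ROI of a track.

    ROIs that already carry a *different* annotation are reported as
    conflicts (and left untouched), never silently overwritten.
    """
    if not track.roi_ids:
        raise ValueError("track is empty")
    conflicts = []
    for rid in track.roi_ids:
        roi = rois_by_id[rid]
        if roi.annotation is not None and roi.annotation != annotation:
            conflicts.append(
                AnnotationConflict(roi_id=rid, existing=roi.annotation, proposed=annotation)
            )
            warnings.warn(
                f"ROI {rid} already annotated {roi.annotation}, not overwriting",
                stacklevel=2,
            )
        else:
            roi.annotation = annotation
    track.annotation = annotation
    return conflicts


def infer_lateral_side(centroid: tuple[float, float], midline: np.ndarray) -> str:
    """Anatomical side of a centroid relative to the anterior→posterior midline.

    In a registered frame (anterior at left, +x rightward, y downward, dorsal
    view) the animal's left side lies at smaller y.  Generally: the side is
    given by the sign of the cross product of the midline direction with the
    centroid offset; points exactly on the midline are assigned "right".
    """
    midline = np.asarray(midline, float).reshape(2, 2)
    a, b = midline
    d = b - a
    p = np.asarray(centroid, float) - a
    cross = d[0] * p[1] - d[1] * p[0]
    return "left" if cross < 0 else "right"
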