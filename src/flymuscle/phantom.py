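"""Synthetic two-channel pupal time-lapse stacks with known ground truth.

Muscle fibers are rendered as anti-aliased capsules (a rectangle with
semicircular caps): a capsule has constant width everywhere along its
medial axis, so skeleton-based diameter ground truth is analytic.  The
green channel carries the fiber cytoplasm plus, before head eversion + a
clearance window, small random blobs emulating the histolysis debris that
clutters early pupal frames; the red channel carries Gaussian nuclear
blobs inside each fiber.  Everything is deterministic given the spec seed.

Default study conditions mirror live imaging of Drosophila metamorphosis:
1.25 µm pixels, 8-bit frames at 30-minute intervals, 240 time points with
head eversion at frame 24, DIOM diameter shrinking linearly from 90 to
30 µm over the first 50 hours AHE in control animals (the atrophy phase),
DEOMs histolysed shortly before head eversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import LineString, Point

from .errors import PhantomSpecError
from .imaging import AcquisitionMetadata, TimeSeriesStack
from .segmentation import SeedPolygon

DEFAULT_PIXEL_SIZE_UM = 1.25
DEFAULT_FRAME_INTERVAL_MIN = 30.0


@dataclass
class MuscleSpec:
    """Ground-truth geometry of one fiber across the whole series.

    Arrays are per frame; a fiber is absent (histolysed) from
    ``histolysis_frame`` onward.
    """

    label: int
    cell_type: str  # DIOM | DEOM
    segment: int
    lateral: str  # left | right
    centroid_px: np.ndarray  # (n_frames, 2) of (x, y)
    length_px: np.ndarray  # (n_frames,) tip-to-tip length
    diameter_px: np.ndarray  # (n_frames,) capsule width
    orientation_deg: float  # fixed per fiber, CCW from +x (y down)
    histolysis_frame: int | None = None

    def present(self, frame_idx: int) -> bool:
        return self.histolysis_frame is None or frame_idx < self.histolysis_frame

    def axis_endpoints(self, frame_idx: int) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of the medial axis (the capsule core segment)."""
        c = self.centroid_px[frame_idx]
        half = (self.length_px[frame_idx] - self.diameter_px[frame_idx]) / 2.0
        theta = np.radians(self.orientation_deg)
        d = np.array([np.cos(theta), -np.sin(theta)])  # y down
        return c - half * d, c + half * d


@dataclass
class PhantomSpec:
    """Full specification of one synthetic animal's time-lapse stack."""

    n_frames: int
    image_size: tuple[int, int]  # (H, W)
    muscles: list[MuscleSpec]
    he_frame: int = 0
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    nuclei_per_muscle: int = 4
    debris_density: float = 8.0  # expected blob count per frame before clearance
    debris_clearance_frame: int | None = None  # default: he_frame + 10
    debris_size_px: tuple[float, float] = (2.0, 5.0)
    noise_sd: float = 3.0
    background: float = 10.0
    foreground: float = 200.0
    seed: int = 0
    genotype: str = "control"
    stack_name: str = "phantom"

    def __post_init__(self) -> None:
        for m in self.muscles:
            for arr_name in ("centroid_px", "length_px", "diameter_px"):
                arr = np.asarray(getattr(m, arr_name), dtype=float)
                if arr.shape[0] != self.n_frames:
                    raise PhantomSpecError(
                        f"muscle {m.label}: {arr_name} must cover all {self.n_frames} frames"
                    )
                setattr(m, arr_name, arr)
            if np.any(m.diameter_px <= 0):
                raise PhantomSpecError(f"muscle {m.label}: diameters must stay positive")
        if self.debris_clearance_frame is None:
            self.debris_clearance_frame = self.he_frame + 10

    def metadata(self) -> AcquisitionMetadata:
        return AcquisitionMetadata(
            stack_name=self.stack_name,
            stock_id=f"syn-{self.genotype}",
            genotype=self.genotype,
            acquisition_date="2014-01-01",
            sample_location=f"seed{self.seed}",
            pixel_size_um=self.pixel_size_um,
            frame_interval_min=self.frame_interval_min,
            layout="gray_pairs",
        )


@dataclass
class GroundTruth:
    """Per-frame truth: fiber masks, correspondences, physical measurements."""

    masks: dict  # (frame_idx, label) -> bool mask
    table: pd.DataFrame  # frame, label, cell_type, segment, lateral, centroid, sizes
    nuclei_labels: dict  # frame_idx -> int label image (one label per muscle)
    spec: PhantomSpec = field(repr=False, default=None)


def _capsule_coverage(
    shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray, width: float
) -> tuple[np.ndarray, tuple[int, int]]:
    """Anti-aliased capsule rendered on a bounding-box crop.

    Returns (coverage in [0, 1], (y-offset, x-offset)); coverage falls off
    linearly across one pixel at the boundary.
    """
    h, w = shape
    r = width / 2.0
    lo = np.floor(np.minimum(p0, p1) - r - 2).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + r + 2).astype(int)
    x0, y0 = np.maximum(lo, 0)
    x1 = min(hi[0], w - 1)
    y1 = min(hi[1], h - 1)
    if x1 < x0 or y1 < y0:
        return np.zeros((0, 0)), (0, 0)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1, dtype=float), np.arange(y0, y1 + 1, dtype=float))
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.hypot(xs - p0[0], ys - p0[1])
    else:
        t = np.clip(((xs - p0[0]) * d[0] + (ys - p0[1]) * d[1]) / L2, 0.0, 1.0)
        dist = np.hypot(xs - (p0[0] + t * d[0]), ys - (p0[1] + t * d[1]))
    coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)
    return coverage, (y0, x0)


def _paste(canvas: np.ndarray, patch: np.ndarray, offset: tuple[int, int]) -> None:
    y0, x0 = offset
    h, w = patch.shape
    if h and w:
        canvas[y0 : y0 + h, x0 : x0 + w] += patch


def generate_phantom(spec: PhantomSpec) -> tuple[TimeSeriesStack, GroundTruth]:
    """Render the stack and its ground truth; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    frames = np.zeros((spec.n_frames, 2, h, w), dtype=np.uint8)
    masks: dict = {}
    nuclei_labels: dict = {}
    rows = []

    # fixed per-muscle nuclear placement (axial fraction, lateral fraction)
    nuc_pos = {
        m.label: np.column_stack(
            [
                rng.uniform(0.12, 0.88, spec.nuclei_per_muscle),
                rng.uniform(-0.35, 0.35, spec.nuclei_per_muscle),
            ]
        )
        for m in spec.muscles
    }

    for f in range(spec.n_frames):
        green = np.full((h, w), spec.background, dtype=float)
        red = np.full((h, w), spec.background, dtype=float)
        nuc_lab = np.zeros((h, w), dtype=np.uint16)
        present = [m for m in spec.muscles if m.present(f)]

        # overlap guard: fibers must stay disjoint for ground truth to be usable
        geoms = []
        for m in present:
            p0, p1 = m.axis_endpoints(f)
            geoms.append(LineString([p0, p1]).buffer(m.diameter_px[f] / 2.0))
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                if geoms[i].intersects(geoms[j]):
                    raise PhantomSpecError(
                        f"muscles {present[i].label} and {present[j].label} overlap in frame {f}"
                    )

        for m in present:
            p0, p1 = m.axis_endpoints(f)
            width = float(m.diameter_px[f])
            cov, off = _capsule_coverage((h, w), p0, p1, width)
            _paste(green, (spec.foreground - spec.background) * cov, off)
            full = np.zeros((h, w))
            _paste(full, cov, off)
            mask = full >= 0.5
            masks[(f, m.label)] = mask

            # nuclei ride along with the fiber
            axis = p1 - p0
            theta = np.radians(m.orientation_deg)
            normal = np.array([np.sin(theta), np.cos(theta)])
            sigma = max(2.0, min(4.0, width / 6.0))
            for frac_ax, frac_lat in nuc_pos[m.label]:
                centre = p0 + frac_ax * axis + frac_lat * width * normal
                ccov, coff = _capsule_coverage((h, w), centre, centre, 3.0 * sigma)
                patch = np.zeros((h, w))
                _paste(patch, ccov, coff)
                yy, xx = np.nonzero(patch)
                if len(yy) == 0:
                    continue
                g = 170.0 * np.exp(
                    -((xx - centre[0]) ** 2 + (yy - centre[1]) ** 2) / (2 * sigma**2)
                )
                red[yy, xx] += g
                near = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 <= (1.5 * sigma) ** 2
                sel = near & mask[yy, xx]
                nuc_lab[yy[sel], xx[sel]] = m.label

            hrs = (f - spec.he_frame) * spec.frame_interval_min / 60.0
            rows.append(
                {
                    "frame": f,
                    "label": m.label,
                    "cell_type": m.cell_type,
                    "segment": m.segment,
                    "lateral": m.lateral,
                    "hours_ahe": hrs,
                    "centroid_x": float(m.centroid_px[f][0]),
                    "centroid_y": float(m.centroid_px[f][1]),
                    "diameter_um": width * spec.pixel_size_um,
                    "length_um": float(m.length_px[f]) * spec.pixel_size_um,
                }
            )

        # histolysis debris clutters early frames, away from live fibers
        if f < spec.debris_clearance_frame and spec.debris_density > 0:
            n_debris = rng.poisson(spec.debris_density)
            placed = 0
            attempts = 0
            while placed < n_debris and attempts < 20 * n_debris + 20:
                attempts += 1
                c = rng.uniform([0, 0], [w - 1, h - 1])
                size = rng.uniform(*spec.debris_size_px)
                if any(g.distance(Point(c)) < size + 4 for g in geoms):
                    continue
                cov, off = _capsule_coverage((h, w), c, c, 2 * size)
                _paste(green, rng.uniform(60, 150) * cov, off)
                placed += 1

        if spec.noise_sd > 0:
            green = green + rng.normal(0.0, spec.noise_sd, green.shape)
            red = red + rng.normal(0.0, spec.noise_sd, red.shape)
        frames[f, 0] = np.clip(green, 0, 255).astype(np.uint8)
        frames[f, 1] = np.clip(red, 0, 255).astype(np.uint8)
        nuclei_labels[f] = nuc_lab

    table = pd.DataFrame(rows)
    stack = TimeSeriesStack(frames=frames, metadata=spec.metadata())
    return stack, GroundTruth(masks=masks, table=table, nuclei_labels=nuclei_labels, spec=spec)


def seed_polygons(
    gt: GroundTruth, frame_idx: int, margin_px: float = 10.0
) -> dict[int, SeedPolygon]:
    """Rectangular seed polygons around each fiber's true mask (bbox + margin),
    emulating the user's hand-drawn enclosing polygons."""
    h, w = gt.spec.image_size
    seeds = {}
    for (f, label), mask in gt.masks.items():
        if f != frame_idx:
            continue
        ys, xs = np.nonzero(mask)
        x0 = max(xs.min() - margin_px, 0.0)
        x1 = min(xs.max() + margin_px, w - 1.0)
        y0 = max(ys.min() - margin_px, 0.0)
        y1 = min(ys.max() + margin_px, h - 1.0)
        seeds[label] = SeedPolygon(
            vertices=[(x0, y0), (x1, y0), (x1, y1), (x0, y1)], frame_idx=frame_idx
        )
    return seeds


# ---------------------------------------------------------------------------
# scenarios


def _diameter_um_profile(effect: str, hours: np.ndarray) -> np.ndarray:
    """Median DIOM diameter trajectories by genotype effect.

    control: 90 µm before head eversion, shrinking linearly to 30 µm at 50 h
    AHE, then plateau.  enhanced (Tor-silencing-like): thinner throughout,
    atrophy prolonged to 45 h AHE down to 20 µm.  suppressed
    (Atg9-silencing-like): identical to control until 30 h AHE, then the
    diameter recovers instead of shrinking further.
    """
    t = np.asarray(hours, dtype=float)
    if effect == "control":
        return np.clip(90.0 - 1.2 * np.clip(t, 0, None), 30.0, 90.0)
    if effect == "enhanced":
        return np.clip(70.0 - (50.0 / 45.0) * np.clip(t, 0, None), 20.0, 70.0)
    if effect == "suppressed":
        base = np.clip(90.0 - 1.2 * np.clip(t, 0, None), 30.0, 90.0)
        rec = 54.0 + 0.6 * (t - 30.0)
        return np.where(t <= 30.0, base, np.minimum(np.maximum(rec, base), 80.0))
    raise ValueError(f"unknown genotype effect {effect!r}")


def default_atrophy_scenario(
    genotype_effect: str = "control",
    seed: int = 0,
    *,
    hours_ahe: np.ndarray | None = None,
    n_diom_segments: int = 3,
    noise_sd: float = 3.0,
    animal_cv: float = 0.05,
) -> PhantomSpec:
    """One-animal spec emulating the atrophy time course of one genotype.

    By default the series covers -12 h to +107.5 h AHE at 30-minute
    intervals (240 frames, head eversion at frame 24).  ``hours_ahe`` may
    be any uniformly spaced grid instead (e.g. the 5-hour sampling grid).
    DIOMs occupy abdominal segments 3..(2+n) on both sides; two DEOMs
    histolyse four frames before head eversion.  Per-animal and per-muscle
    multiplicative size variability is drawn from the seed.
    """
    if hours_ahe is None:
        hours_ahe = -12.0 + 0.5 * np.arange(240)
    hours_ahe = np.asarray(hours_ahe, dtype=float)
    steps = np.diff(hours_ahe)
    if len(hours_ahe) > 1 and not np.allclose(steps, steps[0]):
        raise PhantomSpecError("hours_ahe must be uniformly spaced")
    interval_min = float(steps[0] * 60.0) if len(hours_ahe) > 1 else DEFAULT_FRAME_INTERVAL_MIN
    he_candidates = np.nonzero(np.isclose(hours_ahe, 0.0))[0]
    he_frame = int(he_candidates[0]) if len(he_candidates) else 0
    n_frames = len(hours_ahe)

    rng = np.random.default_rng(seed)
    animal_scale = float(rng.normal(1.0, animal_cv))
    px = DEFAULT_PIXEL_SIZE_UM
    diam_um = _diameter_um_profile(genotype_effect, hours_ahe)

    cell_w = 170  # px per segment column
    cell_h = 120  # px per hemisegment row
    img_w = n_diom_segments * cell_w + 40
    img_h = 2 * cell_h + 150  # extra row below the DIOMs for the DEOMs
    muscles: list[MuscleSpec] = []
    label = 1
    for si in range(n_diom_segments):
        for li, lateral in enumerate(("left", "right")):
            muscle_scale = animal_scale * float(rng.normal(1.0, 0.02))
            base = np.array(
                [40 + cell_w * si + cell_w / 2.0, 30 + cell_h * li + cell_h / 2.0]
            )
            phase = rng.uniform(0, 2 * np.pi)
            tt = np.arange(n_frames, dtype=float)
            drift = np.column_stack(
                [
                    3.0 * np.sin(2 * np.pi * tt / max(n_frames, 2) + phase),
                    2.0 * np.cos(2 * np.pi * tt / max(n_frames, 2) + phase),
                ]
            )
            jitter = rng.normal(0.0, 0.3, size=(n_frames, 2)).cumsum(axis=0)
            jitter -= jitter.mean(axis=0)
            centroids = base[None, :] + drift + 0.2 * jitter
            length_um = (180.0 - 0.5 * np.clip(hours_ahe, 0, 50)) * muscle_scale
            muscles.append(
                MuscleSpec(
                    label=label,
                    cell_type="DIOM",
                    segment=3 + si,
                    lateral=lateral,
                    centroid_px=centroids,
                    length_px=length_um / px,
                    diameter_px=diam_um * muscle_scale / px,
                    orientation_deg=float(rng.uniform(-12, 12)),
                )
            )
            label += 1

    # DEOMs: present only before head eversion, then histolysed; they sit in
    # their own row below the DIOMs so oblique fibers never collide
    if he_frame > 0:
        dx = min(90.0, img_w / 2.0 - 55.0)
        for li, lateral in enumerate(("left", "right")):
            base = np.array([img_w / 2.0 + (dx if li else -dx), 30 + 2 * cell_h + 55.0])
            centroids = np.tile(base, (n_frames, 1))
            muscles.append(
                MuscleSpec(
                    label=label,
                    cell_type="DEOM",
                    segment=2,
                    lateral=lateral,
                    centroid_px=centroids,
                    length_px=np.full(n_frames, 120.0 / px * 1.0),
                    diameter_px=np.full(n_frames, 40.0 / px),
                    orientation_deg=float(rng.uniform(-8, 8)),
                    histolysis_frame=max(he_frame - 4, 1),
                )
            )
            label += 1

    return PhantomSpec(
        n_frames=n_frames,
        image_size=(img_h, img_w),
        muscles=muscles,
        he_frame=he_frame,
        frame_interval_min=interval_min,
        pixel_size_um=px,
        noise_sd=noise_sd,
        seed=seed,
        genotype=genotype_effect,
        stack_name=f"phantom-{genotype_effect}-{seed}",
        # debris clears ~5 h after head eversion regardless of sampling step
        debris_clearance_frame=int(np.searchsorted(hours_ahe, 5.0)),
    )


def feature_validation_phantom(seed: int = 0, n_fibers: int = 10, noise_sd: float = 3.0) -> PhantomSpec:
    """Single-frame spec with ``n_fibers`` capsules spanning widths 24-72 px,
    mildly oblique, used to validate feature measurements against the
    manual-protocol oracle."""
    rng = np.random.default_rng(seed)
    widths = np.linspace(24.0, 72.0, n_fibers)
    n_cols = 2
    n_rows = int(np.ceil(n_fibers / n_cols))
    cell_w, cell_h = 260, 120
    img_w, img_h = n_cols * cell_w + 40, n_rows * cell_h + 40
    muscles = []
    for i, width in enumerate(widths):
        row, col = divmod(i, n_cols)
        centre = np.array([20 + cell_w * col + cell_w / 2.0, 20 + cell_h * row + cell_h / 2.0])
        length = float(rng.uniform(180, 230))
        muscles.append(
            MuscleSpec(
                label=i + 1,
                cell_type="DIOM",
                segment=3 + (i % 3),
                lateral="left" if i % 2 == 0 else "right",
                centroid_px=centre[None, :],
                length_px=np.array([length]),
                diameter_px=np.array([width]),
                orientation_deg=float(rng.uniform(-15, 15)),
            )
        )
    return PhantomSpec(
        n_frames=1,
        image_size=(img_h, img_w),
        muscles=muscles,
        noise_sd=noise_sd,
        debris_density=0.0,
        he_frame=0,
        seed=seed,
        stack_name=f"validation-{seed}",
    )


def manual_protocol_oracle(gt: GroundTruth, frame_idx: int = 0) -> pd.DataFrame:
    """Independent manual-protocol measurements on ground-truth geometry.

    Emulates how a person validates the pipeline with external tools:
    average diameter is the mean of 5 widths measured perpendicular to the
    medial axis (chord lengths through the analytic capsule, via shapely);
    length is the analytic medial-axis length; area is the analytic capsule
    area; elongation comes from skimage.measure.regionprops on the true
    mask (the moment-based definition used by external regionprops tools).
    None of these touch the pipeline's measurement code.
    """
    from skimage.measure import regionprops

    spec = gt.spec
    px = spec.pixel_size_um
    rows = []
    for m in spec.muscles:
        if not m.present(frame_idx):
            continue
        p0, p1 = m.axis_endpoints(frame_idx)
        width = float(m.diameter_px[frame_idx])
        axis = LineString([p0, p1])
        capsule = axis.buffer(width / 2.0, quad_segs=64)
        d = (p1 - p0) / max(axis.length, 1e-12)
        normal = np.array([-d[1], d[0]])
        widths = []
        for frac in (1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6):
            pt = p0 + frac * (p1 - p0)
            probe = LineString([pt - 500 * normal, pt + 500 * normal])
            widths.append(capsule.intersection(probe).length)
        props = regionprops(gt.masks[(frame_idx, m.label)].astype(np.uint8))[0]
        elong = (
            (props.axis_major_length - props.axis_minor_length) / props.axis_major_length
        )
        rows.append(
            {
                "roi_label": m.label,
                "avg_diameter_um": float(np.mean(widths)) * px,
                "length_um": axis.length * px,
                "area_um2": capsule.area * px**2,
                "elongation": float(elong),
            }
        )
    return pd.DataFrame(rows)


def estimate_max_distance(gt: GroundTruth) -> float:
    """Empirical tracking gate D: twice the largest per-frame centroid
    movement observed in the ground truth (mirrors estimating D from the
    maximum fiber movement seen over one frame interval)."""
    t = gt.table.sort_values(["label", "frame"])
    best = 0.0
    for _, grp in t.groupby("label"):
        dx = grp["centroid_x"].diff()
        dy = grp["centroid_y"].diff()
        step = np.hypot(dx, dy).max()
        if np.isfinite(step):
            best = max(best, float(step))
    return 2.0 * best if best > 0 else 10.0


def export_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write the truth table as CSV and per-frame label masks as a TIFF."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    gt.table.to_csv(path / "ground_truth.csv", index=False)
    spec = gt.spec
    labels = np.zeros((spec.n_frames, *spec.image_size), dtype=np.uint16)
    for (f, label), mask in gt.masks.items():
        labels[f][mask] = label
    tifffile.imwrite(path / "true_labels.tif", labels)
    nuc = np.stack([gt.nuclei_labels[f] for f in range(spec.n_frames)])
    tifffile.imwrite(path / "true_nuclei_labels.tif", nuc)
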