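"""Time-series image I/O.

Native input is a multi-page TIFF (one page per time point) plus a JSON or
YAML metadata sidecar.  RGB pages carry the muscle cytoplasm in the green
plane and the nuclei in the red plane; the blue plane is ignored.  A
two-channel grayscale layout (two consecutive pages per time point, cytoplasm
first) is accepted when the sidecar sets ``layout: gray_pairs`` — this is the
layout the phantom generator writes.

Coordinates are 0-based pixel-center, x rightward, y downward; every polygon
and mask in the package shares this convention.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, MetadataError, ValidationError

#: index of the cytoplasm (green) channel in a TimeSeriesStack frame
CHANNEL_CYTOPLASM = 0
#: index of the nuclei (red) channel
CHANNEL_NUCLEI = 1

_DEFAULT_CHANNEL_ROLES = {"green": "cytoplasm", "red": "nuclei"}


@dataclass
class AcquisitionMetadata:
    """Acquisition parameters and sample identity for one time-lapse stack.

    A stack is uniquely identified by ``stack_name`` together with the
    triple (``stock_id``, ``acquisition_date``, ``sample_location``).
    """

    stack_name: str
    stock_id: str
    genotype: str
    acquisition_date: str
    sample_location: str
    pixel_size_um: float
    frame_interval_min: float
    z_step_um: float = 11.08
    magnification: str = "10x"
    bit_depth: int = 8
    channel_roles: dict = field(default_factory=lambda: dict(_DEFAULT_CHANNEL_ROLES))
    layout: str = "rgb"

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise MetadataError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if not (self.frame_interval_min > 0):
            raise MetadataError(
                f"frame_interval_min must be positive, got {self.frame_interval_min}"
            )
        if self.layout not in ("rgb", "gray_pairs"):
            raise MetadataError(f"unknown layout {self.layout!r}")
        # normalise the date so identity comparisons are stable
        try:
            self.acquisition_date = _dt.date.fromisoformat(str(self.acquisition_date)).isoformat()
        except ValueError as exc:
            raise MetadataError(f"acquisition_date is not an ISO date: {exc}") from exc

    @property
    def identity(self) -> tuple[str, str, str, str]:
        return (self.stack_name, self.stock_id, self.acquisition_date, self.sample_location)

    @classmethod
    def from_mapping(cls, data: dict) -> "AcquisitionMetadata":
        required = (
            "stack_name",
            "stock_id",
            "genotype",
            "acquisition_date",
            "sample_location",
            "pixel_size_um",
            "frame_interval_min",
        )
        missing = [k for k in required if k not in data]
        if missing:
            raise MetadataError(f"sidecar is missing required fields: {missing}")
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_mapping(self) -> dict:
        return {
            "stack_name": self.stack_name,
            "stock_id": self.stock_id,
            "genotype": self.genotype,
            "acquisition_date": self.acquisition_date,
            "sample_location": self.sample_location,
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_min": self.frame_interval_min,
            "z_step_um": self.z_step_um,
            "magnification": self.magnification,
            "bit_depth": self.bit_depth,
            "channel_roles": dict(self.channel_roles),
            "layout": self.layout,
        }


@dataclass
class TimeSeriesStack:
    """A registered (or raw) two-channel image sequence.

    ``frames`` has shape (n_frames, 2, H, W); channel 0 is cytoplasm,
    channel 1 is nuclei.
    """

    frames: np.ndarray
    metadata: AcquisitionMetadata

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[1] != 2:
            raise FormatError(
                f"frames must have shape (T, 2, H, W), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise FormatError("a stack needs at least one frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (int(self.frames.shape[2]), int(self.frames.shape[3]))

    def channel(self, frame_idx: int, channel: int) -> np.ndarray:
        return self.frames[frame_idx, channel]


@dataclass
class EnvironmentLog:
    """Temperature/humidity readings from a data logger, strictly time-ordered."""

    samples: pd.DataFrame  # columns: timestamp, temperature_c, humidity_rh

    def __post_init__(self) -> None:
        df = self.samples
        expected = ["timestamp", "temperature_c", "humidity_rh"]
        if list(df.columns) != expected:
            raise ValidationError(f"environment log must have columns {expected}")
        ts = pd.to_datetime(df["timestamp"])
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValidationError("environment log timestamps must be increasing")
        if ts.duplicated().any():
            raise ValidationError("environment log timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)


def load_sidecar(path: str | Path) -> dict:
    """Parse a JSON (.json) or YAML (.yaml/.yml) metadata sidecar."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise MetadataError(f"cannot read sidecar {path}: {exc}") from exc
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_timeseries(path: str | Path, sidecar: str | Path) -> TimeSeriesStack:
    """Read a multi-page TIFF time series with its metadata sidecar.

    RGB pages are split into (green -> channel 0, red -> channel 1).  With
    ``layout: gray_pairs`` consecutive page pairs form one time point.
    """
    meta = AcquisitionMetadata.from_mapping(load_sidecar(sidecar))
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path} contains no pages")
    shapes = {p.shape[:2] for p in pages}
    if len(shapes) != 1:
        raise FormatError(f"TIFF pages differ in size: {sorted(shapes)}")

    if meta.layout == "rgb":
        frames = []
        for p in pages:
            if p.ndim != 3 or p.shape[2] < 3:
                raise FormatError(f"expected RGB pages, got page shape {p.shape}")
            frames.append(np.stack([p[..., 1], p[..., 0]]))  # G -> cyto, R -> nuclei
    else:  # gray_pairs
        if any(p.ndim != 2 for p in pages):
            raise FormatError("gray_pairs layout requires 2-D grayscale pages")
        if len(pages) % 2 != 0:
            raise FormatError("gray_pairs layout requires an even page count")
        frames = [np.stack([pages[i], pages[i + 1]]) for i in range(0, len(pages), 2)]
    return TimeSeriesStack(frames=np.asarray(frames), metadata=meta)


def write_timeseries(stack: TimeSeriesStack, path: str | Path) -> None:
    """Write a stack back to multi-page TIFF in the layout named by its metadata."""
    path = Path(path)
    if stack.metadata.layout == "rgb":
        t, _, h, w = stack.frames.shape
        pages = np.zeros((t, h, w, 3), dtype=stack.frames.dtype)
        pages[..., 1] = stack.frames[:, CHANNEL_CYTOPLASM]
        pages[..., 0] = stack.frames[:, CHANNEL_NUCLEI]
        tifffile.imwrite(path, pages, photometric="rgb")
    else:
        pages = stack.frames.reshape(-1, *stack.frames.shape[2:])
        tifffile.imwrite(path, pages, photometric="minisblack")


def max_intensity_project(volume: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise maximum over z-slices; reduces a 3-D stack to one 2-D frame."""
    slices = [np.asarray(s) for s in volume]
    if len(slices) == 0:
        raise ValueError("max_intensity_project needs at least one slice")
    shape = slices[0].shape
    if any(s.shape != shape for s in slices):
        raise FormatError("all slices must share one shape")
    out = slices[0].copy()
    for s in slices[1:]:
        np.maximum(out, s, out=out)
    return out


def load_environment_log(path: str | Path) -> EnvironmentLog:
    """Load a CSV of (timestamp, temperature, humidity) logger readings."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["timestamp", "temperature_c", "humidity_rh"])
    rename = {}
    for col in df.columns:
        lc = col.strip().lower()
        if lc.startswith("time"):
            rename[col] = "timestamp"
        elif lc.startswith("temp"):
            rename[col] = "temperature_c"
        elif lc.startswith("hum"):
            rename[col] = "humidity_rh"
    df = df.rename(columns=rename)
    for col in ("timestamp", "temperature_c", "humidity_rh"):
        if col not in df.columns:
            raise ValidationError(f"environment log is missing a {col} column")
    return EnvironmentLog(samples=df[["timestamp", "temperature_c", "humidity_rh"]])
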