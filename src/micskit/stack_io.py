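"""Image-stack I/O, acquisition metadata, and analysis-window geometry.

Coordinate convention used throughout the package: 0-based ``(row, col)`` =
``(y, x)``, origin at the top-left of the frame. The raster scanner's fast
axis is x (columns), so a column shift ξ probes the pixel-dwell timescale and
a row shift ψ the line timescale.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import tifffile
import yaml

__all__ = [
    "AcquisitionMeta",
    "ImageStack",
    "Window",
    "read_stack",
    "write_stack",
    "read_meta",
    "write_meta",
    "tile_windows",
]


@dataclasses.dataclass(frozen=True)
class AcquisitionMeta:
    """Raster-scan acquisition parameters.

    Parameters
    ----------
    pixel_size : float
        Pixel size δr in µm/pixel.
    pixel_dwell : float
        Pixel dwell time τ_p in seconds.
    line_time : float
        Time between consecutive line starts τ_l in seconds.
    frame_interval : float
        Time between consecutive frame starts in seconds.
    beam_waist : float
        1/e² radius ω₀ of the Gaussian excitation profile, µm.
    axial_waist : float
        Axial 1/e² radius ω_z, µm. Enters only the RICS 3D diffusion model.
    """

    pixel_size: float
    pixel_dwell: float
    line_time: float
    frame_interval: float
    beam_waist: float = 0.25
    axial_waist: float = 0.75

    def __post_init__(self) -> None:
        for name in ("pixel_size", "pixel_dwell", "line_time", "frame_interval",
                     "beam_waist", "axial_waist"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"AcquisitionMeta.{name} must be strictly positive, got {v!r}")

    def validate_frame_shape(self, height: int, width: int) -> None:
        """Check timing consistency against a frame geometry.

        The scanner cannot start a new line before finishing the pixels of the
        current one, nor a new frame before finishing its lines.
        """
        if self.line_time < width * self.pixel_dwell:
            raise ValueError(
                f"line_time {self.line_time} < width*pixel_dwell {width * self.pixel_dwell}"
            )
        if self.frame_interval < height * self.line_time:
            raise ValueError(
                f"frame_interval {self.frame_interval} < height*line_time {height * self.line_time}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: float(v) for k, v in d.items() if k in fields})


@dataclasses.dataclass
class ImageStack:
    """A time-ordered stack of 2D frames with acquisition metadata.

    ``frames`` has shape ``(time, row, col)``; intensities are finite and
    non-negative.
    """

    frames: np.ndarray
    meta: AcquisitionMeta
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3D (time, row, col), got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise ValueError(f"stack must have at least 2 frames, got {self.frames.shape[0]}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if np.any(self.frames < 0):
            raise ValueError("frames contain negative intensities")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def frame_means(self) -> np.ndarray:
        """Spatial mean intensity per frame, f(t_i)."""
        return self.frames.mean(axis=(1, 2))


@dataclasses.dataclass(frozen=True)
class Window:
    """A square analysis window, 0-based origin ``(row, col)``."""

    origin: tuple[int, int]
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("window size must be >= 1")
        if self.origin[0] < 0 or self.origin[1] < 0:
            raise ValueError("window origin must be non-negative")

    @property
    def row(self) -> int:
        return self.origin[0]

    @property
    def col(self) -> int:
        return self.origin[1]

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row, self.row + self.size),
                slice(self.col, self.col + self.size))

    def contained_in(self, height: int, width: int) -> bool:
        return self.row + self.size <= height and self.col + self.size <= width

    def extract(self, frames: np.ndarray) -> np.ndarray:
        """Crop the window region from a (time, row, col) array."""
        rs, cs = self.slices()
        return frames[:, rs, cs]


def read_stack(path: str | Path, meta: AcquisitionMeta, channel_label: str = "") -> ImageStack:
    """Read a multi-frame grayscale TIFF into an :class:`ImageStack`.

    The frames are taken in file order (acquisition order). Raises if the
    file is missing, has fewer than 2 frames, or mixes frame shapes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
    if arr.ndim == 2:
        raise ValueError("fewer than 2 frames in TIFF")
    if arr.ndim != 3:
        raise ValueError(f"expected grayscale multi-frame TIFF, got array ndim={arr.ndim}")
    return ImageStack(frames=arr.astype(np.float64), meta=meta, channel_label=channel_label)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a multi-frame TIFF.

    Integer arrays are written as-is (bit-exact round trip); float arrays as
    32-bit float.
    """
    path = Path(path)
    frames = stack.frames
    if np.issubdtype(frames.dtype, np.integer):
        data = frames
    else:
        data = frames.astype(np.float32)
    tifffile.imwrite(str(path), data)


def read_meta(path: str | Path) -> AcquisitionMeta:
    """Read acquisition metadata from a YAML or JSON sidecar file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        d = json.loads(text)
    else:
        d = yaml.safe_load(text)
    return AcquisitionMeta.from_dict(d)


def write_meta(meta: AcquisitionMeta, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(meta.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(meta.to_dict()))


def tile_windows(stack: ImageStack, size: int, step: int) -> list[Window]:
    """Tile the frame with square windows, left-to-right then top-to-bottom.

    Origins form arithmetic sequences with difference ``step``; windows that
    would overrun the frame edge are dropped (no partial windows).
    """
    h, w = stack.height, stack.width
    if size > min(h, w):
        raise ValueError(f"window size {size} exceeds frame dims ({h}, {w})")
    if not (1 <= step <= size):
        raise ValueError(f"step must satisfy 1 <= step <= size, got {step}")
    windows: list[Window] = []
    for r in range(0, h - size + 1, step):
        for c in range(0, w - size + 1, step):
            windows.append(Window(origin=(r, c), size=size))
    return windows
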