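"""Image containers and raster I/O.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)`` with the origin at the
  top-left corner of the image;
* channel data are 8-bit (0-255); deeper sources are rescaled linearly by
  the *container's* declared bit depth (65535 -> 255 for 16-bit), never by
  the data range, so intensity thresholds stay comparable across a batch;
* physical calibration is a single isotropic ``pixel_size`` in micrometres
  per pixel edge, supplied by the analysis configuration (never parsed
  from TIFF tags).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ImageFrame",
    "ImageStack",
    "FormatError",
    "load_image",
    "save_image",
    "max_project",
]


class FormatError(ValueError):
    """Raised when a file cannot be read as a supported raster image."""


@dataclass
class ImageFrame:
    """A 2D multi-channel 8-bit image with physical calibration.

    Parameters
    ----------
    pixels
        ``(height, width, n_channels)`` uint8 array.  A 2D array is
        promoted to a single-channel 3D array.
    channels
        Ordered channel names, e.g. ``("R", "G", "B")`` or ``("GRAY",)``.
    pixel_size
        Physical edge length of one pixel in micrometres (default 1.0,
        meaning "uncalibrated, units are pixels").
    """

    pixels: np.ndarray
    channels: tuple[str, ...] = ("GRAY",)
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim == 2:
            arr = arr[:, :, np.newaxis]
        if arr.ndim != 3:
            raise ValueError(f"pixels must be 2D or 3D, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValueError(f"zero-size image: shape {arr.shape}")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr
        self.channels = tuple(self.channels)
        if len(self.channels) != arr.shape[2]:
            raise ValueError(
                f"{len(self.channels)} channel names for {arr.shape[2]} planes"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def get_channel(self, name: str) -> np.ndarray:
        """Return one channel as a 2D uint8 array.

        Raises ``KeyError`` listing the available channels if *name* is
        unknown.
        """
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {', '.join(self.channels)}"
            ) from None
        return self.pixels[:, :, idx]


@dataclass
class ImageStack:
    """An ordered z-stack of frames with identical geometry and channels."""

    frames: list[ImageFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("stack must contain at least one frame")
        first = self.frames[0]
        for f in self.frames[1:]:
            if f.shape != first.shape or f.channels != first.channels:
                raise ValueError("all frames must share dimensions and channels")

    def __len__(self) -> int:
        return len(self.frames)


_CHANNEL_NAMES = {1: ("GRAY",), 3: ("R", "G", "B"), 4: ("R", "G", "B", "A")}


def _rescale_to_uint8(arr: np.ndarray) -> np.ndarray:
    """Linear rescale by container bit depth (not by data range)."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return np.round(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    if arr.dtype == bool:
        return arr.astype(np.uint8) * 255
    raise FormatError(f"unsupported sample type {arr.dtype}")


def load_image(path: str | Path, pixel_size: float = 1.0) -> ImageFrame:
    """Read a TIFF/PNG/JPEG/GIF image into an :class:`ImageFrame`.

    Single-channel sources get the channel name ``GRAY``; 3-channel
    sources ``R,G,B``.  Sources deeper than 8 bits per channel are
    rescaled linearly by the declared bit depth.  Loading a JPEG logs a
    warning because lossy compression perturbs intensities.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if suffix in (".jpg", ".jpeg"):
        log.warning("%s is JPEG; lossy compression perturbs intensities", path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[:, :, np.newaxis]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 2D image, got shape {arr.shape}")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError(f"{path}: zero-size image")
    arr = _rescale_to_uint8(arr)
    names = _CHANNEL_NAMES.get(arr.shape[2])
    if names is None:
        names = tuple(f"C{i}" for i in range(arr.shape[2]))
    return ImageFrame(pixels=arr, channels=names, pixel_size=pixel_size)


def save_image(frame: ImageFrame, path: str | Path) -> None:
    """Write a frame as uncompressed TIFF or PNG (by file extension)."""
    path = Path(path)
    arr = frame.pixels
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr, compression=None)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise FormatError(f"unsupported output format: {path.suffix!r}")


def save_label_map(label_map: np.ndarray, path: str | Path) -> None:
    """Export a punctum label map as a 16-bit single-channel TIFF."""
    import tifffile

    if label_map.max(initial=0) > np.iinfo(np.uint16).max:
        warnings.warn("label map exceeds 16-bit range; labels will wrap")
    tifffile.imwrite(Path(path), label_map.astype(np.uint16), compression=None)


def max_project(stack: ImageStack | Sequence[ImageFrame]) -> ImageFrame:
    """Per-pixel, per-channel maximum-intensity projection of a stack.

    Calibration and channel names are copied from the first frame.
    """
    frames = stack.frames if isinstance(stack, ImageStack) else list(stack)
    if not frames:
        raise ValueError("cannot project an empty stack")
    stacked = np.stack([f.pixels for f in frames], axis=0)
    return ImageFrame(
        pixels=stacked.max(axis=0),
        channels=frames[0].channels,
        pixel_size=frames[0].pixel_size,
    )
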