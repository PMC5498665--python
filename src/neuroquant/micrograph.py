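"""Core raster container and spatial calibration.

A :class:`Micrograph` wraps a 2-D grayscale intensity raster together with
its bit depth, a free-text channel tag, and an optional spatial calibration
(micrometres per pixel).  All pipeline stages accept and return this type so
that calibration travels with the pixels.

Coordinate convention used throughout the package: ``(row, col)``, 0-based,
with pixel centres at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile


@dataclass(frozen=True)
class ScaleCalibration:
    """Spatial scale of an image, derived from the microscope's length bar.

    Parameters
    ----------
    um_per_px:
        Micrometres spanned by one pixel.  Must be finite and positive.
    """

    um_per_px: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.um_per_px) or self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be finite and > 0, got {self.um_per_px}")

    @classmethod
    def from_scale_bar(cls, bar_length_um: float, bar_length_px: float) -> "ScaleCalibration":
        """Calibrate from a scale bar of known physical length and pixel span."""
        if bar_length_um <= 0 or bar_length_px <= 0:
            raise ValueError("scale bar lengths must be positive")
        return cls(um_per_px=bar_length_um / bar_length_px)


@dataclass
class Micrograph:
    """A 2-D grayscale intensity raster.

    Attributes
    ----------
    pixels:
        2-D array of intensities.  Stored as provided; analysis stages work
        in float64 internally.
    bit_depth:
        8 or 16; all intensities must lie within ``[0, 2**bit_depth - 1]``.
    channel:
        Free-text tag ("phase", "marker", "nucleus", "blot", ...).
    calibration:
        Optional micrometre-per-pixel scale.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    channel: str = ""
    calibration: ScaleCalibration | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"pixels must be a 2-D array, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        finite = np.isfinite(self.pixels)
        if not finite.all():
            raise ValueError("image contains non-finite pixels")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > self.max_value:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside {self.bit_depth}-bit range [0, {self.max_value}]"
            )

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def as_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64, copy=False)

    # ------------------------------------------------------------------ I/O

    def write(self, path: str | Path) -> None:
        """Write as grayscale TIFF (16-bit) or PNG, inferred from suffix."""
        path = Path(path)
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        data = np.clip(np.rint(self.pixels), 0, self.max_value).astype(dtype)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, data)
        else:
            iio.imwrite(path, data)

    @classmethod
    def read(
        cls,
        path: str | Path,
        channel: str = "",
        calibration: ScaleCalibration | None = None,
    ) -> "Micrograph":
        """Read an 8/16-bit grayscale TIFF or PNG."""
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            data = tifffile.imread(path)
        else:
            data = iio.imread(path)
        data = np.asarray(data)
        if data.ndim == 3:  # collapse trivial colour axes
            if data.shape[-1] in (3, 4) and np.array_equal(data[..., 0], data[..., 1]):
                data = data[..., 0]
            else:
                raise ValueError(f"{path}: expected grayscale image, got shape {data.shape}")
        bit_depth = 8 if data.dtype == np.uint8 else 16
        return cls(pixels=data, bit_depth=bit_depth, channel=channel, calibration=calibration)
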