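"""ROI densitometry of Western-blot bands.

The integrated density value (IDV) of a band is the sum of pixel
intensities over a user-defined rectangular region of interest minus the
local background contribution, estimated as the per-pixel mean of a
same-size region near the band times the band ROI's area.  The same ROI
dimensions must be used for every band in every experiment.  Band IDVs are
normalized twice: first to the loading-control band of the same lane
(typically beta-actin), then to a reference condition to absorb
between-experiment variability.

Films carry dark signal on a light background; by default pixel values are
inverted (bit-depth maximum minus pixel) before summation so that more
protein means a larger IDV.  Synthetic blots from
:mod:`neuroquant.synthetic` use the same polarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .micrograph import Micrograph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROI:
    """A rectangular pixel region: top/left corner plus height/width."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI height and width must be >= 1")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI top/left must be >= 0")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.top, self.top + self.height),
                slice(self.left, self.left + self.width))

    @property
    def area(self) -> int:
        return self.height * self.width

    def inside(self, shape: tuple[int, int]) -> bool:
        return self.top + self.height <= shape[0] and self.left + self.width <= shape[1]

    def overlaps(self, other: "ROI") -> bool:
        return not (
            self.top + self.height <= other.top
            or other.top + other.height <= self.top
            or self.left + self.width <= other.left
            or other.left + other.width <= self.left
        )

    def shifted(self, drow: int, dcol: int) -> "ROI":
        return ROI(self.top + drow, self.left + dcol, self.height, self.width)


@dataclass(frozen=True)
class BandQuant:
    """Background-subtracted integrated density of one band."""

    idv: float
    roi: ROI
    background_mean_per_px: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.idv):
            raise ValueError("idv must be finite")


@dataclass(frozen=True)
class LaneNormalization:
    """A lane's target/loading quantifications and their ratio."""

    target: BandQuant
    loading: BandQuant
    ratio: float
    fold_change_vs_reference: float | None = None


def default_background_roi(band: ROI, image_shape: tuple[int, int]) -> ROI:
    """Place a same-size background region directly above the band (one
    ROI-height offset); falls back to below the band at the image top."""
    if band.top >= band.height:
        above = band.shifted(-band.height, 0)
        if above.inside(image_shape):
            return above
    below = band.shifted(band.height, 0)
    if below.inside(image_shape):
        return below
    raise ValueError("no room for a same-size background ROI above or below the band")


def integrated_density(
    image: Micrograph,
    band_roi: ROI,
    background_roi: ROI,
    invert: bool = True,
) -> BandQuant:
    """Background-subtracted integrated density of a band.

    ``idv = sum(band pixels) - mean(background pixels) * band area``, on
    film-inverted intensities by default (``invert=True``: signal is dark
    on the digitized film, so summation uses ``max_value - pixel``).

    The background ROI must have the same dimensions as the band ROI and be
    disjoint from it.  A negative IDV (noise pushing the band below its
    background) is allowed and reported as-is.
    """
    shape = image.shape
    for name, roi in (("band", band_roi), ("background", background_roi)):
        if not roi.inside(shape):
            raise ValueError(f"{name} ROI {roi} extends outside image of shape {shape}")
    if (band_roi.height, band_roi.width) != (background_roi.height, background_roi.width):
        raise ValueError(
            f"background ROI dimensions {(background_roi.height, background_roi.width)} "
            f"differ from band ROI dimensions {(band_roi.height, band_roi.width)}"
        )
    if band_roi.overlaps(background_roi):
        raise ValueError("background ROI must be disjoint from the band ROI")
    pix = image.as_float()
    if invert:
        pix = image.max_value - pix
    band_sum = float(pix[band_roi.slices].sum())
    bg_mean = float(pix[background_roi.slices].mean())
    idv = band_sum - bg_mean * band_roi.area
    return BandQuant(idv=idv, roi=band_roi, background_mean_per_px=bg_mean)


def enforce_uniform_roi(rois: list[ROI]) -> list[ROI]:
    """Check that all ROIs share identical height and width.

    The rule that makes IDVs comparable across bands and experiments.
    Returns the list unchanged; raises naming every offending index.
    """
    if not rois:
        raise ValueError("empty ROI list")
    ref = (rois[0].height, rois[0].width)
    bad = [i for i, r in enumerate(rois) if (r.height, r.width) != ref]
    if bad:
        raise ValueError(
            f"ROI dimension mismatch at indices {bad}: expected {ref[0]}x{ref[1]}"
        )
    return rois


def normalize_band(target: BandQuant, loading: BandQuant) -> float:
    """Ratio of a target band's IDV to its lane's loading-control IDV."""
    if loading.idv <= 0:
        raise ValueError(
            f"loading-control IDV must be > 0 to normalize, got {loading.idv}"
        )
    ratio = target.idv / loading.idv
    if target.idv < 0:
        logger.warning("negative target IDV %.3g propagates as negative ratio", target.idv)
    return ratio


def fold_change(ratios: dict[str, float], reference: str) -> dict[str, float]:
    """Normalize per-condition ratios to a reference condition (control -> 1)."""
    if reference not in ratios:
        raise ValueError(f"reference condition {reference!r} missing")
    ref = ratios[reference]
    if ref <= 0:
        raise ValueError(f"reference ratio must be > 0, got {ref}")
    return {k: v / ref for k, v in ratios.items()}
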