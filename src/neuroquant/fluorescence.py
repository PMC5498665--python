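"""Suprathreshold relative fluorescence intensity (RFI).

The relative fluorescence intensity of a marker in a picture is the
cumulative sum of the value of every pixel strictly above a pre-determined
threshold.  The marker channel's sum is normalized by the nucleus channel's
sum obtained the same way, which corrects for how many cells the field
contains; the ratio is the RFI reported per picture.

Two threshold policies exist: a fixed per-channel value supplied in
configuration (the reference mode — thresholds are decided once, before
quantification), or Otsu's between-class-variance cut as a fallback when no
value is supplied.  Comparing pictures across conditions presumes identical
acquisition settings per channel; the pipeline can only warn about this, it
cannot verify it from pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.filters import threshold_otsu

from .micrograph import Micrograph


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the suprathreshold cut is chosen for a channel."""

    mode: Literal["fixed", "otsu"] = "fixed"
    fixed_value: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "fixed" and self.fixed_value is None:
            raise ValueError("fixed mode requires fixed_value")
        if self.mode == "otsu" and self.fixed_value is not None:
            raise ValueError("otsu mode takes no fixed_value")


@dataclass(frozen=True)
class RFIResult:
    """Marker and nucleus suprathreshold sums and their ratio."""

    marker_sum: float
    nucleus_sum: float
    rfi: float
    marker_threshold: float
    nucleus_threshold: float

    def __post_init__(self) -> None:
        if self.marker_sum < 0 or self.nucleus_sum <= 0:
            raise ValueError("marker_sum must be >= 0 and nucleus_sum > 0")


def select_threshold(image: Micrograph, policy: ThresholdPolicy) -> float:
    """Resolve a policy to a concrete threshold for one image."""
    if policy.mode == "fixed":
        return float(policy.fixed_value)  # type: ignore[arg-type]
    pix = image.as_float()
    if np.ptp(pix) == 0:
        raise ValueError("constant image: Otsu threshold undefined (no separable classes)")
    return float(threshold_otsu(pix))


def suprathreshold_sum(image: Micrograph, threshold: float) -> float:
    """Cumulative sum of pixel values strictly greater than the threshold."""
    pix = image.as_float()
    return float(pix[pix > threshold].sum())


def rfi(marker: Micrograph, nucleus: Micrograph,
        policy: ThresholdPolicy,
        nucleus_policy: ThresholdPolicy | None = None) -> RFIResult:
    """Marker suprathreshold sum normalized by the nucleus channel's.

    Each channel is thresholded and summed independently; by default the
    same policy serves both channels, or a distinct nucleus policy may be
    given.  A nucleus channel with zero suprathreshold signal cannot
    normalize and is an error.
    """
    if marker.shape != nucleus.shape:
        raise ValueError(f"channel shapes differ: {marker.shape} vs {nucleus.shape}")
    m_thr = select_threshold(marker, policy)
    n_thr = select_threshold(nucleus, nucleus_policy if nucleus_policy is not None else policy)
    m_sum = suprathreshold_sum(marker, m_thr)
    n_sum = suprathreshold_sum(nucleus, n_thr)
    if n_sum <= 0:
        raise ValueError("zero nucleus suprathreshold signal: no normalizer")
    return RFIResult(marker_sum=m_sum, nucleus_sum=n_sum, rfi=m_sum / n_sum,
                     marker_threshold=m_thr, nucleus_threshold=n_thr)
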