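"""Color, size, brightness, and within-object contrast metrics.

All four metrics are restricted to the object mask (non-white pixels):

* ``color_contribution`` — per-channel share of total intensity over the
  object, so a ripe tomato scores high on red;
* ``object_size`` — fraction of the frame covered by the object;
* ``brightness`` — background level (255) minus mean object luminance;
  dark, salient objects on the white background score *high*;
* ``contrast`` — standard deviation of object luminance.

Color contribution is computed as proportion-of-sums (channel sum over
grand sum across channels).  The alternative — averaging per-pixel
proportions — is ill-conditioned for near-black pixels, where a 1-count
channel difference flips the proportion; proportion-of-sums is stable
and reduces to the same value on uniformly colored objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from stimchar.imageio_mask import ObjectMask


class EmptyMaskError(ValueError):
    """Raised when a metric that needs object pixels gets an empty mask."""


def _require_object(mask: ObjectMask) -> None:
    if mask.object_count == 0:
        raise EmptyMaskError("no object pixels: mask is empty")


def color_contribution(
    img: np.ndarray, mask: ObjectMask
) -> tuple[float, float, float]:
    """Proportional contribution of the red, green, and blue channels
    over the object pixels.

    Returns a triple summing to 1.  An all-black object carries no
    channel information; by symmetry it reports (1/3, 1/3, 1/3).
    """
    _require_object(mask)
    arr = np.asarray(img, dtype=np.float64)
    sums = arr[mask.flags].sum(axis=0)
    grand = sums.sum()
    if grand == 0.0:
        return (1 / 3, 1 / 3, 1 / 3)
    r, g, b = sums / grand
    return (float(r), float(g), float(b))


def object_size(mask: ObjectMask) -> float:
    """Proportion of non-white pixels relative to the total pixel count."""
    return mask.object_fraction


def brightness(gray: np.ndarray, mask: ObjectMask) -> float:
    """255 minus the mean object luminance.

    The sign convention makes very dark objects on the white background
    the *highest*-scoring (most salient) stimuli.
    """
    _require_object(mask)
    return float(255.0 - np.asarray(gray, dtype=np.float64)[mask.flags].mean())


def contrast(gray: np.ndarray, mask: ObjectMask, ddof: int = 0) -> float:
    """Standard deviation of luminance across object pixels.

    ``ddof=0`` (population SD) by default; pass ``ddof=1`` for the
    sample convention.  A perfectly uniform object scores exactly 0.
    """
    _require_object(mask)
    values = np.asarray(gray, dtype=np.float64)[mask.flags]
    if values.size <= ddof:
        raise EmptyMaskError(
            f"need more than {ddof} object pixels for SD with ddof={ddof}"
        )
    return float(values.std(ddof=ddof))


@dataclass(frozen=True)
class PhotometricResult:
    """The color/size/brightness/contrast metric vector for one image."""

    red_prop: float
    green_prop: float
    blue_prop: float
    size: float
    brightness: float
    contrast: float


def photometric_profile(
    img: np.ndarray, gray: np.ndarray, mask: ObjectMask, ddof: int = 0
) -> PhotometricResult:
    """Compute all four photometric metrics for one image at once."""
    r, g, b = color_contribution(img, mask)
    return PhotometricResult(
        red_prop=r,
        green_prop=g,
        blue_prop=b,
        size=object_size(mask),
        brightness=brightness(gray, mask),
        contrast=contrast(gray, mask, ddof=ddof),
    )
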