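"""Edge-based objective complexity and its size-normalized variant.

Visually complex stimuli — assortments, dishes with many components —
contain many object outlines.  Complexity is therefore the proportion
of Canny edge pixels in the frame.  Because a magnified copy of the
same object has a longer outline, a size-normalized variant divides the
edge proportion by the object-size proportion, i.e. edge pixels per
object pixel.

Canny thresholds here are *fractions of the gradient-magnitude range*
of the smoothed image, so parameter meaning does not depend on the
image's absolute intensity scale.  Note that neither variant is truly
scale-invariant for a magnified object: the outline grows linearly with
magnification while area grows quadratically, so the normalized measure
falls roughly as 1/side. This behavior is intentional (edge pixels per
object pixel) and documented rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny

from stimchar.imageio_mask import ObjectMask
from stimchar.photometrics import EmptyMaskError

DEFAULT_SIGMA = 1.0
DEFAULT_LOW = 0.1
DEFAULT_HIGH = 0.2


@dataclass(frozen=True)
class EdgeMap:
    """Boolean outline raster plus the detection parameters that built it."""

    flags: np.ndarray
    params: tuple[float, float, float]  # (gaussian_sigma, low, high)

    @property
    def height(self) -> int:
        return self.flags.shape[0]

    @property
    def width(self) -> int:
        return self.flags.shape[1]

    @property
    def edge_count(self) -> int:
        return int(self.flags.sum())


def detect_edges(
    gray: np.ndarray,
    gaussian_sigma: float = DEFAULT_SIGMA,
    low_threshold: float = DEFAULT_LOW,
    high_threshold: float = DEFAULT_HIGH,
) -> EdgeMap:
    """Canny edge detection with thresholds relative to gradient range.

    Pipeline: Gaussian smoothing at ``gaussian_sigma``, Sobel gradient
    magnitude, non-maximum suppression, hysteresis thresholding at
    ``low_threshold``/``high_threshold`` times the maximum gradient
    magnitude of the smoothed frame.  A constant frame has zero
    gradient everywhere and yields an empty edge map.
    """
    if gaussian_sigma <= 0:
        raise ValueError(f"gaussian_sigma must be > 0, got {gaussian_sigma}")
    if not (0 <= low_threshold < high_threshold <= 1):
        raise ValueError(
            "thresholds must satisfy 0 <= low < high <= 1, got "
            f"low={low_threshold}, high={high_threshold}"
        )
    arr = np.asarray(gray, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D gray array, got shape {arr.shape}")

    smoothed = ndi.gaussian_filter(arr, gaussian_sigma)
    gmag = np.hypot(
        ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1)
    )
    gmax = float(gmag.max())
    params = (float(gaussian_sigma), float(low_threshold), float(high_threshold))
    if gmax == 0.0:
        return EdgeMap(flags=np.zeros(arr.shape, dtype=bool), params=params)

    flags = canny(
        arr,
        sigma=gaussian_sigma,
        low_threshold=low_threshold * gmax,
        high_threshold=high_threshold * gmax,
    )
    return EdgeMap(flags=flags, params=params)


def complexity(edges: EdgeMap) -> float:
    """Proportion of outline pixels within the frame."""
    return edges.edge_count / edges.flags.size


def normalized_complexity(
    edges: EdgeMap, mask: ObjectMask, strict_literal: bool = False
) -> float:
    """Edge proportion scaled by object size: edge pixels per object pixel.

    ``strict_literal=True`` instead divides the edge *proportion* by the
    raw object pixel count, a frame-size-dependent quantity kept only
    for comparability with legacy scripts.
    """
    if mask.object_count == 0:
        raise EmptyMaskError(
            "normalized complexity undefined: no object pixels"
        )
    if strict_literal:
        return complexity(edges) / mask.object_count
    return edges.edge_count / mask.object_count
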