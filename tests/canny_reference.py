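"""Independent reference Canny edge detector used as a test oracle.

Deliberately built only from scipy.ndimage primitives — Gaussian
smoothing, Sobel gradients, sector-quantized non-maximum suppression,
and connected-component hysteresis — so it shares no code path with
the package's detector.  Thresholds are fractions of the maximum
gradient magnitude, matching the package's parameter convention.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def reference_canny(
    gray: np.ndarray,
    sigma: float = 1.0,
    low_frac: float = 0.1,
    high_frac: float = 0.2,
) -> np.ndarray:
    """Return a boolean edge map for a 2D gray array."""
    arr = np.asarray(gray, dtype=np.float64)
    smoothed = ndi.gaussian_filter(arr, sigma)
    gy = ndi.sobel(smoothed, axis=0)
    gx = ndi.sobel(smoothed, axis=1)
    mag = np.hypot(gx, gy)
    gmax = mag.max()
    if gmax == 0:
        return np.zeros(arr.shape, dtype=bool)

    # Quantize gradient direction into 4 sectors (0, 45, 90, 135 deg)
    # and keep only local maxima along the gradient direction.
    angle = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    sector = np.zeros(arr.shape, dtype=np.uint8)
    sector[(angle >= 22.5) & (angle < 67.5)] = 1
    sector[(angle >= 67.5) & (angle < 112.5)] = 2
    sector[(angle >= 112.5) & (angle < 157.5)] = 3

    padded = np.pad(mag, 1, mode="constant")
    offsets = {
        0: ((0, 1), (0, -1)),  # horizontal gradient -> compare left/right
        1: ((1, 1), (-1, -1)),  # diagonal
        2: ((1, 0), (-1, 0)),  # vertical gradient -> compare up/down
        3: ((1, -1), (-1, 1)),  # anti-diagonal
    }
    h, w = arr.shape
    yy, xx = np.mgrid[0:h, 0:w]
    keep = np.zeros(arr.shape, dtype=bool)
    for s, ((dy1, dx1), (dy2, dx2)) in offsets.items():
        here = sector == s
        n1 = padded[yy + 1 + dy1, xx + 1 + dx1]
        n2 = padded[yy + 1 + dy2, xx + 1 + dx2]
        # Strict on one side breaks the two-pixel plateau a smoothed
        # step edge produces, keeping outlines one pixel wide.
        keep |= here & (mag > n1) & (mag >= n2)
    nms = np.where(keep, mag, 0.0)

    strong = nms >= high_frac * gmax
    weak = nms >= low_frac * gmax
    labels, n_labels = ndi.label(weak, structure=np.ones((3, 3), dtype=int))
    if n_labels == 0:
        return strong
    has_strong = ndi.labeled_comprehension(
        strong, labels, np.arange(1, n_labels + 1), np.any, bool, False
    )
    good = np.zeros(n_labels + 1, dtype=bool)
    good[1:] = has_strong
    return weak & good[labels]
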