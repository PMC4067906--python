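"""Image loading, luminance conversion, and object-mask extraction.

Stimulus photographs in this domain are single objects (or small
arrangements) on a standardized near-white background.  Every downstream
metric — color contribution, size, brightness, within-object contrast,
normalized complexity — is defined over the set of *non-white* pixels,
so the mask built here is load-bearing and its threshold is recorded in
the mask itself for provenance.

Luminance uses the classic Rec. 601 weighting
``0.2989·R + 0.5870·G + 0.1140·B`` and is kept as fractional values on
the 0–255 scale: no integer quantization, so means and standard
deviations computed downstream are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

log = logging.getLogger(__name__)

#: Rec. 601 luma weights for (red, green, blue).
GRAY_WEIGHTS: tuple[float, float, float] = (0.2989, 0.5870, 0.1140)

#: A pixel is background ("white") iff every channel is >= this value.
#: 250 tolerates JPEG ringing near the background while keeping
#: near-white objects (whipped cream, eggs) in the object mask.
DEFAULT_WHITE_THRESHOLD: int = 250


class ImageLoadError(IOError):
    """Raised when a stimulus file cannot be read or decoded."""


@dataclass(frozen=True)
class ObjectMask:
    """Boolean raster marking non-white (object) pixels.

    Attributes
    ----------
    flags
        ``(height, width)`` boolean array; ``True`` = object pixel.
    white_threshold
        The channel threshold used to build the mask (recorded so runs
        are reproducible from their outputs alone).
    """

    flags: np.ndarray
    white_threshold: int

    @property
    def height(self) -> int:
        return self.flags.shape[0]

    @property
    def width(self) -> int:
        return self.flags.shape[1]

    @property
    def object_count(self) -> int:
        return int(self.flags.sum())

    @property
    def object_fraction(self) -> float:
        return self.object_count / self.flags.size


def load_image(path: str | Path) -> np.ndarray:
    """Load a stimulus image as an ``(H, W, 3)`` uint8 RGB array.

    Alpha channels are composited over pure white, matching the
    white-background convention of the stimulus sets this package
    targets.  Grayscale-only files are promoted to three identical
    channels with a logged warning.

    Raises
    ------
    ImageLoadError
        If the file does not exist or cannot be decoded.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode == "P":
                im = im.convert("RGBA" if "transparency" in im.info else "RGB")
            if im.mode in ("RGBA", "LA"):
                background = Image.new("RGBA", im.size, (255, 255, 255, 255))
                im = Image.alpha_composite(background, im.convert("RGBA"))
                im = im.convert("RGB")
            elif im.mode in ("L", "I", "I;16", "F", "1"):
                log.warning(
                    "%s is grayscale; promoting to 3 identical channels", path
                )
                im = im.convert("L").convert("RGB")
            elif im.mode != "RGB":
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except FileNotFoundError as exc:
        raise ImageLoadError(f"image file not found: {path}") from exc
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageLoadError(f"cannot decode image file: {path}") from exc
    return arr


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to luminance, keeping fractional values.

    Each output value is ``0.2989·R + 0.5870·G + 0.1140·B`` computed in
    float64 with no rounding.  Works for any channel scale (0–255 uint8
    or 0–1 floats); the conversion is linear.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB array, got shape {arr.shape}"
        )
    return arr @ np.asarray(GRAY_WEIGHTS, dtype=np.float64)


def compute_mask(
    img: np.ndarray, white_threshold: int = DEFAULT_WHITE_THRESHOLD
) -> ObjectMask:
    """Mark object pixels: a pixel is background iff *all* channels are
    at or above ``white_threshold``; the mask flags the complement.

    Raising the threshold can only grow the object set (monotonicity),
    since fewer pixels qualify as background.
    """
    if not 0 <= white_threshold <= 255:
        raise ValueError(
            f"white_threshold must be in [0, 255], got {white_threshold}"
        )
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB array, got shape {arr.shape}"
        )
    white = np.all(arr >= white_threshold, axis=-1)
    return ObjectMask(flags=~white, white_threshold=int(white_threshold))
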