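"""Average body-profile images for nest-sample diagnosis.

Lateral-view specimen photographs are standardized to a common scale and
position using the mesosoma (thorax) as the reference structure, converted
to black and white, and averaged pixel-wise.  The resulting mean-darkness
image summarizes subtle, individually noisy shape differences (e.g. the
height of the propodeal dome) that separate look-alike species at the
nest-sample level even when single specimens overlap.

Images are H×W float arrays with intensities in [0, 1], 0 = black.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio
from skimage import transform as sktransform

__all__ = [
    "load_gray",
    "save_gray",
    "standardize_image",
    "binarize",
    "average_profile",
]

#: luminance weights for color → gray conversion
LUMA = np.array([0.299, 0.587, 0.114])


class ImageError(ValueError):
    """Invalid image input."""


def _validate(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ImageError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ImageError("intensities must lie in [0, 1]")
    return np.clip(img, 0.0, 1.0)


def load_gray(path) -> np.ndarray:
    """Read PNG/PGM as a [0,1] grayscale matrix (luminance for color)."""
    arr = iio.imread(str(path)).astype(float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ LUMA
    if arr.max() > 1.0:
        arr = arr / 255.0
    return _validate(arr)


def save_gray(img: np.ndarray, path) -> None:
    img = _validate(img)
    iio.imwrite(str(path), (np.round(img * 255)).astype(np.uint8))


def standardize_image(
    img: np.ndarray,
    anchor: tuple,
    mesosoma_length_px: float,
    target_length_px: float,
    target_size: tuple,
    canonical_anchor: tuple | None = None,
) -> np.ndarray:
    """Rescale and translate a lateral-view image to the canonical frame.

    The image is scaled by ``target_length_px / mesosoma_length_px`` (so
    every specimen's mesosoma spans the same number of pixels) and the
    ``anchor`` landmark — by convention the anterior-most point of the
    pronotum — is mapped to ``canonical_anchor`` (default: mid-height,
    one quarter from the left of the target canvas).  Bilinear resampling;
    regions outside the source fill white (1.0).
    """
    img = _validate(img)
    if mesosoma_length_px <= 0 or target_length_px <= 0:
        raise ImageError("mesosoma and target lengths must be > 0")
    r, c = anchor
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ImageError(f"anchor {anchor} outside image of shape {img.shape}")
    H, W = target_size
    if canonical_anchor is None:
        canonical_anchor = (H / 2.0, W / 4.0)
    s = target_length_px / mesosoma_length_px
    # skimage transforms use (x, y) = (col, row)
    tform = sktransform.AffineTransform(scale=(s, s))
    shift = np.array([canonical_anchor[1], canonical_anchor[0]]) - tform([[c, r]])[0]
    tform = sktransform.AffineTransform(scale=(s, s), translation=shift)
    out = sktransform.warp(
        img, tform.inverse, output_shape=(H, W), order=1, mode="constant", cval=1.0
    )
    return np.clip(out, 0.0, 1.0)


def binarize(img: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Black-and-white conversion: pixel < threshold → 0, else 1. Idempotent."""
    img = _validate(img)
    if not 0.0 < threshold < 1.0:
        raise ImageError("threshold must be in (0, 1)")
    return np.where(img < threshold, 0.0, 1.0)


def average_profile(images) -> np.ndarray:
    """Pixel-wise mean darkness over standardized images of equal shape."""
    images = [np.asarray(im, dtype=float) for im in images]
    if not images:
        raise ImageError("need at least one image")
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ImageError(f"dimension mismatch among images: {sorted(shapes)}")
    return np.mean(np.stack([_validate(im) for im in images]), axis=0)
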