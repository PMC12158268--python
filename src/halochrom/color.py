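"""Color-space feature extraction for film images.

Every stage of the pipeline works on a 12-channel feature vector drawn from
four color spaces: RGB, CIELAB (D65), HSV, and YCbCr (BT.601 analog form).
Channel scales: R, G, B, H, S, V, Y, Cb, Cr in [0, 1]; L in [0, 100];
a, b in [-128, 127]. Hue is stored as a fraction of the hue circle (not
degrees) so that slope thresholds are comparable across channels; the hue of
achromatic pixels is defined as 0. Cb and Cr are offset so that neutral
gray sits at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import color as skcolor

# sRGB (linear-light) -> XYZ, IEC 61966-2-1. The D65 reference white is taken
# as M @ [1, 1, 1] so that the neutral axis maps to a = b = 0 exactly.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_WHITE = _SRGB_TO_XYZ @ np.ones(3)


def _srgb_to_lab(rgb: np.ndarray) -> tuple[float, float, float]:
    linear = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    xyz = _SRGB_TO_XYZ @ linear
    ratio = xyz / _WHITE
    eps, kappa = (6 / 29) ** 3, (29 / 3) ** 3 / 100  # CIE standard constants
    f = np.where(ratio > eps, np.cbrt(ratio), (kappa * ratio + 16) / 116)
    L = 116 * f[1] - 16
    a = 500 * (f[0] - f[1])
    b = 200 * (f[1] - f[2])
    return float(L), float(a), float(b)

#: Canonical channel order used everywhere (CSV columns, tie-breaking, ...).
CHANNELS: tuple[str, ...] = ("R", "G", "B", "L", "a", "b", "H", "S", "V", "Y", "Cb", "Cr")

#: (low, high) bounds per channel, used for clipping noisy synthetic data.
CHANNEL_BOUNDS: dict[str, tuple[float, float]] = {
    **{c: (0.0, 1.0) for c in ("R", "G", "B", "H", "S", "V", "Y", "Cb", "Cr")},
    "L": (0.0, 100.0),
    "a": (-128.0, 127.0),
    "b": (-128.0, 127.0),
}


@dataclass
class FilmImage:
    """An RGB raster of a sensor film plus a binary foreground mask.

    ``pixels`` is an H x W x 3 float array with channel range [0, 1];
    ``mask`` is an H x W boolean array marking film (foreground) pixels.
    """

    pixels: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape must match pixels H x W")


def convert_color_spaces(rgb) -> dict[str, float]:
    """Convert one sRGB triple in [0, 1] to the 12-channel feature vector.

    Lab uses the D65 reference white (linearizing the sRGB gamma first);
    HSV and YCbCr are computed on the gamma-encoded values, the common
    imaging convention. YCbCr is the BT.601 analog form
    ``Y = 0.299 R + 0.587 G + 0.114 B``, ``Cb = (B - Y)/1.772 + 0.5``,
    ``Cr = (R - Y)/1.402 + 0.5``, so neutral gray maps to Cb = Cr = 0.5.

    Raises ``ValueError`` if any component lies outside [0, 1].
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape != (3,):
        raise ValueError("rgb must be a length-3 sequence")
    if not np.all(np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"rgb components must lie in [0, 1], got {arr.tolist()}")
    r, g, b = arr
    L, a, bb = _srgb_to_lab(arr)
    h, s, v = skcolor.rgb2hsv(arr.reshape(1, 1, 3))[0, 0]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = (b - y) / 1.772 + 0.5
    cr = (r - y) / 1.402 + 0.5
    return {
        "R": float(r),
        "G": float(g),
        "B": float(b),
        "L": float(L),
        "a": float(a),
        "b": float(bb),
        "H": float(h),
        "S": float(s),
        "V": float(v),
        "Y": float(y),
        "Cb": float(cb),
        "Cr": float(cr),
    }


def extract_masked_means(image: FilmImage) -> dict[str, float]:
    """Mean foreground RGB of ``image``, converted to the 12-channel vector.

    Averaging happens in RGB space before conversion, which sidesteps the
    hue-wraparound problem of averaging angular channels directly.

    Raises ``ValueError`` when the mask selects no pixels.
    """
    if not image.mask.any():
        raise ValueError("mask selects no foreground pixels (empty region of interest)")
    mean_rgb = image.pixels[image.mask].mean(axis=0)
    return convert_color_spaces(np.clip(mean_rgb, 0.0, 1.0))


def build_time_series(images: list[FilmImage], frame_rate: float = 1.0) -> pd.DataFrame:
    """Stack per-frame feature vectors into a color time series.

    Returns a DataFrame with columns ``frame`` (1-based), ``t_s``
    (``t = index / frame_rate`` seconds) and the 12 channels in canonical
    order — the same schema the synthetic generator writes.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 frames to build a time series")
    shape = images[0].pixels.shape
    for i, img in enumerate(images):
        if img.pixels.shape != shape:
            raise ValueError(f"frame {i} shape {img.pixels.shape} != frame 0 shape {shape}")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    rows = [extract_masked_means(img) for img in images]
    df = pd.DataFrame(rows, columns=list(CHANNELS))
    df.insert(0, "t_s", np.arange(len(images)) / frame_rate)
    df.insert(0, "frame", np.arange(1, len(images) + 1))
    return df


def read_film_image(image_path, mask_path) -> FilmImage:
    """Load an 8-bit RGB PNG and its {0, 255} single-channel mask PNG."""
    from skimage import io as skio

    pixels = skio.imread(image_path)
    if pixels.ndim != 3:
        raise ValueError("image must be RGB")
    mask = skio.imread(mask_path)
    if mask.ndim == 3:
        mask = mask[..., 0]
    return FilmImage(pixels[..., :3] / 255.0, mask > 127)


def write_film_image(image: FilmImage, image_path, mask_path) -> None:
    """Write an image as 8-bit RGB PNG and its mask as {0, 255} PNG."""
    from skimage import io as skio

    skio.imsave(image_path, (np.clip(image.pixels, 0, 1) * 255).round().astype(np.uint8))
    skio.imsave(mask_path, np.where(image.mask, 255, 0).astype(np.uint8))
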