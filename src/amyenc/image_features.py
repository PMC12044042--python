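"""Low-level visual covariates: channel medians and Fourier-band power.

The amygdala is sensitive to low spatial-frequency content, and standard
affective image sets vary systematically in color; these five covariates
(median red/green/blue and spectral power in a low and a high radial
frequency band) are therefore carried as nuisance predictors through the
validation and selectivity regressions.

Conventions (configurable): images are resized to a fixed 128 x 128
working size before the transform so band radii are comparable across
inputs; luminance is the (0.299, 0.587, 0.114) RGB weighting; the DC
component is removed by mean subtraction; band powers are sums of
``|FFT|^2 / N^2`` over bins whose Euclidean radius from the centered
zero-frequency bin is below ``low_radius`` (exclusive of DC) or above
``high_radius``.  With that normalization the total power over all bins
equals the pixel-count-normalized sum of squared mean-subtracted luminance
(Parseval).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])
DEFAULT_WORKING_SIZE = 128
FEATURE_COLUMNS = ["median_r", "median_g", "median_b", "power_low", "power_high"]


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    return image


def color_medians(image: np.ndarray) -> tuple[float, float, float]:
    """Per-channel median intensity (midpoint convention for even counts)."""
    image = _validate_rgb(image)
    med = np.median(image.reshape(-1, 3), axis=0)
    return float(med[0]), float(med[1]), float(med[2])


def luminance(image: np.ndarray) -> np.ndarray:
    """Weighted-RGB luminance channel."""
    return _validate_rgb(image) @ LUMA_WEIGHTS


def _resize_gray(gray: np.ndarray, size: int) -> np.ndarray:
    from PIL import Image

    im = Image.fromarray(gray.astype(np.float32), mode="F")
    return np.asarray(im.resize((size, size), Image.BILINEAR), dtype=float)


def spectral_band_power(
    image: np.ndarray,
    low_radius: float = 6.0,
    high_radius: float = 24.0,
    working_size: int | None = DEFAULT_WORKING_SIZE,
) -> tuple[float, float]:
    """Spectral power in the low and high radial-frequency bands.

    ``image`` may be RGB (converted to luminance) or already single
    channel.  Bins with ``low_radius <= radius <= high_radius`` belong to
    neither band; the DC bin belongs to neither (and carries no power after
    mean subtraction).

    Parameters
    ----------
    low_radius, high_radius
        Band boundaries in frequency-bin units of the centered spectrum:
        low band is ``0 < radius < low_radius``, high band is
        ``radius > high_radius``.
    working_size
        Square size the image is resized to before the transform; ``None``
        keeps the native size (the image must then be square enough to
        contain the bands).
    """
    image = np.asarray(image, dtype=float)
    gray = luminance(image) if image.ndim == 3 else image
    if not np.all(np.isfinite(gray)):
        raise ValueError("image contains non-finite pixels")
    if gray.ndim != 2:
        raise ValueError("expected a 2-D luminance channel")
    if working_size is not None and gray.shape != (working_size, working_size):
        gray = _resize_gray(gray, working_size)
    h, w = gray.shape
    n = h * w
    x = gray - gray.mean()
    spec = np.fft.fftshift(np.fft.fft2(x))
    power = (spec.real**2 + spec.imag**2) / (n * n)
    fy = np.arange(h) - h // 2
    fx = np.arange(w) - w // 2
    radius = np.hypot(fy[:, None], fx[None, :])
    low = float(power[(radius > 0) & (radius < low_radius)].sum())
    high = float(power[radius > high_radius].sum())
    return low, high


def image_features(
    image: np.ndarray,
    low_radius: float = 6.0,
    high_radius: float = 24.0,
    working_size: int | None = DEFAULT_WORKING_SIZE,
) -> dict[str, float]:
    """All five low-level covariates of one RGB image."""
    mr, mg, mb = color_medians(image)
    pl, ph = spectral_band_power(
        image, low_radius=low_radius, high_radius=high_radius, working_size=working_size
    )
    return {
        "median_r": mr,
        "median_g": mg,
        "median_b": mb,
        "power_low": pl,
        "power_high": ph,
    }


def image_feature_table(
    images,
    image_ids=None,
    working_size: int | None = DEFAULT_WORKING_SIZE,
    low_radius: float = 6.0,
    high_radius: float = 24.0,
) -> pd.DataFrame:
    """Feature table for a stack (or iterable) of RGB images.

    Columns: image_id, median_r, median_g, median_b, power_low, power_high.
    """
    rows = []
    for i, img in enumerate(images):
        feats = image_features(
            img, low_radius=low_radius, high_radius=high_radius, working_size=working_size
        )
        feats["image_id"] = image_ids[i] if image_ids is not None else i
        rows.append(feats)
    return pd.DataFrame(rows)[["image_id"] + FEATURE_COLUMNS]


def read_image(path) -> np.ndarray:
    """Read an image file into a float RGB array in [0, 1]."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return arr
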