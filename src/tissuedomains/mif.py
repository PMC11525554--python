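"""Preprocessing for multiplex immunofluorescence slides.

The per-slide chain is: unit scaling -> block downsampling -> tissue-mask
generation -> per-channel log-mean normalization -> Gaussian smoothing.
Masking gates only sampling and assignment; normalization statistics are
computed over the whole (downsampled) image.

Normalization is ``y = log10(x / mu + 1)`` with ``mu`` the mean of the
strictly positive pixels of that channel on that slide. Because ``mu``
scales with any multiplicative channel gain, the normalized image is
invariant to per-slide, per-channel gains -- the property that makes
domains comparable across slides without explicit batch correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.cluster import KMeans

from .datatypes import MultiplexImage, TissueMask

__all__ = [
    "MifPreprocessConfig",
    "ChannelNormStats",
    "DegenerateMaskError",
    "scale_to_unit",
    "block_downsample",
    "log_mean_normalize",
    "gaussian_smooth",
    "create_tissue_mask",
    "preprocess_mif_slide",
]

_GAUSS_TRUNCATE = 4.0  # kernel support in sigmas; reflect boundary


class DegenerateMaskError(ValueError):
    """Raised when an image has no 2-cluster foreground/background structure."""


@dataclass
class MifPreprocessConfig:
    """Settings for the mIF preprocessing chain.

    downsample_factor
        Side length of the averaging block (1 = native resolution). Whole-
        slide scans typically use 8-32; small fixtures use 1-2.
    sigma
        Gaussian smoothing SD in downsampled pixels (0 disables smoothing).
    scale_8bit
        Divide integer input by 255 on ingest.
    """

    downsample_factor: int = 1
    sigma: float = 2.0
    scale_8bit: bool = True

    def __post_init__(self) -> None:
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class ChannelNormStats:
    """Per-slide normalization statistics: mean of non-zero pixels per channel.

    ``mu`` is NaN for channels with no positive pixel; those channel indices
    are listed in ``zero_channels`` and pass through normalization unchanged.
    """

    mu: np.ndarray
    slide_id: str = "slide"
    zero_channels: list[int] = field(default_factory=list)


def scale_to_unit(image: MultiplexImage) -> MultiplexImage:
    """Scale 8-bit intensities to [0, 1]; float input passes through."""
    px = image.pixels
    if np.issubdtype(px.dtype, np.integer):
        if px.min() < 0 or px.max() > 255:
            raise ValueError("integer input must be in [0, 255]")
        return image.with_pixels(px.astype(float) / 255.0)
    if px.min() < 0:
        raise ValueError("negative intensities")
    return image.with_pixels(px.astype(float))


def block_downsample(image: MultiplexImage, factor: int) -> MultiplexImage:
    """Average ``factor x factor`` blocks per channel.

    Output shape is ``(ceil(H/factor), ceil(W/factor))``; edge blocks average
    only the pixels they cover. Pixel size is multiplied by ``factor``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return image.with_pixels(image.pixels.copy())
    h, w, _ = image.pixels.shape
    if factor > h and factor > w:
        raise ValueError(f"factor {factor} exceeds both image dimensions {h}x{w}")
    row_idx = np.arange(0, h, factor)
    col_idx = np.arange(0, w, factor)
    sums = np.add.reduceat(np.add.reduceat(image.pixels, row_idx, axis=0),
                           col_idx, axis=1)
    row_cnt = np.diff(np.append(row_idx, h))
    col_cnt = np.diff(np.append(col_idx, w))
    counts = np.outer(row_cnt, col_cnt)[:, :, None].astype(float)
    return image.with_pixels(sums / counts,
                             resolution=image.resolution_um_per_px * factor)


def log_mean_normalize(image: MultiplexImage
                       ) -> tuple[MultiplexImage, ChannelNormStats]:
    """Per-channel log normalization ``y = log10(x / mu + 1)``.

    ``mu`` is the mean over the channel's strictly positive pixels, so sparse
    channels are not dragged down by empty background. Zero pixels map to
    zero; all-zero channels pass through unchanged and are flagged.

    The ratio is evaluated as ``(x * n) / s`` with ``n`` the positive-pixel
    count and ``s`` their sum (a single rounding), so a channel gain that
    scales pixel values and sums exactly leaves the output bit-identical.
    """
    px = image.pixels
    if px.min() < 0:
        raise ValueError("negative intensities")
    out = np.empty_like(px, dtype=float)
    c = px.shape[2]
    mu = np.full(c, np.nan)
    zero_channels: list[int] = []
    for j in range(c):
        chan = px[:, :, j]
        pos = chan > 0
        n = int(pos.sum())
        if n == 0:
            zero_channels.append(j)
            out[:, :, j] = chan
            continue
        s = chan[pos].sum()
        mu[j] = s / n
        out[:, :, j] = np.log10((chan * n) / s + 1.0)
    if zero_channels:
        warnings.warn(f"channels {zero_channels} are all zero on slide "
                      f"'{image.slide_id}'; passed through unnormalized",
                      stacklevel=2)
    stats = ChannelNormStats(mu=mu, slide_id=image.slide_id,
                             zero_channels=zero_channels)
    return image.with_pixels(out), stats


def gaussian_smooth(image: MultiplexImage, sigma: float) -> MultiplexImage:
    """2-D Gaussian smoothing per channel (truncated at 4 sigma, reflect
    boundary). ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image.with_pixels(image.pixels.copy())
    out = np.empty_like(image.pixels, dtype=float)
    for j in range(image.pixels.shape[2]):
        out[:, :, j] = gaussian_filter(image.pixels[:, :, j], sigma=sigma,
                                       mode="reflect", truncate=_GAUSS_TRUNCATE)
    return image.with_pixels(out)


def create_tissue_mask(image: MultiplexImage, config: MifPreprocessConfig
                       ) -> TissueMask:
    """Separate tissue foreground from slide background by 2-means.

    The image (already unit-scaled and downsampled) is log-mean normalized
    and Gaussian smoothed on its own, then every pixel's C-vector is
    clustered into two groups. The two cluster centers are Z-normalized
    across centers per channel; the center whose channel-mean Z-score is
    <= 0 (the dimmer one) is background.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero channels handled below
        normed, stats = log_mean_normalize(image)
    smoothed = gaussian_smooth(normed, config.sigma)
    keep = [j for j in range(image.n_channels) if j not in stats.zero_channels]
    if not keep:
        raise DegenerateMaskError("all channels are zero; no tissue structure")
    feats = smoothed.pixels[:, :, keep].reshape(-1, len(keep))
    if np.allclose(feats.std(axis=0), 0):
        raise DegenerateMaskError("zero variance in all channels; no "
                                  "foreground/background structure")
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(feats)
    centers = km.cluster_centers_
    sd = centers.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (centers - centers.mean(axis=0)) / sd
    center_means = z.mean(axis=1)
    # with 2 Z-normalized centers the means are +/-m; ties resolve to the
    # lower raw-mean center as background
    if center_means[0] == center_means[1]:
        background = int(np.argmin(centers.mean(axis=1)))
    else:
        background = int(np.argmin(center_means))
    mask = (km.labels_ != background).reshape(image.pixels.shape[:2])
    return TissueMask(mask=mask, slide_id=image.slide_id)


def preprocess_mif_slide(image: MultiplexImage, config: MifPreprocessConfig
                         ) -> tuple[MultiplexImage, TissueMask, ChannelNormStats]:
    """Run the full per-slide chain; returns (features, mask, norm stats).

    The returned image holds the normalized, smoothed feature planes at
    downsampled resolution; the mask indexes the same grid.
    """
    if config.scale_8bit or np.issubdtype(image.pixels.dtype, np.integer):
        image = scale_to_unit(image)
    image = block_downsample(image, config.downsample_factor)
    mask = create_tissue_mask(image, config)
    normed, stats = log_mean_normalize(image)
    smoothed = gaussian_smooth(normed, config.sigma)
    return smoothed, mask, stats
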