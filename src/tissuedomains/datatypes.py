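"""Shared data containers for the tissue-domain pipeline.

All containers are lightweight dataclasses around numpy arrays. Images are
indexed ``(row, col)`` from the top-left, 0-based. Spot array coordinates
follow the Visium convention: a position ``(array_row, array_col)`` is valid
when ``array_row + array_col`` is even, giving the hexagonal lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiplexImage",
    "SpotDataset",
    "TissueMask",
    "SyntheticTruth",
]


@dataclass
class MultiplexImage:
    """A single multichannel fluorescence slide.

    Parameters
    ----------
    pixels
        ``H x W x C`` float array of intensities. Unit-scaled data lives in
        ``[0, 1]``; normalized data may exceed 1 but is always finite and
        non-negative on input.
    channels
        Ordered channel (marker) names, one per plane.
    resolution_um_per_px
        Isotropic pixel size in micrometres.
    slide_id
        Identifier of the specimen/slide the image came from.
    """

    pixels: np.ndarray
    channels: list[str]
    resolution_um_per_px: float = 1.0
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be H x W x C, got shape {self.pixels.shape}")
        self.channels = list(self.channels)
        h, w, c = self.pixels.shape
        if min(h, w, c) < 1:
            raise ValueError("image dimensions must all be >= 1")
        if len(self.channels) != c:
            raise ValueError(
                f"{len(self.channels)} channel names for {c} image planes"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")
        if np.issubdtype(self.pixels.dtype, np.floating):
            if not np.all(np.isfinite(self.pixels)):
                raise ValueError("pixel intensities must be finite")
            if self.pixels.min() < 0:
                raise ValueError("pixel intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def with_pixels(self, pixels: np.ndarray, *, resolution: float | None = None
                    ) -> "MultiplexImage":
        """Copy of this image with new pixel data (and optionally resolution)."""
        return MultiplexImage(
            pixels=pixels,
            channels=list(self.channels),
            resolution_um_per_px=self.resolution_um_per_px if resolution is None else resolution,
            slide_id=self.slide_id,
        )


@dataclass
class SpotDataset:
    """Spatial transcriptomics spots of one slide on a hexagonal lattice.

    ``matrix`` is ``S x G`` (spots by genes) with raw counts or continuous
    expression; ``array_row``/``array_col`` are the integer lattice
    coordinates of each spot.
    """

    matrix: np.ndarray
    spot_ids: list[str]
    array_row: np.ndarray
    array_col: np.ndarray
    slide_id: str = "slide"
    batch: str = "batch0"
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (spots x genes)")
        s, g = self.matrix.shape
        if s < 1 or g < 1:
            raise ValueError("matrix must have at least one spot and one gene")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix entries must be finite")
        self.spot_ids = [str(x) for x in self.spot_ids]
        if len(self.spot_ids) != s:
            raise ValueError("spot_ids length must match matrix rows")
        if len(set(self.spot_ids)) != s:
            raise ValueError("spot_ids must be unique")
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        if self.array_row.shape != (s,) or self.array_col.shape != (s,):
            raise ValueError("array_row/array_col must have one entry per spot")
        coords = set(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(coords) != s:
            raise ValueError("duplicate (array_row, array_col) positions within slide")
        if self.gene_names is not None:
            self.gene_names = [str(x) for x in self.gene_names]
            if len(self.gene_names) != g:
                raise ValueError("gene_names length must match matrix columns")

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]


@dataclass
class TissueMask:
    """Boolean foreground map for one slide (True = tissue)."""

    mask: np.ndarray
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic slide.

    ``labels`` holds the planted domain id per pixel (``H x W``, background
    ``-1``) or per spot (length ``S``); ``profiles`` is the ``K x C`` (or
    ``K x G``) mean signal of each domain before slide gain and noise.
    """

    labels: np.ndarray
    profiles: np.ndarray
    gains: np.ndarray
    noise_sd: float
    seed: int
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.profiles = np.asarray(self.profiles, dtype=float)
        self.gains = np.asarray(self.gains, dtype=float)
        k = self.profiles.shape[0]
        if self.labels.max() >= k:
            raise ValueError("labels contain a domain id >= number of profiles")
        if np.any(self.gains <= 0):
            raise ValueError("gains must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def k_true(self) -> int:
        return self.profiles.shape[0]
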