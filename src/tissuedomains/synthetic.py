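"""Synthetic multi-slide fixtures with planted tissue domains.

The generators emulate the structure the pipeline is built to handle:

* mIF — per slide, a rectangular tissue region surrounded by a zero
  background ring, partitioned into ``k_true`` spatially contiguous domains
  by a seeded Voronoi tessellation. Each domain has a distinct per-channel
  intensity profile; each slide applies a per-channel multiplicative gain
  (the batch effect that per-slide normalization must remove) and additive
  Gaussian noise. Final intensities are clipped to ``>= 0`` and quantized to
  a 12-bit grid, emulating the fixed bit depth of scanner output.
* ST — per slide, spots on a full Visium-style hex lattice, partitioned
  into ``k_true`` contiguous domains, each expressing a distinct gene
  program; counts are Poisson with a per-slide library-size scaling.

Everything is deterministic given ``seed``; truths carry the planted labels
and profiles for evaluation. Default parameter values are the fixture's
study conditions (3 slides, 128 x 128 pixels, 4 domains, noise well below
the profile separation) and are documented in the methods note.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import MultiplexImage, SpotDataset, SyntheticTruth

__all__ = [
    "generate_synthetic_mif",
    "generate_synthetic_st",
    "default_mif_profiles",
    "default_st_programs",
]

# 12-bit intensity grid: values are exact multiples of 2**-12, so slide gains
# such as 0.5, 2 or 10 scale every pixel (and every block sum) exactly in
# float64 -- the substrate of the bitwise gain-invariance guarantee.
_QUANT = 4096.0

# per-slide gain cycle emulating slide-to-slide staining/exposure variation
_GAIN_CYCLE = (1.0, 1.625, 0.6875)
_BATCH_CYCLE = (1.0, 1.5, 0.7)


def default_mif_profiles(k: int, n_channels: int | None = None) -> np.ndarray:
    """K x C dyadic intensity profiles over a bright ubiquitous baseline.

    Channel 0 mimics a nuclear stain present in all tissue but at a
    domain-dependent density; each domain additionally has one dominant
    marker channel. The baseline (3/16) keeps every tissue pixel well above
    the zero background in every channel, as ubiquitous matrix /
    autofluorescence signal does in real panels, so foreground/background
    masking has true 2-cluster structure.
    """
    c = n_channels if n_channels is not None else k + 1
    if c < 1:
        raise ValueError("need at least one channel")
    profiles = np.full((k, c), 3.0 / 16.0)
    # nuclear-like channel: bright everywhere, density varies by domain
    nuclear_levels = [8, 4, 12, 6, 10, 3, 13, 5]
    for d in range(k):
        profiles[d, 0] = nuclear_levels[d % len(nuclear_levels)] / 16.0
        if c > 1:
            profiles[d, 1 + d % (c - 1)] = 13.0 / 16.0
    return profiles


def default_st_programs(k: int, n_genes: int = 40, markers_per_domain: int = 8
                        ) -> np.ndarray:
    """K x G gene programs: uniform baseline with a block of marker genes
    upregulated 8-fold in each domain."""
    programs = np.ones((k, n_genes))
    for d in range(k):
        lo = (d * markers_per_domain) % n_genes
        hi = min(lo + markers_per_domain, n_genes)
        programs[d, lo:hi] = 8.0
    return programs


def _check_distinct_rows(arr: np.ndarray, what: str) -> None:
    for i in range(arr.shape[0]):
        for j in range(i + 1, arr.shape[0]):
            if np.array_equal(arr[i], arr[j]):
                raise ValueError(f"{what} rows {i} and {j} are identical")


def generate_synthetic_mif(
    n_slides: int = 3,
    shape: tuple[int, int] = (128, 128),
    k_true: int = 4,
    profiles: np.ndarray | None = None,
    gains: np.ndarray | None = None,
    noise_sd: float = 0.025,
    seed: int = 0,
    *,
    margin: int = 10,
    n_sites: int | None = None,
    quantize: bool = True,
) -> tuple[list[MultiplexImage], list[SyntheticTruth]]:
    """Generate multi-slide mIF images with planted Voronoi tissue domains.

    Parameters
    ----------
    n_slides, shape, k_true
        Number of slides, image shape ``(H, W)``, number of planted domains.
    profiles
        ``K x C`` per-domain mean intensities; defaults to
        :func:`default_mif_profiles`.
    gains
        ``n_slides x C`` multiplicative slide gains; defaults to a fixed
        per-slide cycle applied uniformly across channels.
    noise_sd
        SD of additive Gaussian pixel noise (before gain), in intensity units.
    margin
        Width of the zero background ring around the tissue rectangle.
    n_sites
        Voronoi sites per slide (``>= k_true``); default ``k_true + 2``.
    quantize
        Snap intensities to the 12-bit grid (default). Disable only for
        continuous-valued experiments.

    Returns
    -------
    (images, truths)
        One :class:`MultiplexImage` and one :class:`SyntheticTruth` per slide.
    """
    h, w = shape
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if profiles is None:
        profiles = default_mif_profiles(k_true)
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] != k_true:
        raise ValueError("profiles must have k_true rows")
    _check_distinct_rows(profiles, "profile")
    n_channels = profiles.shape[1]
    if n_sites is None:
        n_sites = k_true + 2
    if n_sites < k_true:
        raise ValueError(f"k_true={k_true} exceeds number of Voronoi sites {n_sites}")
    if gains is None:
        gains = np.array([[_GAIN_CYCLE[s % len(_GAIN_CYCLE)]] * n_channels
                          for s in range(n_slides)])
    gains = np.asarray(gains, dtype=float)
    if np.any(gains <= 0):
        raise ValueError("gains must be positive")
    if 2 * margin >= min(h, w):
        raise ValueError("margin leaves no tissue foreground")

    rng = np.random.default_rng(seed)
    channels = [f"marker{c}" for c in range(n_channels)]
    images, truths = [], []
    rr, cc = np.mgrid[0:h, 0:w]
    for s in range(n_slides):
        fg = np.zeros((h, w), dtype=bool)
        fg[margin:h - margin, margin:w - margin] = True
        sites = np.column_stack([
            rng.uniform(margin, h - margin, size=n_sites),
            rng.uniform(margin, w - margin, size=n_sites),
        ])
        # a few Lloyd relaxation steps toward a centroidal tessellation keep
        # the planted domains organic but comparably sized
        pts = np.column_stack([rr[fg], cc[fg]]).astype(float)
        for _ in range(3):
            cell = np.argmin(((pts[:, None, :] - sites[None, :, :]) ** 2).sum(2), axis=1)
            for i in range(n_sites):
                if np.any(cell == i):
                    sites[i] = pts[cell == i].mean(axis=0)
        site_domain = np.concatenate(
            [np.arange(k_true), rng.integers(0, k_true, size=n_sites - k_true)]
        )
        d2 = ((rr[:, :, None] - sites[:, 0]) ** 2
              + (cc[:, :, None] - sites[:, 1]) ** 2)
        labels = site_domain[np.argmin(d2, axis=2)]
        labels = np.where(fg, labels, -1)

        pixels = np.zeros((h, w, n_channels))
        noise = rng.normal(0.0, noise_sd, size=(h, w, n_channels)) if noise_sd > 0 else 0.0
        vals = gains[s] * profiles[np.clip(labels, 0, None)] + noise
        pixels = np.where(fg[:, :, None], np.clip(vals, 0.0, None), 0.0)
        if quantize:
            pixels = np.round(pixels * _QUANT) / _QUANT
        slide_id = f"mif_slide{s}"
        images.append(MultiplexImage(pixels=pixels, channels=channels,
                                     resolution_um_per_px=1.0, slide_id=slide_id))
        truths.append(SyntheticTruth(labels=labels, profiles=profiles,
                                     gains=gains[s], noise_sd=noise_sd,
                                     seed=seed, slide_id=slide_id))
    return images, truths


def _hex_xy(array_row: np.ndarray, array_col: np.ndarray) -> np.ndarray:
    """Physical xy positions of Visium array coordinates (unit spot pitch)."""
    x = array_col * 0.5
    y = array_row * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x, y])


def generate_synthetic_st(
    n_slides: int = 3,
    lattice: tuple[int, int] = (40, 40),
    k_true: int = 4,
    programs: np.ndarray | None = None,
    library_size: float = 1000.0,
    seed: int = 0,
    *,
    batch_scale: np.ndarray | None = None,
) -> tuple[list[SpotDataset], list[SyntheticTruth]]:
    """Generate multi-slide hex-lattice ST data with planted domains.

    Spots occupy every valid Visium position (``array_row + array_col`` even)
    of a ``rows x cols`` lattice. Domain labels come from a seeded Voronoi
    partition in physical hex coordinates, so domains are contiguous blocks.
    Counts for spot i, gene g are Poisson with mean
    ``library_size * batch_scale[slide] * p[label_i, g]`` where ``p`` is each
    domain's program normalized to sum 1.
    """
    rows, cols = lattice
    if programs is None:
        programs = default_st_programs(k_true)
    programs = np.asarray(programs, dtype=float)
    if programs.shape[0] != k_true:
        raise ValueError("programs must have k_true rows")
    if np.any(programs < 0):
        raise ValueError("programs must be non-negative")
    _check_distinct_rows(programs, "program")
    n_genes = programs.shape[1]
    r, c = np.mgrid[0:rows, 0:cols]
    valid = (r + c) % 2 == 0
    array_row, array_col = r[valid], c[valid]
    n_spots = array_row.size
    if n_spots < k_true:
        raise ValueError(f"lattice with {n_spots} spots cannot hold {k_true} domains")
    if k_true == 1:
        warnings.warn("k_true=1: all spots share one program; clustering "
                      "evaluation against this truth is degenerate", stacklevel=2)
    if batch_scale is None:
        batch_scale = np.array([_BATCH_CYCLE[s % len(_BATCH_CYCLE)]
                                for s in range(n_slides)])
    batch_scale = np.asarray(batch_scale, dtype=float)

    rng = np.random.default_rng(seed)
    xy = _hex_xy(array_row, array_col)
    p = programs / programs.sum(axis=1, keepdims=True)
    gene_names = [f"gene{g}" for g in range(n_genes)]
    datasets, truths = [], []
    for s in range(n_slides):
        sites = np.column_stack([
            rng.uniform(xy[:, 0].min(), xy[:, 0].max(), size=k_true),
            rng.uniform(xy[:, 1].min(), xy[:, 1].max(), size=k_true),
        ])
        d2 = ((xy[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        # guarantee every domain is present: relabel the nearest spot to an
        # absent domain's site
        for d in range(k_true):
            if not np.any(labels == d):
                labels[np.argmin(d2[:, d])] = d
        mean = library_size * batch_scale[s] * p[labels]
        counts = rng.poisson(mean).astype(float)
        slide_id = f"st_slide{s}"
        datasets.append(SpotDataset(
            matrix=counts,
            spot_ids=[f"{slide_id}_spot{i}" for i in range(n_spots)],
            array_row=array_row,
            array_col=array_col,
            slide_id=slide_id,
            batch=slide_id,
            gene_names=gene_names,
        ))
        truths.append(SyntheticTruth(labels=labels, profiles=programs,
                                     gains=np.full(n_genes, batch_scale[s]),
                                     noise_sd=0.0, seed=seed, slide_id=slide_id))
    return datasets, truths
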