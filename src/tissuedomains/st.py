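"""Preprocessing for spatial transcriptomics slides.

Counts from all slides are stacked, library-size normalized, log1p
transformed and reduced by PCA; technical differences between slides are
then reduced by a pluggable batch-correction hook (default: per-batch
centroid matching), and each spot's reduced vector is smoothed by averaging
over its hexagonal lattice neighborhood (``n_rings`` adjacency steps).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .datatypes import SpotDataset

__all__ = [
    "StPreprocessConfig",
    "ReducedEmbedding",
    "normalize_counts",
    "reduce_dimensions",
    "batch_correct",
    "hex_neighbors",
    "smooth_spots",
    "preprocess_st_slides",
]

# Visium 6-neighbor offsets in (array_row, array_col)
_HEX_OFFSETS = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass
class StPreprocessConfig:
    """Settings for the ST preprocessing chain.

    n_components
        Number of principal components kept (chosen from the variance-ratio
        rank plot in practice; 10-12 is typical for brain-scale data).
    n_rings
        Hex-lattice smoothing radius in adjacency steps (0 = no smoothing).
    use_batch_correction
        Apply the batch-correction hook between reduction and smoothing.
    normalize
        Library-size normalize to the median total and log1p before PCA.
    """

    n_components: int = 10
    n_rings: int = 1
    use_batch_correction: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_rings < 0:
            raise ValueError("n_rings must be >= 0")


@dataclass
class ReducedEmbedding:
    """PCA embedding of stacked spots with the pieces needed to back-project.

    ``coords`` is S x d; ``loadings`` is G x d with orthonormal columns;
    ``center`` is the length-G mean removed before projection, so
    ``coords @ loadings.T + center`` returns to (preprocessed) gene space.
    """

    coords: np.ndarray
    loadings: np.ndarray
    center: np.ndarray
    slide_of_spot: np.ndarray
    explained_variance_ratio: np.ndarray | None = None
    gene_names: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    def replace_coords(self, coords: np.ndarray) -> "ReducedEmbedding":
        return ReducedEmbedding(coords=coords, loadings=self.loadings,
                                center=self.center,
                                slide_of_spot=self.slide_of_spot,
                                explained_variance_ratio=self.explained_variance_ratio,
                                gene_names=self.gene_names)


def normalize_counts(matrix: np.ndarray) -> np.ndarray:
    """Scale each spot to the median total count, then log1p."""
    totals = matrix.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every spot must have a positive total count")
    target = np.median(totals)
    return np.log1p(matrix * (target / totals)[:, None])


def reduce_dimensions(data: Sequence[SpotDataset] | np.ndarray,
                      n_components: int, *, normalize: bool = True,
                      slide_of_spot: np.ndarray | None = None,
                      gene_names: list[str] | None = None) -> ReducedEmbedding:
    """Mean-centered PCA of the stacked spots-by-genes matrix.

    Accepts a list of :class:`SpotDataset` (stacked row-wise) or a raw
    matrix. ``normalize`` applies median-library-size scaling and log1p
    first; pass ``False`` for data that is already on a continuous scale.
    """
    if isinstance(data, np.ndarray):
        matrix = data
        if slide_of_spot is None:
            slide_of_spot = np.array(["slide"] * matrix.shape[0])
    else:
        datasets = list(data)
        matrix = np.vstack([d.matrix for d in datasets])
        slide_of_spot = np.concatenate(
            [np.full(d.n_spots, d.slide_id) for d in datasets])
        if gene_names is None:
            gene_names = datasets[0].gene_names
    if n_components > min(matrix.shape[0] - 1, matrix.shape[1]):
        raise ValueError(f"n_components={n_components} exceeds the rank bound "
                         f"of a {matrix.shape} matrix")
    if normalize:
        matrix = normalize_counts(matrix)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(matrix)
    return ReducedEmbedding(coords=coords,
                            loadings=pca.components_.T,
                            center=pca.mean_,
                            slide_of_spot=np.asarray(slide_of_spot),
                            explained_variance_ratio=pca.explained_variance_ratio_,
                            gene_names=gene_names)


def batch_correct(embedding: ReducedEmbedding,
                  batch: np.ndarray | Sequence[str],
                  method: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
                  ) -> ReducedEmbedding:
    """Reduce between-batch displacement in the embedding.

    The default moves each batch's centroid onto the global centroid
    (subtract batch mean, add overall mean) -- a rigid shift that removes
    first-order batch offsets while preserving within-batch structure. An
    external harmonization algorithm can be plugged in as ``method(coords,
    batch) -> coords`` behind the same shape-preserving contract.
    """
    batch = np.asarray(batch)
    if batch.shape[0] != embedding.coords.shape[0]:
        raise ValueError("one batch label per spot required")
    if method is not None:
        coords = np.asarray(method(embedding.coords, batch))
        if coords.shape != embedding.coords.shape:
            raise ValueError("batch-correction hook changed the embedding shape")
        return embedding.replace_coords(coords)
    coords = embedding.coords.copy()
    global_mean = coords.mean(axis=0)
    for b in np.unique(batch):
        sel = batch == b
        coords[sel] += global_mean - coords[sel].mean(axis=0)
    return embedding.replace_coords(coords)


def hex_neighbors(dataset: SpotDataset, n_rings: int) -> list[np.ndarray]:
    """Spot indices within ``n_rings`` hex-adjacency steps of each spot.

    Neighborhoods include the central spot itself (so ``n_rings=0`` gives
    singletons) and never cross slides -- call per dataset. Interior spots
    have 6 direct neighbors via the Visium offsets (row +-1 / col +-1 and
    col +-2).
    """
    if n_rings < 0:
        raise ValueError("n_rings must be >= 0")
    r, c = dataset.array_row, dataset.array_col
    if np.any((r + c) % 2 != 0):
        bad = int(np.argmax((r + c) % 2 != 0))
        raise ValueError(f"invalid lattice position (row+col odd) at spot "
                         f"{dataset.spot_ids[bad]}")
    index = {(int(r[i]), int(c[i])): i for i in range(dataset.n_spots)}
    out = []
    for i in range(dataset.n_spots):
        seen = {i}
        frontier = deque([(int(r[i]), int(c[i]))])
        for _ in range(n_rings):
            nxt = deque()
            while frontier:
                rr, cc = frontier.popleft()
                for dr, dc in _HEX_OFFSETS:
                    j = index.get((rr + dr, cc + dc))
                    if j is not None and j not in seen:
                        seen.add(j)
                        nxt.append((rr + dr, cc + dc))
            frontier = nxt
        out.append(np.fromiter(sorted(seen), dtype=int))
    return out


def smooth_spots(embedding: ReducedEmbedding,
                 neighborhoods: list[np.ndarray],
                 spot_slice: slice | np.ndarray | None = None) -> ReducedEmbedding:
    """Replace each spot's vector by the unweighted mean over its neighborhood.

    ``neighborhoods`` indexes the rows selected by ``spot_slice`` (default:
    all rows) -- pass the per-slide slice when smoothing a stacked embedding
    slide by slide.
    """
    coords = embedding.coords.copy()
    block = coords if spot_slice is None else coords[spot_slice]
    if len(neighborhoods) != block.shape[0]:
        raise ValueError("one neighborhood per spot required")
    smoothed = np.empty_like(block)
    for i, nbrs in enumerate(neighborhoods):
        if len(nbrs) == 0:
            raise ValueError("empty neighborhood")
        smoothed[i] = block[nbrs].mean(axis=0)
    if spot_slice is None:
        coords = smoothed
    else:
        coords[spot_slice] = smoothed
    return embedding.replace_coords(coords)


def preprocess_st_slides(datasets: Sequence[SpotDataset],
                         config: StPreprocessConfig) -> ReducedEmbedding:
    """Full ST chain: reduce -> batch-correct -> per-slide hex smoothing."""
    datasets = list(datasets)
    embedding = reduce_dimensions(datasets, config.n_components,
                                  normalize=config.normalize)
    if config.use_batch_correction and len(datasets) > 1:
        batch = np.concatenate([np.full(d.n_spots, d.batch) for d in datasets])
        embedding = batch_correct(embedding, batch)
    if config.n_rings > 0:
        start = 0
        for d in datasets:
            nbrs = hex_neighbors(d, config.n_rings)
            embedding = smooth_spots(embedding, nbrs,
                                     spot_slice=slice(start, start + d.n_spots))
            start += d.n_spots
    return embedding
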