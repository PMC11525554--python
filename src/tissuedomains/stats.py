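"""Domain-level statistics and benchmarking utilities.

Per image: domain proportions and maximum connected-component sizes
(optionally restricted to a region mask), exported as tidy tables suitable
for downstream association modeling in external statistical software. For
ST: gene-set signature scoring with argmax annotation, and per-sample plus
consensus adjusted Rand index for comparison against reference labelings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import adjusted_rand_score

from .datatypes import SpotDataset

__all__ = [
    "DomainStats",
    "SignatureScoreTable",
    "domain_proportions",
    "max_connected_component",
    "compute_domain_stats",
    "domain_stats_table",
    "signature_score",
    "adjusted_rand_index",
    "consensus_ari",
]


@dataclass
class DomainStats:
    """Per-image domain composition summary."""

    proportions: dict[int, float]
    max_cc_size: dict[int, int]
    tissue_area: int
    slide_id: str = "slide"


@dataclass
class SignatureScoreTable:
    """Spots-by-signatures score matrix with argmax annotations."""

    scores: pd.DataFrame
    annotations: np.ndarray


def domain_proportions(labels: np.ndarray) -> dict[int, float]:
    """Fraction of in-mask pixels per domain (background -1 excluded)."""
    labels = np.asarray(labels)
    fg = labels[labels >= 0]
    if fg.size == 0:
        raise ValueError("no in-mask pixels")
    values, counts = np.unique(fg, return_counts=True)
    total = counts.sum()
    return {int(v): float(c) / total for v, c in zip(values, counts)}


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)  # cross
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)  # full block
    raise ValueError("connectivity must be 4 or 8")


def max_connected_component(labels: np.ndarray, domain: int,
                            connectivity: int = 4) -> int:
    """Pixel count of the domain's largest connected component (0 if absent)."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be a 2-D image")
    binary = labels == domain
    if not binary.any():
        return 0
    comp, n = ndimage.label(binary, structure=_structure(connectivity))
    sizes = ndimage.sum_labels(binary, comp, index=np.arange(1, n + 1))
    return int(sizes.max())


def compute_domain_stats(labels: np.ndarray, slide_id: str = "slide",
                         region_mask: np.ndarray | None = None,
                         connectivity: int = 4) -> DomainStats:
    """Proportions and max-CC sizes for one label image.

    ``region_mask`` restricts the statistics to a region of interest (pixels
    outside it are treated as background).
    """
    labels = np.asarray(labels)
    if region_mask is not None:
        labels = np.where(np.asarray(region_mask, dtype=bool), labels, -1)
    props = domain_proportions(labels)
    max_cc = {d: max_connected_component(labels, d, connectivity) for d in props}
    return DomainStats(proportions=props, max_cc_size=max_cc,
                       tissue_area=int((labels >= 0).sum()), slide_id=slide_id)


def domain_stats_table(stats: list[DomainStats]) -> pd.DataFrame:
    """Tidy per-(image, domain) table for external association modeling."""
    records = []
    for st in stats:
        for d in sorted(st.proportions):
            records.append({"slide_id": st.slide_id, "domain": d,
                            "proportion": st.proportions[d],
                            "max_cc_size": st.max_cc_size[d],
                            "tissue_area": st.tissue_area})
    return pd.DataFrame(records, columns=["slide_id", "domain", "proportion",
                                          "max_cc_size", "tissue_area"])


def signature_score(dataset: SpotDataset, gene_sets: dict[str, list[str]],
                    n_bins: int = 25, n_reference: int = 50, seed: int = 0,
                    *, lognorm: bool = True) -> SignatureScoreTable:
    """Expression-bin-controlled gene-set scores with argmax annotation.

    Per spot and signature: mean expression over the set minus mean over a
    seeded control pool. Genes are binned into ``n_bins`` by mean
    expression; each signature gene draws ``n_reference`` controls from its
    own bin (the gene itself may be drawn), and the pooled unique controls
    form the reference. Annotation is the argmax signature per spot, ties
    resolving to the first signature in input order.
    """
    if dataset.gene_names is None:
        raise ValueError("dataset must carry gene names for signature scoring")
    expr = dataset.matrix
    if lognorm:
        totals = expr.sum(axis=1)
        if np.all(totals > 0):
            expr = np.log1p(expr * (np.median(totals) / totals)[:, None])
        else:
            expr = np.log1p(expr)
    gene_index = {g: i for i, g in enumerate(dataset.gene_names)}
    gene_mean = expr.mean(axis=0)
    order = np.argsort(gene_mean, kind="stable")
    n_genes = len(gene_index)
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // max(n_genes, 1), n_bins - 1)
    bin_members = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}

    rng = np.random.default_rng(seed)
    names = list(gene_sets)
    scores = np.empty((dataset.n_spots, len(names)))
    for j, name in enumerate(names):
        members = [gene_index[g] for g in gene_sets[name] if g in gene_index]
        if not members:
            raise ValueError(f"gene set '{name}' shares no genes with the dataset")
        controls: set[int] = set()
        for gi in members:
            pool = bin_members[bins[gi]]
            take = min(n_reference, pool.size)
            controls.update(rng.choice(pool, size=take, replace=False).tolist())
        ctrl = np.fromiter(sorted(controls), dtype=int)
        scores[:, j] = expr[:, members].mean(axis=1) - expr[:, ctrl].mean(axis=1)
    table = pd.DataFrame(scores, index=dataset.spot_ids, columns=names)
    return SignatureScoreTable(scores=table,
                               annotations=np.argmax(scores, axis=1))


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Permutation-model adjusted Rand index between two labelings."""
    a, b = np.asarray(a).ravel(), np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 elements")
    return float(adjusted_rand_score(a, b))


def consensus_ari(per_sample_a: list[np.ndarray],
                  per_sample_b: list[np.ndarray]) -> float:
    """ARI of the concatenation across samples (one shared label space).

    Unlike averaging per-sample ARIs, this penalizes a method whose label
    identities are inconsistent from sample to sample.
    """
    if len(per_sample_a) != len(per_sample_b):
        raise ValueError("sample counts differ")
    for i, (x, y) in enumerate(zip(per_sample_a, per_sample_b)):
        if np.asarray(x).ravel().shape != np.asarray(y).ravel().shape:
            raise ValueError(f"sample {i}: label lengths differ")
    return adjusted_rand_index(
        np.concatenate([np.asarray(x).ravel() for x in per_sample_a]),
        np.concatenate([np.asarray(y).ravel() for y in per_sample_b]))
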