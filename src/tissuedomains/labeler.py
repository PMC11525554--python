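"""The consensus tissue labeler.

One k-means model is fitted on pixels/spots pooled from *all* slides, so a
centroid (= tissue domain) means the same thing in every specimen. The fit
chain is:

1. subsample pixels uniformly within each slide's tissue mask (default
   fraction 0.2; ST uses all spots),
2. Z-normalize the pooled subsample and store the mean/SD,
3. k-means over a range of k, best of ``n_init`` restarts per k,
4. choose k by minimizing the adjusted inertia
   ``inertia(k) / inertia(1) + alpha * k`` (smaller ``alpha`` = finer
   domains), unless a fixed k is requested,
5. assign every in-mask pixel/spot of the full dataset to its nearest
   centroid using the *stored* subsample Z-parameters.

The fitted model is portable: it can be serialized to JSON and applied to
new slides without refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .st import ReducedEmbedding

__all__ = [
    "LabelerConfig",
    "ZNormParams",
    "FittedLabeler",
    "subsample_pixels",
    "z_normalize",
    "fit_kmeans_over_k",
    "adjusted_inertia",
    "assign_domains",
    "domain_profile",
    "fit_tissue_labeler",
    "save_labeler",
    "load_labeler",
]


@dataclass
class LabelerConfig:
    """Fit settings.

    alpha
        Adjusted-inertia penalty per cluster (0.05 gives coarse domains,
        0.02 finer ones); ignored when ``k`` is fixed.
    subsample_fraction
        Per-slide fraction of in-mask pixels pooled for fitting (mIF);
        use 1.0 to fit on everything (the ST convention).
    k_range
        Inclusive (k_min, k_max) interval searched when selecting k.
    k
        Fixed number of domains, bypassing k-selection (used when ground
        truth prescribes the domain count).
    """

    alpha: float = 0.05
    subsample_fraction: float = 0.2
    k_range: tuple[int, int] = (2, 8)
    k: int | None = None
    seed: int = 0
    n_init: int = 10
    max_iter: int = 300

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.k is None:
            if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
                raise ValueError("k_range must satisfy 2 <= k_min <= k_max")
        elif self.k < 1:
            raise ValueError("fixed k must be >= 1")


@dataclass
class ZNormParams:
    """Feature standardization parameters estimated on the fit subsample.

    ``mean``/``sd`` cover all input features (population SD, 1/N divisor);
    ``kept`` flags features with positive variance -- zero-variance features
    are dropped from the clustering space and recorded here.
    """

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        """Map raw feature rows into the model's Z-space (kept columns)."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"expected {self.mean.shape[0]} features, got {matrix.shape[1]}")
        return (matrix[:, self.kept] - self.mean[self.kept]) / self.sd[self.kept]


@dataclass
class FittedLabeler:
    """A portable consensus tissue-domain model.

    ``centroids`` (k x d) live in Z-space over the kept features;
    ``inertia_curve``/``adjusted_curve`` record the k-selection trace (empty
    in fixed-k mode).
    """

    centroids: np.ndarray
    znorm: ZNormParams
    k: int
    inertia_curve: dict[int, float]
    adjusted_curve: dict[int, float]
    config: LabelerConfig
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        uniq = np.unique(self.centroids, axis=0)
        if uniq.shape[0] != self.centroids.shape[0]:
            raise ValueError("centroids must be pairwise distinct")


def subsample_pixels(slides: Sequence[tuple[np.ndarray, np.ndarray | None]],
                     fraction: float, seed: int) -> np.ndarray:
    """Pool a uniform spatial-agnostic subsample of in-mask rows per slide.

    Each slide is ``(features, mask)``: features ``H x W x C`` with a boolean
    mask (mIF), or ``N x d`` with ``mask=None`` meaning use all rows (ST).
    ``floor(fraction * N_mask)`` rows are drawn per slide without
    replacement; deterministic given ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    parts = []
    for features, mask in slides:
        features = np.asarray(features, dtype=float)
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            rows = features[mask]
        else:
            rows = features.reshape(-1, features.shape[-1])
        n = rows.shape[0]
        if n == 0:
            raise ValueError("slide has an empty mask")
        take = n if fraction == 1.0 else int(np.floor(fraction * n))
        take = max(take, 1)
        idx = np.sort(rng.choice(n, size=take, replace=False))
        parts.append(rows[idx])
    return np.vstack(parts)


def z_normalize(matrix: np.ndarray) -> tuple[np.ndarray, ZNormParams]:
    """Standardize columns to mean 0, population SD 1.

    Zero-variance columns are dropped from the output and recorded in the
    returned parameters; an error is raised if nothing remains.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)  # population (1/N)
    kept = sd > 0
    if not kept.any():
        raise ValueError("all features have zero variance")
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} zero-variance feature(s) "
                      f"at indices {np.flatnonzero(~kept).tolist()}", stacklevel=2)
    params = ZNormParams(mean=mean, sd=np.where(kept, sd, 1.0), kept=kept)
    return (matrix[:, kept] - mean[kept]) / sd[kept], params


def fit_kmeans_over_k(matrix: np.ndarray, k_range: Sequence[int], seed: int,
                      n_init: int = 10, max_iter: int = 300
                      ) -> tuple[dict[int, float], dict[int, np.ndarray]]:
    """Lloyd's k-means (k-means++ init, best of ``n_init`` restarts) for each
    k in ``k_range``; returns (inertia curve, centroids per k)."""
    matrix = np.asarray(matrix, dtype=float)
    inertia_curve: dict[int, float] = {}
    centroid_sets: dict[int, np.ndarray] = {}
    for k in k_range:
        if k > matrix.shape[0]:
            raise ValueError(f"k={k} exceeds the {matrix.shape[0]} available rows")
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                    max_iter=max_iter, tol=1e-4,
                    random_state=(int(seed) + k) % (2 ** 31)).fit(matrix)
        inertia_curve[k] = float(km.inertia_)
        centroid_sets[k] = km.cluster_centers_
    return inertia_curve, centroid_sets


def adjusted_inertia(inertia_curve: dict[int, float], alpha: float,
                     inertia1: float | None = None
                     ) -> tuple[dict[int, float], int]:
    """Penalized k-selection: ``adjusted(k) = inertia(k)/inertia(1) + alpha*k``.

    ``inertia(1)`` (the total sum of squares) is taken from the curve if
    present, else from ``inertia1``. Returns the adjusted curve over the
    supplied k values and the argmin ``k_star`` (ties -> smallest k).
    """
    if 1 in inertia_curve:
        inertia1 = inertia_curve[1]
    if inertia1 is None:
        raise ValueError("inertia(1) required: include k=1 in the curve or "
                         "pass inertia1")
    if inertia1 <= 0:
        raise ValueError("inertia(1) is zero: degenerate single-point data")
    ks = sorted(k for k in inertia_curve if k >= 1)
    adjusted = {k: inertia_curve[k] / inertia1 + alpha * k for k in ks}
    k_star = min(ks, key=lambda k: (adjusted[k], k))
    return adjusted, k_star


def total_sum_of_squares(matrix: np.ndarray) -> float:
    """Closed-form inertia at k=1 (sum of squared deviations from the mean)."""
    matrix = np.asarray(matrix, dtype=float)
    return float(((matrix - matrix.mean(axis=0)) ** 2).sum())


def fit_tissue_labeler(slides: Sequence[tuple[np.ndarray, np.ndarray | None]],
                       config: LabelerConfig,
                       feature_names: Sequence[str] | None = None
                       ) -> FittedLabeler:
    """Fit the consensus labeler on pooled slides (see module docstring)."""
    sub = subsample_pixels(slides, config.subsample_fraction, config.seed)
    z, params = z_normalize(sub)
    if config.k is not None:
        curve, centroid_sets = fit_kmeans_over_k(
            z, [config.k], config.seed, config.n_init, config.max_iter)
        adjusted: dict[int, float] = {}
        k_star = config.k
    else:
        ks = range(config.k_range[0], config.k_range[1] + 1)
        curve, centroid_sets = fit_kmeans_over_k(
            z, ks, config.seed, config.n_init, config.max_iter)
        adjusted, k_star = adjusted_inertia(curve, config.alpha,
                                            inertia1=total_sum_of_squares(z))
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(params.mean.shape[0])]
    return FittedLabeler(centroids=centroid_sets[k_star], znorm=params,
                         k=k_star, inertia_curve=curve,
                         adjusted_curve=adjusted, config=config,
                         feature_names=names)


def _nearest_centroid(z_rows: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # argmin returns the lowest index on ties, the documented tie-break
    return np.argmin(cdist(z_rows, centroids), axis=1)


def assign_domains(slides: Sequence[tuple[np.ndarray, np.ndarray | None]],
                   model: FittedLabeler) -> list[np.ndarray]:
    """Label every in-mask pixel/spot of each slide by its nearest centroid.

    Features are mapped into Z-space with the model's stored subsample
    parameters. Image slides return ``H x W`` label maps with background
    ``-1``; table slides return length-N label vectors.
    """
    out = []
    for features, mask in slides:
        features = np.asarray(features, dtype=float)
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            labels = np.full(mask.shape, -1, dtype=int)
            rows = features[mask]
            if rows.size:
                labels[mask] = _nearest_centroid(model.znorm.transform(rows),
                                                 model.centroids)
        else:
            rows = features.reshape(-1, features.shape[-1])
            labels = _nearest_centroid(model.znorm.transform(rows),
                                       model.centroids)
        out.append(labels)
    return out


def domain_profile(model: FittedLabeler, space: str = "marker",
                   reduction: ReducedEmbedding | None = None) -> np.ndarray:
    """Express centroids in interpretable units (K x F).

    ``space='marker'`` / ``'component'`` un-Z-normalizes the centroids back
    to the input feature units (dropped zero-variance features reappear at
    their constant mean). ``space='gene'`` additionally back-projects
    component centroids through the stored PCA loadings plus center.
    """
    if space not in ("marker", "component", "gene"):
        raise ValueError(f"unknown space {space!r}")
    n_all = model.znorm.mean.shape[0]
    profiles = np.tile(model.znorm.mean, (model.centroids.shape[0], 1))
    profiles[:, model.znorm.kept] = (
        model.centroids * model.znorm.sd[model.znorm.kept]
        + model.znorm.mean[model.znorm.kept])
    if space == "gene":
        if reduction is None:
            raise ValueError("gene-space profiles require the stored reduction")
        if n_all != reduction.loadings.shape[1]:
            raise ValueError("model features do not match reduction components")
        return profiles @ reduction.loadings.T + reduction.center
    return profiles


def save_labeler(model: FittedLabeler, path: str | Path) -> Path:
    """Serialize the fitted model to a single JSON document."""
    path = Path(path)
    cfg = model.config
    doc = {
        "format": "tissuedomains-labeler-v1",
        "k": model.k,
        "centroids": model.centroids.tolist(),
        "znorm": {
            "mean": model.znorm.mean.tolist(),
            "sd": model.znorm.sd.tolist(),
            "kept": model.znorm.kept.astype(int).tolist(),
        },
        "inertia_curve": {str(k): v for k, v in model.inertia_curve.items()},
        "adjusted_curve": {str(k): v for k, v in model.adjusted_curve.items()},
        "config": {
            "alpha": cfg.alpha,
            "subsample_fraction": cfg.subsample_fraction,
            "k_range": list(cfg.k_range),
            "k": cfg.k,
            "seed": cfg.seed,
            "n_init": cfg.n_init,
            "max_iter": cfg.max_iter,
        },
        "feature_names": model.feature_names,
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def load_labeler(path: str | Path) -> FittedLabeler:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "tissuedomains-labeler-v1":
        raise ValueError(f"{path} is not a serialized tissue labeler")
    c = doc["config"]
    config = LabelerConfig(alpha=c["alpha"],
                           subsample_fraction=c["subsample_fraction"],
                           k_range=tuple(c["k_range"]), k=c["k"],
                           seed=c["seed"], n_init=c["n_init"],
                           max_iter=c["max_iter"])
    znorm = ZNormParams(mean=np.array(doc["znorm"]["mean"]),
                        sd=np.array(doc["znorm"]["sd"]),
                        kept=np.array(doc["znorm"]["kept"], dtype=bool))
    return FittedLabeler(centroids=np.array(doc["centroids"]), znorm=znorm,
                         k=int(doc["k"]),
                         inertia_curve={int(k): v for k, v in doc["inertia_curve"].items()},
                         adjusted_curve={int(k): v for k, v in doc["adjusted_curve"].items()},
                         config=config,
                         feature_names=list(doc["feature_names"]))
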