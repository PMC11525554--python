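"""Quality-control metrics for fitted tissue-domain models.

Per pixel/spot: a confidence score ``(d2 - d1) / d2`` from the distances to
the assigned (closest) and second-closest centroids -- a fast simplification
of the Silhouette index, 1 at a centroid, 0 at an equidistant point. Per
slide: variance explained and mean squared error of the clustering in
Z-space, plus mean confidence per domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .labeler import FittedLabeler

__all__ = [
    "DomainResult",
    "SlideQC",
    "confidence_scores",
    "slide_qc",
    "mean_confidence_by_domain",
]


@dataclass
class DomainResult:
    """Per-pixel/spot domain labels and confidences for one slide.

    ``labels`` is ``H x W`` (background -1) or length-N; ``confidence`` has
    the same shape, holds values in [0, 1] where ``labels >= 0`` and NaN on
    background.
    """

    labels: np.ndarray
    confidence: np.ndarray
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.labels.shape != self.confidence.shape:
            raise ValueError("labels and confidence shapes differ")
        fg = self.labels >= 0
        conf = self.confidence[fg]
        if conf.size and (np.nanmin(conf) < 0 or np.nanmax(conf) > 1):
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class SlideQC:
    """Whole-slide fit summary (computed in the clustering Z-space)."""

    variance_explained: float
    mse: float
    mean_confidence_by_domain: dict[int, float] = field(default_factory=dict)
    slide_id: str = "slide"


def confidence_scores(z_rows: np.ndarray, model: FittedLabeler) -> np.ndarray:
    """Confidence ``(d2 - d1) / d2`` per row against the model centroids.

    ``z_rows`` must already be in the model's Z-space. Requires k >= 2 (the
    second-closest centroid is undefined otherwise). Returns values in
    [0, 1]: 1 iff the row coincides with its centroid, 0 iff it is
    equidistant to the two nearest centroids.
    """
    if model.centroids.shape[0] < 2:
        raise ValueError("confidence scores require a model with k >= 2")
    z_rows = np.asarray(z_rows, dtype=float)
    d = cdist(z_rows, model.centroids)
    d.sort(axis=1)
    d1, d2 = d[:, 0], d[:, 1]
    out = np.zeros(z_rows.shape[0])
    ok = d2 > 0
    if not ok.all():
        warnings.warn("duplicate centroids encountered; confidence set to 0",
                      stacklevel=2)
    out[ok] = (d2[ok] - d1[ok]) / d2[ok]
    return out


def slide_qc(z_rows: np.ndarray, result: DomainResult, model: FittedLabeler
             ) -> SlideQC:
    """Variance explained, MSE, and per-domain mean confidence of one slide.

    ``z_rows`` are the slide's in-mask rows in Z-space, ordered as
    ``result.labels[result.labels >= 0]``. Variance explained is
    ``1 - SS_within / SS_total`` with SS_total around the slide mean; a
    (pathological) negative value is clipped to 0 with a warning.
    """
    z_rows = np.asarray(z_rows, dtype=float)
    labels = result.labels[result.labels >= 0]
    if z_rows.shape[0] != labels.shape[0]:
        raise ValueError("one Z-space row per labeled pixel required")
    if z_rows.shape[0] < 2:
        raise ValueError("need at least 2 in-mask rows")
    ss_within = float(((z_rows - model.centroids[labels]) ** 2).sum())
    ss_total = float(((z_rows - z_rows.mean(axis=0)) ** 2).sum())
    if ss_total == 0:
        raise ValueError("constant slide: total sum of squares is zero")
    ve = 1.0 - ss_within / ss_total
    if ve < 0:
        warnings.warn(f"slide '{result.slide_id}': SS_within exceeds SS_total "
                      f"(variance explained {ve:.3f}); clipping to 0",
                      stacklevel=2)
        ve = 0.0
    conf = result.confidence[result.labels >= 0]
    by_domain = {int(d): float(conf[labels == d].mean())
                 for d in np.unique(labels)}
    return SlideQC(variance_explained=ve, mse=ss_within / z_rows.shape[0],
                   mean_confidence_by_domain=by_domain,
                   slide_id=result.slide_id)


def mean_confidence_by_domain(results: list[DomainResult]) -> pd.DataFrame:
    """Tidy table of (slide_id, domain, mean_confidence, n_pixels).

    Domains absent from an image contribute no row for that image.
    """
    records = []
    for res in results:
        fg = res.labels >= 0
        labels, conf = res.labels[fg], res.confidence[fg]
        for d in np.unique(labels):
            sel = labels == d
            records.append({"slide_id": res.slide_id, "domain": int(d),
                            "mean_confidence": float(conf[sel].mean()),
                            "n_pixels": int(sel.sum())})
    return pd.DataFrame(records,
                        columns=["slide_id", "domain", "mean_confidence",
                                 "n_pixels"])
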