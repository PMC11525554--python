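"""End-to-end orchestration: preprocess -> fit -> assign -> QC.

These are the high-level entry points the CLI, the examples and most users
call; each returns a small run object bundling the fitted model with
per-slide labels, confidences and QC summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import MultiplexImage, SpotDataset, TissueMask
from .labeler import (FittedLabeler, LabelerConfig, assign_domains,
                      fit_tissue_labeler)
from .mif import ChannelNormStats, MifPreprocessConfig, preprocess_mif_slide
from .qc import DomainResult, SlideQC, confidence_scores, slide_qc
from .st import ReducedEmbedding, StPreprocessConfig, preprocess_st_slides

__all__ = ["MifRun", "StRun", "fit_mif_pipeline", "label_mif_slides",
           "fit_st_pipeline"]


@dataclass
class MifRun:
    """Everything produced by one consensus fit over mIF slides."""

    model: FittedLabeler
    results: list[DomainResult]
    qc: list[SlideQC]
    masks: list[TissueMask]
    features: list[MultiplexImage]
    norm_stats: list[ChannelNormStats] = field(default_factory=list)


@dataclass
class StRun:
    """Everything produced by one consensus fit over ST slides."""

    model: FittedLabeler
    results: list[DomainResult]
    qc: list[SlideQC]
    embedding: ReducedEmbedding


def _mif_results(features: list[MultiplexImage], masks: list[TissueMask],
                 model: FittedLabeler) -> tuple[list[DomainResult], list[SlideQC]]:
    slides = [(f.pixels, m.mask) for f, m in zip(features, masks)]
    labels = assign_domains(slides, model)
    results, qcs = [], []
    for feat, mask, lab in zip(features, masks, labels):
        z = model.znorm.transform(feat.pixels[mask.mask])
        conf_rows = confidence_scores(z, model) if model.k >= 2 else np.ones(len(z))
        conf = np.full(lab.shape, np.nan)
        conf[mask.mask] = conf_rows
        res = DomainResult(labels=lab, confidence=conf, slide_id=feat.slide_id)
        results.append(res)
        qcs.append(slide_qc(z, res, model))
    return results, qcs


def fit_mif_pipeline(images: Sequence[MultiplexImage],
                     mif_config: MifPreprocessConfig | None = None,
                     labeler_config: LabelerConfig | None = None) -> MifRun:
    """Preprocess every slide, fit the consensus labeler, label everything.

    Per slide: scale -> downsample -> tissue mask -> log-mean normalize ->
    Gaussian smooth; then pixels from all slides are pooled (subsampled
    within the masks) for a single k-means fit, and every in-mask pixel is
    assigned its nearest centroid with a confidence score.
    """
    mif_config = mif_config or MifPreprocessConfig()
    labeler_config = labeler_config or LabelerConfig()
    features, masks, stats = [], [], []
    for image in images:
        feat, mask, st = preprocess_mif_slide(image, mif_config)
        features.append(feat)
        masks.append(mask)
        stats.append(st)
    model = fit_tissue_labeler(
        [(f.pixels, m.mask) for f, m in zip(features, masks)],
        labeler_config, feature_names=list(images[0].channels))
    results, qcs = _mif_results(features, masks, model)
    return MifRun(model=model, results=results, qc=qcs, masks=masks,
                  features=features, norm_stats=stats)


def label_mif_slides(images: Sequence[MultiplexImage], model: FittedLabeler,
                     mif_config: MifPreprocessConfig | None = None
                     ) -> tuple[list[DomainResult], list[SlideQC]]:
    """Apply a fitted model to (possibly new) slides without refitting."""
    mif_config = mif_config or MifPreprocessConfig()
    for image in images:
        if list(image.channels) != list(model.feature_names):
            extra = set(image.channels) ^ set(model.feature_names)
            raise ValueError(
                f"slide '{image.slide_id}' channels do not match the model's "
                f"features (mismatch: {sorted(extra)})")
    features, masks = [], []
    for image in images:
        feat, mask, _ = preprocess_mif_slide(image, mif_config)
        features.append(feat)
        masks.append(mask)
    return _mif_results(features, masks, model)


def fit_st_pipeline(datasets: Sequence[SpotDataset],
                    st_config: StPreprocessConfig | None = None,
                    labeler_config: LabelerConfig | None = None) -> StRun:
    """Reduce, batch-correct and smooth stacked ST slides, then fit and label.

    All spots enter the fit (the ST convention); the labeler's
    ``subsample_fraction`` is ignored for this modality.
    """
    st_config = st_config or StPreprocessConfig()
    labeler_config = labeler_config or LabelerConfig(subsample_fraction=1.0)
    datasets = list(datasets)
    embedding = preprocess_st_slides(datasets, st_config)
    model = fit_tissue_labeler(
        [(embedding.coords, None)],
        LabelerConfig(alpha=labeler_config.alpha, subsample_fraction=1.0,
                      k_range=labeler_config.k_range, k=labeler_config.k,
                      seed=labeler_config.seed, n_init=labeler_config.n_init,
                      max_iter=labeler_config.max_iter),
        feature_names=[f"PC{i + 1}" for i in range(embedding.n_components)])
    results, qcs = [], []
    start = 0
    for d in datasets:
        coords = embedding.coords[start:start + d.n_spots]
        start += d.n_spots
        z = model.znorm.transform(coords)
        labels = np.argmin(
            np.linalg.norm(z[:, None, :] - model.centroids[None, :, :], axis=2),
            axis=1)
        conf = confidence_scores(z, model) if model.k >= 2 else np.ones(len(z))
        res = DomainResult(labels=labels, confidence=conf, slide_id=d.slide_id)
        results.append(res)
        qcs.append(slide_qc(z, res, model))
    return StRun(model=model, results=results, qc=qcs, embedding=embedding)
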