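"""Shared fixtures: small synthetic cohorts and fitted pipeline runs."""

import numpy as np
import pytest

from tissuedomains import (LabelerConfig, MifPreprocessConfig,
                           StPreprocessConfig, fit_mif_pipeline,
                           fit_st_pipeline, generate_synthetic_mif,
                           generate_synthetic_st)

MIF_CFG = MifPreprocessConfig(downsample_factor=2, sigma=2.0)
LAB_CFG = LabelerConfig(alpha=0.05, seed=7)


@pytest.fixture(scope="session")
def mif_small():
    """Two 64x64 slides, 4 planted domains, slide gains and mild noise."""
    return generate_synthetic_mif(n_slides=2, shape=(64, 64), seed=7)


@pytest.fixture(scope="session")
def mif_run(mif_small):
    images, _ = mif_small
    return fit_mif_pipeline(images, MIF_CFG, LAB_CFG)


@pytest.fixture(scope="session")
def st_small():
    """Three hex-lattice slides, 4 planted domains, Poisson counts."""
    return generate_synthetic_st(n_slides=3, lattice=(30, 30), seed=3)


@pytest.fixture(scope="session")
def st_run(st_small):
    datasets, _ = st_small
    return fit_st_pipeline(datasets,
                           StPreprocessConfig(n_components=8, n_rings=1),
                           LabelerConfig(k=4, seed=3, subsample_fraction=1.0))


def masked_ari_pairs(results, truths):
    """Per-slide (truth, predicted) label vectors over evaluable pixels."""
    true, pred = [], []
    for res, truth in zip(results, truths):
        if res.labels.ndim == 2:
            sel = (res.labels >= 0) & (truth.labels >= 0)
            true.append(truth.labels[sel])
            pred.append(res.labels[sel])
        else:
            true.append(truth.labels)
            pred.append(res.labels)
    return true, pred
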