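"""Detect consensus tissue domains across synthetic mIF slides.

Generates three slides with four planted domains, distinct per-slide channel
gains and pixel noise, runs the full pipeline (mask -> normalize -> smooth ->
pooled k-means with adjusted-inertia k-selection), and compares the labels
with the planted truth.
"""

import numpy as np

from tissuedomains import (LabelerConfig, MifPreprocessConfig, consensus_ari,
                           domain_profile, fit_mif_pipeline,
                           generate_synthetic_mif)

images, truths = generate_synthetic_mif(n_slides=3, shape=(128, 128),
                                        k_true=4, seed=1)
run = fit_mif_pipeline(
    images,
    MifPreprocessConfig(downsample_factor=1, sigma=0.5),
    LabelerConfig(alpha=0.05, k_range=(2, 8), seed=1),
)

print(f"selected k = {run.model.k} (planted: 4)")
print("adjusted inertia:",
      {k: round(v, 3) for k, v in sorted(run.model.adjusted_curve.items())})

true, pred = [], []
for res, truth in zip(run.results, truths):
    sel = (res.labels >= 0) & (truth.labels >= 0)
    true.append(truth.labels[sel])
    pred.append(res.labels[sel])
print(f"consensus ARI vs planted truth = {consensus_ari(true, pred):.3f}")

print("domain profiles (marker space, one row per domain):")
print(np.round(domain_profile(run.model), 3))
# The selected k matches the planted domain count, ARI ~1 means the pixel
# labels recover the planted geometry, and each profile row shows which
# marker dominates that domain.
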