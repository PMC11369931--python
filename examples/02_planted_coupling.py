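"""Leakage-corrected envelope correlation recovers planted coupling.

Generates two band-limited signals whose envelopes share a controlled
fraction of variance (the planted coupling), then compares the AEC-c
estimate against the correlation of the stored ground-truth envelopes (the
oracle).  Also demonstrates the leakage-rejection contrast: for
y = x + small independent noise, the naive envelope correlation is ~1
(pure zero-lag leakage) while AEC-c stays near 0.
"""
import numpy as np

from mstmeg import (CohortSpec, aec_corrected, aec_uncorrected,
                    generate_subject_timeseries)
from mstmeg.signal import ALPHA

spec = CohortSpec(n_subjects=1, n_fhpos=1, n_regions=3, n_epochs=1,
                  epoch_samples=15000, fs=125.0, bands=(ALPHA,), seed=0)

print("coupling   planted-env-corr   AEC-c")
rng = np.random.default_rng(1)
for coupling in (0.0, 0.3, 0.6, 0.8):
    ts, truth = generate_subject_timeseries(spec, coupling, rng,
                                            return_truth=True)
    env = truth["alpha"]
    oracle = np.corrcoef(env[0, 0], env[1, 0])[0, 1]
    est = aec_corrected(ts.data[0, 0], ts.data[1, 0])
    print(f"  {coupling:.1f}        {oracle: .3f}            {est: .3f}")

ts = generate_subject_timeseries(spec, 0.0, rng)
x, eps = ts.data[0, 0], ts.data[1, 0]
y = x + 0.1 * eps
print("\nleakage contrast for y = x + 0.1*noise:")
print(f"  naive AEC      = {aec_uncorrected(x, y):.3f}   (spurious, zero-lag)")
print(f"  corrected AEC-c = {aec_corrected(x, y):.3f}   (leakage removed)")
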