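"""Dissociate spatial from temporal structure with the two shuffle controls.

A consistent relabeling of voxels (label shuffle) cannot change any
covariance eigenvalue — it only scrambles where the activation pattern lives.
Shuffling labels independently at every timepoint (point-wise shuffle)
destroys cross-voxel covariance and collapses the leading eigenvalue toward
the chance level 100 / n_voxels.
"""

import numpy as np

import freqness as fn

spec = fn.default_two_network_spec(seed=3, n_voxels=100, duration_s=40.0)
broad, _ = fn.simulate_dataset(spec)
kernel = fn.design_gaussian_kernel(10.8, 1.0, broad.n_samples, broad.sampling_rate)
narrow = fn.narrowband_filter(broad, kernel)


def top_pct(b, n):
    pair = fn.compute_covariances(b, n)
    lam, _ = fn.solve_ged(pair)
    return fn.normalize_eigenvalues(lam)[0]


original = top_pct(broad, narrow)
label_b, label_n = fn.label_shuffle(broad, narrow, seed=1)
labeled = top_pct(label_b, label_n)
pw_b, pw_n = fn.pointwise_label_shuffle(broad, narrow, seed=1)
pointwise = top_pct(pw_b, pw_n)

print(f"top normalized eigenvalue at 10.8 Hz, original data:   {original:7.3f}%")
print(f"after consistent label shuffle (spatial control):      {labeled:7.3f}%")
print(f"after point-wise label shuffle (temporal control):     {pointwise:7.3f}%")
print(f"chance level 100 / n_voxels:                           {100.0 / broad.n_voxels:7.3f}%")
print(
    "\nThe label shuffle leaves the eigenvalue untouched (identical spectra,\n"
    "permuted patterns); the point-wise shuffle collapses it toward chance,\n"
    "showing the estimate rests on genuine spatio-temporal covariance."
)
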