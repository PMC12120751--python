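"""Scan a synthetic recording and locate its frequency-specific networks.

Simulates 200 voxels / 120 s with two planted narrowband networks (10.8 and
16.8 Hz blobs over a 1/f background), scans a small frequency grid with the
narrowband-vs-broadband generalized eigendecomposition, and reports where the
eigenspectrum peaks and how well the recovered patterns match the planted
loadings.
"""

import numpy as np

import freqness as fn
from freqness.datamodel import FrequencyGrid

spec = fn.default_two_network_spec(seed=7)
dataset, truth = fn.simulate_dataset(spec)

centers = np.array([6.0, 8.4, 10.8, 13.2, 16.8, 20.4, 24.0])
grid = FrequencyGrid(
    centers=centers,
    fwhms=np.array([fn.fwhm_schedule(c) for c in centers]),
    stimulation_frequency=2.4,
)
landscape = fn.scan_frequencies(dataset, grid, n_keep=3)

print("top normalized eigenvalue (percent of total variance) per frequency:")
top = landscape.select(component=1).sort_values("frequency_hz")
for _, row in top.iterrows():
    bar = "#" * int(row.eigenvalue_pct)
    print(f"  {row.frequency_hz:5.1f} Hz  {row.eigenvalue_pct:6.2f}%  {bar}")

for i, net in enumerate(spec.networks):
    key = (dataset.subject_id, dataset.condition, net.center_frequency, 1)
    pattern = landscape.patterns[key]
    r = np.corrcoef(pattern, truth["loadings"][i])[0, 1]
    n_active = fn.threshold_pattern_for_display(pattern).sum()
    print(
        f"network at {net.center_frequency} Hz: pattern-loading correlation "
        f"r = {r:.3f}; {n_active} voxels above mean + 1 SD"
    )
print(
    "\nA large eigenvalue peak at a planted frequency means the generalized\n"
    "eigendecomposition found a spatial filter concentrating that narrowband\n"
    "activity; the pattern correlation shows the filter's forward projection\n"
    "recovers the planted spatial loading."
)
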