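"""Paired group inference on network landscapes.

Simulates a small paired cohort in which the stimulation-like condition adds
a 2.4 Hz network, scans both conditions per subject, and contrasts the
normalized eigenvalues with paired Wilcoxon signed-rank tests plus FDR.  A
cluster-based permutation test on synthetic group differences shows the
complementary correction for contiguous frequency effects.
"""

import numpy as np

import freqness as fn
from freqness.simulate import (
    ConditionEffect, PlantedNetwork, gaussian_blob_loading,
    make_lattice_coordinates, simulate_group, simulate_group_differences,
)

base = fn.default_two_network_spec(seed=0, n_voxels=60, duration_s=30.0)
coords = make_lattice_coordinates(60)
effect = ConditionEffect(
    added_network=PlantedNetwork(
        loading=gaussian_blob_loading(coords, coords.mean(axis=0), 12.0),
        center_frequency=2.4, bandwidth=0.3, amplitude=2.0,
    )
)
group = simulate_group(base, n_subjects=8, condition_effect=effect, seed=1)

from freqness.datamodel import FrequencyGrid, Landscape

centers = np.array([1.2, 2.4, 3.6, 10.8, 16.8, 24.0])
grid = FrequencyGrid(centers=centers, fwhms=np.array([fn.fwhm_schedule(c) for c in centers]))

per_condition = {"RS": Landscape(), "PL": Landscape()}
for record in group:
    for condition in ("RS", "PL"):
        part = fn.scan_frequencies(record[condition], grid, n_keep=2,
                                   store_patterns=False, store_filters=False)
        per_condition[condition].merge(part)

table = fn.landscape_contrast(per_condition["PL"], per_condition["RS"], components=[1, 2])
print("PL vs RS eigenvalue contrast (component 1):")
for _, row in table[table.component == 1].iterrows():
    mark = " *" if row.significant else ""
    print(f"  {row.frequency_hz:5.1f} Hz  z = {row.z:+5.2f}  p_fdr = {row.p_fdr:.4f}{mark}")
print("Positive significant z at 2.4 Hz = the added stimulation network emerging in PL.\n")

diffs = simulate_group_differences(
    n_subjects=26, n_bins=40, effect_bins=range(18, 22), effect_size=1.0, seed=5
)
clusters, _ = fn.cluster_permutation(diffs, n_perm=1000, seed=2)
for c in clusters:
    print(
        f"cluster over bins {c.member_bins.min()}..{c.member_bins.max()} "
        f"(|z| sum = {c.cluster_stat:.1f}): p = {c.p_cluster:.4f}"
    )
print("The planted 4-bin contiguous effect survives the max-cluster permutation null.")
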