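# freqness

**Frequency-resolved brain-network estimation via source separation** for
voxel-space M/EEG time series.

Given a broadband source-reconstructed recording — a `voxels x time` matrix
per subject and condition — the package asks, for every frequency on a scan
grid: *which weighted combination of voxels behaves as a coherent network at
this frequency, and how much variance does it explain?*  It answers with a
generalized eigendecomposition (GED) contrasting narrowband against
broadband covariance:

```
S w = lambda R w,    S = X_narrow X_narrow^T,   R = X_broad X_broad^T
```

where `X_narrow` is the data filtered with a Gaussian frequency-domain
kernel centered on the scan frequency.  Eigenvectors `w` are spatial filters
maximizing the narrow-to-broad variance ratio; eigenvalues, normalized to
percent of total variance, traced over an 86-frequency grid (0.2–97.6 Hz
band, 1.2 Hz steps above a 2.4 Hz stimulation frequency) form the
*eigenspectrum*, and the forward projections `a = |S w|` are the *spatial
activation patterns* — together, the network landscape.  On top of that the
package provides:

* network time series `y = w^T X_broad` and a PCA backend for comparison;
* phase-amplitude cross-frequency coupling between estimated networks
  (36 phase bins of 10°, one-cycle sine fit; its amplitude is the
  modulation strength);
* the two shuffle controls that dissociate spatial from temporal structure
  (consistent vs. per-timepoint voxel relabeling), plus a matrix-free
  chance-level measurement at full source-grid scale (3559 voxels);
* paired group statistics: Wilcoxon signed-rank (Edgeworth-refined normal
  approximation, exact-enumeration oracle for small n), Benjamini–Hochberg
  FDR, cluster-based permutation with a max-cluster Monte-Carlo null;
* a synthetic-data generator planting frequency-specific networks, 1/f
  background and controllable coupling, with full ground truth — every
  pipeline stage is testable without any external recording.

It is intended for computational neuroscientists analyzing source-space
MEG/EEG rhythms and for methodologists studying covariance-based source
separation.  See `docs/methods.md` for the full model description and
numerical choices.

## Worked example

`examples/scan_landscape.py` simulates 200 voxels / 120 s with two planted
narrowband networks over a 1/f background, scans a small grid and prints:

```
top normalized eigenvalue (percent of total variance) per frequency:
    6.0 Hz    2.30%  ##
    8.4 Hz    1.86%  #
   10.8 Hz   26.03%  ##########################
   13.2 Hz    1.56%  #
   16.8 Hz   24.40%  ########################
   20.4 Hz    1.33%  #
   24.0 Hz    1.24%  #
network at 10.8 Hz: pattern-loading correlation r = 1.000; 35 voxels above mean + 1 SD
network at 16.8 Hz: pattern-loading correlation r = 1.000; 30 voxels above mean + 1 SD
```

The eigenspectrum peaks exactly at the planted frequencies — the GED filter
concentrates each network's narrowband variance — and the activation
patterns reproduce the planted spatial loadings.  The other examples cover
coupling (`cross_frequency_coupling.py`), the shuffle controls
(`randomization_controls.py`: a label shuffle leaves the 44.0 % eigenvalue
untouched, the point-wise shuffle collapses it to 3.2 %, near the 1 %
chance floor) and group inference (`group_statistics.py`).

The same operations are scriptable from the shell:

```
freqness simulate --out data.h5 --seed 1
freqness scan --in data.h5 --out landscape.h5
freqness cfc --in data.h5 --landscape landscape.h5 --modulator-freq 2.4 --out cfc.tsv
freqness run --config pipeline.yaml        # simulate -> scan -> stats, with manifest
```

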