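# Methods

## The estimation problem

Source-reconstructed M/EEG gives one broadband time series per brain voxel —
a matrix `X_broad` of shape `n_voxels x n_samples` per subject and condition.
The question this package answers is: *which weighted combinations of voxels
behave as coherent networks at each frequency, and how much of the signal's
variance do they explain?*  Volume conduction, the 1/f aperiodic background
and the sheer dimensionality (thousands of voxels) make per-voxel spectral
analysis uninformative; instead the package contrasts narrowband against
broadband covariance structure.

## Generalized eigendecomposition (GED)

For each scan frequency `f`:

1. `X_narrow = F^-1( G_f . F(X_broad) )` — each voxel row is filtered by
   element-wise multiplication of its full-length FFT with a Gaussian gain
   `G_f(nu) = exp(-4 ln2 (|nu| - f)^2 / w^2)`, mirrored over negative
   frequencies (real output) and peak-normalized to 1 at the bin nearest
   `f`.  No windowing or segmentation: the transform covers the whole
   recording, so the frequency resolution is `1/duration`.
2. Covariances as raw cross-products of row-mean-centered data:
   `S = X_narrow X_narrow^T`, `R = X_broad X_broad^T` (no `1/(T-1)`;
   normalized eigenvalues are scale-invariant, raw eigenvalues are documented
   as unscaled).  Diagonal regularization: `S += 1e-6 I`,
   `R += 0.01 (trace(R)/n) I` (1 % of R's average eigenvalue, computed as
   trace/n so no pre-decomposition is needed).
3. Solve `S w = lambda R w` (`scipy.linalg.eigh` on the symmetric-definite
   pencil).  Eigenvalues are sorted descending and expressed as percent of
   total variance, `100 lambda_i / sum_j lambda_j`.  Filter columns are
   normalized to unit Euclidean length, and signs fixed so the
   largest-magnitude entry of each activation pattern is positive
   (reproducible across eigensolver implementations; the patterns are
   absolute-valued anyway, only time-series polarity is affected).
4. Products per component: the *network activation time series*
   `y = w^T X_broad` (on centered broadband data) and the *spatial
   activation pattern* `a = |S w| / max|S w|`, in [0, 1].  For display, a
   pattern is thresholded at `mean + 1 sample SD` over voxels.

The top `n_keep = 10` components per frequency (configurable) enter the
landscape; the eigenvalue normalization always uses the full spectrum.  `R`
is computed once per subject/condition and reused across frequencies.  A PCA
backend (`pca_decomposition`) eigendecomposes `S` alone — algebraically GED
with `R = I` — with identical downstream products, so the two backends are
directly comparable.

Normalization choice: it is the *generalized* eigenvalues that are
normalized to percent (`lambda / sum lambda`), not the component variances.
Absolute percentages depend on this choice; the shape of the eigenspectrum
does not.

## The frequency grid

The default grid anchors on a 2.4 Hz stimulation frequency: six centers
below it (an ascending series anchored at 0.2 Hz with step 0.2 Hz, i.e.
0.2–1.2 Hz; the placement is configurable because no single arithmetic rule
reproduces every printed property of the reference grid), the stimulation
frequency itself, and `2.4 + 1.2 k` Hz while at or below the `f_max = 97.6`
Hz ceiling.  That yields 86 centers whose maximum is 97.2 Hz — the largest
1.2 Hz lattice point under the ceiling; the package treats the count (86),
the lower endpoint (0.2 Hz) and the 1.2 Hz step as the defining constraints.
Every second center at or above 2.4 Hz is an integer multiple of it
(harmonics interleaved with off-harmonics).

Filter bandwidth follows a log10-linear schedule
`fwhm(f) = 0.3 Hz * (f / 2.4)^s` with slope `s = 1` by default (constant
relative bandwidth, the usual wavelet convention), anchored at 0.3 Hz FWHM
for the 2.4 Hz kernel.  `s = 0` gives constant absolute bandwidth.

## Cross-frequency coupling

Network-level phase-amplitude coupling: the modulator is a low-frequency
component's time series, narrowband filtered with the same kernel used for
its estimation and Hilbert-transformed; its instantaneous phase is split
into 36 left-closed bins of 10 degrees starting at -180.  Each carrier (the
first component of every higher grid frequency, by default) contributes an
instantaneous power series (squared analytic magnitude); the mean power per
phase bin forms the modulation profile, and the amplitude of the one-cycle
sine `A sin(theta + phi) + c` fitted to the profile is the modulation
strength.  With the period fixed, the fit is linear — a closed-form
projection onto the sin/cos/constant basis — so it is deterministic and
exactly equals the optimum an iterative fitter would find.

Numerical choices: one second is discarded at each edge before binning
(filter/Hilbert transients); empty bins (possible only on short recordings)
are filled by circular interpolation and reported, with an error above 25 %
empty; carrier power is used raw, so strengths carry carrier power units —
paired contrasts within frequency cancel the units, and the
`relative_strength` property (amplitude / offset) provides the
power-normalized depth for comparisons *across* carriers.

## Randomization controls

* **Label shuffle** — one voxel permutation applied to all time points (and
  to coordinates).  It commutes with per-voxel filtering and leaves every
  eigenvalue exactly invariant while permuting pattern entries: the spatial
  control.
* **Point-wise label shuffle** — an independent permutation at every time
  sample, shared between the broadband and narrowband matrices of a pair.
  Column-wise moments are preserved exactly, cross-voxel covariance is
  destroyed, and the leading normalized eigenvalue collapses toward
  `100 / n_voxels`: the temporal control.

Both operate on already-filtered data (re-filtering after a point-wise
shuffle would smear the randomization).

## Chance level at full scale

The expected top normalized eigenvalue under point-wise randomization is
measured on a seeded white-Gaussian surrogate at the full source-grid scale
(3559 voxels, 5 min at 250 Hz), at an even 10-frequency subsample of the
grid.  Following the procedure's placement of the randomization *after*
filtering of the narrowband data, the shuffle is applied to the narrowband
matrix and the broadband reference covariance comes from the unshuffled
surrogate (which also lets one implicit `R` serve all frequencies).

Dense covariances at that scale are out of reach (~1e15 flops), so this path
is matrix-free: `S` and `R` act as operators `X (X^T v)` on float32 data;
the leading generalized eigenvalue comes from LOBPCG (block size 2, a fixed
30-iteration budget with an unreachable tolerance; the narrowband matrix is
rescaled to unit variance first so absolute residual tolerances are
meaningful across frequencies), and the normalization
`sum lambda = trace(R^-1 S)` from a Hutchinson estimator (3 Rademacher
probes, conjugate-gradient solves against `R`; relative standard error about
`sqrt(2 / (m n))` ~ 1 %).  The small-scale agreement of this route with the
dense solver is part of the test suite.  The measured chance level is ~0.05 %
per frequency — the `100/3559 = 0.028 %` floor inflated by the sampling
spread of a covariance estimated from finitely many samples, consistent with
the largest-root edge of an F-matrix at these aspect ratios.

## Group statistics

Paired Wilcoxon signed-rank tests per (frequency, component) cell — two-tailed
for eigenvalue contrasts (networks may emerge or be suppressed), right-tailed
for modulation strengths (coupling is hypothesized to increase under
stimulation).  Zeros are dropped and ties mid-ranked.  The p-value uses a
continuity-corrected normal approximation refined with an Edgeworth
fourth-cumulant term: the signed-rank null is platykurtic
(`kappa4 = -sum r^4 / 8`), and the plain normal approximation is off by up
to ~0.02 in p at n = 8 while the refined tail stays within ~0.003 of exact
enumeration (an exact-enumeration oracle for n <= 20 ships with the package
and backs the tests).  The reported z is signed: positive means the first
condition exceeds the second.

Multiple comparisons: Benjamini–Hochberg FDR (statsmodels), applied jointly
across all cells of one contrast.  Complementarily, a cluster-based
permutation test groups contiguous frequency bins whose per-bin p falls
below a forming threshold (default 0.05, configurable — a knob, not a claim
about any published setting), sums |z| over members, and compares against
the Monte-Carlo null of the maximum cluster statistic under random
within-subject condition flips (`p = (1 + #null >= obs) / (n_perm + 1)`;
since sign flips leave |difference| ranks untouched, the null is computed by
re-signing precomputed ranks, which makes thousands of permutations cheap).

## Synthetic data

`simulate_dataset` builds `X = sum_k loading_k s_k(t) + B(t) + E(t)`:

* **Networks** — Gaussian spatial blobs (unit max) on an axis-aligned 8 mm
  lattice; sources are Gaussian-filtered white noise at (center, bandwidth),
  scaled to a target RMS — filtered noise rather than pure sinusoids so the
  Hilbert phase is non-degenerate and coupling is realistic.
* **Background** — per-voxel independent `1/f^beta` noise (spectral shaping,
  beta = 1 by default) at RMS 1, plus white noise at RMS 0.5.
* **PAC** — the carrier source is multiplied by
  `(1 + kappa sin(phi_mod)) / (1 + kappa)`; the normalization keeps mean
  carrier power approximately depth-invariant, isolating coupling from power.
* Identical spec + seed gives bit-identical data.

Default conditions: 200 voxels, 120 s at 250 Hz; source RMS twice the
background RMS (the planted networks sit at grid centers 10.8 and 16.8 Hz);
the coupling scenario uses 48 voxels / 60 s with a 2.4 Hz modulator and a
40.8 Hz carrier.  Group simulations share loadings within subject across
paired conditions, jitter amplitudes (log-normal, sigma 0.1) and loadings
(additive, sigma 0.02) across subjects, and apply the condition effect
(added network, amplitude scaling, coupling-depth change) to the
stimulation-like condition only.  `simulate_group_differences` is a
group-level shortcut (unit-variance Gaussian paired differences with a mean
shift at chosen bins) used to calibrate the statistics without running the
full pipeline per subject.

What the generator does *not* emulate — and hence what passing tests do not
show about real recordings: no leadfield or beamformer, so no volume
conduction, source leakage or depth bias; background noise is independent
across voxels (real aperiodic activity is spatially correlated); sources are
stationary; no artifacts, head movement or sensor noise structure.  Recovery
correlations near 1.0 here are an upper bound, not a field expectation.

## Problem sizes in the test suite

Checks run at the scale that defines them: the chance-level collapse at the
full 3559 x 75,000 surrogate (10 grid frequencies), parameter recovery at
the 200-voxel / 120 s default over the full 86-bin grid, coupling recovery
at 48 voxels / 60 s over 10 seeds and five depths, statistics calibration at
n = 26 subjects with 100 null replicates and 20 power replicates.  Unit and
property tests use smaller fixtures (tens of voxels, tens of seconds).

## Known limitations

* Normalized eigenvalues are compositional (sum to 100): planting a new
  network *depresses* other components' percentages, so paired contrasts can
  show mirrored negative effects at unrelated frequencies.
* The FFT-domain filter assumes the whole recording is one stationary
  segment; edge transients are handled only by the coupling module's guard.
* The matrix-free chance-level path trades ~1 % accuracy (solver budget,
  trace probes) for tractability; it is for large-n surrogates, not a
  replacement for the dense solver at analysis scale.
* `wilcoxon_exact_p` enumerates `2^n` sign patterns and is limited to
  n <= 20.
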