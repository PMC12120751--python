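"""Group-level inference on landscapes and modulation strengths.

Paired Wilcoxon signed-rank tests per (frequency, component) cell, jointly
FDR-corrected (Benjamini-Hochberg), plus a cluster-based permutation test over
contiguous frequency bins with a Monte-Carlo max-cluster-statistic null.

The signed-rank z follows the convention that a positive z means the first
condition exceeds the second (median difference > 0), so with PL-vs-RS input a
positive z reads as the emergence of a frequency-resolved network under
stimulation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .datamodel import Landscape
from .errors import DataError

__all__ = [
    "GroupStatResult",
    "ClusterResult",
    "wilcoxon_signed_rank",
    "wilcoxon_exact_p",
    "fdr_bh",
    "cluster_permutation",
    "landscape_contrast",
    "modulation_contrast",
]


@dataclass
class GroupStatResult:
    """One (frequency, component) cell of a group contrast."""

    frequency: float
    component: int
    statistic: float  # signed-rank z
    p_raw: float
    p_adjusted: float
    tail: str
    significant: bool


@dataclass
class ClusterResult:
    """Contiguous set of frequency bins surviving the cluster-forming threshold."""

    member_bins: np.ndarray  # indices into the frequency axis, contiguous
    cluster_stat: float  # sum of |z| over members
    p_cluster: float

    @property
    def size(self) -> int:
        return len(self.member_bins)


def _rank_moments(ranks: np.ndarray) -> tuple[float, float, float]:
    """Null mean, SD and excess-kurtosis coefficient of W+ for given midranks.

    W+ = sum r_i B_i with B_i iid Bernoulli(1/2), so kappa2 = sum r^2 / 4
    (this form is automatically tie-corrected) and kappa4 = -sum r^4 / 8.
    """
    mean = ranks.sum() / 2.0
    kappa2 = (ranks**2).sum() / 4.0
    kappa4 = -((ranks**4).sum()) / 8.0
    gamma2 = kappa4 / kappa2**2 if kappa2 > 0 else 0.0
    return mean, float(np.sqrt(kappa2)), gamma2


def _edgeworth_sf(z: np.ndarray, gamma2: float) -> np.ndarray:
    """Upper tail of the standardized null with a fourth-cumulant correction."""
    sf = norm.sf(z) + norm.pdf(z) * (gamma2 / 24.0) * (z**3 - 3.0 * z)
    return np.clip(sf, 0.0, 1.0)


def _signed_rank_z_p(
    w_plus: np.ndarray, mean: float, sd: float, gamma2: float, tail: str
) -> tuple[np.ndarray, np.ndarray]:
    """Continuity-corrected z and Edgeworth-refined p for (arrays of) W+."""
    delta = np.asarray(w_plus, dtype=float) - mean
    z = np.where(delta != 0, (delta - 0.5 * np.sign(delta)) / sd, 0.0)
    if tail == "two":
        z_two = np.maximum(np.abs(delta) - 0.5, 0.0) / sd
        p = np.minimum(2.0 * _edgeworth_sf(z_two, gamma2), 1.0)
    else:
        p = _edgeworth_sf((delta - 0.5) / sd, gamma2)
    return z, p


def wilcoxon_signed_rank(diffs: np.ndarray, tail: str = "two") -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test via a refined normal approximation.

    Zero differences are dropped, ties mid-ranked, a 0.5 continuity
    correction applied, and the normal tail carries an Edgeworth
    fourth-cumulant term (the signed-rank null is platykurtic; the plain
    normal approximation is off by up to ~0.02 in p at n = 8, the refined one
    by ~0.003).  Returns ``(z, p)``; z is signed, positive when positive
    differences dominate.  ``tail`` is ``"two"`` or ``"right"``.
    """
    if tail not in ("two", "right"):
        raise DataError(f"unknown tail {tail!r}")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0
    if n < 5:
        warnings.warn(f"only {n} non-zero differences; approximation is crude", stacklevel=2)
    ranks = rankdata(np.abs(d))
    mean, sd, gamma2 = _rank_moments(ranks)
    if sd == 0:
        return 0.0, 1.0
    w_plus = ranks[d > 0].sum()
    z, p = _signed_rank_z_p(np.array(w_plus), mean, sd, gamma2, tail)
    return float(z), float(p)


def wilcoxon_exact_p(diffs: np.ndarray, tail: str = "two") -> float:
    """Exact signed-rank p by enumerating all sign assignments (n <= 20)."""
    if tail not in ("two", "right"):
        raise DataError(f"unknown tail {tail!r}")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    if n > 20:
        raise DataError("exact enumeration limited to n <= 20")
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    w_null = np.array(
        [sum(itertools.compress(ranks, signs)) for signs in itertools.product((0, 1), repeat=n)]
    )
    if tail == "right":
        p = np.mean(w_null >= w_obs)
    else:
        p = np.mean(np.abs(w_null - mean) >= abs(w_obs - mean))
    return float(min(p, 1.0))


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (adjusted p, significance mask)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def cluster_permutation(
    per_subject_values: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster_forming: float = 0.05,
    seed: int | None = None,
    tail: str = "two",
) -> tuple[list[ClusterResult], np.ndarray]:
    """Cluster-based permutation test over contiguous frequency bins.

    ``per_subject_values`` is a ``subjects x frequencies`` matrix of paired
    condition differences.  Per bin a Wilcoxon signed-rank z is computed; bins
    with p below the forming threshold are grouped into contiguous clusters
    whose statistic is the sum of |z|.  The null distribution of the maximum
    cluster statistic comes from ``n_perm`` random within-subject condition
    label flips (global sign flips of each subject's difference row), and
    ``p_cluster = (1 + #null >= observed) / (n_perm + 1)``.

    Returns ``(clusters, per_bin_z)``.
    """
    values = np.asarray(per_subject_values, dtype=float)
    if values.ndim != 2:
        raise DataError("expected a subjects x frequencies matrix")
    if n_perm < 1000:
        warnings.warn(f"n_perm={n_perm} < 1000; cluster p-values will be coarse", stacklevel=2)
    n_subjects, n_bins = values.shape
    rng = np.random.default_rng(seed)

    def _per_bin(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = np.empty(n_bins)
        p = np.empty(n_bins)
        for b in range(n_bins):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                z[b], p[b] = wilcoxon_signed_rank(vals[:, b], tail=tail)
        return z, p

    def _clusters(mask: np.ndarray, z: np.ndarray) -> list[tuple[np.ndarray, float]]:
        found = []
        b = 0
        while b < n_bins:
            if mask[b]:
                start = b
                while b < n_bins and mask[b]:
                    b += 1
                members = np.arange(start, b)
                found.append((members, float(np.abs(z[members]).sum())))
            else:
                b += 1
        return found

    z_obs, p_obs = _per_bin(values)
    observed = _clusters(p_obs < alpha_cluster_forming, z_obs)
    if not observed:
        return [], z_obs

    # Sign flips leave |d| (hence the ranks) untouched, so the permutation
    # null reduces to re-signing precomputed ranks: W+ = sum of ranks where
    # the flipped difference is positive.
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subjects))
    z_null = np.zeros((n_perm, n_bins))
    p_null = np.ones((n_perm, n_bins))
    for b in range(n_bins):
        d = values[:, b]
        nz = d != 0
        if not nz.any():
            continue
        ranks = rankdata(np.abs(d[nz]))
        mean, sd, gamma2 = _rank_moments(ranks)
        if sd == 0:
            continue
        positive = (flips[:, nz] * d[nz]) > 0  # n_perm x n
        w_plus = positive @ ranks
        z_null[:, b], p_null[:, b] = _signed_rank_z_p(w_plus, mean, sd, gamma2, tail)

    null_max = np.zeros(n_perm)
    marked = p_null < alpha_cluster_forming
    for i in range(n_perm):
        perm_clusters = _clusters(marked[i], z_null[i])
        if perm_clusters:
            null_max[i] = max(stat for _, stat in perm_clusters)

    results = []
    for members, stat in observed:
        p_cluster = (1.0 + np.sum(null_max >= stat)) / (n_perm + 1.0)
        results.append(ClusterResult(member_bins=members, cluster_stat=stat, p_cluster=float(p_cluster)))
    return results, z_obs


def _paired_table_contrast(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    key_cols: list[str],
    value_col: str,
    tail: str,
    q: float,
) -> pd.DataFrame:
    subj_a = set(table_a["subject"])
    subj_b = set(table_b["subject"])
    if subj_a != subj_b:
        missing = sorted(subj_a.symmetric_difference(subj_b))
        raise DataError(f"subject sets differ between conditions; unmatched: {missing}")
    merged = table_a.merge(
        table_b, on=["subject"] + key_cols, suffixes=("_a", "_b"), validate="one_to_one"
    )
    rows = []
    for keys, grp in merged.groupby(key_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        diffs = (grp[f"{value_col}_a"] - grp[f"{value_col}_b"]).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z, p = wilcoxon_signed_rank(diffs, tail=tail)
        rows.append(keys + (z, p))
    frame = pd.DataFrame(rows, columns=key_cols + ["z", "p_raw"])
    frame["p_fdr"], frame["significant"] = fdr_bh(frame["p_raw"].to_numpy(), q)
    frame["tail"] = tail
    return frame


def landscape_contrast(
    landscape_a: Landscape,
    landscape_b: Landscape,
    components: range | list[int] = range(1, 11),
    tail: str = "two",
    q: float = 0.05,
) -> pd.DataFrame:
    """Paired Wilcoxon contrast of normalized eigenvalues (A minus B).

    One test per (frequency, component) cell, FDR-corrected jointly across all
    tested cells.  Returns a table with columns
    frequency_hz, component, z, p_raw, p_fdr, significant, tail.
    """
    comps = list(components)
    table_a = landscape_a.eigenvalues.query("component in @comps")
    table_b = landscape_b.eigenvalues.query("component in @comps")
    return _paired_table_contrast(
        table_a.drop(columns="condition"),
        table_b.drop(columns="condition"),
        ["frequency_hz", "component"],
        "eigenvalue_pct",
        tail,
        q,
    )


def modulation_contrast(
    strengths_a: pd.DataFrame,
    strengths_b: pd.DataFrame,
    tail: str = "right",
    q: float = 0.05,
) -> pd.DataFrame:
    """Paired contrast of modulation strengths per carrier frequency.

    Inputs are tidy tables with columns (subject, carrier_freq_hz, strength),
    one row per subject and carrier.  Right-tailed by default (coupling is
    hypothesized to increase, not decrease, under stimulation).
    """
    for name, tbl in (("A", strengths_a), ("B", strengths_b)):
        missing = {"subject", "carrier_freq_hz", "strength"} - set(tbl.columns)
        if missing:
            raise DataError(f"table {name} lacks columns {sorted(missing)}")
    return _paired_table_contrast(
        strengths_a, strengths_b, ["carrier_freq_hz"], "strength", tail, q
    )
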