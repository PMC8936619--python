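"""Group-level statistics for coupling maps.

Voxelwise paired t tests of empirical against chance PLV, a cluster-based
permutation test with max-statistic family-wise-error control, paired
Cohen's d (t / sqrt(n)) with bootstrap variability, and frequency-domain
shared variance (squared coherence at the gastric frequency).

For the paired empirical-vs-chance design, shuffling the condition labels
within a participant is exactly equivalent to flipping the sign of that
participant's difference map, which is how the permutation null is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

__all__ = [
    "Cluster",
    "ClusterSet",
    "EffectMaps",
    "paired_t_map",
    "cluster_permutation",
    "cohens_d_map",
    "bootstrap_d_sd",
    "shared_variance",
]


@dataclass
class Cluster:
    """One candidate cluster of supra-threshold connected voxels."""

    voxels: np.ndarray  # (k, 3) integer indices
    sign: int  # +1 or -1
    mass: float  # sum of t values over the cluster
    monte_carlo_p: float
    significant: bool


@dataclass
class ClusterSet:
    """Candidate clusters plus the permutation null they were scored on."""

    clusters: list[Cluster]
    null_max: np.ndarray  # per-permutation largest positive mass
    null_min: np.ndarray  # per-permutation smallest negative mass
    n_perm: int
    voxel_alpha: float
    cluster_alpha: float
    connectivity: int
    t_map: np.ndarray = field(default=None, repr=False)

    def significant_mask(self, shape=None, sign: int | None = +1) -> np.ndarray:
        """Boolean volume of voxels in significant clusters of one sign."""
        if shape is None:
            shape = self.t_map.shape
        out = np.zeros(shape, dtype=bool)
        for cl in self.clusters:
            if cl.significant and (sign is None or cl.sign == sign):
                out[tuple(cl.voxels.T)] = True
        return out


def _t_stats(diff_flat: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0, with +-inf markers for zero variance."""
    n = diff_flat.shape[0]
    mean = diff_flat.mean(axis=0)
    sd = diff_flat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    if np.any(zero_var):
        t[zero_var & (mean > 0)] = np.inf
        t[zero_var & (mean < 0)] = -np.inf
        t[zero_var & (mean == 0)] = np.nan
    return t


def paired_t_map(empirical: np.ndarray, chance: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t of (empirical - chance) across participants.

    Inputs are stacked per-participant volumes of shape (n, x, y, z) (or
    (n, voxels)).  Voxels with zero variance get +-inf (nonzero mean) or
    NaN (degenerate), with a warning.
    """
    empirical = np.asarray(empirical, dtype=float)
    chance = np.asarray(chance, dtype=float)
    if empirical.shape != chance.shape:
        raise ValueError("empirical and chance stacks must share a shape")
    n = empirical.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    diff = empirical - chance
    t = _t_stats(diff.reshape(n, -1)).reshape(diff.shape[1:])
    if not np.all(np.isfinite(t[~np.isnan(t)])):
        warnings.warn("zero-variance voxels marked with +-inf")
    return t


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _cluster_masses(t_vol, thresh, structure, positive: bool):
    above = (t_vol > thresh) if positive else (t_vol < -thresh)
    if not above.any():
        return [], None, 0
    labels, n = ndimage.label(above, structure=structure)
    masses = ndimage.sum_labels(t_vol, labels, index=np.arange(1, n + 1))
    return masses, labels, n


def cluster_permutation(
    diff: np.ndarray,
    mask: np.ndarray,
    voxel_alpha: float = 0.005,
    n_perm: int = 1000,
    cluster_alpha: float = 0.025,
    connectivity: int = 6,
    seed: int | None = None,
) -> ClusterSet:
    """Cluster-mass permutation test of per-participant difference maps.

    Candidate clusters are connected voxels whose one-sample t exceeds the
    one-sided ``voxel_alpha`` threshold (positively or negatively); each is
    scored by its summed t.  The null distribution records, per sign-flip
    permutation, the largest positive and smallest negative cluster mass
    anywhere in the volume, which intrinsically corrects for multiple
    comparisons.  Monte Carlo p = (1 + #{null >= mass}) / (n_perm + 1);
    clusters with p < ``cluster_alpha`` (one-sided per sign) are flagged
    significant.  When 2^n <= n_perm the sign flips are enumerated
    exhaustively instead of sampled.
    """
    diff = np.asarray(diff, dtype=float)
    n = diff.shape[0]
    mask = np.asarray(mask, dtype=bool)
    if diff.shape[1:] != mask.shape:
        raise ValueError("difference maps and mask must share the spatial grid")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value granularity")
    structure = _connectivity_structure(connectivity)
    tcrit = float(stats.t.ppf(1 - voxel_alpha, n - 1))

    flat = diff.reshape(n, -1)[:, mask.ravel()]
    sq_sum = np.sum(flat**2, axis=0)  # invariant under sign flips

    def t_from_signs(signs):
        mean = signs @ flat / n
        var = (sq_sum - n * mean**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        bad = ~np.isfinite(t)
        if bad.any():
            m = mean[bad]
            t[bad] = np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0))
        return t

    t_obs_flat = _t_stats(flat)
    t_vol = np.zeros(mask.shape)
    t_vol[mask] = np.nan_to_num(t_obs_flat, nan=0.0)

    # observed candidate clusters
    clusters: list[tuple[int, np.ndarray, float]] = []
    for sign in (+1, -1):
        masses, labels, ncl = _cluster_masses(t_vol, tcrit, structure, positive=sign > 0)
        for i in range(ncl):
            vox = np.argwhere(labels == i + 1)
            clusters.append((sign, vox, float(masses[i])))

    # permutation null of extreme cluster masses
    if 2**n <= n_perm:
        bits = np.arange(2**n)
        sign_mat = np.where((bits[:, None] >> np.arange(n)[None, :]) & 1, 1.0, -1.0)
    else:
        rng = np.random.default_rng(seed)
        sign_mat = rng.choice([-1.0, 1.0], size=(n_perm, n))
    n_eff = sign_mat.shape[0]

    null_max = np.zeros(n_eff)
    null_min = np.zeros(n_eff)
    for p in range(n_eff):
        t_p = t_from_signs(sign_mat[p])
        vol_p = np.zeros(mask.shape)
        vol_p[mask] = t_p
        pos, _, npos = _cluster_masses(vol_p, tcrit, structure, positive=True)
        neg, _, nneg = _cluster_masses(vol_p, tcrit, structure, positive=False)
        null_max[p] = np.max(pos) if npos else 0.0
        null_min[p] = np.min(neg) if nneg else 0.0

    out = []
    for sign, vox, mass in clusters:
        if sign > 0:
            exceed = int(np.sum(null_max >= mass))
        else:
            exceed = int(np.sum(null_min <= mass))
        p_mc = (1 + exceed) / (n_eff + 1)
        out.append(
            Cluster(voxels=vox, sign=sign, mass=mass, monte_carlo_p=p_mc, significant=p_mc < cluster_alpha)
        )
    return ClusterSet(
        clusters=out,
        null_max=null_max,
        null_min=null_min,
        n_perm=n_eff,
        voxel_alpha=voxel_alpha,
        cluster_alpha=cluster_alpha,
        connectivity=connectivity,
        t_map=t_vol,
    )


@dataclass
class EffectMaps:
    """Paired effect sizes: d = t / sqrt(n), with bootstrap variability."""

    d: np.ndarray
    d_boot_sd: np.ndarray
    n: int


def cohens_d_map(t_volume: np.ndarray, n: int) -> np.ndarray:
    """Paired Cohen's d from the t volume: d = t / sqrt(n), elementwise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.asarray(t_volume, dtype=float) / np.sqrt(n)


def bootstrap_d_sd(
    empirical: np.ndarray,
    chance: np.ndarray,
    summary_masks: list[np.ndarray],
    n_boot: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Bootstrap SD of the mean Cohen's d inside each summary mask.

    Participants are resampled with replacement ``n_boot`` times; for each
    resample the mean d over the mask voxels is computed, and the SD across
    resamples is returned (one value per mask).
    """
    empirical = np.asarray(empirical, dtype=float)
    chance = np.asarray(chance, dtype=float)
    n = empirical.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants to bootstrap")
    diff = (empirical - chance).reshape(n, -1)
    flat_masks = [np.asarray(m, dtype=bool).ravel() for m in summary_masks]
    rng = np.random.default_rng(seed)
    out = np.zeros((n_boot, len(flat_masks)))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        t = _t_stats(diff[idx])
        d = t / np.sqrt(n)
        for j, fm in enumerate(flat_masks):
            vals = d[fm]
            finite = vals[np.isfinite(vals)]
            if finite.size < vals.size and not finite.size:
                # degenerate mask: every voxel has zero variance
                out[b, j] = np.inf if np.all(vals > 0) else -np.inf
            else:
                out[b, j] = finite.mean() if finite.size else np.nan
    # identical resamples (e.g. identical participants) have zero spread
    # even when the summary itself is infinite
    sd = out.std(axis=0, ddof=1)
    constant = np.all(out == out[0:1], axis=0)
    sd[constant] = 0.0
    return sd


def shared_variance(
    egg: np.ndarray,
    roi_mean_bold: np.ndarray,
    f0: float,
    fs: float,
    window_s: float = 200.0,
    overlap_s: float = 150.0,
) -> float:
    """Squared coherence between EGG and ROI-mean BOLD at the gastric bin.

    The magnitude-squared coherence from Welch cross- and auto-spectra is
    evaluated at the frequency bin containing ``f0``; its value in [0, 1]
    is interpreted as the fraction of variance the two signals share at
    that frequency.  Welch settings default to the EGG spectral settings.
    """
    egg = np.asarray(egg, dtype=float)
    y = np.asarray(roi_mean_bold, dtype=float)
    if egg.size != y.size:
        raise ValueError("signals must have equal length")
    nperseg = int(window_s * fs)
    noverlap = int(overlap_s * fs)
    if egg.size < 2 * nperseg - noverlap:
        raise ValueError("signals shorter than two Welch windows")
    f, cxy = signal.coherence(egg, y, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    i = int(np.argmin(np.abs(f - f0)))
    _, pxx = signal.welch(egg, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    _, pyy = signal.welch(y, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    if pxx[i] == 0 or pyy[i] == 0:
        return float("nan")
    return float(cxy[i])
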