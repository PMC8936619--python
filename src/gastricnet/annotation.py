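"""Anatomical characterization of a significant-voxel mask.

Overlap of the mask with label volumes (resting-state networks or a fine
parcellation), nearest-neighbor resampling between grids, and profiles of
the mask along a continuous cortical-gradient map in one hundred
equidistant bins, with a random-relocation null (surrogate masks of the
same size drawn uniformly over the cortex).

The relocation null ignores the spatial autocorrelation of the mask; the
flags it produces are pointwise 5% tests under uniform placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GradientProfile",
    "parcel_overlap",
    "resample_nearest",
    "gradient_profile",
    "gradient_null",
]


def parcel_overlap(
    mask: np.ndarray,
    labels: np.ndarray,
    d_map: np.ndarray | None = None,
    label_names: dict | None = None,
) -> pd.DataFrame:
    """Two-way overlap between a voxel mask and a label volume.

    Per label: the percentage of the mask falling inside the label, the
    percentage of the label covered by the mask, and the mean effect size
    over the intersection.  Grids must already match (resample first).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(labels)
    if labels.shape != mask.shape or (d_map is not None and d_map.shape != mask.shape):
        raise ValueError("grids do not match; resample the volumes to a common grid first")
    n_mask = int(mask.sum())
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        in_label = labels == lab
        inter = mask & in_label
        n_inter = int(inter.sum())
        mean_d = float(np.nanmean(d_map[inter])) if (d_map is not None and n_inter) else np.nan
        rows.append(
            {
                "label_id": lab,
                "label_name": (label_names or {}).get(lab, str(lab)),
                "n_label": int(in_label.sum()),
                "n_overlap": n_inter,
                "pct_of_mask_in_label": 100.0 * n_inter / n_mask if n_mask else 0.0,
                "pct_of_label_in_mask": 100.0 * n_inter / int(in_label.sum()),
                "mean_d_in_overlap": mean_d,
            }
        )
    return pd.DataFrame(rows)


def resample_nearest(
    volume: np.ndarray,
    source_affine: np.ndarray,
    target_grid: tuple[int, int, int],
    target_affine: np.ndarray,
) -> np.ndarray:
    """Nearest-neighbor pull-back of a volume through world space.

    Each target voxel center is mapped to world mm and back into source
    voxel indices, rounded to the nearest voxel; labels and booleans are
    preserved exactly.  Out-of-bounds targets get 0.
    """
    volume = np.asarray(volume)
    try:
        inv_src = np.linalg.inv(np.asarray(source_affine, dtype=float))
    except np.linalg.LinAlgError as e:
        raise ValueError("source affine is not invertible") from e
    tgt = np.asarray(target_affine, dtype=float)
    ii, jj, kk = np.indices(target_grid)
    ones = np.ones_like(ii)
    idx = np.stack([ii, jj, kk, ones], axis=-1).reshape(-1, 4).T
    src = inv_src @ (tgt @ idx.astype(float))
    # half-up rounding: banker's rounding would split ties inconsistently
    src_idx = np.floor(src[:3] + 0.5).astype(int)
    inb = np.all((src_idx >= 0) & (src_idx < np.array(volume.shape)[:, None]), axis=0)
    out = np.zeros(int(np.prod(target_grid)), dtype=volume.dtype)
    out[inb] = volume[src_idx[0, inb], src_idx[1, inb], src_idx[2, inb]]
    return out.reshape(target_grid)


@dataclass
class GradientProfile:
    """Mask prevalence along a gradient map, binned over the cortex.

    ``pct_in_mask_per_bin`` holds, per bin, 100 x (mask voxels in the bin)
    / (cortex voxels in the bin); NaN where the bin is empty.  The null
    table and two-sided exceedance flags are filled by ``gradient_null``.
    """

    bin_edges: np.ndarray  # nbins + 1 values over the cortex gradient range
    pct_in_mask_per_bin: np.ndarray  # nbins values (%)
    cortex_per_bin: np.ndarray  # cortex voxel counts per bin
    mask_per_bin: np.ndarray  # mask voxel counts per bin
    null_pct: np.ndarray | None = None  # (n_perm, nbins)
    flags: np.ndarray | None = None  # bool per bin, outside [2.5, 97.5] envelope
    n_perm: int = 0

    @property
    def mask_size(self) -> int:
        return int(self.mask_per_bin.sum())


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # values exactly at an inner edge go to the higher bin; max to the last
    idx = np.digitize(values, edges[1:-1], right=False)
    return idx


def gradient_profile(
    mask: np.ndarray,
    gradient: np.ndarray,
    cortex_mask: np.ndarray,
    nbins: int = 100,
) -> GradientProfile:
    """Fraction of cortex voxels belonging to the mask per gradient bin.

    Bins are equidistant over the observed [min, max] of gradient values
    within the cortex mask, the last bin closed.
    """
    mask = np.asarray(mask, dtype=bool)
    cortex_mask = np.asarray(cortex_mask, dtype=bool)
    gradient = np.asarray(gradient, dtype=float)
    if not (mask.shape == cortex_mask.shape == gradient.shape):
        raise ValueError("mask, gradient and cortex_mask must share a grid")
    if np.any(mask & ~cortex_mask):
        raise ValueError("mask must be contained in cortex_mask")
    vals = gradient[cortex_mask]
    edges = np.linspace(vals.min(), vals.max(), nbins + 1)
    idx = _bin_index(vals, edges)
    cortex_per_bin = np.bincount(idx, minlength=nbins)
    mask_idx = _bin_index(gradient[mask], edges)
    mask_per_bin = np.bincount(mask_idx, minlength=nbins)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * mask_per_bin / cortex_per_bin
    pct[cortex_per_bin == 0] = np.nan
    return GradientProfile(
        bin_edges=edges,
        pct_in_mask_per_bin=pct,
        cortex_per_bin=cortex_per_bin,
        mask_per_bin=mask_per_bin,
    )


def gradient_null(
    profile: GradientProfile,
    gradient: np.ndarray,
    cortex_mask: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> GradientProfile:
    """Random-relocation null for a gradient profile.

    Each permutation draws ``mask_size`` cortex voxels uniformly without
    replacement and recomputes the per-bin percentages.  Empirical bins
    are flagged when they fall outside the null's [2.5, 97.5] percentile
    envelope; empty bins are excluded from the null and never flagged.
    """
    cortex_mask = np.asarray(cortex_mask, dtype=bool)
    gradient = np.asarray(gradient, dtype=float)
    n_cortex = int(cortex_mask.sum())
    mask_size = profile.mask_size
    if mask_size > n_cortex:
        raise ValueError("mask larger than the cortex")
    nbins = profile.pct_in_mask_per_bin.size
    idx = _bin_index(gradient[cortex_mask], profile.bin_edges)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, nbins))
    counts = profile.cortex_per_bin.astype(float)
    for p in range(n_perm):
        pick = rng.choice(n_cortex, size=mask_size, replace=False, shuffle=False)
        sel = np.bincount(idx[pick], minlength=nbins)
        with np.errstate(divide="ignore", invalid="ignore"):
            null[p] = 100.0 * sel / counts
    null[:, counts == 0] = np.nan
    lo = np.nanpercentile(null, 2.5, axis=0)
    hi = np.nanpercentile(null, 97.5, axis=0)
    emp = profile.pct_in_mask_per_bin
    flags = np.zeros(nbins, dtype=bool)
    ok = counts > 0
    flags[ok] = (emp[ok] < lo[ok]) | (emp[ok] > hi[ok])
    return GradientProfile(
        bin_edges=profile.bin_edges,
        pct_in_mask_per_bin=emp,
        cortex_per_bin=profile.cortex_per_bin,
        mask_per_bin=profile.mask_per_bin,
        null_pct=null,
        flags=flags,
        n_perm=n_perm,
    )
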