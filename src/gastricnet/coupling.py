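"""Gastric-BOLD phase locking and its cross-participant chance level.

The phase-locking value between a voxel and the gastric rhythm is the
modulus of the time-averaged unit phasor of their phase difference,

    PLV = | (1/T) sum_t exp(i (phi_voxel(t) - phi_gastric(t))) |,

which is 1 for any constant lag and tends to 0 for unrelated phases.
Because narrow-band signals are autocorrelated, the null expectation is
not the white-phase value sqrt(pi)/(2 sqrt(T)); instead, chance level is
estimated per voxel as the median PLV obtained by pairing one
participant's BOLD phases with every *other* participant's gastric
phase.  Coupling strength is the empirical PLV minus that chance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .bold import VolumeSeries

__all__ = [
    "PhaseSeries",
    "PLVMaps",
    "instantaneous_phase",
    "plv",
    "voxel_phases",
    "empirical_map",
    "chance_map",
    "coupling_maps",
]


@dataclass
class PhaseSeries:
    """An unwrapped instantaneous-phase sequence with its sampling rate."""

    phi: np.ndarray
    fs: float

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 1:
            raise ValueError("phi must be one-dimensional")

    @property
    def T(self) -> int:
        return self.phi.size


@dataclass
class PLVMaps:
    """Per-participant empirical, chance, and strength volumes."""

    empirical: np.ndarray
    chance: np.ndarray
    strength: np.ndarray
    n_surrogates: int

    def __post_init__(self):
        for name in ("empirical", "chance"):
            v = getattr(self, name)
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError(f"{name} PLV outside [0, 1]")
        if not np.allclose(
            self.strength, self.empirical - self.chance, equal_nan=True
        ):
            raise ValueError("strength must equal empirical - chance")


def instantaneous_phase(x: np.ndarray, fs: float = 1.0) -> PhaseSeries:
    """Unwrapped angle of the analytic signal (Hilbert transform).

    The caller is responsible for the input being narrow-band; broadband
    input yields a phase without physical meaning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("signal too short for an analytic phase")
    if not np.any(x):
        raise ValueError("phase undefined for an all-zero signal")
    return PhaseSeries(phi=np.unwrap(np.angle(signal.hilbert(x))), fs=fs)


def plv(a: PhaseSeries, b: PhaseSeries) -> float:
    """Phase-locking value between two equally long phase series.

    Wrapped phase differences are used, so unwrapping conventions cannot
    change the result.  Always in [0, 1]; symmetric in its arguments.
    """
    if a.T != b.T:
        raise ValueError(f"length mismatch: {a.T} vs {b.T}")
    return float(np.abs(np.mean(np.exp(1j * (a.phi - b.phi)))))


def voxel_phases(bold_nb: VolumeSeries) -> np.ndarray:
    """Hilbert phase per in-mask voxel, shape (n_mask_voxels, T)."""
    flat = bold_nb.data.reshape(-1, bold_nb.n_volumes)[bold_nb.mask.ravel()]
    return np.angle(signal.hilbert(flat, axis=1))


def _plv_rows(phases: np.ndarray, ref: np.ndarray) -> np.ndarray:
    return np.abs(np.mean(np.exp(1j * (phases - ref[None, :])), axis=1))


def empirical_map(bold_nb: VolumeSeries, egg_phase: PhaseSeries) -> np.ndarray:
    """Voxelwise PLV against the participant's own gastric phase.

    Out-of-mask voxels are set to NaN.
    """
    if bold_nb.n_volumes != egg_phase.T:
        raise ValueError(
            f"time axes not aligned: {bold_nb.n_volumes} volumes vs {egg_phase.T} phase samples"
        )
    phases = voxel_phases(bold_nb)
    out = np.full(bold_nb.mask.shape, np.nan)
    out[bold_nb.mask] = _plv_rows(phases, egg_phase.phi)
    return out


def chance_map(
    participant: int,
    cohort_eggs: list[PhaseSeries],
    bold_nb: VolumeSeries,
) -> np.ndarray:
    """Voxelwise median PLV against every other participant's gastric phase.

    The participant's BOLD stays filtered at their own gastric frequency;
    only the EGG phase is swapped, so the surrogates share the length,
    sampling rate, and frequency range of real gastric rhythms without the
    participant-specific frequency and phase.  Each other participant
    contributes exactly one surrogate, in cohort order, so the median is
    reproducible; an even surrogate count uses the mean of the two middle
    order statistics.  Mismatched lengths are truncated to the common
    minimum with a warning.
    """
    if len(cohort_eggs) < 3:
        raise ValueError("need a cohort of at least 3 for a surrogate distribution")
    others = [ps for i, ps in enumerate(cohort_eggs) if i != participant]
    t_min = min([bold_nb.n_volumes] + [ps.T for ps in others])
    if any(ps.T != t_min for ps in others) or bold_nb.n_volumes != t_min:
        import warnings

        warnings.warn(f"mismatched retained lengths; truncating all series to {t_min} samples")
    phases = voxel_phases(bold_nb)[:, :t_min]
    surro = np.stack([_plv_rows(phases, ps.phi[:t_min]) for ps in others])
    med = np.median(surro, axis=0)
    out = np.full(bold_nb.mask.shape, np.nan)
    out[bold_nb.mask] = med
    return out


def coupling_maps(
    participant: int,
    cohort_eggs: list[PhaseSeries],
    bold_nb: VolumeSeries,
) -> PLVMaps:
    """Empirical, chance, and strength maps for one participant."""
    emp = empirical_map(bold_nb, cohort_eggs[participant])
    cha = chance_map(participant, cohort_eggs, bold_nb)
    return PLVMaps(
        empirical=emp,
        chance=cha,
        strength=emp - cha,
        n_surrogates=len(cohort_eggs) - 1,
    )
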