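"""Synthetic cohort generator for gastric-BOLD coupling studies.

Produces multi-participant datasets (EGG, BOLD, ECG R-peaks, covariates)
with a *known, planted* coupling structure: a compact cluster of voxels
whose narrow-band BOLD signal holds a constant phase lag to the gastric
phase plus circular (von Mises) jitter.  Because the jitter concentration
``kappa`` fixes the long-run phase-locking value analytically
(PLV -> I1(kappa)/I0(kappa)), every downstream stage of the analysis has a
ground-truth surface to be validated against.

The simulated recordings mirror a typical resting-state protocol: a 900-s
scan sampled every 2 s (450 volumes), cutaneous EGG channels carrying a
participant-specific gastric rhythm inside the normogastric band
(0.033-0.066 Hz), and nuisance structure (polynomial drift, a shared
CSF-like signal, cardiac pulsation aliased by the 2-s TR, broadband noise).
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, special

from .bold import VolumeSeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "GastricSim",
    "make_ground_truth",
    "simulate_gastric_phase",
    "simulate_bold",
    "simulate_ibi",
    "simulate_cohort",
    "expected_plv",
    "iid_phase_plv_expectation",
]

# stream identifiers: one independent seed stream per participant per
# signal class, so adding participants never perturbs earlier ones
_STREAM_EGG = 0
_STREAM_BOLD = 1
_STREAM_IBI = 2
_STREAM_COV = 3


def _rng(master_seed: int, participant: int, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(participant, stream))
    return np.random.Generator(np.random.PCG64(ss))


def expected_plv(kappa: float) -> float:
    """Long-run PLV of a phase locked up to von Mises(0, kappa) jitter.

    The resultant length of a von Mises distribution is the ratio of
    modified Bessel functions I1(kappa)/I0(kappa).  Exponentially scaled
    Bessel functions keep the ratio finite for arbitrarily large kappa.
    """
    return float(special.i1e(kappa) / special.i0e(kappa))


def iid_phase_plv_expectation(n_samples: int) -> float:
    """E[PLV] for i.i.d. uniform phase differences with ``n_samples`` samples.

    The mean resultant length of T i.i.d. uniform unit phasors is
    sqrt(pi)/(2 sqrt(T)).  Applies to the white-phase construction only;
    narrow-band signals have fewer effective degrees of freedom.
    """
    return float(np.sqrt(np.pi) / (2.0 * np.sqrt(n_samples)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults encode the emulated protocol: 900-s scans, TR 2 s, EGG at
    10 Hz (after decimation from the raw amplifier rate), a 24x24x12 grid
    of 3-mm isotropic voxels, and per-participant gastric peak frequencies
    drawn uniformly from 0.041-0.057 Hz.
    """

    n_participants: int = 12
    duration_s: float = 900.0
    egg_fs: float = 10.0
    tr_s: float = 2.0
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_mm: float = 3.0
    f0_range: tuple[float, float] = (0.041, 0.057)
    #: Wiener phase-noise intensity in rad/sqrt(s).  0.2 yields a gastric
    #: cycle-length SD of ~3 s at 0.05 Hz (inverse-Gaussian passage-time
    #: SD = sigma / (2 pi f0^(3/2))), the scale seen in adult cohorts.
    phase_noise_sd: float = 0.2
    #: Circular concentration of the planted phase jitter.
    kappa: float = 2.0
    n_coupled_voxels: int = 200
    #: Planted phase lags vary linearly over this range across the region.
    delay_range: tuple[float, float] = (0.0, np.pi)
    gastric_amp: float = 1.0
    # nuisance amplitudes (arbitrary BOLD units)
    drift_amp: float = 1.0
    csf_amp: float = 1.0
    cardiac_amp: float = 0.5
    noise_sd: float = 1.0
    #: kept clear of the planted central region, as the fourth ventricle
    #: lies outside cortex; overlap would contaminate the CSF regressor
    #: with gastric-locked signal (voxel (1,1,1) at 3-mm voxels)
    csf_center_world: tuple[float, float, float] = (3.0, 3.0, 3.0)
    csf_sphere_diameter_mm: float = 9.0
    # EGG channel model
    n_egg_channels: int = 4
    egg_gain_uv: tuple[float, ...] = (30.0, 20.0, 12.0, 8.0)
    egg_harmonic_frac: float = 0.2
    egg_noise_sd_uv: float = 2.0
    #: physiological recordings extend this far beyond the scan on each side
    pad_s: float = 30.0
    # heart model
    mean_hr_bpm: float = 66.0
    hr_bpm_sd: float = 5.0
    lf_hz: float = 0.1
    hf_hz: float = 0.25
    lf_ibi_amp_s: float = 0.05
    hf_ibi_amp_s: float = 0.025
    ibi_noise_sd_s: float = 0.005
    # covariates: mean, sd per column; optional planted slope of a
    # covariate on the participant's expected coupling level
    covariate_spec: dict = field(
        default_factory=lambda: {
            "bmi": (21.0, 1.8),
            "anxiety": (33.0, 8.7),
            "time_of_day": (812.0, 150.0),
            "time_since_meal": (4.0, 2.0),
        }
    )
    covariate_slope: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.egg_fs <= 0 or self.tr_s <= 0:
            raise ValueError("duration_s, egg_fs and tr_s must be positive")
        if self.phase_noise_sd < 0:
            raise ValueError("phase_noise_sd must be >= 0")
        lo, hi = self.f0_range
        if not (0.033 <= lo <= hi <= 0.066):
            raise ValueError("f0_range must lie inside the normogastric band [0.033, 0.066] Hz")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.n_coupled_voxels > int(np.prod(self.grid_shape)):
            raise ValueError("coupled region larger than the grid")

    @property
    def n_volumes(self) -> int:
        return int(round(self.duration_s / self.tr_s))

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_mm] * 3 + [1.0])
        return a


@dataclass
class GroundTruth:
    """What was planted: where, with which lags, and how tightly locked."""

    coupled_mask: np.ndarray  # 3-D bool
    delay_map: np.ndarray  # 3-D float, rad (modulo 2 pi; 0 where uncoupled)
    kappa: float
    expected_plv: float

    def __post_init__(self):
        self.delay_map = np.mod(self.delay_map, 2 * np.pi)
        want = expected_plv(self.kappa)
        if not np.isclose(self.expected_plv, want, rtol=1e-9):
            raise ValueError("expected_plv must equal I1(kappa)/I0(kappa)")


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Plant a compact quasi-spherical region at the grid center.

    The ``n_coupled_voxels`` voxels closest to the grid center are coupled;
    their phase lags ramp linearly along x over ``delay_range``, emulating
    a region traversed by a travelling delay.
    """
    nx, ny, nz = config.grid_shape
    ii, jj, kk = np.indices(config.grid_shape)
    center = (np.array(config.grid_shape) - 1) / 2.0
    dist = np.sqrt((ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2)
    order = np.argsort(dist, axis=None, kind="stable")
    mask = np.zeros(config.grid_shape, dtype=bool)
    mask.flat[order[: config.n_coupled_voxels]] = True

    delay = np.zeros(config.grid_shape)
    xs = ii[mask].astype(float)
    lo, hi = config.delay_range
    if xs.max() > xs.min():
        delay[mask] = lo + (hi - lo) * (xs - xs.min()) / (xs.max() - xs.min())
    else:
        delay[mask] = lo
    return GroundTruth(
        coupled_mask=mask,
        delay_map=delay,
        kappa=config.kappa,
        expected_plv=expected_plv(config.kappa),
    )


@dataclass
class GastricSim:
    """One participant's simulated gastric rhythm and EGG recording."""

    f0: float  # Hz
    phase: np.ndarray  # unwrapped rad, at egg_fs, covering the padded record
    time_s: np.ndarray  # seconds; scan onset at t = 0, so the record starts at -pad_s
    egg: pd.DataFrame  # columns time_s, chan1..chanK (microvolts)


def simulate_gastric_phase(config: SimulationConfig, participant_index: int) -> GastricSim:
    """Gastric phase as Wiener-noise-perturbed rotation plus EGG voltages.

    The phase evolves as ``dphi = 2 pi f0 dt + sigma sqrt(dt) eps`` with
    ``eps ~ N(0,1)``; each EGG channel is ``A sin(phi)`` with a
    channel-specific gain, a second harmonic and broadband noise.
    """
    rng = _rng(config.seed, participant_index, _STREAM_EGG)
    lo, hi = config.f0_range
    f0 = float(rng.uniform(lo, hi))

    dt = 1.0 / config.egg_fs
    total_s = config.duration_s + 2 * config.pad_s
    n = int(round(total_s * config.egg_fs))
    if n * dt < 2 * 200.0 and config.duration_s >= 400:  # pragma: no cover - config sanity
        raise ValueError("record too short for spectral estimation")
    increments = 2 * np.pi * f0 * dt + config.phase_noise_sd * np.sqrt(dt) * rng.standard_normal(n)
    phase = np.concatenate(([rng.uniform(0, 2 * np.pi)], increments)).cumsum()[:n]
    time_s = np.arange(n) * dt - config.pad_s

    gains = np.asarray(config.egg_gain_uv, dtype=float)[: config.n_egg_channels]
    # per-participant multiplicative spread of electrode gains
    gains = gains * rng.lognormal(mean=0.0, sigma=0.3, size=gains.size)
    cols = {"time_s": time_s}
    for c, gain in enumerate(gains):
        volt = gain * np.sin(phase) + config.egg_harmonic_frac * gain * np.sin(2 * phase)
        volt = volt + config.egg_noise_sd_uv * rng.standard_normal(n)
        cols[f"chan{c + 1}"] = volt
    return GastricSim(f0=f0, phase=phase, time_s=time_s, egg=pd.DataFrame(cols))


def _cardiac_phase_at(times: np.ndarray, rpeaks: np.ndarray) -> np.ndarray:
    """Linear cardiac phase 0..2pi between consecutive R peaks."""
    idx = np.searchsorted(rpeaks, times, side="right")
    idx = np.clip(idx, 1, len(rpeaks) - 1)
    prev = rpeaks[idx - 1]
    nxt = rpeaks[idx]
    return 2 * np.pi * (times - prev) / (nxt - prev)


def simulate_bold(
    config: SimulationConfig,
    truth: GroundTruth,
    gastric: GastricSim,
    participant_index: int,
    rpeak_times_s: np.ndarray | None = None,
) -> VolumeSeries:
    """BOLD volumes carrying the planted phase-locked component.

    Coupled voxels receive ``amp * cos(phi_t + delay + eta_t)`` where
    ``phi_t`` is the gastric phase sampled at volume times and ``eta_t`` is
    i.i.d. von Mises(0, kappa) jitter.  Every voxel additionally carries
    linear+quadratic drift, a shared CSF-like low-frequency signal (weight
    ~1 inside the configured CSF sphere), a cardiac pulsation proxy locked
    to the R-peak times (aliased by the TR), and white noise.
    """
    if truth.coupled_mask.shape != tuple(config.grid_shape):
        raise ValueError(
            f"ground-truth mask shape {truth.coupled_mask.shape} does not match "
            f"grid {tuple(config.grid_shape)}"
        )
    rng = _rng(config.seed, participant_index, _STREAM_BOLD)
    n_vol = config.n_volumes
    vol_times = np.arange(n_vol) * config.tr_s

    # gastric phase at volume times (the padded record starts at -pad_s)
    phi = np.interp(vol_times, gastric.time_s, gastric.phase)

    shape = tuple(config.grid_shape)
    nvox = int(np.prod(shape))
    data = np.zeros((nvox, n_vol))

    # planted coupling
    flat_mask = truth.coupled_mask.ravel()
    delays = truth.delay_map.ravel()[flat_mask]
    eta = rng.vonmises(0.0, truth.kappa, size=(flat_mask.sum(), n_vol))
    data[flat_mask] = config.gastric_amp * np.cos(phi[None, :] + delays[:, None] + eta)

    # polynomial drift
    tn = np.linspace(-1, 1, n_vol)
    a1 = config.drift_amp * rng.standard_normal(nvox)
    a2 = config.drift_amp * rng.standard_normal(nvox)
    data += a1[:, None] * tn[None, :] + a2[:, None] * tn[None, :] ** 2

    # shared CSF-like signal: low-pass-filtered noise, weight ~1 inside the
    # CSF sphere and small positive weights elsewhere
    raw = rng.standard_normal(n_vol + 40)
    sos = signal.butter(2, 0.05, fs=1.0 / config.tr_s, btype="low", output="sos")
    csf_src = signal.sosfiltfilt(sos, raw)[20:-20]
    csf_src = csf_src / (np.std(csf_src) + 1e-12)
    weights = 0.1 * rng.random(nvox)
    ii, jj, kk = np.indices(shape)
    world = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * config.voxel_mm
    d2 = np.sum((world - np.asarray(config.csf_center_world)) ** 2, axis=1)
    in_sphere = d2 < (config.csf_sphere_diameter_mm / 2.0) ** 2
    weights[in_sphere] = 1.0
    data += config.csf_amp * weights[:, None] * csf_src[None, :]

    # cardiac pulsation proxy, locked to the participant's R peaks and
    # therefore aliased by the 2-s volume sampling
    if rpeak_times_s is None:
        rpeak_times_s, _ = simulate_ibi(config, participant_index)
    theta = _cardiac_phase_at(vol_times, np.asarray(rpeak_times_s))
    card = np.cos(theta) + 0.5 * np.cos(2 * theta)
    cweights = config.cardiac_amp * rng.uniform(0.5, 1.0, size=nvox)
    data += cweights[:, None] * card[None, :]

    data += config.noise_sd * rng.standard_normal((nvox, n_vol))

    vol = data.reshape(shape + (n_vol,))
    mask = np.ones(shape, dtype=bool)
    return VolumeSeries(data=vol, tr_s=config.tr_s, affine=config.affine, mask=mask)


def simulate_ibi(config: SimulationConfig, participant_index: int):
    """R-peak times and interbeat intervals with LF/HF sinusoidal modulation.

    IBI(t) = base + a_LF sin(2 pi f_LF t) + a_HF sin(2 pi f_HF t) + noise;
    R-peak times are cumulative sums of the IBIs.
    """
    rng = _rng(config.seed, participant_index, _STREAM_IBI)
    hr = float(np.clip(rng.normal(config.mean_hr_bpm, config.hr_bpm_sd), 41.0, 119.0))
    base = 60.0 / hr
    total = config.duration_s + 2 * config.pad_s
    t = 0.0
    peaks = [0.0]
    while t < total:
        ibi = (
            base
            + config.lf_ibi_amp_s * np.sin(2 * np.pi * config.lf_hz * t)
            + config.hf_ibi_amp_s * np.sin(2 * np.pi * config.hf_hz * t)
            + config.ibi_noise_sd_s * rng.standard_normal()
        )
        ibi = max(ibi, 0.25)
        t += ibi
        peaks.append(t)
    rpeaks = np.asarray(peaks) - config.pad_s  # scan onset at t = 0
    return rpeaks, np.diff(rpeaks)


def _participant_kappa(config: SimulationConfig, participant_index: int) -> float:
    return config.kappa


def _covariates_row(config, participant_index, rng):
    row = {}
    for name, (mean, sd) in config.covariate_spec.items():
        row[name] = mean + sd * rng.standard_normal()
    return row


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Write a full cohort to disk and return the output directory.

    Per participant: one BOLD NIfTI (diagonal 3-mm affine), one EGG TSV
    (with a sampling-rate header line), one R-peak TSV, one covariate row.
    A JSON manifest records f0, kappa, planted delays, per-file checksums
    and the seed, so that the ground truth travels with the data.
    On any failure the partially written directory is removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created = []
    try:
        import nibabel as nib

        truth = make_ground_truth(config)
        # a CSF sphere intersecting the coupled region would feed locked
        # signal into the nuisance regressor and corrupt the ground truth
        ii, jj, kk = np.indices(config.grid_shape)
        world = np.stack([ii, jj, kk], axis=-1) * config.voxel_mm
        d = np.linalg.norm(world - np.asarray(config.csf_center_world), axis=-1)
        if np.any(truth.coupled_mask & (d < config.csf_sphere_diameter_mm / 2.0)):
            import warnings

            warnings.warn("CSF sphere overlaps the planted coupled region")
        cov_rows = []
        manifest = {
            "seed": config.seed,
            "n_participants": config.n_participants,
            "tr_s": config.tr_s,
            "duration_s": config.duration_s,
            "egg_fs": config.egg_fs,
            "pad_s": config.pad_s,
            "kappa": config.kappa,
            "expected_plv": truth.expected_plv,
            "csf_center_world": list(config.csf_center_world),
            "coupled_voxels": np.argwhere(truth.coupled_mask).tolist(),
            "delays_rad": truth.delay_map[truth.coupled_mask].tolist(),
            "participants": [],
            "files": {},
        }
        for p in range(config.n_participants):
            gast = simulate_gastric_phase(config, p)
            rpeaks, _ = simulate_ibi(config, p)
            vs = simulate_bold(config, truth, gast, p, rpeak_times_s=rpeaks)

            sub = f"sub-{p:02d}"
            bold_path = out / f"{sub}_bold.nii.gz"
            img = nib.Nifti1Image(vs.data.astype(np.float32), vs.affine)
            img.header.set_zooms((config.voxel_mm,) * 3 + (config.tr_s,))
            nib.save(img, bold_path)
            created.append(bold_path)

            egg_path = out / f"{sub}_egg.tsv"
            with open(egg_path, "w") as fh:
                fh.write(f"# sampling_rate_hz: {config.egg_fs}\n")
                gast.egg.to_csv(fh, sep="\t", index=False, float_format="%.6f")
            created.append(egg_path)

            rp_path = out / f"{sub}_rpeaks.tsv"
            pd.DataFrame({"rpeak_time_s": rpeaks}).to_csv(
                rp_path, sep="\t", index=False, float_format="%.6f"
            )
            created.append(rp_path)

            rng_cov = _rng(config.seed, p, _STREAM_COV)
            row = {"participant": sub, "gender": "f" if rng_cov.random() < 0.5 else "m"}
            row.update(_covariates_row(config, p, rng_cov))
            if config.covariate_slope != 0.0:
                # plant a linear relation between BMI and expected coupling
                row["bmi"] += config.covariate_slope * truth.expected_plv
            cov_rows.append(row)
            manifest["participants"].append(
                {"id": sub, "f0_hz": gast.f0, "kappa": _participant_kappa(config, p)}
            )

        cov_path = out / "covariates.csv"
        pd.DataFrame(cov_rows).to_csv(cov_path, index=False, float_format="%.6f")
        created.append(cov_path)

        for f in created:
            manifest["files"][f.name] = _sha256(f)
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return out
    except Exception:
        for f in created:
            f.unlink(missing_ok=True)
        if not any(out.iterdir()):
            shutil.rmtree(out, ignore_errors=True)
        raise
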