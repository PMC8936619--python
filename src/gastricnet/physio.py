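"""EGG and heart-rate-variability preprocessing.

Turns raw electrogastrogram tables and R-peak times into a per-participant
gastric rhythm record (peak frequency, narrow-band signal at the BOLD
sampling rate, instantaneous phase, cycle statistics) and an HRV band-power
summary.  The gastric peak is searched in the normogastric band
(0.033-0.066 Hz) with a Welch estimate on 200-s windows with 150-s overlap;
the selected channel is band-passed +-0.015 Hz around the peak with a
zero-phase FIR filter and decimated to the volume sampling rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal

__all__ = [
    "PowerSpectrum",
    "GastricRhythm",
    "HRVSummary",
    "welch_psd",
    "select_gastric_peak",
    "design_gastric_fir",
    "gastric_bandpass",
    "decimate_to",
    "cycle_metrics",
    "hrv_band_power",
    "extract_gastric_rhythm",
    "read_physio_tsv",
    "NORMOGASTRIC_BAND_HZ",
    "NORMOGASTRIC_CYCLE_S",
]

NORMOGASTRIC_BAND_HZ = (0.033, 0.066)
NORMOGASTRIC_CYCLE_S = (15.0, 30.0)


@dataclass
class PowerSpectrum:
    """One-sided Welch power spectral density with its bandwidth metadata.

    ``density`` integrates to the signal variance over frequency
    (units^2 / Hz); ``enbw_hz`` is the equivalent noise bandwidth of the
    taper, which converts a density value at a sinusoid peak back into the
    sinusoid's total power (A^2/2).
    """

    frequency_hz: np.ndarray
    density: np.ndarray
    enbw_hz: float

    def band_power(self, lo_hz: float, hi_hz: float) -> float:
        """Integrated power inside [lo, hi] (trapezoidal, units^2)."""
        f, p = self.frequency_hz, self.density
        sel = (f >= lo_hz) & (f <= hi_hz)
        if sel.sum() < 2:
            return float(p[sel].sum() * (f[1] - f[0])) if sel.any() else 0.0
        return float(np.trapezoid(p[sel], f[sel]))

    def peak_power(self, index: int) -> float:
        """Total power attributable to a spectral peak at one bin."""
        return float(self.density[index] * self.enbw_hz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_hz": self.frequency_hz, "density": self.density})


@dataclass
class GastricRhythm:
    """One participant's gastric rhythm, ready for phase-coupling analysis."""

    channel_id: int
    f0: float  # Hz, inside the normogastric band
    psd: PowerSpectrum
    narrowband_egg: np.ndarray  # at the BOLD rate, trimmed to the retained volumes
    phase: np.ndarray  # unwrapped rad, same length as narrowband_egg
    cycle_durations_s: np.ndarray
    cycle_sd_s: float
    pct_normogastric: float
    peak_power_uv2: float = float("nan")

    def __post_init__(self):
        lo, hi = NORMOGASTRIC_BAND_HZ
        if not (lo <= self.f0 <= hi):
            raise ValueError(f"f0={self.f0} Hz outside normogastric band {NORMOGASTRIC_BAND_HZ}")
        if not (0.0 <= self.pct_normogastric <= 100.0):
            raise ValueError("pct_normogastric must lie in [0, 100]")
        if len(self.narrowband_egg) != len(self.phase):
            raise ValueError("narrowband_egg and phase must share the time axis")

    @property
    def excluded(self) -> bool:
        """Participant-exclusion rule: <70% of cycles in the 15-30 s range."""
        return self.pct_normogastric < 70.0


@dataclass
class HRVSummary:
    """Band powers of the interpolated interbeat-interval series (ms^2)."""

    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    mean_ibi_s: float

    def __post_init__(self):
        if self.lf_power < 0 or self.hf_power < 0:
            raise ValueError("band powers must be nonnegative")


def welch_psd(
    x: np.ndarray, fs: float, window_s: float = 200.0, overlap_s: float = 150.0
) -> PowerSpectrum:
    """Welch PSD on Hann-tapered windows (defaults: 200 s with 150 s overlap).

    Density scaling: the band-integrated power approximates the signal
    variance, and a sinusoid of amplitude A integrates to ~A^2/2 over its
    peak.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    nperseg = int(window_s * fs)
    noverlap = int(overlap_s * fs)
    if x.size < nperseg:
        raise ValueError(f"signal of {x.size / fs:.0f} s shorter than one {window_s:.0f}-s window")
    win = signal.get_window("hann", nperseg)
    f, p = signal.welch(
        x, fs=fs, window=win, nperseg=nperseg, noverlap=noverlap, detrend="constant", scaling="density"
    )
    enbw = fs * np.sum(win**2) / np.sum(win) ** 2
    return PowerSpectrum(frequency_hz=f, density=p, enbw_hz=float(enbw))


def _local_maxima(p: np.ndarray) -> np.ndarray:
    idx, _ = signal.find_peaks(p)
    return idx


def select_gastric_peak(
    psd_per_channel: list[PowerSpectrum],
    band_hz: tuple[float, float] = NORMOGASTRIC_BAND_HZ,
    min_power_uv2: float = 15.0,
):
    """Pick the EGG channel and frequency of the sharpest normogastric peak.

    Candidates are in-band local maxima whose peak power exceeds
    ``min_power_uv2``.  Sharpness is the peak power minus the mean power in
    the two flanking bands of equal width (a prominence measure); ties are
    broken by larger absolute power, then lower channel index.  Returns
    ``(channel_id, f0, peak_power)`` or ``None`` when no candidate
    qualifies -- the participant-exclusion signal for a spectrum without a
    clear gastric peak.
    """
    if not psd_per_channel:
        raise ValueError("need at least one channel spectrum")
    lo, hi = band_hz
    width = hi - lo
    best = None  # (sharpness, power, -channel, f0)
    for c, ps in enumerate(psd_per_channel):
        f = ps.frequency_hz
        in_band = (f >= lo) & (f <= hi)
        if not in_band.any():
            continue
        for i in _local_maxima(ps.density):
            if not in_band[i]:
                continue
            power = ps.peak_power(i)
            if power <= min_power_uv2:
                continue
            left = ps.band_power(max(f[i] - 1.5 * width, 0.0), max(f[i] - 0.5 * width, 0.0))
            right = ps.band_power(f[i] + 0.5 * width, f[i] + 1.5 * width)
            sharpness = power - 0.5 * (left + right)
            key = (sharpness, power, -c)
            if best is None or key > best[0]:
                best = (key, c, float(f[i]), power)
    if best is None:
        return None
    return best[1], best[2], best[3]


def design_gastric_fir(fs: float, f0: float, halfwidth_hz: float = 0.015) -> np.ndarray:
    """Frequency-sampled FIR band-pass taps for [f0 - hw, f0 + hw].

    The filter length is five cycles of the band's low edge
    (``round(5 fs / (f0 - hw))`` taps, forced odd), which keeps the design
    usable across sampling rates; unit gain inside the band, zero outside.
    """
    f_lo = f0 - halfwidth_hz
    f_hi = f0 + halfwidth_hz
    nyq = fs / 2.0
    if f_lo <= 0:
        raise ValueError("f0 - halfwidth must be positive")
    if f_hi >= nyq:
        raise ValueError(f"band edge {f_hi} Hz at or above Nyquist {nyq} Hz")
    numtaps = int(round(5.0 * fs / f_lo))
    if numtaps % 2 == 0:
        numtaps += 1
    # small transition bands around the passband keep the design well posed
    trans = min(0.2 * (f_hi - f_lo), f_lo / 2, (nyq - f_hi) / 2)
    freqs = np.array([0.0, f_lo - trans, f_lo, f_hi, f_hi + trans, nyq]) / nyq
    gains = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 0.0])
    return signal.firwin2(numtaps, freqs, gains)


def gastric_bandpass(
    x: np.ndarray, fs: float, f0: float, halfwidth_hz: float = 0.015
) -> np.ndarray:
    """Zero-phase narrow-band filter around the gastric peak frequency.

    Applied forward and backward so the group delay cancels exactly and
    the instantaneous phase of in-band components is untouched.
    """
    x = np.asarray(x, dtype=float)
    taps = design_gastric_fir(fs, f0, halfwidth_hz)
    if taps.size >= x.size:
        raise ValueError(f"filter of {taps.size} taps longer than signal of {x.size} samples")
    padlen = min(3 * taps.size, x.size - 1)
    return signal.filtfilt(taps, [1.0], x, padlen=padlen)


def decimate_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased integer-ratio downsampling, first samples aligned.

    The ratio is factorized into stages of at most 10 so the FIR
    anti-alias filter stays short at each stage.
    """
    x = np.asarray(x, dtype=float)
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(f"fs_in/fs_out = {ratio} is not a positive integer")
    if q == 1:
        return x.copy()
    out = x
    remaining = q
    while remaining > 1:
        step = remaining if remaining <= 10 else _largest_factor_leq(remaining, 10)
        out = _decimate_once(out, step)
        remaining //= step
    return out


def _decimate_once(x: np.ndarray, q: int) -> np.ndarray:
    """One anti-alias + subsample stage, zero phase with edge padding."""
    taps = signal.firwin(8 * q + 1, 0.8 / q)
    padlen = min(3 * taps.size, x.size - 1)
    y = signal.filtfilt(taps, [1.0], x, padlen=padlen)
    return y[::q]


def _largest_factor_leq(n: int, cap: int) -> int:
    for f in range(cap, 1, -1):
        if n % f == 0:
            return f
    return n  # prime larger than cap: decimate in one (longer) stage


def cycle_metrics(phase: np.ndarray, fs: float):
    """Cycle durations from upward crossings of the unwrapped phase.

    Cycles are delimited by crossings of successive multiples of 2 pi
    (linearly interpolated between samples).  Returns the durations, their
    SD, and the percentage inside the normogastric 15-30 s range.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.size < 2:
        raise ValueError("phase series too short")
    first_level = np.ceil(phase[0] / (2 * np.pi) + 1e-12) * 2 * np.pi
    levels = np.arange(first_level, phase.max(), 2 * np.pi)
    if levels.size < 3:
        raise ValueError("fewer than two full cycles in the record")
    # phase is monotone up to noise; use first-crossing interpolation
    t = np.arange(phase.size) / fs
    crossings = []
    j = 0
    for lev in levels:
        while j < phase.size and phase[j] < lev:
            j += 1
        if j >= phase.size:
            break
        if j == 0:
            continue
        frac = (lev - phase[j - 1]) / (phase[j] - phase[j - 1])
        crossings.append(t[j - 1] + frac / fs)
    durations = np.diff(np.asarray(crossings))
    if durations.size < 2:
        raise ValueError("fewer than two full cycles in the record")
    lo, hi = NORMOGASTRIC_CYCLE_S
    pct = 100.0 * float(np.mean((durations >= lo) & (durations <= hi)))
    sd = float(np.std(durations, ddof=1))
    return durations, sd, pct


def hrv_band_power(
    rpeak_times_s,
    lf_band_hz: tuple[float, float] = (0.06, 0.15),
    hf_band_hz: tuple[float, float] = (0.16, 0.4),
    window_s: float = 120.0,
    overlap_s: float = 100.0,
) -> HRVSummary:
    """LF/HF band power of the 1-Hz cubic-spline-interpolated IBI series.

    Interbeat intervals (ms) are assigned to the time of the closing beat,
    interpolated at 1 Hz with a cubic spline, and their Welch spectrum
    (120-s windows, 100-s overlap) is integrated over the LF (0.06-0.15 Hz)
    and HF (0.16-0.4 Hz) bands.
    """
    rpeaks = np.asarray(rpeak_times_s, dtype=float)
    if rpeaks.size < 2:
        raise ValueError("need at least two R peaks")
    span = rpeaks[-1] - rpeaks[0]
    if span < window_s:
        raise ValueError(f"record of {span:.0f} s shorter than one {window_s:.0f}-s window")
    ibi_ms = np.diff(rpeaks) * 1000.0
    beat_t = rpeaks[1:]
    spline = interpolate.CubicSpline(beat_t, ibi_ms)
    t_grid = np.arange(np.ceil(beat_t[0]), np.floor(beat_t[-1]) + 1.0)
    ibi_1hz = spline(t_grid)
    ps = welch_psd(ibi_1hz, fs=1.0, window_s=window_s, overlap_s=overlap_s)
    lf = ps.band_power(*lf_band_hz)
    hf = ps.band_power(*hf_band_hz)
    ratio = lf / hf if hf > 0 else float("inf")
    return HRVSummary(lf_power=lf, hf_power=hf, lf_hf_ratio=ratio, mean_ibi_s=float(np.mean(np.diff(rpeaks))))


def read_physio_tsv(path):
    """Read a physio TSV whose first line names the sampling rate.

    Header convention: ``# sampling_rate_hz: <value>`` followed by a
    tab-separated table with a ``time_s`` column.
    Returns ``(dataframe, fs_hz)``.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#") or "sampling_rate_hz" not in first:
            raise ValueError(f"{path}: missing '# sampling_rate_hz:' header line")
        fs = float(first.split(":", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    return df, fs


def extract_gastric_rhythm(
    egg: pd.DataFrame,
    fs: float,
    scan_duration_s: float,
    tr_s: float = 2.0,
    trim_volumes: int = 15,
    band_hz: tuple[float, float] = NORMOGASTRIC_BAND_HZ,
    min_power_uv2: float = 15.0,
    halfwidth_hz: float = 0.015,
):
    """Full EGG preprocessing for one participant.

    Steps: Welch PSD per channel; peak selection in the normogastric band;
    zero-phase narrow-band filtering of the selected channel on the padded
    record (any samples with ``time_s`` outside [0, scan) are used for
    filtering, then cut); decimation to the volume rate; trimming of the
    first and last ``trim_volumes`` samples; Hilbert phase of the retained
    series.  Cycle statistics come from the full-rate narrow-band phase
    over the scan window.  Returns a ``GastricRhythm``, or ``None`` when
    no channel shows a qualifying spectral peak (exclusion signal).
    """
    chan_cols = [c for c in egg.columns if c != "time_s"]
    time = egg["time_s"].to_numpy() if "time_s" in egg.columns else np.arange(len(egg)) / fs
    in_scan = (time >= 0) & (time < scan_duration_s)

    spectra = [welch_psd(egg[c].to_numpy()[in_scan], fs) for c in chan_cols]
    picked = select_gastric_peak(spectra, band_hz=band_hz, min_power_uv2=min_power_uv2)
    if picked is None:
        return None
    channel_id, f0, peak_power = picked

    # filter on the padded record, then cut the padding
    x_full = egg[chan_cols[channel_id]].to_numpy()
    nb_full = gastric_bandpass(x_full, fs, f0, halfwidth_hz)
    nb_scan = nb_full[in_scan]

    phase_full = np.unwrap(np.angle(signal.hilbert(nb_scan)))
    durations, sd, pct = cycle_metrics(phase_full, fs)

    nb_tr = decimate_to(nb_scan, fs, 1.0 / tr_s)
    n_vol = int(round(scan_duration_s * (1.0 / tr_s)))
    nb_tr = nb_tr[:n_vol]
    if trim_volumes > 0:
        nb_tr = nb_tr[trim_volumes:-trim_volumes]
    phase_tr = np.unwrap(np.angle(signal.hilbert(nb_tr)))

    return GastricRhythm(
        channel_id=channel_id,
        f0=f0,
        psd=spectra[channel_id],
        narrowband_egg=nb_tr,
        phase=phase_tr,
        cycle_durations_s=durations,
        cycle_sd_s=sd,
        pct_normogastric=pct,
        peak_power_uv2=peak_power,
    )
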