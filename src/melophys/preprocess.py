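"""Raw physiological recordings -> nine analysis channels on a 5 Hz grid.

Channels: ``rr`` (interpolated RR intervals, s), ``resp`` (respiratory
intervals, s), ``sys``/``dia``/``pp`` (beat-wise blood pressure, mmHg),
``plf``/``phf`` (instantaneous LF/HF band powers, ms^2) and
``flf``/``fhf`` (instantaneous LF/HF peak frequencies, Hz). The HF band
is time-varying, centred on the instantaneous respiratory frequency
Fr(t) +/- 0.125 Hz; the LF band is fixed at 0.04-0.15 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from melophys.core import GRID_RATE_HZ, DataError, UniformSeries, common_grid

#: Fixed LF band (Hz) and the half-width of the respiration-centred HF band.
LF_BAND = (0.04, 0.15)
HF_HALF_WIDTH = 0.125
#: Fallback HF band used where Fr(t) is unavailable.
HF_FALLBACK = (0.15, 0.40)

#: STFT configuration: 50-sample Hamming window, 50 % overlap; the FFT is
#: zero-padded to refine peak-frequency estimates (the raw 0.1 Hz bin
#: width of a 50-sample window at 5 Hz is too coarse for the LF band).
STFT_WINDOW = 50
STFT_OVERLAP = 25
STFT_NFFT = 256

#: Ectopic-beat surrogate filter: relative deviation from a running median.
ARTIFACT_THRESHOLD = 0.25
ARTIFACT_MEDIAN_WINDOW = 5


@dataclass(frozen=True)
class Spectrogram:
    times: np.ndarray      # STFT slice centres (s)
    freqs: np.ndarray      # Hz
    power: np.ndarray      # (freq, time), ms^2/Hz
    window: int
    overlap: int


@dataclass(frozen=True)
class BandMetrics:
    plf: UniformSeries
    phf: UniformSeries
    flf: UniformSeries
    fhf: UniformSeries


def clean_rr(rr, threshold: float = ARTIFACT_THRESHOLD):
    """Remove artifact beats deviating from a running median by > threshold.

    Automated surrogate for manual ectopic-beat editing. Returns
    ``(cleaned, flags)`` where ``flags['removed']`` lists dropped indices
    and ``flags['unreliable']`` is set when > 20 % of beats are removed.
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise DataError("RR intervals must be positive")
    if len(rr) < ARTIFACT_MEDIAN_WINDOW:
        return rr.copy(), {"removed": [], "unreliable": False}
    med = sps.medfilt(rr, kernel_size=ARTIFACT_MEDIAN_WINDOW)
    # medfilt zero-pads the edges; fall back to the global median there
    half = ARTIFACT_MEDIAN_WINDOW // 2
    med[:half] = np.median(rr[: ARTIFACT_MEDIAN_WINDOW])
    med[-half:] = np.median(rr[-ARTIFACT_MEDIAN_WINDOW:])
    keep = np.abs(rr - med) / med <= threshold
    removed = np.flatnonzero(~keep).tolist()
    frac = len(removed) / len(rr)
    return rr[keep], {"removed": removed, "unreliable": frac > 0.20}


def beat_times(rr) -> np.ndarray:
    """Cumulative beat occurrence times, starting at the end of the first interval."""
    return np.cumsum(np.asarray(rr, dtype=float))


def resample_rr(rr, rate: float = GRID_RATE_HZ, duration: float | None = None) -> UniformSeries:
    """Cubic-spline interpolation of the RR tachogram onto a uniform grid.

    The tachogram places each interval value at its beat occurrence time;
    grid points outside the beat support hold the endpoint values.
    """
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 4:
        raise DataError("need >= 4 beats to resample")
    t = beat_times(rr)
    dur = t[-1] if duration is None else duration
    grid = common_grid(dur, rate)
    spline = CubicSpline(t, rr, extrapolate=False)
    out = spline(grid)
    out[grid <= t[0]] = rr[0]
    out[grid >= t[-1]] = rr[-1]
    return UniformSeries("rr", out, rate=rate, units="s")


def highpass_rr(series: UniformSeries, cutoff_hz: float = 0.03, order: int = 4) -> UniformSeries:
    """Zero-phase 4th-order Butterworth high-pass (forward-backward)."""
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=series.rate, output="sos")
    padlen = 3 * (2 * order + 1)
    if len(series) <= 3 * padlen:
        raise DataError(f"series too short for filter startup ({len(series)} samples)")
    out = sps.sosfiltfilt(sos, series.values)
    return series.with_values(out, channel=series.channel + "_hp")


def detect_resp_intervals(wave: UniformSeries, lowpass_hz: float = 1.0):
    """Respiratory intervals from a respiration waveform.

    Detrends and low-pass filters the waveform (4th-order Butterworth,
    1 Hz), detects inspiration peaks, and returns ``(intervals,
    peak_times, fr)`` where ``fr`` is the instantaneous respiratory
    frequency 1/interval interpolated onto the 5 Hz grid.
    """
    if wave.rate < 5.0:
        raise DataError("respiration waveform must be sampled at >= 5 Hz")
    x = sps.detrend(wave.values)
    sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=wave.rate, output="sos")
    x = sps.sosfiltfilt(sos, x)
    min_dist = max(1, int(1.5 * wave.rate))  # breaths slower than 40/min apart
    peaks, _ = sps.find_peaks(x, distance=min_dist, prominence=0.3 * np.std(x))
    if len(peaks) < 2:
        raise DataError("no respiratory peaks found")
    # parabolic sub-sample refinement of each peak position
    refined = peaks.astype(float)
    inner = (peaks > 0) & (peaks < len(x) - 1)
    i = peaks[inner]
    denom = x[i - 1] - 2 * x[i] + x[i + 1]
    shift = np.where(denom != 0, 0.5 * (x[i - 1] - x[i + 1]) / denom, 0.0)
    refined[inner] = i + np.clip(shift, -0.5, 0.5)
    peak_times = wave.start + refined / wave.rate
    intervals = np.diff(peak_times)
    mid_times = (peak_times[1:] + peak_times[:-1]) / 2
    grid = common_grid(wave.duration, GRID_RATE_HZ, start=wave.start)
    fr = np.interp(grid, mid_times, 1.0 / intervals)
    return intervals, peak_times, UniformSeries("fr", fr, units="Hz", start=wave.start)


def resp_interval_series(intervals, peak_times, duration: float) -> UniformSeries:
    """Respiratory interval series on the 5 Hz grid (units s)."""
    mid = (np.asarray(peak_times)[1:] + np.asarray(peak_times)[:-1]) / 2
    grid = common_grid(duration)
    return UniformSeries("resp", np.interp(grid, mid, intervals), units="s")


def bp_channels(sys_bp, dia_bp, beat_t, duration: float | None = None):
    """Beat-wise SYS/DIA -> (sys, dia, pp) UniformSeries at 5 Hz.

    Pulse pressure PP = SYS - DIA is computed beat-wise before
    interpolation; any beat with SYS <= DIA is an error.
    """
    sys_bp = np.asarray(sys_bp, dtype=float)
    dia_bp = np.asarray(dia_bp, dtype=float)
    beat_t = np.asarray(beat_t, dtype=float)
    if sys_bp.shape != dia_bp.shape or sys_bp.shape != beat_t.shape:
        raise DataError("SYS, DIA and beat times must be aligned")
    bad = np.flatnonzero(sys_bp <= dia_bp)
    if len(bad):
        raise DataError(f"SYS <= DIA at beat index {bad[0]}")
    pp = sys_bp - dia_bp
    dur = beat_t[-1] if duration is None else duration
    grid = common_grid(dur)
    out = []
    for name, vals in (("sys", sys_bp), ("dia", dia_bp), ("pp", pp)):
        out.append(UniformSeries(name, np.interp(grid, beat_t, vals), units="mmHg"))
    return tuple(out)


def spectrogram_rr(series: UniformSeries, window: int = STFT_WINDOW,
                   overlap: int = STFT_OVERLAP, nfft: int = STFT_NFFT) -> Spectrogram:
    """Magnitude-squared STFT of a (filtered) RR series, power in ms^2/Hz."""
    if len(series) <= window:
        raise DataError(f"series shorter than the {window}-sample STFT window")
    freqs, times, sxx = sps.spectrogram(
        series.values, fs=series.rate, window=sps.get_window("hamming", window),
        noverlap=overlap, nfft=nfft, scaling="density", mode="psd",
    )
    return Spectrogram(times + series.start, freqs, sxx * 1e6, window, overlap)


def band_metrics(spec: Spectrogram, fr: UniformSeries | None) -> BandMetrics:
    """Instantaneous band powers and peak frequencies on the 5 Hz grid.

    LF uses the fixed 0.04-0.15 Hz band. HF uses Fr(t) +/- 0.125 Hz,
    replacing the standard fixed band entirely (the lower edge may drop
    below 0.15 Hz); where Fr is unavailable the fixed 0.15-0.4 Hz band
    is used instead. Powers are band integrals; peak frequencies are
    band-restricted argmax values.
    """
    f, p = spec.freqs, spec.power
    df = f[1] - f[0]
    nyq = f[-1]
    n_t = len(spec.times)
    plf = np.zeros(n_t)
    flf = np.zeros(n_t)
    phf = np.zeros(n_t)
    fhf = np.full(n_t, np.nan)

    lf_mask = (f >= LF_BAND[0]) & (f <= LF_BAND[1])
    fr_at = fr.value_at(spec.times) if fr is not None else np.full(n_t, np.nan)
    for i in range(n_t):
        col = p[:, i]
        plf[i] = np.trapezoid(col[lf_mask], dx=df)
        flf[i] = f[lf_mask][np.argmax(col[lf_mask])]
        fc = fr_at[i]
        if np.isfinite(fc):
            lo, hi = max(fc - HF_HALF_WIDTH, df), min(fc + HF_HALF_WIDTH, nyq)
        else:
            lo, hi = HF_FALLBACK
        hf_mask = (f >= lo) & (f <= hi)
        if not hf_mask.any():
            continue  # fhf stays NaN — band empty after clipping
        phf[i] = np.trapezoid(col[hf_mask], dx=df)
        fhf[i] = f[hf_mask][np.argmax(col[hf_mask])]

    t_end = spec.times[-1]
    grid = common_grid(t_end)
    ok = np.isfinite(fhf)

    def interp(vals, valid=None):
        if valid is None:
            return np.interp(grid, spec.times, vals)
        return np.interp(grid, spec.times[valid], vals[valid])

    return BandMetrics(
        plf=UniformSeries("plf", interp(plf), units="ms^2"),
        phf=UniformSeries("phf", interp(phf), units="ms^2"),
        flf=UniformSeries("flf", interp(flf), units="Hz"),
        fhf=UniformSeries("fhf", interp(fhf, ok), units="Hz"),
    )


def process_session(session) -> dict:
    """One listener-performance session -> the nine analysis channels.

    Takes a :class:`melophys.synthetic.SessionSignals`-shaped object
    (attributes ``rr``, ``resp_wave``, ``sys``, ``dia``, ``duration``)
    and returns a ``{channel: UniformSeries}`` dict, all on the common
    5 Hz session grid.
    """
    rr_clean, _ = clean_rr(session.rr)
    dur = session.duration
    rr_series = resample_rr(rr_clean, duration=dur)

    intervals, peak_times, fr = detect_resp_intervals(session.resp_wave)
    resp = resp_interval_series(intervals, peak_times, dur)

    t_beats = beat_times(session.rr)[: len(session.sys)]
    sys_s, dia_s, pp_s = bp_channels(session.sys, session.dia, t_beats, duration=dur)

    spec = spectrogram_rr(highpass_rr(rr_series))
    bands = band_metrics(spec, fr)

    grid_n = len(common_grid(dur))

    def fit(series):
        # pad/trim derived series (STFT support is shorter) to the session grid
        v = np.interp(common_grid(dur), series.times, series.values)
        return series.with_values(v[:grid_n])

    return {
        "rr": rr_series,
        "resp": resp,
        "sys": sys_s,
        "dia": dia_s,
        "pp": pp_s,
        "plf": fit(bands.plf),
        "phf": fit(bands.phf),
        "flf": fit(bands.flf),
        "fhf": fit(bands.fhf),
    }
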