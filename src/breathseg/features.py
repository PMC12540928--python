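"""Per-segment acoustic feature battery.

For every inspiratory (S1) and expiratory (S2) segment the package computes
intensity statistics (frame-RMS dBFS: max/min/mean/middle, where "middle"
is the median), a fundamental-frequency battery from framewise normalized
autocorrelation (start/max/min/mean/middle/range/end f0, f0 variation and
skew, and the start-to-max and max-to-end f0 slopes SSM and SME),
periodicity measures (relative local jitter, harmonics-to-noise ratio,
SNR), classical time-domain shape statistics (energy, absolute mean,
peak-to-valley, crest/shape/margin factors, skewness and non-excess
kurtosis), spectral features (energy, peak frequency, dB-vs-log-frequency
slope) and Daubechies-4 wavelet per-level energy fractions.

Unvoiced, silent or otherwise degenerate segments carry explicit flags
instead of spurious values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import stats

from .audio_io import AudioSignal, amplitude_to_db, DB_FLOOR
from . import spectral as sp

__all__ = [
    "F0Track",
    "FEATURE_COLUMNS",
    "intensity_stats",
    "estimate_f0",
    "f0_summary",
    "jitter",
    "harmonicity",
    "snr",
    "time_domain_stats",
    "spectral_features",
    "wavelet_features",
    "extract_all",
]


@dataclass
class F0Track:
    """Framewise fundamental frequency with a voicing decision per frame."""

    times_s: np.ndarray
    f0_hz: np.ndarray
    voiced: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.f0_hz = np.asarray(self.f0_hz, dtype=np.float64)
        self.voiced = np.asarray(self.voiced, dtype=bool)

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0_hz[self.voiced]


# ---------------------------------------------------------------------------
# Intensity


def intensity_stats(
    segment: AudioSignal, frame_s: float = 0.05, hop_s: float = 0.025
) -> tuple[float, float, float, float]:
    """(max_db, min_db, mean_db, middle_db) of framewise RMS in dBFS."""
    rate = segment.sample_rate
    flen = int(round(frame_s * rate))
    hop = max(1, int(round(hop_s * rate)))
    if segment.n_samples < flen:
        raise ValueError("segment shorter than one frame")
    n_frames = (segment.n_samples - flen) // hop + 1
    starts = np.arange(n_frames) * hop
    rms = np.array([
        np.sqrt(np.mean(segment.samples[a : a + flen] ** 2)) for a in starts
    ])
    db = amplitude_to_db(rms)
    return float(db.max()), float(db.min()), float(db.mean()), float(np.median(db))


# ---------------------------------------------------------------------------
# Fundamental frequency


def _norm_autocorr_peak(x: np.ndarray, lag_min: int, lag_max: int) -> tuple[float, float]:
    """(best_lag, r) of the per-lag-normalized autocorrelation in the band,
    with parabolic lag interpolation."""
    n = x.size
    lag_max = min(lag_max, n - 2)
    if lag_max <= lag_min:
        return float("nan"), 0.0
    x = x - x.mean()
    full = np.correlate(x, x, mode="full")[n - 1 :]
    e = np.concatenate([[0.0], np.cumsum(x**2)])
    # per-lag normalization: r(k) = sum(x[:n-k]*x[k:]) / sqrt(E(x[:n-k]) E(x[k:]))
    lags = np.arange(lag_min, lag_max + 1)
    e0 = e[n - lags] - e[0]
    e1 = e[n] - e[lags]
    r = full[lags] / np.sqrt(np.maximum(e0 * e1, 1e-300))
    # prefer the shortest near-maximal lag: integer multiples of the true
    # period correlate equally well, and picking them halves the f0
    r_max = float(r.max())
    local_max = np.ones(r.size, dtype=bool)
    if r.size > 2:
        local_max[1:-1] = (r[1:-1] >= r[:-2]) & (r[1:-1] >= r[2:])
    near_best = np.nonzero(local_max & (r >= r_max - 0.05))[0]
    k = int(near_best[0]) if near_best.size else int(np.argmax(r))
    best = lags[k]
    # parabolic interpolation on the raw autocorrelation around the peak
    if 0 < k < r.size - 1:
        y0, y1, y2 = r[k - 1], r[k], r[k + 1]
        denom_p = y0 - 2 * y1 + y2
        if abs(denom_p) > 1e-12:
            best = best + 0.5 * (y0 - y2) / denom_p
    return float(best), float(r[k])


def estimate_f0(
    segment: AudioSignal,
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    f0_min: float = 50.0,
    f0_max: float = 800.0,
    voicing_threshold: float = 0.3,
) -> F0Track:
    """Framewise autocorrelation f0 with a voicing decision.

    A frame is voiced when its best normalized autocorrelation in the
    ``[1/f0_max, 1/f0_min]`` lag band reaches ``voicing_threshold``.
    """
    rate = segment.sample_rate
    if not (0 < f0_min < f0_max < rate / 2):
        raise ValueError("need 0 < f0_min < f0_max < rate/2")
    flen = int(round(frame_s * rate))
    hop = max(1, int(round(hop_s * rate)))
    lag_min = max(2, int(np.floor(rate / f0_max)))
    lag_max = int(np.ceil(rate / f0_min))
    n_frames = max((segment.n_samples - flen) // hop + 1, 0)
    times = np.empty(n_frames)
    f0 = np.full(n_frames, np.nan)
    voiced = np.zeros(n_frames, dtype=bool)
    for i in range(n_frames):
        a = i * hop
        lag, r = _norm_autocorr_peak(segment.samples[a : a + flen], lag_min, lag_max)
        times[i] = (a + flen / 2) / rate
        if np.isfinite(lag) and r >= voicing_threshold:
            f0[i] = rate / lag
            voiced[i] = True
    return F0Track(times, f0, voiced)


def f0_summary(track: F0Track) -> dict[str, float]:
    """The f0 battery over voiced frames; raises if none are voiced."""
    if not track.voiced.any():
        raise ValueError("no voiced frames: f0 battery undefined")
    f = track.voiced_f0
    t = track.times_s[track.voiced]
    i_max = int(np.argmax(f))
    out = {
        "start_f0": float(f[0]),
        "end_f0": float(f[-1]),
        "max_f0": float(f.max()),
        "min_f0": float(f.min()),
        "mean_f0": float(f.mean()),
        "middle_f0": float(np.median(f)),
        "range_f0": float(f.max() - f.min()),
        "f0_variation": float(f.std(ddof=1)) if f.size > 1 else 0.0,
        "f0_skew": float(stats.skew(f, bias=True)) if f.size > 2 and f.std() > 0 else 0.0,
    }
    dt_up = t[i_max] - t[0]
    dt_down = t[-1] - t[i_max]
    out["ssm"] = float((f[i_max] - f[0]) / dt_up) if dt_up > 0 else 0.0
    out["sme"] = float((f[-1] - f[i_max]) / dt_down) if dt_down > 0 else 0.0
    return out


def jitter(track: F0Track) -> float:
    """Relative local jitter: mean |consecutive period difference| / mean period,
    over the longest run of consecutive voiced frames (needs >= 3)."""
    runs, cur = [], []
    for v, f in zip(track.voiced, track.f0_hz):
        if v:
            cur.append(f)
        else:
            if cur:
                runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    best = max(runs, key=len, default=[])
    if len(best) < 3:
        raise ValueError("need at least 3 consecutive voiced frames for jitter")
    periods = 1.0 / np.asarray(best)
    return float(np.mean(np.abs(np.diff(periods))) / np.mean(periods))


def harmonicity(
    segment: AudioSignal, f0_min: float = 50.0, f0_max: float = 800.0
) -> float:
    """Harmonics-to-noise ratio 10*log10(r/(1-r)) in dB, clamped to [-20, 60],
    where r is the peak normalized autocorrelation in the f0 lag band."""
    rate = segment.sample_rate
    lag_min = max(2, int(np.floor(rate / f0_max)))
    lag_max = int(np.ceil(rate / f0_min))
    _, r = _norm_autocorr_peak(segment.samples, lag_min, lag_max)
    r = min(max(r, 0.0), 1.0 - 1e-12)
    if r <= 0.0:
        return -20.0
    return float(np.clip(10.0 * np.log10(r / (1.0 - r)), -20.0, 60.0))


def snr(segment: AudioSignal, noise_ref: AudioSignal | np.ndarray) -> float:
    """10*log10(signal power / noise power); +inf for zero noise power."""
    p_sig = float(np.mean(segment.samples**2))
    noise = noise_ref.samples if isinstance(noise_ref, AudioSignal) else np.asarray(noise_ref)
    p_noise = float(np.mean(noise**2))
    if p_noise == 0.0:
        return float("inf")
    return 10.0 * np.log10(p_sig / p_noise)


# ---------------------------------------------------------------------------
# Time-domain shape statistics


def time_domain_stats(segment: AudioSignal) -> dict[str, float]:
    """Energy, abs mean, peak-to-valley, crest/shape/margin factors,
    skewness and (non-excess) kurtosis.  All-zero input raises."""
    x = segment.samples
    if x.size == 0 or not np.any(x):
        raise ValueError("time-domain shape statistics undefined for silent input")
    absx = np.abs(x)
    rms = float(np.sqrt(np.mean(x**2)))
    abs_mean = float(absx.mean())
    peak = float(absx.max())
    degenerate = np.ptp(x) == 0.0  # constant signal: centered moments vanish
    return {
        "energy": float(np.sum(x**2)),
        "abs_mean": abs_mean,
        "peak2valley": float(x.max() - x.min()),
        "crest_factor": peak / rms,
        "shape_factor": rms / abs_mean,
        "margin_factor": peak / float(np.mean(np.sqrt(absx))) ** 2,
        "skewness": 0.0 if degenerate else float(stats.skew(x, bias=True)),
        "kurtosis": 0.0 if degenerate else float(stats.kurtosis(x, fisher=False, bias=True)),
    }


# ---------------------------------------------------------------------------
# Spectral and wavelet features


def spectral_features(
    segment: AudioSignal,
    slope_band_hz: tuple[float, float] = (50.0, 4000.0),
) -> dict[str, float]:
    """Spectral energy (Parseval-consistent), peak frequency, and the
    least-squares slope of dB magnitude vs log10 frequency in ``slope_band_hz``."""
    spec = sp.stft(segment)
    energy = sp.spectrogram_energy(spec)
    power = (np.abs(spec.values) ** 2).mean(axis=1)
    peak_hz = float(spec.freqs_hz[int(np.argmax(power))])
    hi = min(slope_band_hz[1], segment.sample_rate / 2.0)
    sel = (spec.freqs_hz >= slope_band_hz[0]) & (spec.freqs_hz <= hi) & (power > 0)
    if sel.sum() >= 2:
        db = 10.0 * np.log10(power[sel])
        logf = np.log10(spec.freqs_hz[sel])
        slope = float(np.polyfit(logf, db, 1)[0])
    else:
        slope = 0.0
    return {"spectral_energy": energy, "frequency_peak_hz": peak_hz, "spectral_slope": slope}


def wavelet_features(segment: AudioSignal, levels: int = 5, wavelet: str = "db4") -> dict[str, float]:
    """Per-level energy fractions of an orthogonal DWT (periodized db4).

    Keys ``wavelet_a{L}`` (deepest approximation, lowest band) then
    ``wavelet_d{L}..wavelet_d1`` (detail bands, coarse to fine); fractions
    sum to 1 and total coefficient energy equals the time-domain energy.
    """
    x = segment.samples
    if x.size < 2**levels:
        raise ValueError(f"segment too short for {levels} wavelet levels")
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="periodization")
    energies = np.array([float(np.sum(c**2)) for c in coeffs])
    total = energies.sum()
    fracs = energies / total if total > 0 else np.zeros_like(energies)
    keys = [f"wavelet_a{levels}"] + [f"wavelet_d{levels - i}" for i in range(levels)]
    return dict(zip(keys, fracs.astype(float)))


# ---------------------------------------------------------------------------
# Tidy per-phase feature table

_WAVELET_LEVELS = 5
FEATURE_COLUMNS = [
    "cycle", "phase", "duration_s",
    "max_db", "min_db", "mean_db", "middle_db",
    "start_f0", "max_f0", "min_f0", "mean_f0", "middle_f0", "range_f0", "end_f0",
    "f0_variation", "f0_skew", "sme", "ssm",
    "jitter", "harmonicity_db", "snr_db",
    "energy", "abs_mean", "peak2valley", "crest_factor", "shape_factor",
    "margin_factor", "skewness", "kurtosis",
    "spectral_energy", "frequency_peak_hz", "spectral_slope",
    *(
        [f"wavelet_a{_WAVELET_LEVELS}"]
        + [f"wavelet_d{_WAVELET_LEVELS - i}" for i in range(_WAVELET_LEVELS)]
    ),
    "flags",
]


def _segment_row(signal: AudioSignal, start_s: float, end_s: float, noise_ref) -> dict:
    rate = signal.sample_rate
    a, b = int(round(start_s * rate)), int(round(end_s * rate))
    seg = AudioSignal(signal.samples[a:b], rate)
    row: dict = {"duration_s": end_s - start_s}
    flags: list[str] = []
    try:
        row["max_db"], row["min_db"], row["mean_db"], row["middle_db"] = intensity_stats(seg)
    except ValueError:
        row.update(max_db=DB_FLOOR, min_db=DB_FLOOR, mean_db=DB_FLOOR, middle_db=DB_FLOOR)
        flags.append("too_short")
    try:
        row.update(time_domain_stats(seg))
    except ValueError:
        flags.append("silent")
    track = estimate_f0(seg) if seg.n_samples >= int(0.04 * rate) else None
    if track is not None and track.voiced.any():
        row.update(f0_summary(track))
        try:
            row["jitter"] = jitter(track)
        except ValueError:
            flags.append("jitter_undefined")
    else:
        flags.append("unvoiced")
    row["harmonicity_db"] = harmonicity(seg) if seg.n_samples > 40 else np.nan
    if noise_ref is not None and noise_ref.size:
        row["snr_db"] = snr(seg, noise_ref)
    else:
        flags.append("no_noise_reference")
    if seg.n_samples >= sp.DEFAULT_WINDOW_LEN:
        row.update(spectral_features(seg))
    try:
        row.update(wavelet_features(seg))
    except ValueError:
        flags.append("too_short_for_wavelet")
    row["flags"] = ";".join(flags)
    return row


def _quiet_noise_reference(signal: AudioSignal, quantile: float = 0.1) -> np.ndarray:
    """Concatenated samples of the quietest frames: the recording's own
    pause floor, used as the SNR noise reference."""
    rate = signal.sample_rate
    flen = int(0.05 * rate)
    if signal.n_samples < 4 * flen:
        return np.zeros(0)
    n_frames = signal.n_samples // flen
    frames = signal.samples[: n_frames * flen].reshape(n_frames, flen)
    rms = np.sqrt((frames**2).mean(axis=1))
    cutoff = np.quantile(rms, quantile)
    quiet = frames[rms <= cutoff]
    return quiet.ravel()


def extract_all(signal: AudioSignal, cycles) -> pd.DataFrame:
    """One feature row per phase segment (S1 and S2 of every cycle) plus a
    per-cycle duration row; columns fixed to :data:`FEATURE_COLUMNS`."""
    noise_ref = _quiet_noise_reference(signal)
    rows = []
    for k, cyc in enumerate(cycles):
        for phase, (a, b) in (("S1", (cyc.s1_start_s, cyc.s1_end_s)),
                              ("S2", (cyc.s2_start_s, cyc.s2_end_s))):
            row = _segment_row(signal, a, b, noise_ref)
            row.update(cycle=k, phase=phase)
            rows.append(row)
        rows.append({"cycle": k, "phase": "cycle", "duration_s": cyc.duration_s,
                     "flags": ";".join(cyc.flags)})
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df["flags"] = df["flags"].fillna("")
    return df
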