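"""Cardiac interference: detection, heart-rate estimation and suppression.

Heart tones picked up at the chest wall occupy roughly 20-150 Hz and ride
on top of the broader-band breath noise.  The chain here is: zero-phase
band-pass into the cardiac band, Hilbert envelope, adaptive peak picking
(median + k*MAD threshold, so beat times are invariant to global gain),
heart rate from the median inter-beat interval, and suppression of the
cardiac band inside the detected beat intervals via the spectral module's
mask mechanism — the timeline is never cut, so phase boundaries found later
stay aligned with the original recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, hilbert, peak_widths, sosfiltfilt

from .audio_io import AudioSignal
from .spectral import DEFAULT_HOP, DEFAULT_WINDOW_LEN, MaskEstimate, apply_mask, istft, stft

__all__ = [
    "Envelope",
    "CardiacDetection",
    "CARDIAC_BAND",
    "bandpass",
    "hilbert_envelope",
    "detect_beats",
    "suppress_cardiac",
]

#: Default heart-sound band in Hz.
CARDIAC_BAND = (20.0, 150.0)


@dataclass
class Envelope:
    """Non-negative amplitude contour at the source signal's sample rate."""

    values: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size and (not np.all(np.isfinite(self.values)) or self.values.min() < 0):
            raise ValueError("envelope values must be finite and non-negative")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sample_rate


@dataclass
class CardiacDetection:
    beat_times_s: np.ndarray
    heart_rate_bpm: float
    beat_intervals: list[tuple[float, float]] = field(default_factory=list)
    reliable: bool = True

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=np.float64)
        if self.beat_times_s.size > 1 and np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")


def bandpass(signal: AudioSignal, low_hz: float, high_hz: float, order: int = 4) -> AudioSignal:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    nyq = signal.sample_rate / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) at rate {signal.sample_rate}")
    sos = butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")
    return AudioSignal(sosfiltfilt(sos, signal.samples), signal.sample_rate)


def hilbert_envelope(signal: AudioSignal, smooth_ms: float = 20.0) -> Envelope:
    """Modulus of the analytic signal, moving-average smoothed over ``smooth_ms``."""
    if signal.n_channels != 1:
        raise ValueError("hilbert_envelope expects a mono signal")
    env = np.abs(hilbert(signal.samples))
    n = max(1, int(round(smooth_ms * 1e-3 * signal.sample_rate)))
    if n > 1:
        kernel = np.ones(n) / n
        env = np.convolve(env, kernel, mode="same")
    return Envelope(env, signal.sample_rate)


def detect_beats(
    envelope: Envelope,
    min_interval_s: float = 0.35,
    threshold_mads: float = 3.0,
) -> CardiacDetection:
    """Pick cardiac beats as envelope maxima above median + k*MAD.

    Fewer than 3 detected beats yields an unreliable detection (heart rate
    NaN).  Beat intervals span each peak by its half-prominence width.
    """
    v = envelope.values
    rate = envelope.sample_rate
    if v.size == 0:
        return CardiacDetection(np.empty(0), float("nan"), [], reliable=False)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    height = med + threshold_mads * mad
    distance = max(1, int(round(min_interval_s * rate)))
    peaks, props = find_peaks(v, height=height, distance=distance, prominence=mad)
    times = peaks / rate
    if peaks.size >= 1:
        widths = peak_widths(v, peaks, rel_height=0.5)[0] / rate
    else:
        widths = np.empty(0)
    intervals = [
        (max(0.0, t - max(w, 0.05)), min(envelope.duration_s, t + max(w, 0.05)))
        for t, w in zip(times, widths)
    ]
    if peaks.size < 3:
        return CardiacDetection(times, float("nan"), intervals, reliable=False)
    ibi = np.median(np.diff(times))
    hr = 60.0 / ibi
    reliable = 30.0 <= hr <= 220.0
    return CardiacDetection(times, hr, intervals, reliable=reliable)


def suppress_cardiac(
    signal: AudioSignal,
    detection: CardiacDetection,
    band: tuple[float, float] = CARDIAC_BAND,
    gain: float = 0.1,
    window_len: int = DEFAULT_WINDOW_LEN,
    hop: int = DEFAULT_HOP,
) -> AudioSignal:
    """Attenuate the cardiac band inside detected beat intervals.

    Realized as a time-frequency mask (gain ``gain`` on bins within ``band``
    for frames overlapping a beat interval, 1 elsewhere) so the timeline and
    everything outside the beats is preserved.
    """
    if not detection.beat_intervals:
        return signal
    spec = stft(signal, window_len, hop)
    gains = np.ones_like(spec.values, dtype=np.float64)
    freq_sel = (spec.freqs_hz >= band[0]) & (spec.freqs_hz <= band[1])
    half_win = window_len / (2.0 * signal.sample_rate)
    frame_hit = np.zeros(spec.n_frames, dtype=bool)
    for start, end in detection.beat_intervals:
        frame_hit |= (spec.times_s + half_win > start) & (spec.times_s - half_win < end)
    gains[np.ix_(freq_sel, frame_hit)] = gain
    return istft(apply_mask(spec, MaskEstimate(gains)))
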