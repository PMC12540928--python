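"""End-to-end processing chains shared by the CLI, tests and validation runs.

``preprocess`` is the standard conditioning applied to every recording
before segmentation: mono mixdown, resampling to the 16 kHz canonical rate,
peak normalization, spectral-gate denoising, and cardiac-tone suppression
inside detected beat intervals.  ``segment_recording`` runs either or both
segmentation routes on the conditioned audio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal, CANONICAL_RATE, peak_normalize, resample, to_mono
from .cardiac import CARDIAC_BAND, CardiacDetection, bandpass, detect_beats, hilbert_envelope, suppress_cardiac
from .phase_segmentation import RespiratoryCycle, segment_hmm, segment_peaks
from .spectral import denoise

__all__ = ["PreprocessInfo", "preprocess", "segment_recording"]


@dataclass
class PreprocessInfo:
    cardiac: CardiacDetection | None = None
    steps: list[str] = field(default_factory=list)


def preprocess(
    signal: AudioSignal,
    denoise_audio: bool = True,
    suppress_heart: bool = True,
    target_peak: float = 0.9,
) -> tuple[AudioSignal, PreprocessInfo]:
    """Standard conditioning chain; returns the cleaned mono 16 kHz signal
    plus diagnostics (detected beats, applied steps)."""
    info = PreprocessInfo()
    x = to_mono(signal)
    if x.sample_rate != CANONICAL_RATE:
        x = resample(x, CANONICAL_RATE)
        info.steps.append(f"resampled to {CANONICAL_RATE} Hz")
    if np.any(x.samples):
        x = peak_normalize(x, target_peak)
        info.steps.append(f"peak normalized to {target_peak}")
    if denoise_audio and x.n_samples > 5 * 512:
        x, _ = denoise(x)
        info.steps.append("spectral gate denoise")
    if suppress_heart and x.n_samples > 5 * 512:
        cardiac_band = bandpass(x, *CARDIAC_BAND)
        det = detect_beats(hilbert_envelope(cardiac_band, smooth_ms=20.0))
        info.cardiac = det
        if det.beat_intervals:
            x = suppress_cardiac(x, det)
            info.steps.append(f"suppressed {len(det.beat_intervals)} cardiac beats")
    return x, info


def segment_recording(
    signal: AudioSignal,
    method: str = "peaks",
    do_preprocess: bool = True,
    pre_highpass_hz: float | None = 150.0,
) -> dict[str, list[RespiratoryCycle]]:
    """Run the requested segmentation route(s) on a recording.

    ``method`` is ``"peaks"``, ``"hmm"`` or ``"both"``.  Returns a dict
    keyed by method name.
    """
    if method not in ("peaks", "hmm", "both"):
        raise ValueError("method must be 'peaks', 'hmm' or 'both'")
    x = signal
    if do_preprocess:
        x, _ = preprocess(signal)
    out: dict[str, list[RespiratoryCycle]] = {}
    if method in ("peaks", "both"):
        out["peaks"] = segment_peaks(x, pre_highpass_hz=pre_highpass_hz)
    if method in ("hmm", "both"):
        out["hmm"] = segment_hmm(x)
    return out
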