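"""Reading, writing and elementary conditioning of auscultation audio.

Audio travels between pipeline stages as :class:`AudioSignal` — float64
samples in [-1, 1] plus a sample rate.  Annotations (phase labels, beat
marks, ground truth from the simulator) travel as :class:`LabelTrack`, a
sorted list of half-open ``[start_s, end_s)`` intervals with a text label,
serialized either as an Audacity-style TSV label track or as CSV with a
``start_s,end_s,label`` header.

All decibel values in the package are dBFS: 0 dB corresponds to digital
full-scale amplitude 1.0.  Silence is floored at -120 dB, below the dynamic
range of 16-bit audio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioSignal",
    "LabelEntry",
    "LabelTrack",
    "RecordingMeta",
    "AudioFormatError",
    "LabelParseError",
    "DB_FLOOR",
    "CANONICAL_RATE",
    "AUSCULTATION_SITES",
    "read_wav",
    "write_wav",
    "to_mono",
    "resample",
    "peak_normalize",
    "amplitude_to_db",
    "read_labels",
    "write_labels",
    "read_meta",
    "write_meta",
]

logger = logging.getLogger(__name__)

#: dBFS value reported for exactly-zero amplitudes.
DB_FLOOR = -120.0

#: All analysis runs at this rate; higher-rate recordings are resampled on load.
CANONICAL_RATE = 16000

#: The six standardized chest auscultation sites.
AUSCULTATION_SITES = (
    "right_upper",
    "left_upper",
    "right_middle",
    "left_middle",
    "right_lower",
    "left_lower",
)


class AudioFormatError(ValueError):
    """Raised for files that are not PCM WAV or have an unsupported codec."""


class LabelParseError(ValueError):
    """Raised for malformed label-track rows; names the offending line."""


@dataclass
class AudioSignal:
    """A sampled waveform.

    ``samples`` is float64, shape ``(n,)`` for mono or ``(n, 2)`` for
    dual-channel, nominally within [-1, 1].
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (mono) or 2-D (multi-channel)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def copy(self) -> "AudioSignal":
        return AudioSignal(self.samples.copy(), self.sample_rate)


@dataclass(frozen=True)
class LabelEntry:
    start_s: float
    end_s: float
    label: str


@dataclass
class LabelTrack:
    """Sorted, validated list of labelled half-open intervals."""

    entries: list[LabelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [
            e if isinstance(e, LabelEntry) else LabelEntry(float(e[0]), float(e[1]), str(e[2]))
            for e in self.entries
        ]
        self.entries.sort(key=lambda e: (e.start_s, e.end_s))
        for e in self.entries:
            if not (0.0 <= e.start_s < e.end_s):
                raise ValueError(f"invalid interval ({e.start_s}, {e.end_s}) for label {e.label!r}")
        by_label: dict[str, float] = {}
        for e in self.entries:
            prev_end = by_label.get(e.label)
            if prev_end is not None and e.start_s < prev_end - 1e-9:
                raise ValueError(f"overlapping {e.label!r} intervals at {e.start_s:.6f}s")
            by_label[e.label] = max(e.end_s, prev_end or 0.0)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def with_label(self, label: str) -> list[LabelEntry]:
        return [e for e in self.entries if e.label == label]


@dataclass
class RecordingMeta:
    """Sidecar metadata: auscultation site, session and subject identifiers."""

    site: str
    session: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.site not in AUSCULTATION_SITES:
            raise ValueError(
                f"site {self.site!r} not one of {AUSCULTATION_SITES}"
            )


# ---------------------------------------------------------------------------
# WAV I/O

_FULL_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
    np.dtype(np.uint8): 128.0,  # offset binary
}


def read_wav(path: str | Path) -> AudioSignal:
    """Read a PCM WAV file, scaling integer samples to [-1, 1] by full scale.

    Supports 8-bit unsigned, 16/24/32-bit signed integer and 32/64-bit float
    PCM.  Dual-channel files are preserved as two channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # chunk warnings from odd writers
            rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise AudioFormatError(f"{path}: not a supported PCM WAV file ({exc})") from exc
    if data.dtype.kind == "f":
        samples = data.astype(np.float64)
    elif data.dtype in _FULL_SCALE:
        fs = _FULL_SCALE[data.dtype]
        if data.dtype == np.dtype(np.uint8):
            samples = (data.astype(np.float64) - 128.0) / fs
        else:
            samples = data.astype(np.float64) / fs
    else:
        raise AudioFormatError(f"{path}: unsupported sample dtype {data.dtype}")
    return AudioSignal(samples, int(rate))


def write_wav(path: str | Path, signal: AudioSignal, bit_depth: int = 16) -> None:
    """Write an :class:`AudioSignal` as PCM WAV (16- or 32-bit int, or float32)."""
    x = np.clip(signal.samples, -1.0, 1.0)
    if bit_depth == 16:
        data = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    elif bit_depth == 32:
        data = np.clip(np.round(x * 2147483648.0), -2147483648, 2147483647).astype(np.int32)
    elif bit_depth == 0:  # float32 passthrough
        data = signal.samples.astype(np.float32)
    else:
        raise ValueError("bit_depth must be 16, 32 or 0 (float32)")
    wavfile.write(str(path), signal.sample_rate, data)


# ---------------------------------------------------------------------------
# Elementary conditioning


def to_mono(signal: AudioSignal) -> AudioSignal:
    """Mix down to one channel by the per-sample channel mean."""
    if signal.n_channels == 1:
        return signal
    if signal.n_channels != 2:
        raise ValueError("only mono or dual-channel signals are supported")
    return AudioSignal(signal.samples.mean(axis=1), signal.sample_rate)


def resample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Band-limited (polyphase) resampling to ``target_rate``."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == signal.sample_rate:
        return signal
    frac = Fraction(int(target_rate), int(signal.sample_rate))
    out = resample_poly(signal.samples, frac.numerator, frac.denominator, axis=0)
    return AudioSignal(out, int(target_rate))


def peak_normalize(signal: AudioSignal, target_peak: float = 0.9) -> AudioSignal:
    """Scale so the absolute peak equals ``target_peak`` (in (0, 1])."""
    if not (0.0 < target_peak <= 1.0):
        raise ValueError("target_peak must be in (0, 1]")
    peak = float(np.max(np.abs(signal.samples))) if signal.n_samples else 0.0
    if peak == 0.0:
        logger.warning("peak_normalize: all-zero signal left unchanged")
        return signal
    return AudioSignal(signal.samples * (target_peak / peak), signal.sample_rate)


def amplitude_to_db(x, ref: float = 1.0):
    """Convert amplitude(s) to decibels: ``20*log10(x/ref)``, floored at -120 dB.

    ``ref`` is the 0 dB reference amplitude (full scale 1.0 throughout the
    package, i.e. dBFS).
    """
    if ref <= 0:
        raise ValueError("ref must be positive")
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("amplitudes must be non-negative")
    floor_amp = ref * 10.0 ** (DB_FLOOR / 20.0)
    out = 20.0 * np.log10(np.maximum(x, floor_amp) / ref)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Label tracks


def read_labels(path: str | Path) -> LabelTrack:
    """Read a label track: Audacity TSV (``start<TAB>end<TAB>label``) or CSV
    with a ``start_s,end_s,label`` header."""
    path = Path(path)
    entries: list[LabelEntry] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            sep = "\t" if "\t" in line else ","
            parts = [p.strip() for p in line.split(sep)]
            if lineno == 1 and parts[:2] == ["start_s", "end_s"]:
                continue  # CSV header
            if len(parts) < 3:
                raise LabelParseError(f"{path}: line {lineno}: expected 3 fields, got {len(parts)}")
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise LabelParseError(f"{path}: line {lineno}: non-numeric time") from exc
            if not (0.0 <= start < end):
                raise LabelParseError(
                    f"{path}: line {lineno}: requires 0 <= start < end, got ({start}, {end})"
                )
            entries.append(LabelEntry(start, end, sep.join(parts[2:]) if len(parts) > 3 else parts[2]))
    return LabelTrack(entries)


def write_labels(track: LabelTrack, path: str | Path, dialect: str = "tsv") -> None:
    """Write a label track as Audacity TSV or headered CSV (times to 1e-6 s)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "csv":
            fh.write("start_s,end_s,label\n")
            for e in track:
                fh.write(f"{e.start_s:.6f},{e.end_s:.6f},{e.label}\n")
        elif dialect == "tsv":
            for e in track:
                fh.write(f"{e.start_s:.6f}\t{e.end_s:.6f}\t{e.label}\n")
        else:
            raise ValueError("dialect must be 'tsv' or 'csv'")


# ---------------------------------------------------------------------------
# Metadata sidecar (key: value text)


def read_meta(path: str | Path) -> RecordingMeta:
    kv: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            kv[key.strip()] = val.strip()
    try:
        return RecordingMeta(
            site=kv["site"], session=kv.get("session", ""), subject_id=kv.get("subject_id", "")
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing required metadata key {exc}") from exc


def write_meta(meta: RecordingMeta, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"site: {meta.site}\nsession: {meta.session}\nsubject_id: {meta.subject_id}\n")
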