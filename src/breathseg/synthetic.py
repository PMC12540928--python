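"""Seedable synthetic auscultation-audio generator with ground-truth labels.

Breath cycles are quasi-periodic bursts of band-limited noise with
raised-cosine onsets/offsets: the inspiratory burst is longer and louder
than the expiratory burst, separated by short pauses, matching the
qualitative structure of chest-wall breath sounds.  Cardiac interference is
a train of exponentially damped low-frequency tones at a fixed heart rate,
and background noise is stationary white or pink noise mixed at an exact,
configurable SNR relative to the breath component.  Everything is
deterministic given the top-level seed; per-component seeds are derived by
seed splitting so adding a component never perturbs the others.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import tukey

from .audio_io import (
    AudioSignal,
    LabelEntry,
    LabelTrack,
    peak_normalize,
    read_labels,
    write_labels,
    write_wav,
)

__all__ = [
    "BreathSpec",
    "HeartSpec",
    "NoiseSpec",
    "Mixture",
    "generate_breath",
    "generate_heart",
    "mix",
    "mix_recording",
    "make_dataset",
    "regenerate_from_manifest",
    "default_suite",
]

DEFAULT_RATE = 16000


@dataclass
class BreathSpec:
    """Breath-component parameters (mean, sd pairs where applicable).

    Defaults describe a resting adult: ~4.5 s cycles, inspiration occupying
    half the cycle and expiration 40% (so S1 is longer than S2), expiratory
    amplitude 0.6 of inspiratory, 10% of the cycle silent.
    """

    n_cycles: int = 5
    cycle_period_s: tuple[float, float] = (4.5, 0.8)
    insp_frac: tuple[float, float] = (0.5, 0.05)
    insp_band_hz: tuple[float, float] = (300.0, 1800.0)
    exp_band_hz: tuple[float, float] = (200.0, 1200.0)
    exp_amp_ratio: float = 0.6
    pause_frac: float = 0.1
    edge_s: float = 0.06  # raised-cosine onset/offset length
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.exp_amp_ratio <= 1.0):
            raise ValueError("exp_amp_ratio must be in (0, 1]")
        if self.insp_frac[0] + self.pause_frac >= 1.0:
            raise ValueError("inspiration plus pauses must leave room for expiration")
        if self.cycle_period_s[1] >= self.cycle_period_s[0] / 3.0:
            raise ValueError("period sd must be below period mean / 3")


@dataclass
class HeartSpec:
    """Cardiac-tone parameters: damped sinusoid bursts at a fixed rate."""

    rate_bpm: float = 72.0
    tone_freq_hz: float = 40.0
    tone_decay_s: float = 0.05
    amplitude: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (30.0 <= self.rate_bpm <= 220.0):
            raise ValueError("rate_bpm must lie in [30, 220]")


@dataclass
class NoiseSpec:
    """Stationary background noise relative to the breath component."""

    kind: str = "white"
    snr_db: float = 15.0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "pink"):
            raise ValueError("noise kind must be 'white' or 'pink'")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclass
class Mixture:
    """A mixed recording with its scaled components retained."""

    signal: AudioSignal
    breath: AudioSignal
    heart: AudioSignal
    noise: AudioSignal
    labels: LabelTrack
    snr_db: float


def _bandnoise(rng: np.random.Generator, n: int, band: tuple[float, float], rate: int) -> np.ndarray:
    x = rng.standard_normal(n)
    nyq = rate / 2.0
    sos = butter(4, [band[0] / nyq, min(band[1], nyq * 0.99) / nyq], btype="bandpass", output="sos")
    return sosfiltfilt(sos, x)


def generate_breath(spec: BreathSpec, rate_hz: int = DEFAULT_RATE) -> tuple[AudioSignal, LabelTrack]:
    """Render the breath component and its exact S1/S2 truth labels.

    Each cycle: inspiratory burst, pause, expiratory burst, pause.  Bursts
    are band-passed white noise shaped by a Tukey (raised-cosine-edged)
    window and normalized so the expiratory/inspiratory RMS ratio equals
    ``exp_amp_ratio`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    chunks: list[np.ndarray] = []
    entries: list[LabelEntry] = []
    t = 0.0
    for _ in range(spec.n_cycles):
        period = max(float(rng.normal(*spec.cycle_period_s)), 0.5)
        # inspiration stays the longer phase: its fraction never drops below
        # half of the non-pause budget
        frac_lo = (1.0 - spec.pause_frac) / 2.0 + 0.01
        frac = float(np.clip(rng.normal(*spec.insp_frac), frac_lo, 0.8))
        pause_total = spec.pause_frac * period
        insp_dur = frac * period
        exp_dur = max(period - insp_dur - pause_total, 0.2)
        p_half = pause_total / 2.0
        for dur, amp, band, label in (
            (insp_dur, 1.0, spec.insp_band_hz, "S1"),
            (exp_dur, spec.exp_amp_ratio, spec.exp_band_hz, "S2"),
        ):
            n = max(int(round(dur * rate_hz)), 8)
            burst = _bandnoise(rng, n, band, rate_hz)
            alpha = min(1.0, 2.0 * spec.edge_s / dur)
            burst *= tukey(n, alpha)
            rms = np.sqrt(np.mean(burst**2))
            if rms > 0:
                burst *= amp / rms
            start = t
            chunks.append(burst)
            t += n / rate_hz
            entries.append(LabelEntry(start, t, label))
            n_pause = int(round(p_half * rate_hz))
            chunks.append(np.zeros(n_pause))
            t += n_pause / rate_hz
    samples = np.concatenate(chunks) if chunks else np.zeros(0)
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak > 0:  # keep within full scale, preserve internal ratios
        samples = samples / (peak / 0.9)
    return AudioSignal(samples, rate_hz), LabelTrack(entries)


def generate_heart(spec: HeartSpec, duration_s: float, rate_hz: int = DEFAULT_RATE) -> AudioSignal:
    """Exponentially damped sinusoid bursts at exact ``60/rate_bpm`` spacing."""
    n = int(round(duration_s * rate_hz))
    out = np.zeros(n)
    if spec.amplitude == 0.0:
        return AudioSignal(out, rate_hz)
    ibi = 60.0 / spec.rate_bpm
    tone_len = int(round(6.0 * spec.tone_decay_s * rate_hz))
    tt = np.arange(tone_len) / rate_hz
    tone = spec.amplitude * np.exp(-tt / spec.tone_decay_s) * np.sin(2 * np.pi * spec.tone_freq_hz * tt)
    k = 0
    while k * ibi < duration_s:
        a = int(round(k * ibi * rate_hz))
        b = min(a + tone_len, n)
        if b > a:
            out[a:b] += tone[: b - a]
        k += 1
    return AudioSignal(out, rate_hz)


def mix(
    breath: AudioSignal,
    heart: AudioSignal,
    noise: NoiseSpec,
    seed: int = 0,
    labels: LabelTrack | None = None,
    target_peak: float = 0.9,
) -> Mixture:
    """Sum breath + heart + background noise at an exact breath-vs-noise SNR.

    The shorter component is zero-padded; the mixture is peak-normalized to
    ``target_peak`` with all components scaled identically, so
    ``signal == breath + heart + noise`` holds exactly after mixing.
    """
    if breath.sample_rate != heart.sample_rate:
        raise ValueError("breath and heart sample rates differ")
    rate = breath.sample_rate
    n = max(breath.n_samples, heart.n_samples)
    b = np.pad(breath.samples, (0, n - breath.n_samples))
    h = np.pad(heart.samples, (0, n - heart.n_samples))
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(n)
    if noise.kind == "pink":
        spec = np.fft.rfft(w)
        freqs = np.fft.rfftfreq(n, d=1.0 / rate)
        with np.errstate(divide="ignore"):
            spec /= np.sqrt(np.maximum(freqs, freqs[1]))
        w = np.fft.irfft(spec, n)
    p_breath = float(np.mean(b**2))
    p_noise = float(np.mean(w**2))
    gain = np.sqrt(p_breath / (p_noise * 10.0 ** (noise.snr_db / 10.0)))
    w *= gain
    total = b + h + w
    peak = np.max(np.abs(total)) if n else 0.0
    scale = target_peak / peak if peak > 0 else 1.0
    return Mixture(
        AudioSignal(total * scale, rate),
        AudioSignal(b * scale, rate),
        AudioSignal(h * scale, rate),
        AudioSignal(w * scale, rate),
        labels if labels is not None else LabelTrack([]),
        noise.snr_db,
    )


def mix_recording(
    breath_spec: BreathSpec,
    heart_spec: HeartSpec,
    noise_spec: NoiseSpec,
    seed: int = 0,
    rate_hz: int = DEFAULT_RATE,
) -> Mixture:
    """Convenience: render breath + heart, then mix, carrying truth labels."""
    breath, labels = generate_breath(breath_spec, rate_hz)
    heart = generate_heart(heart_spec, breath.duration_s, rate_hz)
    return mix(breath, heart, noise_spec, seed=seed, labels=labels)


_MANIFEST_FIELDS = [
    "file", "label_file", "seed", "n_cycles", "cycle_period_mean", "cycle_period_sd",
    "insp_frac_mean", "insp_frac_sd", "exp_amp_ratio", "pause_frac",
    "heart_rate_bpm", "heart_amplitude", "noise_kind", "snr_db",
]


def make_dataset(
    n_recordings: int,
    out_dir: str | Path,
    seed: int = 0,
    breath_spec: BreathSpec | None = None,
    heart_spec: HeartSpec | None = None,
    noise_spec: NoiseSpec | None = None,
    rate_hz: int = DEFAULT_RATE,
) -> Path:
    """Write WAV + truth-label files + a reproducibility manifest CSV.

    Per-recording seeds are split deterministically from ``seed``; the
    manifest records every parameter needed to regenerate each file
    bit-identically (:func:`regenerate_from_manifest`).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    breath_spec = breath_spec or BreathSpec()
    heart_spec = heart_spec or HeartSpec()
    noise_spec = noise_spec or NoiseSpec()
    ss = np.random.SeedSequence(seed)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MANIFEST_FIELDS)
        writer.writeheader()
        for i, child in enumerate(ss.spawn(n_recordings)):
            child_seed = int(child.generate_state(1)[0] % (2**31))
            bs = BreathSpec(**{**asdict(breath_spec), "seed": child_seed})
            hs = HeartSpec(**{**asdict(heart_spec), "seed": child_seed + 1})
            mixture = mix_recording(bs, hs, noise_spec, seed=child_seed + 2, rate_hz=rate_hz)
            wav = out_dir / f"rec_{i:04d}.wav"
            lab = out_dir / f"rec_{i:04d}.truth.tsv"
            write_wav(wav, mixture.signal)
            write_labels(mixture.labels, lab)
            writer.writerow({
                "file": wav.name, "label_file": lab.name, "seed": child_seed,
                "n_cycles": bs.n_cycles,
                "cycle_period_mean": bs.cycle_period_s[0], "cycle_period_sd": bs.cycle_period_s[1],
                "insp_frac_mean": bs.insp_frac[0], "insp_frac_sd": bs.insp_frac[1],
                "exp_amp_ratio": bs.exp_amp_ratio, "pause_frac": bs.pause_frac,
                "heart_rate_bpm": hs.rate_bpm, "heart_amplitude": hs.amplitude,
                "noise_kind": noise_spec.kind, "snr_db": noise_spec.snr_db,
            })
    return manifest_path


def regenerate_from_manifest(manifest_path: str | Path, out_dir: str | Path, rate_hz: int = DEFAULT_RATE) -> list[Path]:
    """Re-render every recording listed in a manifest, bit-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            seed = int(row["seed"])
            bs = BreathSpec(
                n_cycles=int(row["n_cycles"]),
                cycle_period_s=(float(row["cycle_period_mean"]), float(row["cycle_period_sd"])),
                insp_frac=(float(row["insp_frac_mean"]), float(row["insp_frac_sd"])),
                exp_amp_ratio=float(row["exp_amp_ratio"]),
                pause_frac=float(row["pause_frac"]),
                seed=seed,
            )
            hs = HeartSpec(rate_bpm=float(row["heart_rate_bpm"]),
                           amplitude=float(row["heart_amplitude"]), seed=seed + 1)
            ns = NoiseSpec(kind=row["noise_kind"], snr_db=float(row["snr_db"]))
            mixture = mix_recording(bs, hs, ns, seed=seed + 2, rate_hz=rate_hz)
            wav = out_dir / row["file"]
            write_wav(wav, mixture.signal)
            write_labels(mixture.labels, out_dir / row["label_file"])
            written.append(wav)
    return written


def default_suite(n_recordings: int = 50, seed: int = 0) -> list[Mixture]:
    """The default in-memory validation suite: ``n_recordings`` mixtures at
    the generator defaults, deterministically seeded."""
    ss = np.random.SeedSequence(seed)
    suite = []
    for child in ss.spawn(n_recordings):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        suite.append(
            mix_recording(
                BreathSpec(seed=child_seed),
                HeartSpec(seed=child_seed + 1),
                NoiseSpec(),
                seed=child_seed + 2,
            )
        )
    return suite
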