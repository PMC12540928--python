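"""Flat, validated run configuration for the command-line interface.

One documented key set covering every tunable that matters downstream;
unknown keys are rejected by name.  Config files are plain ``key = value``
text; CLI ``--set key=value`` overrides win over the file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # STFT geometry (samples at the 16 kHz canonical rate)
    window_len: int = 512
    hop: int = 128
    # spectral gating
    noise_quantile: float = 0.2
    over_subtraction: float = 1.5
    mask_floor: float = 0.05
    # cardiac suppression
    cardiac_low_hz: float = 20.0
    cardiac_high_hz: float = 150.0
    cardiac_gain: float = 0.1
    beat_min_interval_s: float = 0.35
    # peak-heuristic segmentation
    envelope_lp_hz: float = 4.0
    boundary_alpha: float = 0.1
    min_cycle_s: float = 1.5
    max_cycle_s: float = 12.0
    s2_outlier_k: float = 2.0
    pre_highpass_hz: float = 150.0
    # HMM segmentation
    hmm_frame_s: float = 0.05
    hmm_hop_s: float = 0.025
    hmm_adapt_iterations: int = 3
    hmm_reference_cycles: int = 1000
    # f0 battery
    f0_min_hz: float = 50.0
    f0_max_hz: float = 800.0
    voicing_threshold: float = 0.3
    # randomness
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            cfg.set(key, val)
        return cfg

    def set(self, key: str, value: str) -> None:
        valid = {f.name: f.type for f in fields(self)}
        if key not in valid:
            raise KeyError(f"unknown config key {key!r}")
        current = getattr(self, key)
        caster = int if isinstance(current, int) else float
        setattr(self, key, caster(value))

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")
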