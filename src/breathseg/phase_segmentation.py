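"""Respiratory-cycle segmentation: peak/valley heuristic and six-state HMM.

A breathing cycle is inhalation (S1) followed by exhalation (S2).  Following
the convention of the underlying method, the inhalation phase of a cycle
runs from the start of S1 to the start of S2, the exhalation phase from the
start of S2 to the start of the next cycle's S1; the cycle duration is the
S1-start-to-next-S1-start interval.  ``s1_start/s1_end`` and
``s2_start/s2_end`` always bound the sounding bursts themselves.

Two independent segmentation routes are provided:

* **Peak heuristic** — the slow (4 Hz low-passed) Hilbert envelope of the
  denoised recording is scanned for dominant inspiratory peaks; burst
  boundaries are located where the envelope falls to
  ``valley + alpha * (peak - valley)``; the expiratory peak is the largest
  interior envelope maximum between adjacent inspiratory peaks, with a
  2-sigma amplitude outlier filter.
* **Six-state ring HMM** — states inspiration_onset, inspiration,
  inspiration_end, expiration_onset, expiration, expiration_end with only
  self- and cyclic-successor transitions.  Transition rows are initialized
  from reference normal-cycle duration statistics (self-transition
  ``1 - 1/(mean_dwell * frame_rate)``), Gaussian emissions from
  phase-conditional feature moments, and the model is adapted to each
  recording by MAP expectation-maximization with Dirichlet transition
  priors (Bayesian adaptation).  Decoding is exact Viterbi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import butter, find_peaks, get_window, sosfiltfilt

from .audio_io import AudioSignal, LabelEntry, LabelTrack
from .cardiac import Envelope, bandpass, hilbert_envelope

__all__ = [
    "STATES",
    "RespiratoryCycle",
    "PhaseSpan",
    "ObservationSequence",
    "PhaseHMM",
    "CycleAssemblyError",
    "breath_envelope",
    "detect_s1_peaks",
    "locate_phase_boundaries",
    "detect_s2_peaks",
    "filter_s2_outliers",
    "segment_cycles",
    "segment_peaks",
    "build_observations",
    "init_phase_hmm",
    "viterbi_decode",
    "adapt_hmm",
    "states_to_cycles",
    "reference_cycle_durations",
    "build_reference_hmm",
    "segment_hmm",
    "labels_to_cycles",
    "cycles_to_labels",
    "cycles_to_table",
]

#: The six respiratory phase states, in ring order.
STATES = (
    "inspiration_onset",
    "inspiration",
    "inspiration_end",
    "expiration_onset",
    "expiration",
    "expiration_end",
)

# fraction of each burst assigned to its onset / steady / end sub-state when
# mapping reference frames to states and when budgeting dwell durations
_ONSET_FRAC, _STEADY_FRAC, _END_FRAC = 0.2, 0.6, 0.2


class CycleAssemblyError(ValueError):
    """Raised when phase boundaries cannot be assembled into valid cycles."""


@dataclass
class RespiratoryCycle:
    """One breathing cycle with burst boundaries in seconds.

    Invariants: ``s1_start < s1_end <= s2_start < s2_end <= cycle_end``.
    The inhalation phase spans ``[s1_start, s2_start)``, exhalation
    ``[s2_start, cycle_end)``.  Cycles violating the typical amplitude or
    duration pattern (S1 louder and longer than S2) are flagged, never
    rejected.
    """

    s1_start_s: float
    s1_end_s: float
    s2_start_s: float
    s2_end_s: float
    cycle_end_s: float
    s1_peak_amp: float = float("nan")
    s2_peak_amp: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ok = (
            self.s1_start_s < self.s1_end_s <= self.s2_start_s < self.s2_end_s <= self.cycle_end_s
        )
        if not ok:
            raise CycleAssemblyError(
                "cycle boundaries out of order: "
                f"s1=[{self.s1_start_s:.3f},{self.s1_end_s:.3f}] "
                f"s2=[{self.s2_start_s:.3f},{self.s2_end_s:.3f}] end={self.cycle_end_s:.3f}"
            )
        if np.isfinite(self.s1_peak_amp) and np.isfinite(self.s2_peak_amp):
            if self.s1_peak_amp <= self.s2_peak_amp and "atypical_amplitude" not in self.flags:
                self.flags.append("atypical_amplitude")
        if (self.s1_end_s - self.s1_start_s) <= (self.s2_end_s - self.s2_start_s):
            if "atypical_duration" not in self.flags:
                self.flags.append("atypical_duration")

    @property
    def duration_s(self) -> float:
        return self.cycle_end_s - self.s1_start_s

    @property
    def inhalation_span(self) -> tuple[float, float]:
        return (self.s1_start_s, self.s2_start_s)

    @property
    def exhalation_span(self) -> tuple[float, float]:
        return (self.s2_start_s, self.cycle_end_s)

    @property
    def is_partial(self) -> bool:
        return "partial" in self.flags


@dataclass
class PhaseSpan:
    """A located burst: boundary times plus the peak that anchored it."""

    start_s: float
    end_s: float
    peak_time_s: float
    peak_amp: float
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Peak/valley heuristic


def breath_envelope(
    signal: AudioSignal, lp_cutoff_hz: float = 4.0, pre_highpass_hz: float | None = None
) -> Envelope:
    """Slow respiratory amplitude contour: Hilbert envelope low-passed at
    ``lp_cutoff_hz`` (default 4 Hz).  ``pre_highpass_hz`` optionally removes
    residual low-frequency (cardiac) content first."""
    if signal.n_channels != 1:
        raise ValueError("breath_envelope expects a mono signal")
    x = signal
    if pre_highpass_hz is not None:
        nyq = signal.sample_rate / 2.0
        sos = butter(4, pre_highpass_hz / nyq, btype="highpass", output="sos")
        x = AudioSignal(sosfiltfilt(sos, signal.samples), signal.sample_rate)
    env = hilbert_envelope(x, smooth_ms=10.0).values
    nyq = signal.sample_rate / 2.0
    sos = butter(4, lp_cutoff_hz / nyq, btype="lowpass", output="sos")
    smoothed = sosfiltfilt(sos, env)
    return Envelope(np.maximum(smoothed, 0.0), signal.sample_rate)


def detect_s1_peaks(
    envelope: Envelope, min_cycle_s: float = 1.5, max_cycle_s: float = 12.0
) -> list[tuple[float, float]]:
    """Dominant inspiratory peaks of the breath envelope.

    Candidates are prominent local maxima; when inspiratory and expiratory
    peaks form two amplitude clusters, only the louder cluster is kept
    (inspiration is the louder phase); remaining conflicts within
    ``min_cycle_s`` are resolved greedily largest-first.  Returns
    time-sorted ``(time_s, amplitude)`` pairs.
    """
    v = envelope.values
    rate = envelope.sample_rate
    if v.size == 0 or v.max() <= 0:
        return []
    prominence = 0.15 * (v.max() - v.min())
    idx, _ = find_peaks(v, prominence=prominence)
    if idx.size == 0:
        return []
    amps = v[idx]
    keep = _upper_amplitude_cluster(amps)
    idx, amps = idx[keep], amps[keep]
    # greedy largest-first with minimum spacing
    order = np.argsort(-amps, kind="stable")
    accepted: list[int] = []
    min_gap = min_cycle_s * rate
    for j in order:
        if all(abs(idx[j] - idx[a]) >= min_gap for a in accepted):
            accepted.append(j)
    accepted.sort(key=lambda j: idx[j])
    # merge peaks of the same burst: true phases are separated by
    # near-silent pauses, so require a deep valley between distinct peaks
    merged = True
    while merged and len(accepted) > 1:
        merged = False
        for k in range(len(accepted) - 1):
            a, b = accepted[k], accepted[k + 1]
            valley = v[idx[a] : idx[b] + 1].min()
            if valley > 0.5 * min(amps[a], amps[b]):
                del accepted[k if amps[a] < amps[b] else k + 1]
                merged = True
                break
    return [(idx[j] / rate, float(amps[j])) for j in accepted]


def _upper_amplitude_cluster(amps: np.ndarray) -> np.ndarray:
    """Boolean mask of the louder cluster from a deterministic 1-D 2-means
    split; all-true when the clusters are not meaningfully separated."""
    if amps.size < 3:
        return np.ones(amps.size, dtype=bool)
    lo, hi = float(amps.min()), float(amps.max())
    if hi - lo < 1e-12:
        return np.ones(amps.size, dtype=bool)
    c0, c1 = lo, hi
    for _ in range(50):
        assign = np.abs(amps - c1) <= np.abs(amps - c0)
        if assign.all() or not assign.any():
            return np.ones(amps.size, dtype=bool)
        n0, n1 = c0, c1
        c0, c1 = float(amps[~assign].mean()), float(amps[assign].mean())
        if abs(c0 - n0) < 1e-12 and abs(c1 - n1) < 1e-12:
            break
    if (c1 - c0) < 0.25 * hi:  # clusters too close: keep everything
        return np.ones(amps.size, dtype=bool)
    return assign


def locate_phase_boundaries(
    envelope: Envelope,
    peak_time: float,
    alpha: float = 0.1,
    left_bound_s: float | None = None,
    right_bound_s: float | None = None,
) -> PhaseSpan:
    """Burst boundaries around a detected peak.

    The start is the latest time before the peak at which the envelope falls
    to ``valley + alpha * (peak - valley)`` where the valley is the envelope
    minimum between the peak and its left neighbour (``left_bound_s``, or
    the recording start); the end is symmetric toward ``right_bound_s``.
    Boundaries clamped at the recording edges are flagged ``"edge"``.
    """
    v = envelope.values
    rate = envelope.sample_rate
    p = int(round(peak_time * rate))
    p = min(max(p, 0), v.size - 1)
    peak_amp = float(v[p])
    flags: list[str] = []

    li = 0 if left_bound_s is None else min(max(int(round(left_bound_s * rate)), 0), p)
    ri = v.size - 1 if right_bound_s is None else min(max(int(round(right_bound_s * rate)), p), v.size - 1)

    # left boundary
    if p > li:
        left_seg = v[li : p + 1]
        valley_l = float(left_seg.min())
        thr = valley_l + alpha * (peak_amp - valley_l)
        below = np.nonzero(left_seg <= thr)[0]
        if below.size:
            start = (li + below[-1]) / rate
        else:
            start = li / rate
            flags.append("edge")
    else:
        start = p / rate
        flags.append("edge")

    # right boundary
    if ri > p:
        right_seg = v[p : ri + 1]
        valley_r = float(right_seg.min())
        thr = valley_r + alpha * (peak_amp - valley_r)
        below = np.nonzero(right_seg <= thr)[0]
        if below.size:
            end = (p + below[0]) / rate
        else:
            end = ri / rate
            flags.append("edge")
    else:
        end = p / rate
        flags.append("edge")

    if end <= start:  # degenerate flat envelope around the peak
        end = start + 1.0 / rate
        flags.append("degenerate")
    return PhaseSpan(start, end, p / rate, peak_amp, flags)


def detect_s2_peaks(
    envelope: Envelope,
    s1_peaks: list[tuple[float, float]],
    outlier_k: float = 2.0,
    guard_s: float = 0.05,
    search_to_end: bool = True,
    gaps_s: list[tuple[float, float]] | None = None,
) -> list[tuple[float, float] | None]:
    """Expiratory peak per inter-S1 gap: the largest interior local maximum.

    By default the gaps run between adjacent S1 peak times; ``gaps_s``
    (e.g. the located S1 burst edges) narrows the search so shoulders of
    the inspiratory bursts themselves cannot be picked.  The gap after the
    final S1 peak is searched up to the recording end when
    ``search_to_end`` (the recording edge closes the final, partial cycle).
    Amplitude outliers beyond ``outlier_k`` sample standard deviations are
    dropped (single pass); gaps without an interior maximum yield ``None``
    ("no S2").
    """
    if len(s1_peaks) < 1:
        return []
    v = envelope.values
    rate = envelope.sample_rate
    guard = int(round(guard_s * rate))
    if gaps_s is None:
        # bound each gap by the located S1 burst edges so shoulders of the
        # inspiratory bursts themselves are never picked as S2
        times = [t for t, _ in s1_peaks]
        spans = []
        for i, t in enumerate(times):
            left = times[i - 1] if i > 0 else None
            right = times[i + 1] if i + 1 < len(times) else None
            spans.append(locate_phase_boundaries(envelope, t, 0.1, left, right))
        gaps_s = [(spans[i].end_s, spans[i + 1].start_s) for i in range(len(spans) - 1)]
        if search_to_end:
            gaps_s.append((spans[-1].end_s, envelope.duration_s))
    gaps = [(int(round(a * rate)), int(round(b * rate))) for a, b in gaps_s]

    candidates: list[tuple[float, float] | None] = []
    for a, b in gaps:
        lo, hi = a + guard, b - guard
        if hi - lo < 3:
            candidates.append(None)
            continue
        seg = v[lo : hi + 1]
        pidx, _ = find_peaks(seg)
        if pidx.size == 0:
            candidates.append(None)
            continue
        best = pidx[np.argmax(seg[pidx])]
        candidates.append(((lo + best) / rate, float(seg[best])))

    present = [c for c in candidates if c is not None]
    kept = set(id(c) for c in filter_s2_outliers(present, k=outlier_k))
    return [c if (c is not None and id(c) in kept) else None for c in candidates]


def filter_s2_outliers(
    candidates: list[tuple[float, float]], k: float = 2.0
) -> list[tuple[float, float]]:
    """Drop candidates whose amplitude deviates from the mean by more than
    ``k`` sample standard deviations (single pass; pass-through below 3)."""
    if len(candidates) < 3:
        return list(candidates)
    amps = np.array([a for _, a in candidates])
    mean, std = amps.mean(), amps.std(ddof=1)
    if std == 0:
        return list(candidates)
    return [c for c, a in zip(candidates, amps) if abs(a - mean) <= k * std]


def segment_cycles(
    s1_spans: list[PhaseSpan],
    s2_spans: list[PhaseSpan | None],
    recording_end_s: float,
) -> list[RespiratoryCycle]:
    """Assemble located S1/S2 bursts into respiratory cycles.

    ``s2_spans[i]`` is the expiratory burst following ``s1_spans[i]`` (or
    None).  A cycle closes at the next S1 start; the final cycle closes at
    ``recording_end_s`` and is flagged ``"partial"``.  Cycles without an S2
    are dropped.  Overlapping boundaries raise :class:`CycleAssemblyError`
    naming the pair.
    """
    cycles: list[RespiratoryCycle] = []
    n = len(s1_spans)
    for i, s1 in enumerate(s1_spans):
        s2 = s2_spans[i] if i < len(s2_spans) else None
        if s2 is None:
            continue
        if s2.start_s < s1.end_s - 1e-9:
            raise CycleAssemblyError(
                f"S2 starting {s2.start_s:.3f}s overlaps S1 ending {s1.end_s:.3f}s"
            )
        if i + 1 < n:
            cycle_end = s1_spans[i + 1].start_s
            flags = []
        else:
            cycle_end = recording_end_s
            flags = ["partial"]
        if s2.end_s > cycle_end + 1e-9:
            raise CycleAssemblyError(
                f"S2 ending {s2.end_s:.3f}s overlaps the next cycle at {cycle_end:.3f}s"
            )
        cycles.append(
            RespiratoryCycle(
                s1.start_s, s1.end_s, s2.start_s, min(s2.end_s, cycle_end), cycle_end,
                s1_peak_amp=s1.peak_amp, s2_peak_amp=s2.peak_amp, flags=flags,
            )
        )
    return cycles


def segment_peaks(
    signal: AudioSignal,
    lp_cutoff_hz: float = 4.0,
    alpha: float = 0.1,
    min_cycle_s: float = 1.5,
    max_cycle_s: float = 12.0,
    pre_highpass_hz: float | None = None,
) -> list[RespiratoryCycle]:
    """Full peak/valley-heuristic segmentation of a (denoised) recording."""
    env = breath_envelope(signal, lp_cutoff_hz, pre_highpass_hz)
    s1_peaks = detect_s1_peaks(env, min_cycle_s, max_cycle_s)
    if not s1_peaks:
        return []
    times = [t for t, _ in s1_peaks]
    s1_spans = []
    for i, t in enumerate(times):
        left = times[i - 1] if i > 0 else None
        right = times[i + 1] if i + 1 < len(times) else None
        s1_spans.append(locate_phase_boundaries(env, t, alpha, left, right))
    gaps_s = [
        (s1_spans[i].end_s, s1_spans[i + 1].start_s) for i in range(len(s1_spans) - 1)
    ] + [(s1_spans[-1].end_s, signal.duration_s)]
    s2_peaks = detect_s2_peaks(env, s1_peaks, gaps_s=gaps_s)
    s2_spans: list[PhaseSpan | None] = []
    for i, cand in enumerate(s2_peaks):
        if cand is None:
            s2_spans.append(None)
            continue
        right = times[i + 1] if i + 1 < len(times) else None
        span = locate_phase_boundaries(env, cand[0], alpha, times[i], right)
        # guard against smoothing artifacts: a burst bleeding into its S1
        # or into the next cycle's S1
        if span.start_s < s1_spans[i].end_s:
            span.start_s = s1_spans[i].end_s
            span.flags.append("clipped")
        if i + 1 < len(s1_spans) and span.end_s > s1_spans[i + 1].start_s:
            span.end_s = s1_spans[i + 1].start_s
            span.flags.append("clipped")
        if span.end_s <= span.start_s:
            span = None
        s2_spans.append(span)
    return segment_cycles(s1_spans, s2_spans, signal.duration_s)


# ---------------------------------------------------------------------------
# HMM route


@dataclass
class ObservationSequence:
    """Per-frame HMM emission features: log envelope, envelope slope,
    spectral centroid; z-scored per recording."""

    frames: np.ndarray  # (n_frames, n_features)
    frame_rate: float
    times_s: np.ndarray  # frame centers

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=np.float64))
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("observation features must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class PhaseHMM:
    """Gaussian-emission HMM over respiratory phase states.

    The six-state phase model uses a left-to-right ring topology: row i of
    the transition matrix is non-zero only at i (self) and (i+1) mod n
    (successor).  ``prior_counts`` are Dirichlet pseudo-counts for MAP
    adaptation of the transition rows.  ``topology="full"`` admits arbitrary
    chains (used for small test models).
    """

    states: tuple[str, ...]
    transition: np.ndarray
    means: np.ndarray  # (n_states, n_features)
    variances: np.ndarray  # (n_states, n_features), diagonal
    initial: np.ndarray
    prior_counts: np.ndarray
    topology: str = "ring"

    def __post_init__(self) -> None:
        n = len(self.states)
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=np.float64))
        self.initial = np.asarray(self.initial, dtype=np.float64)
        self.prior_counts = np.asarray(self.prior_counts, dtype=np.float64)
        if self.transition.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("emission variances must be positive")
        if self.topology == "ring":
            allowed = np.zeros((n, n), dtype=bool)
            for i in range(n):
                allowed[i, i] = allowed[i, (i + 1) % n] = True
            if np.any(self.transition[~allowed] != 0):
                raise ValueError("ring topology admits only self and successor transitions")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def log_emission(self, frames: np.ndarray) -> np.ndarray:
        """(n_frames, n_states) diagonal-Gaussian log-likelihoods."""
        x = frames[:, None, :]  # (T, 1, d)
        mu = self.means[None, :, :]
        var = self.variances[None, :, :]
        return -0.5 * np.sum(np.log(2 * np.pi * var) + (x - mu) ** 2 / var, axis=2)


def build_observations(
    signal: AudioSignal, frame_s: float = 0.05, hop_s: float = 0.025
) -> ObservationSequence:
    """Frame the recording into (log envelope, envelope slope, spectral
    centroid) features, z-scored per recording.

    Frame count is ``floor((duration - frame) / hop) + 1`` with frames
    anchored at the recording start.
    """
    if signal.n_channels != 1:
        raise ValueError("build_observations expects a mono signal")
    rate = signal.sample_rate
    flen = int(round(frame_s * rate))
    hop = int(round(hop_s * rate))
    if signal.n_samples < flen:
        raise ValueError("recording shorter than one frame")
    n_frames = (signal.n_samples - flen) // hop + 1

    env = breath_envelope(signal).values
    win = get_window("hann", flen, fftbins=True)
    freqs = np.fft.rfftfreq(flen, d=1.0 / rate)

    log_env = np.empty(n_frames)
    centroid = np.empty(n_frames)
    eps = 1e-10
    for i in range(n_frames):
        a = i * hop
        seg = signal.samples[a : a + flen]
        log_env[i] = math.log(float(env[a : a + flen].mean()) + eps)
        mag = np.abs(np.fft.rfft(seg * win))
        denom = mag.sum()
        centroid[i] = float((freqs * mag).sum() / denom) if denom > eps else 0.0
    slope = np.gradient(log_env)

    feats = np.column_stack([log_env, slope, centroid])
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    constant = std <= 1e-10 * np.maximum(1.0, np.abs(mean))
    std[constant] = 1.0
    feats = (feats - mean) / std
    feats[:, constant] = 0.0
    times = (np.arange(n_frames) * hop + flen / 2.0) / rate
    return ObservationSequence(feats, rate / hop, times)


def init_phase_hmm(
    mean_durations_s,
    frame_rate: float,
    emission_means=None,
    emission_variances=None,
    n_reference_cycles: int = 1000,
    states: tuple[str, ...] = STATES,
) -> PhaseHMM:
    """Ring HMM from per-state mean dwell durations.

    Self-transition ``p_i = 1 - 1/(mean_dur_i * frame_rate)`` gives the
    geometric dwell matching the reference mean; Dirichlet prior counts are
    the expected transition counts over ``n_reference_cycles`` reference
    cycles.  Emissions default to standard normals when no reference
    moments are supplied.
    """
    dur = np.asarray(mean_durations_s, dtype=np.float64)
    n = len(states)
    if dur.shape != (n,) or np.any(dur <= 0):
        raise ValueError(f"need {n} positive mean durations")
    dwell = np.maximum(dur * frame_rate, 1.0 + 1e-6)  # at least one frame
    p_self = 1.0 - 1.0 / dwell
    trans = np.zeros((n, n))
    prior = np.zeros((n, n))
    for i in range(n):
        trans[i, i] = p_self[i]
        trans[i, (i + 1) % n] = 1.0 - p_self[i]
        # per reference cycle: dwell-1 self transitions and 1 exit
        prior[i, i] = n_reference_cycles * (dwell[i] - 1.0)
        prior[i, (i + 1) % n] = n_reference_cycles * 1.0
    d = 3 if emission_means is None else np.atleast_2d(emission_means).shape[1]
    means = np.zeros((n, d)) if emission_means is None else np.atleast_2d(emission_means)
    variances = np.ones((n, d)) if emission_variances is None else np.atleast_2d(emission_variances)
    initial = np.full(n, 1.0 / n)
    return PhaseHMM(tuple(states), trans, means, variances, initial, prior, topology="ring")


def viterbi_decode(obs: ObservationSequence, model: PhaseHMM) -> np.ndarray:
    """Maximum-a-posteriori state path (log-domain Viterbi).

    Ties break toward the lowest state index.  Raises on numerically
    impossible observations (all transitions/emissions -inf at some frame).
    """
    frames = obs.frames
    if frames.shape[0] == 0:
        raise ValueError("need at least one frame")
    with np.errstate(divide="ignore"):
        log_trans = np.log(model.transition)
        log_init = np.log(model.initial)
    log_emis = model.log_emission(frames)
    T, n = log_emis.shape
    delta = log_init + log_emis[0]
    back = np.zeros((T, n), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + log_trans  # (from, to)
        back[t] = np.argmax(scores, axis=0)  # first max -> lowest index
        delta = scores[back[t], np.arange(n)] + log_emis[t]
        if not np.any(np.isfinite(delta)):
            raise FloatingPointError(f"all paths impossible at frame {t}")
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _forward_backward(model: PhaseHMM, frames: np.ndarray):
    """Scaled forward-backward; returns (gamma, xi_sum, loglik)."""
    log_emis = model.log_emission(frames)
    # per-frame shift keeps the scaled recursion in range
    b = np.exp(log_emis - log_emis.max(axis=1, keepdims=True))
    shift = log_emis.max(axis=1)
    A = model.transition
    T, n = b.shape
    alpha = np.empty((T, n))
    c = np.empty(T)
    alpha[0] = model.initial * b[0]
    c[0] = alpha[0].sum()
    if c[0] <= 0:
        raise FloatingPointError("zero likelihood at frame 0")
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * b[t]
        c[t] = alpha[t].sum()
        if c[t] <= 0:
            raise FloatingPointError(f"zero likelihood at frame {t}")
        alpha[t] /= c[t]
    beta = np.empty((T, n))
    beta[-1] = 1.0
    xi_sum = np.zeros((n, n))
    for t in range(T - 2, -1, -1):
        beta[t] = (A * (b[t + 1] * beta[t + 1])[None, :]).sum(axis=1) / c[t + 1]
        xi = alpha[t][:, None] * A * (b[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(c)) + np.sum(shift))
    return gamma, xi_sum, loglik


# weak conjugate emission priors (normal-inverse-gamma) for MAP adaptation
_EM_KAPPA = 1.0
_EM_ALPHA = 1.0
_EM_BETA = 0.1


def _log_prior(model: PhaseHMM, mu0: np.ndarray, var0: np.ndarray) -> float:
    """Unnormalized log prior: Dirichlet transitions + NIG emissions."""
    with np.errstate(divide="ignore"):
        lt = np.log(model.transition)
    mask = model.prior_counts > 0
    lp = float(np.sum(model.prior_counts[mask] * lt[mask]))
    var = model.variances
    lp += float(
        np.sum(
            -(_EM_ALPHA + 1.5) * np.log(var)
            - (_EM_BETA + 0.5 * _EM_KAPPA * (model.means - mu0) ** 2) / var
        )
    )
    return lp


def adapt_hmm(model: PhaseHMM, obs: ObservationSequence, iterations: int = 20) -> PhaseHMM:
    """Bayesian (MAP) adaptation of transitions and emissions to one recording.

    Expectation-maximization with Dirichlet transition priors
    (``prior_counts``) and weak conjugate normal-inverse-gamma emission
    priors centered on the current model.  Structural zeros are preserved;
    the recorded posterior objective (``objective_history_`` on the result)
    is non-decreasing.  States with degenerate posterior occupancy keep
    their prior parameters.
    """
    if obs.n_frames < model.n_states:
        raise ValueError("need at least one frame per state to adapt")
    cur = PhaseHMM(
        model.states, model.transition.copy(), model.means.copy(),
        model.variances.copy(), model.initial.copy(), model.prior_counts.copy(),
        model.topology,
    )
    mu0, var0 = model.means.copy(), model.variances.copy()
    history: list[float] = []
    frames = obs.frames
    structure = model.transition > 0
    for _ in range(max(iterations, 0)):
        gamma, xi_sum, loglik = _forward_backward(cur, frames)
        history.append(loglik + _log_prior(cur, mu0, var0))
        # M-step: MAP transitions over the structural support
        counts = xi_sum + cur.prior_counts
        counts[~structure] = 0.0
        row = counts.sum(axis=1, keepdims=True)
        new_trans = np.where(row > 0, counts / np.maximum(row, 1e-300), cur.transition)
        # M-step: MAP emissions
        occ = gamma.sum(axis=0)  # (n,)
        new_means = cur.means.copy()
        new_vars = cur.variances.copy()
        for i in range(cur.n_states):
            if occ[i] < 1e-8:
                continue  # degenerate: revert to prior for this state
            sx = gamma[:, i] @ frames
            mu = (_EM_KAPPA * mu0[i] + sx) / (_EM_KAPPA + occ[i])
            sse = gamma[:, i] @ (frames - mu) ** 2
            var = (2 * _EM_BETA + _EM_KAPPA * (mu - mu0[i]) ** 2 + sse) / (
                occ[i] + 2 * _EM_ALPHA + 3
            )
            new_means[i] = mu
            new_vars[i] = np.maximum(var, 1e-8)
        cur = PhaseHMM(
            cur.states, new_trans, new_means, new_vars, cur.initial,
            cur.prior_counts, cur.topology,
        )
    if iterations > 0:
        _, _, loglik = _forward_backward(cur, frames)
        history.append(loglik + _log_prior(cur, mu0, var0))
    cur.objective_history_ = history
    return cur


def states_to_cycles(
    path: np.ndarray,
    frame_rate: float,
    time_offset_s: float = 0.0,
    keep_final_partial: bool = True,
) -> list[RespiratoryCycle]:
    """Convert a decoded six-state path into respiratory cycles.

    ``s1_start`` at each entry into inspiration_onset, ``s1_end``/``s2_start``
    at the entry into expiration_onset (the exit of inspiration_end), and
    ``s2_end``/``cycle_end`` at the next inspiration_onset entry.  A final
    traversal that reached expiration but not the next cycle start is closed
    at the path end and flagged partial.
    """
    path = np.asarray(path)
    t = lambda j: j / frame_rate + time_offset_s

    entries0 = [0] if path.size and path[0] == 0 else []
    entries0 += [j for j in range(1, path.size) if path[j] == 0 and path[j - 1] != 0]
    cycles: list[RespiratoryCycle] = []
    for k, a in enumerate(entries0):
        b = entries0[k + 1] if k + 1 < len(entries0) else path.size
        seg = path[a:b]
        rel3 = np.nonzero((seg == 3) & (np.roll(seg, 1) != 3))[0]
        rel3 = rel3[rel3 > 0]
        if rel3.size == 0:
            continue  # never reached expiration: no complete phase pair
        j3 = a + int(rel3[0])
        partial = k + 1 >= len(entries0)
        if partial and not keep_final_partial:
            continue
        end_t = t(b)
        flags = ["partial"] if partial else []
        try:
            cycles.append(
                RespiratoryCycle(t(a), t(j3), t(j3), end_t, end_t, flags=flags)
            )
        except CycleAssemblyError:
            continue
    return cycles


# ---------------------------------------------------------------------------
# Reference priors ("normal respiratory cycle statistics")

# No reference corpus of normal cycles is distributable, so the prior
# statistics are computed from the package's own breath-sound simulator:
# dwell durations analytically from the generator's cycle distribution and
# emission moments from a small set of rendered, labelled recordings.


def reference_cycle_durations(n_cycles: int = 1000, seed: int = 0, spec=None) -> np.ndarray:
    """Mean dwell duration (s) per phase state over ``n_cycles`` reference
    cycles drawn from the breath generator's cycle distribution.

    Inter-phase pauses are split evenly between the adjacent end/onset
    states, so each state's dwell covers a contiguous share of the cycle.
    """
    from .synthetic import BreathSpec

    spec = spec or BreathSpec()
    rng = np.random.default_rng(seed)
    period = np.maximum(rng.normal(spec.cycle_period_s[0], spec.cycle_period_s[1], n_cycles), 0.5)
    frac_lo = (1.0 - spec.pause_frac) / 2.0 + 0.01
    insp_frac = np.clip(rng.normal(spec.insp_frac[0], spec.insp_frac[1], n_cycles), frac_lo, 0.8)
    pause = spec.pause_frac * period
    insp = insp_frac * period
    exp = period - insp - pause
    p_half = pause / 4.0  # two pauses, each split in half
    dwell = np.column_stack([
        _ONSET_FRAC * insp + p_half,
        _STEADY_FRAC * insp,
        _END_FRAC * insp + p_half,
        _ONSET_FRAC * exp + p_half,
        _STEADY_FRAC * exp,
        _END_FRAC * exp + p_half,
    ])
    return dwell.mean(axis=0)


def _frame_states_from_cycles(
    cycles: list[RespiratoryCycle], times_s: np.ndarray
) -> np.ndarray:
    """Hard state label per frame center; -1 outside any cycle."""
    labels = np.full(times_s.size, -1, dtype=np.intp)
    for cyc in cycles:
        t0, t1 = cyc.s1_start_s, cyc.s1_end_s
        t2, t3 = cyc.s2_start_s, cyc.s2_end_s
        end = cyc.cycle_end_s
        insp_len, exp_len = t1 - t0, t3 - t2
        edges = [
            (t0, t0 + _ONSET_FRAC * insp_len, 0),
            (t0 + _ONSET_FRAC * insp_len, t1 - _END_FRAC * insp_len, 1),
            (t1 - _END_FRAC * insp_len, (t1 + t2) / 2.0, 2),  # tail + half pause
            ((t1 + t2) / 2.0, t2 + _ONSET_FRAC * exp_len, 3),
            (t2 + _ONSET_FRAC * exp_len, t3 - _END_FRAC * exp_len, 4),
            (t3 - _END_FRAC * exp_len, end, 5),
        ]
        for lo, hi, s in edges:
            labels[(times_s >= lo) & (times_s < hi)] = s
    return labels


@lru_cache(maxsize=4)
def build_reference_hmm(
    frame_s: float = 0.05,
    hop_s: float = 0.025,
    n_reference_cycles: int = 1000,
    n_reference_recordings: int = 6,
    seed: int = 0,
) -> PhaseHMM:
    """Six-state phase HMM with priors from simulated normal cycles.

    Transition rows come from :func:`reference_cycle_durations`; emission
    moments from ``n_reference_recordings`` rendered recordings passed
    through the same preprocessing as real input.
    """
    from .pipeline import preprocess
    from .synthetic import BreathSpec, HeartSpec, NoiseSpec, mix_recording

    durations = reference_cycle_durations(n_reference_cycles, seed)
    frame_rate = 1.0 / hop_s

    pooled: list[np.ndarray] = []
    pooled_states: list[np.ndarray] = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_reference_recordings):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        mixture = mix_recording(
            BreathSpec(seed=child_seed),
            HeartSpec(seed=child_seed + 1),
            NoiseSpec(),
            seed=child_seed + 2,
        )
        clean, _ = preprocess(mixture.signal)
        obs = build_observations(clean, frame_s, hop_s)
        truth = labels_to_cycles(mixture.labels, mixture.signal.duration_s)
        states = _frame_states_from_cycles(truth, obs.times_s)
        pooled.append(obs.frames)
        pooled_states.append(states)
    frames = np.concatenate(pooled, axis=0)
    states = np.concatenate(pooled_states)
    d = frames.shape[1]
    means = np.zeros((6, d))
    variances = np.ones((6, d))
    for i in range(6):
        sel = states == i
        if sel.sum() >= 2:
            means[i] = frames[sel].mean(axis=0)
            variances[i] = np.maximum(frames[sel].var(axis=0), 1e-4)
    return init_phase_hmm(durations, frame_rate, means, variances, n_reference_cycles)


def segment_hmm(
    signal: AudioSignal,
    model: PhaseHMM | None = None,
    frame_s: float = 0.05,
    hop_s: float = 0.025,
    adapt_iterations: int = 3,
) -> list[RespiratoryCycle]:
    """HMM-route segmentation of a (denoised) recording."""
    if model is None:
        model = build_reference_hmm(frame_s, hop_s)
    obs = build_observations(signal, frame_s, hop_s)
    if adapt_iterations > 0:
        model = adapt_hmm(model, obs, adapt_iterations)
    path = viterbi_decode(obs, model)
    return states_to_cycles(path, obs.frame_rate, time_offset_s=float(obs.times_s[0]))


# ---------------------------------------------------------------------------
# Cycle <-> label conversions


def labels_to_cycles(track: LabelTrack, recording_end_s: float) -> list[RespiratoryCycle]:
    """Build cycles from S1/S2 labels (e.g. simulator ground truth)."""
    s1 = track.with_label("S1")
    s2 = track.with_label("S2")
    cycles = []
    for i, e1 in enumerate(s1):
        nxt = s1[i + 1].start_s if i + 1 < len(s1) else recording_end_s
        match = [e for e in s2 if e1.end_s - 1e-9 <= e.start_s and e.end_s <= nxt + 1e-9]
        if not match:
            continue
        e2 = match[0]
        flags = ["partial"] if i + 1 >= len(s1) else []
        cycles.append(
            RespiratoryCycle(e1.start_s, e1.end_s, e2.start_s, e2.end_s, nxt, flags=flags)
        )
    return cycles


def cycles_to_labels(cycles: list[RespiratoryCycle]) -> LabelTrack:
    """Burst spans as an S1/S2 label track (Audacity-style export)."""
    entries = []
    for c in cycles:
        entries.append(LabelEntry(c.s1_start_s, c.s1_end_s, "S1"))
        entries.append(LabelEntry(c.s2_start_s, c.s2_end_s, "S2"))
    return LabelTrack(entries)


def cycles_to_table(cycles: list[RespiratoryCycle]):
    """Per-cycle DataFrame: s1_start,s1_end,s2_start,s2_end,cycle_end,duration_s."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "s1_start": c.s1_start_s,
                "s1_end": c.s1_end_s,
                "s2_start": c.s2_start_s,
                "s2_end": c.s2_end_s,
                "cycle_end": c.cycle_end_s,
                "duration_s": c.duration_s,
            }
            for c in cycles
        ],
        columns=["s1_start", "s1_end", "s2_start", "s2_end", "cycle_end", "duration_s"],
    )
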