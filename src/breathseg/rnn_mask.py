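"""Trainable recurrent time-frequency mask estimator.

Architecture: three stacked bidirectional recurrent (tanh) layers over the
log-magnitude spectrogram frames, followed by a per-bin sigmoid readout, so
the output is a gain matrix in [0, 1] with exactly the input's shape.  The
recurrent weights are drawn once from the seed (echo-state style, spectral
radius < 1 for stability); training fits the readout to ideal-ratio-mask
targets ``|clean| / (|clean| + |noise|)`` by full-batch gradient descent
with a backtracking line search, which makes the recorded mask-MSE history
non-increasing by construction and the whole procedure deterministic given
the seed.

This is the package's trainable counterpart to the deterministic
spectral-gating path; both produce a :class:`~breathseg.spectral.MaskEstimate`
from a :class:`~breathseg.spectral.Spectrogram`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio_io import AudioSignal
from .spectral import DEFAULT_HOP, DEFAULT_WINDOW_LEN, MaskEstimate, Spectrogram, stft

__all__ = ["MaskEstimatorModel", "train_mask_estimator", "ideal_ratio_mask"]

_LOG_EPS = 1e-8


def _log_features(spec: Spectrogram) -> np.ndarray:
    """Frame-major (n_frames, n_bins) log-magnitude features."""
    return np.log(np.abs(spec.values).T + _LOG_EPS)


def ideal_ratio_mask(clean: Spectrogram, noise: Spectrogram) -> MaskEstimate:
    """IRM target |clean| / (|clean| + |noise|), 0.5 where both vanish."""
    c, n = np.abs(clean.values), np.abs(noise.values)
    denom = c + n
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(denom > 0, c / np.maximum(denom, 1e-300), 0.5)
    return MaskEstimate(m)


@dataclass
class MaskEstimatorModel:
    """Seed-deterministic bidirectional recurrent mask estimator."""

    n_bins: int
    hidden_size: int = 24
    n_layers: int = 3
    window_len: int = DEFAULT_WINDOW_LEN
    hop: int = DEFAULT_HOP
    seed: int = 0
    # learned / derived state
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None
    layers: list[dict] = field(default_factory=list)
    readout_w: np.ndarray | None = None
    readout_b: np.ndarray | None = None
    loss_history: list[float] = field(default_factory=list)

    def init_weights(self) -> None:
        """Draw the fixed recurrent weights from the seed."""
        rng = np.random.default_rng(self.seed)
        self.layers = []
        in_dim = self.n_bins
        for _ in range(self.n_layers):
            layer = {}
            for direction in ("fwd", "bwd"):
                w_in = rng.standard_normal((self.hidden_size, in_dim)) / np.sqrt(in_dim)
                w_rec = rng.standard_normal((self.hidden_size, self.hidden_size))
                rho = np.max(np.abs(np.linalg.eigvals(w_rec)))
                w_rec *= 0.9 / max(rho, 1e-12)
                b = rng.standard_normal(self.hidden_size) * 0.1
                layer[direction] = (w_in, w_rec, b)
            self.layers.append(layer)
            in_dim = 2 * self.hidden_size
        self.readout_w = np.zeros((2 * self.hidden_size, self.n_bins))
        self.readout_b = np.zeros(self.n_bins)

    # -- forward ----------------------------------------------------------

    def _run_direction(self, x: np.ndarray, w_in, w_rec, b, reverse: bool) -> np.ndarray:
        T = x.shape[0]
        h = np.zeros((T, self.hidden_size))
        state = np.zeros(self.hidden_size)
        order = range(T - 1, -1, -1) if reverse else range(T)
        pre = x @ w_in.T + b
        for t in order:
            state = np.tanh(pre[t] + w_rec @ state)
            h[t] = state
        return h

    def hidden_states(self, features: np.ndarray) -> np.ndarray:
        """(n_frames, n_bins) normalized features -> (n_frames, 2*hidden)."""
        x = features
        for layer in self.layers:
            fwd = self._run_direction(x, *layer["fwd"], reverse=False)
            bwd = self._run_direction(x, *layer["bwd"], reverse=True)
            x = np.concatenate([fwd, bwd], axis=1)
        return x

    def _normalize(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self.feat_mean) / self.feat_std

    def predict_mask(self, spec: Spectrogram) -> MaskEstimate:
        if spec.n_freq_bins != self.n_bins:
            raise ValueError("spectrogram geometry does not match the model")
        if self.readout_w is None or self.feat_mean is None:
            raise RuntimeError("model is untrained")
        h = self.hidden_states(self._normalize(_log_features(spec)))
        logits = h @ self.readout_w + self.readout_b
        gains = 1.0 / (1.0 + np.exp(-logits))
        return MaskEstimate(gains.T)

    def denoise(self, signal: AudioSignal) -> AudioSignal:
        from .spectral import apply_mask, istft

        spec = stft(signal, self.window_len, self.hop)
        return istft(apply_mask(spec, self.predict_mask(spec)))

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint as JSON with a self-describing geometry header."""
        payload = {
            "geometry": {
                "n_bins": self.n_bins,
                "hidden_size": self.hidden_size,
                "n_layers": self.n_layers,
                "window_len": self.window_len,
                "hop": self.hop,
                "seed": self.seed,
            },
            "feat_mean": self.feat_mean.tolist(),
            "feat_std": self.feat_std.tolist(),
            "layers": [
                {d: [w.tolist() for w in layer[d]] for d in ("fwd", "bwd")}
                for layer in self.layers
            ],
            "readout_w": self.readout_w.tolist(),
            "readout_b": self.readout_b.tolist(),
            "loss_history": self.loss_history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MaskEstimatorModel":
        payload = json.loads(Path(path).read_text())
        model = cls(**payload["geometry"])
        model.feat_mean = np.asarray(payload["feat_mean"])
        model.feat_std = np.asarray(payload["feat_std"])
        model.layers = [
            {d: tuple(np.asarray(w) for w in layer[d]) for d in ("fwd", "bwd")}
            for layer in payload["layers"]
        ]
        model.readout_w = np.asarray(payload["readout_w"])
        model.readout_b = np.asarray(payload["readout_b"])
        model.loss_history = list(payload["loss_history"])
        return model


def train_mask_estimator(
    pairs: list[tuple[AudioSignal, AudioSignal]],
    epochs: int = 60,
    seed: int = 0,
    hidden_size: int = 24,
    window_len: int = DEFAULT_WINDOW_LEN,
    hop: int = DEFAULT_HOP,
) -> MaskEstimatorModel:
    """Fit the readout of a :class:`MaskEstimatorModel` on (noisy, clean) pairs.

    Targets are ideal ratio masks computed from each pair (noise taken as
    ``noisy - clean`` in the time domain).  Deterministic given ``seed``;
    ``model.loss_history`` records the non-increasing training mask MSE.
    """
    if not pairs:
        raise ValueError("need at least one (noisy, clean) training pair")
    specs, targets = [], []
    for noisy, clean in pairs:
        if noisy.sample_rate != clean.sample_rate or noisy.n_samples != clean.n_samples:
            raise ValueError("each pair must share sample rate and length")
        s_noisy = stft(noisy, window_len, hop)
        s_clean = stft(clean, window_len, hop)
        noise = AudioSignal(noisy.samples - clean.samples, noisy.sample_rate)
        s_noise = stft(noise, window_len, hop)
        specs.append(s_noisy)
        targets.append(ideal_ratio_mask(s_clean, s_noise).gains.T)

    model = MaskEstimatorModel(
        n_bins=specs[0].n_freq_bins, hidden_size=hidden_size,
        window_len=window_len, hop=hop, seed=seed,
    )
    model.init_weights()

    feats = [_log_features(s) for s in specs]
    stacked = np.concatenate(feats, axis=0)
    model.feat_mean = stacked.mean(axis=0)
    model.feat_std = np.maximum(stacked.std(axis=0), 1e-6)

    hidden = np.concatenate(
        [model.hidden_states(model._normalize(f)) for f in feats], axis=0
    )
    target = np.concatenate(targets, axis=0)
    n, _ = hidden.shape

    w = np.zeros((hidden.shape[1], model.n_bins))
    b = np.zeros(model.n_bins)

    def loss_of(wm, bm):
        p = 1.0 / (1.0 + np.exp(-(hidden @ wm + bm)))
        return float(np.mean((p - target) ** 2)), p

    loss, p = loss_of(w, b)
    model.loss_history = [loss]
    step = 1.0
    for _ in range(epochs):
        delta = 2.0 * (p - target) * p * (1.0 - p) / p.size
        grad_w = hidden.T @ delta
        grad_b = delta.sum(axis=0)
        # backtracking line search keeps the recorded loss monotone
        improved = False
        for _ in range(40):
            cand_w = w - step * grad_w
            cand_b = b - step * grad_b
            cand_loss, cand_p = loss_of(cand_w, cand_b)
            if cand_loss <= loss:
                w, b, loss, p = cand_w, cand_b, cand_loss, cand_p
                improved = True
                step *= 1.5  # allow growth again after a success
                break
            step *= 0.5
        model.loss_history.append(loss)
        if not improved:
            break

    model.readout_w = w
    model.readout_b = b
    return model
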