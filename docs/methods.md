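# Methods

This note records the models, parameter choices and known limitations of
`breathseg` — what the package computes and why, in enough detail to
re-derive every default.

## Signal model and conditioning

A recording is a mono (after mean mixdown of dual-channel input) waveform
in [-1, 1] at the canonical 16 kHz analysis rate; 44.1 kHz input is
polyphase-resampled on load. Breath-sound energy lies well below the 8 kHz
Nyquist, so nothing audible is lost. All decibels are dBFS (0 dB =
full-scale amplitude 1.0) with a -120 dB silence floor, below the dynamic
range of 16-bit audio. The "0 dB = 1 pW" convention seen on acoustic
power displays is hardware calibration that digital samples cannot
recover; dBFS is reproducible and device-independent.

STFT geometry: periodic Hann window of 512 samples (32 ms) with hop 128
(75% overlap). This resolves the breath band (~100–2000 Hz) at 31 Hz bin
spacing while satisfying the overlap-add condition, so `istft(stft(x))`
is exact to machine precision and masking is the only source of change.

## Denoising

The noise floor is assumed stationary. Its per-bin magnitude is estimated
as the 0.2 quantile of the magnitude spectrogram across frames — breath is
intermittent, so a low quantile sees mostly noise-only frames. Two gain
rules are provided:

* **Amplitude over-subtraction** `g = clip(1 − 1.5·profile/|S|, 0.05, 1)`
  — simple and conservative.
* **Decision-directed Wiener** (the default): the noise *power* per bin is
  recovered from the quantile assuming Rayleigh cell magnitudes
  (`E|N|² = profile²/(−ln(1−q))`), the posterior SNR is smoothed over 9
  neighbouring bins (band-shaped breath energy is smooth in frequency),
  the a priori SNR follows the decision-directed recursion with weight
  0.5, and the gain is `ξ/(1+ξ)` floored at 0.05. On synthetic breath +
  white noise at 0 dB this buys roughly 2.5–4 dB more noise suppression
  than plain over-subtraction at comparable signal distortion.

Denoising benefit is measured by passing the known clean and noise
components separately through the estimated mask (a mask is a linear
time-varying filter) and comparing output energies — the standard
evaluation for time-frequency masks. Against that metric the default gate
gains ≈ 6.5 dB at 0 dB input SNR on the simulator's material. A
distortion-inclusive measure (energy of `output − clean`) saturates near
4 dB for *any* blind stationary-noise gate on this material because breath
is itself band noise: an oracle mask with per-cell knowledge of the clean
magnitudes reaches only ≈ 10 dB.

The trainable estimator reproduces a three-layer bidirectional recurrent
architecture in plain numpy: tanh recurrences with fixed, seed-drawn
weights (input scale 1/√d, recurrent spectral radius 0.9) and a trained
per-bin sigmoid readout on the final layer's states. Targets are ideal
ratio masks `|clean|/(|clean|+|noise|)`; the readout is fitted by
full-batch gradient descent with a backtracking line search, which makes
the recorded mask-MSE history non-increasing by construction and the whole
procedure deterministic given the seed. This is a desk-scale component
trained on simulator pairs; it demonstrates the architecture and training
loop, not a clinically trained denoiser.

## Cardiac detection and suppression

Heart tones occupy roughly 20–150 Hz. The chain is: order-4 zero-phase
Butterworth band-pass (no group delay, so beat times stay aligned),
Hilbert envelope smoothed 20 ms, peaks above median + 3·MAD with a 0.35 s
minimum spacing (≈170 bpm ceiling), heart rate = 60 / median inter-beat
interval, flagged unreliable outside 30–220 bpm or below 3 beats. The
threshold is scale-adaptive, so beat times are invariant to global gain.
Suppression multiplies the 20–150 Hz bins of frames overlapping a beat
interval by 0.1 (-20 dB); everything outside the beats reconstructs
bit-identically, and the timeline is never cut.

## Phase segmentation

### Peak/valley heuristic

The respiratory envelope is the Hilbert envelope low-passed at 4 Hz
(optionally high-passed at 150 Hz first to reject residual cardiac
energy). Inspiratory (S1) peak picking: prominent local maxima
(prominence ≥ 0.15 of the envelope range); when peak amplitudes split into
two clusters (deterministic 1-D 2-means), only the louder cluster is kept
— inspiration is the louder phase; greedy largest-first selection enforces
a minimum cycle spacing of 1.5 s; finally, adjacent peaks whose
interleaving valley stays above half the smaller peak are merged — real
phases are separated by near-silent pauses, so a shallow valley means one
burst, not two.

Burst boundaries: from each peak, the latest/earliest time the envelope
falls to `valley + α(peak − valley)` with α = 0.1, valleys taken between
neighbouring peaks; edge-clamped boundaries are flagged. The expiratory
(S2) peak is the largest interior envelope maximum between the located S1
burst edges (searching between raw peak positions would pick shoulders of
the inspiratory bursts themselves); the gap after the final S1 is searched
to the recording end, closing the final cycle as `partial`. S2 candidates
deviating more than 2 sample standard deviations from the mean amplitude
are dropped in a single pass. The cycle-period gate [1.5 s, 12 s] covers
5–40 breaths/min.

### Six-state ring HMM

States: inspiration onset, inspiration, inspiration end, expiration
onset, expiration, expiration end, with only self- and cyclic-successor
transitions (phases cannot be skipped). Observations are framed at
50 ms / 25 ms hop: log mean envelope, its slope, and the spectral
centroid, z-scored per recording (hence gain-invariant). Transition rows
come from reference dwell durations via `p_self = 1 − 1/(dwell·rate)`,
the geometric-dwell match; Dirichlet pseudo-counts are the expected
transition counts over the reference cycles. Emissions are
phase-conditional Gaussian moments of labelled reference frames.

No corpus of expert-labelled normal cycles is distributable, so the
reference statistics are computed from the package's own simulator: dwell
durations analytically from 1000 draws of the cycle distribution
(onset/steady/end sub-states at 20/60/20% of each burst, inter-phase
pauses split between the adjacent end and onset states) and emission
moments from six rendered recordings passed through the same
preprocessing as real input. This substitution is the central caveat of
the HMM route: its priors describe the simulator's physiology, not a
clinical population.

Adaptation to a recording is MAP expectation-maximization: Dirichlet
transition priors (the pseudo-counts above), weak conjugate
normal-inverse-gamma emission priors centered on the current model
(κ = 1, α = 1, β = 0.1), exact M-steps, structural zeros preserved. The
posterior objective is non-decreasing by the EM argument; the
implementation records it per iteration and the tests assert monotonicity.
Decoding is log-domain Viterbi with deterministic tie-breaking (lowest
state index). Cycle read-out: cycle start at each entry into inspiration
onset, the S1/S2 boundary at the entry into expiration onset, cycle end at
the next inspiration-onset entry; a final traversal that reached
expiration is closed at the recording end and flagged partial. Because the
ring has no pause state, the decoded S1-end and S2-start coincide inside
the inter-phase pause; against burst-edge truth this contributes
``pause/2`` per boundary on average and dominates the HMM route's ~0.13 s
mean boundary error (the peak route, which locates burst edges directly,
achieves ~0.03 s).

## Feature battery

"Middle" statistics (middle dB, middle f0) are medians. f0 is the
framewise (40 ms / 10 ms) normalized autocorrelation peak in the 50–800 Hz
lag band with parabolic lag interpolation; among near-maximal local maxima
(within 0.05 of the best) the *shortest* lag wins, since integer multiples
of the true period correlate equally well. A frame is voiced when the peak
correlation reaches 0.3. Jitter is relative local jitter — mean absolute
consecutive period difference over mean period — on the longest voiced
run. Harmonicity is `10·log10(r/(1−r))` clamped to [-20, 60] dB.
Kurtosis is reported non-excess (a Gaussian scores 3, a sinusoid 1.5).
Peak-to-valley is `max(x) − min(x)`. The max-to-end f0 slope is signed as
computed (end minus max over elapsed time), typically negative. Wavelet
features use an orthogonal Daubechies-4 decomposition at 5 levels with
periodization, so coefficient energy equals waveform energy exactly and
per-level fractions sum to 1. The SNR feature uses the recording's own
quietest 10% of frames as the noise reference when no explicit reference
is given. Segments that are silent, unvoiced or too short carry explicit
flags instead of fabricated values — an f0 for a noise-like unvoiced
breath segment is not physically meaningful, and the voiced-frame
mechanism makes that visible.

## Synthetic data

The simulator emulates resting adult auscultation: cycles of
4.5 ± 0.8 s; inspiration one half of the cycle and expiration 0.4 of it
(inspiration is drawn ≥ half the non-pause budget so it is always the
longer phase); inspiratory band 300–1800 Hz, expiratory 200–1200 Hz;
expiratory/inspiratory RMS ratio 0.6; 10% of each cycle silent, split
into two pauses; 60 ms raised-cosine burst edges. Heart tones are 40 Hz
damped sinusoids (decay 50 ms) at 72 bpm, amplitude 0.25 of the breath
peak scale. Background noise is white (or 1/f) at an exactly realized
SNR, 15 dB by default. One top-level seed splits deterministically into
per-component seeds, so regeneration is bit-identical and adding a
component never perturbs another.

What the simulator does *not* model: adventitious sounds (crackles,
wheezes, rhonchi), airflow physics, room acoustics, sensor placement
variation, or non-stationary interference such as speech. Passing the
validation suite therefore demonstrates correctness of the algorithms
under the stated signal model — clean quasi-periodic burst structure with
stationary noise — not clinical performance.

## Numerical choices and problem sizes

Tie-breaks are deterministic everywhere (earliest time, lowest index).
Intervals are half-open `[start, end)` in seconds from recording start.
Emission variances are floored at 1e-8; z-scoring treats a column as
constant when its spread is below 1e-10 relative. The validation suite
is 50 recordings of 5 cycles (≈ 250 cycles, ~20 min of audio); the
recurrent mask estimator trains on 20 two-cycle pairs for 40 epochs;
HMM parameter recovery uses 200 frames and 20 EM iterations. These sizes
keep the full test suite and the acceptance script in the minutes range
on a single CPU while leaving the measured quantities stable across
seeds.

## Known limitations

* The HMM reference priors come from the simulator (see above); applying
  the HMM route to clinical audio should re-estimate priors from labelled
  recordings via `init_phase_hmm`.
* The segmentation assumes one dominant breath source; overlapping
  speech or two-subject recordings are out of scope.
* The peak heuristic requires the inspiratory phase to be the louder one;
  pathologies that invert the amplitude relation would need the HMM route
  with re-estimated emissions (such cycles are flagged, not dropped).
* Heart-rate estimation assumes beats are audible above the breath noise
  in the 20–150 Hz band; at very low cardiac SNR the detection flags
  itself unreliable rather than guessing.
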