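import numpy as np
import pytest

from breathseg.audio_io import AudioSignal
from breathseg.cardiac import Envelope
from breathseg.phase_segmentation import (
    STATES,
    CycleAssemblyError,
    ObservationSequence,
    PhaseHMM,
    PhaseSpan,
    RespiratoryCycle,
    adapt_hmm,
    breath_envelope,
    build_observations,
    build_reference_hmm,
    cycles_to_labels,
    detect_s1_peaks,
    detect_s2_peaks,
    filter_s2_outliers,
    init_phase_hmm,
    labels_to_cycles,
    locate_phase_boundaries,
    segment_cycles,
    segment_hmm,
    segment_peaks,
    states_to_cycles,
    viterbi_decode,
)
from breathseg.pipeline import preprocess
from breathseg.synthetic import BreathSpec, HeartSpec, NoiseSpec, generate_breath, mix_recording
from breathseg.validation import match_cycles, score_segmentation

from oracles import viterbi_bruteforce

RATE = 16000


def triangle_envelope(peak_idx=8000, width=4000, n=16000, height=1.0):
    v = np.zeros(n)
    left = np.linspace(0, height, width)
    right = np.linspace(height, 0, width)
    v[peak_idx - width : peak_idx] = left
    v[peak_idx : peak_idx + width] = right
    return Envelope(v, RATE)


class TestBreathEnvelope:
    def test_silence_gives_zero(self):
        env = breath_envelope(AudioSignal(np.zeros(2 * RATE), RATE))
        np.testing.assert_allclose(env.values, 0.0, atol=1e-12)

    def test_single_burst_unimodal(self):
        breath, _ = generate_breath(BreathSpec(n_cycles=1, seed=5))
        env = breath_envelope(breath)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(env.values, prominence=0.25 * env.values.max())
        assert len(peaks) <= 2  # one per burst (S1 and possibly S2)

    def test_scale_equivariance(self):
        breath, _ = generate_breath(BreathSpec(n_cycles=2, seed=6))
        e1 = breath_envelope(breath)
        e2 = breath_envelope(AudioSignal(2.0 * breath.samples, RATE))
        np.testing.assert_allclose(e2.values, 2.0 * e1.values, atol=1e-9)


class TestS1Peaks:
    def test_five_cycles_five_peaks(self):
        spec = BreathSpec(n_cycles=5, cycle_period_s=(4.0, 0.0), insp_frac=(0.5, 0.0), seed=9)
        breath, labels = generate_breath(spec)
        env = breath_envelope(breath)
        peaks = detect_s1_peaks(env)
        s1_entries = labels.with_label("S1")
        assert len(peaks) == 5
        for (t, _), entry in zip(peaks, s1_entries):
            assert entry.start_s <= t <= entry.end_s  # inside the burst

    def test_greedy_spacing_keeps_larger(self):
        v = np.zeros(6 * RATE)
        v[2 * RATE - 2000 : 2 * RATE + 2000] = np.hanning(4000) * 1.0
        v[3 * RATE - 2000 : 3 * RATE + 2000] += np.hanning(4000) * 0.9
        peaks = detect_s1_peaks(Envelope(v, RATE), min_cycle_s=2.0)
        assert len(peaks) == 1
        assert peaks[0][0] == pytest.approx(2.0, abs=0.05)

    def test_flat_envelope_empty(self):
        assert detect_s1_peaks(Envelope(np.zeros(RATE), RATE)) == []


class TestPhaseBoundaries:
    def test_symmetric_triangle_boundaries(self):
        env = triangle_envelope()
        span = locate_phase_boundaries(env, 0.5, alpha=0.1)
        left_off = 0.5 - span.start_s
        right_off = span.end_s - 0.5
        assert left_off == pytest.approx(right_off, abs=1.5 / RATE)

    def test_alpha_zero_reaches_valleys(self):
        env = triangle_envelope()
        span = locate_phase_boundaries(env, 0.5, alpha=0.0)
        # the triangle reaches zero (its valley) a quarter second around the peak
        assert span.start_s <= 0.25 + 1e-3
        assert span.end_s >= 0.75 - 1e-3

    def test_edge_peak_clamped_and_flagged(self):
        v = np.linspace(1, 0, RATE)  # peak exactly at the first sample
        span = locate_phase_boundaries(Envelope(v, RATE), 0.0)
        assert span.start_s == 0.0
        assert "edge" in span.flags

    def test_boundary_error_on_generated_bursts(self):
        errs = []
        for seed in range(10):
            breath, labels = generate_breath(BreathSpec(seed=seed))
            env = breath_envelope(breath)
            peaks = detect_s1_peaks(env)
            times = [t for t, _ in peaks]
            truth = labels.with_label("S1")
            assert len(peaks) == len(truth)
            for i, (t, entry) in enumerate(zip(times, truth)):
                left = times[i - 1] if i else None
                right = times[i + 1] if i + 1 < len(times) else None
                span = locate_phase_boundaries(env, t, 0.1, left, right)
                errs += [abs(span.start_s - entry.start_s), abs(span.end_s - entry.end_s)]
        assert np.mean(errs) < 0.15


class TestS2Detection:
    def test_one_s2_per_gap_near_truth(self):
        spec = BreathSpec(n_cycles=4, seed=13)
        breath, labels = generate_breath(spec)
        env = breath_envelope(breath)
        s1 = detect_s1_peaks(env)
        cands = detect_s2_peaks(env, s1)
        truth = labels.with_label("S2")
        assert len(cands) == len(truth)
        for cand, entry in zip(cands, truth):
            assert cand is not None
            lo, hi = entry.start_s, entry.end_s
            assert lo - 0.25 <= cand[0] <= hi + 0.25

    def test_monotone_gap_flags_no_s2(self):
        v = np.concatenate([
            np.linspace(0, 1, RATE), np.linspace(1, 0.2, 2 * RATE), np.linspace(0.2, 1, RATE)
        ])
        env = Envelope(v, RATE)
        s1 = [(1.0, 1.0), (4.0, 1.0)]
        cands = detect_s2_peaks(env, s1, search_to_end=False)
        assert cands == [None]

    def test_candidates_never_at_s1_times(self):
        breath, _ = generate_breath(BreathSpec(seed=14))
        env = breath_envelope(breath)
        s1 = detect_s1_peaks(env)
        for cand in detect_s2_peaks(env, s1):
            if cand is None:
                continue
            assert all(abs(cand[0] - t) > 1e-6 for t, _ in s1)


class TestS2OutlierFilter:
    def test_clear_outlier_removed(self):
        cands = [(float(i), 1.0) for i in range(9)] + [(9.0, 5.0)]
        kept = filter_s2_outliers(cands, k=2.0)
        assert (9.0, 5.0) not in kept
        assert len(kept) == 9

    def test_identical_amplitudes_unchanged(self):
        cands = [(0.0, 1.0), (1.0, 1.0), (2.0, 1.0)]
        assert filter_s2_outliers(cands) == cands

    def test_two_candidates_pass_through(self):
        cands = [(0.0, 1.0), (1.0, 99.0)]
        assert filter_s2_outliers(cands) == cands


class TestSegmentCycles:
    def test_definition_arithmetic(self):
        s1 = [PhaseSpan(0.0, 1.9, 1.0, 1.0), PhaseSpan(4.9, 6.5, 5.5, 1.0)]
        s2 = [PhaseSpan(2.5, 3.2, 2.8, 0.6), None]
        cycles = segment_cycles(s1, s2, recording_end_s=7.0)
        assert len(cycles) == 1
        c = cycles[0]
        assert c.inhalation_span == (0.0, 2.5)
        assert c.exhalation_span == (2.5, 4.9)
        assert c.duration_s == pytest.approx(4.9)

    def test_single_s1_no_s2_yields_nothing(self):
        cycles = segment_cycles([PhaseSpan(0.0, 1.9, 1.0, 1.0)], [None], 5.0)
        assert cycles == []

    def test_overlap_raises_naming_pair(self):
        s1 = [PhaseSpan(0.0, 3.0, 1.0, 1.0), PhaseSpan(4.9, 6.5, 5.5, 1.0)]
        s2 = [PhaseSpan(2.5, 3.2, 2.8, 0.6), None]
        with pytest.raises(CycleAssemblyError, match="2.5"):
            segment_cycles(s1, s2, 7.0)

    def test_cycles_ordered_and_disjoint(self):
        breath, _ = generate_breath(BreathSpec(seed=15))
        cycles = segment_peaks(breath)
        for a, b in zip(cycles, cycles[1:]):
            assert a.cycle_end_s == pytest.approx(b.s1_start_s, abs=1e-9)


class TestObservations:
    def test_frame_count_arithmetic(self):
        sig = AudioSignal(np.random.default_rng(0).standard_normal(RATE), RATE)
        obs = build_observations(sig, frame_s=0.05, hop_s=0.025)
        expected = (RATE - 800) // 400 + 1
        assert obs.n_frames == expected

    def test_zscored_columns(self, default_mixture):
        obs = build_observations(default_mixture.signal)
        np.testing.assert_allclose(obs.frames.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(obs.frames.std(axis=0), 1.0, atol=1e-9)

    def test_silence_constant_features(self):
        obs = build_observations(AudioSignal(np.zeros(RATE), RATE))
        # constant log-floor envelope: z-scoring collapses to zeros
        np.testing.assert_allclose(obs.frames[:, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(obs.frames[:, 1], 0.0, atol=1e-9)

    def test_too_short_recording(self):
        with pytest.raises(ValueError):
            build_observations(AudioSignal(np.zeros(100), RATE))


class TestInitPhaseHmm:
    def test_self_transition_formula(self):
        model = init_phase_hmm(np.full(6, 2.0), frame_rate=10.0)
        np.testing.assert_allclose(np.diag(model.transition), 0.95)

    def test_rows_sum_to_one(self):
        model = init_phase_hmm([0.5, 2.0, 0.4, 0.5, 1.5, 0.6], 40.0)
        np.testing.assert_allclose(model.transition.sum(axis=1), 1.0, atol=1e-12)

    def test_geometric_dwell_matches(self):
        durations = np.array([0.5, 2.0, 0.4, 0.5, 1.5, 0.6])
        fr = 40.0
        model = init_phase_hmm(durations, fr)
        dwell = 1.0 / (1.0 - np.diag(model.transition))
        np.testing.assert_allclose(dwell, durations * fr, rtol=1e-9)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            init_phase_hmm([1.0, 1.0, 0.0, 1.0, 1.0, 1.0], 10.0)

    def test_ring_structure_enforced(self):
        model = init_phase_hmm(np.full(6, 1.0), 10.0)
        allowed = np.zeros((6, 6), dtype=bool)
        for i in range(6):
            allowed[i, i] = allowed[i, (i + 1) % 6] = True
        assert np.all(model.transition[~allowed] == 0)


def random_toy_hmm(rng, n_states, n_frames, topology="full"):
    init = rng.dirichlet(np.ones(n_states))
    if topology == "full":
        trans = rng.dirichlet(np.ones(n_states), size=n_states)
    else:
        trans = np.zeros((n_states, n_states))
        for i in range(n_states):
            p = rng.uniform(0.5, 0.95)
            trans[i, i] = p
            trans[i, (i + 1) % n_states] = 1 - p
    d = 2
    means = rng.normal(0, 2, (n_states, d))
    variances = rng.uniform(0.3, 1.5, (n_states, d))
    model = PhaseHMM(tuple(f"s{i}" for i in range(n_states)), trans, means, variances,
                     init, np.ones((n_states, n_states)), topology=topology)
    frames = rng.normal(0, 2, (n_frames, d))
    obs = ObservationSequence(frames, 10.0, np.arange(n_frames) / 10.0)
    return model, obs


class TestViterbi:
    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(101)
        for trial in range(100):
            n_states = int(rng.integers(2, 4))
            n_frames = int(rng.integers(2, 9))
            model, obs = random_toy_hmm(rng, n_states, n_frames)
            path = viterbi_decode(obs, model)
            with np.errstate(divide="ignore"):
                expected, _ = viterbi_bruteforce(
                    np.log(model.initial), np.log(model.transition),
                    model.log_emission(obs.frames),
                )
            assert list(path) == expected, f"trial {trial}"

    def test_matches_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(55)
        for _ in range(10):
            model, obs = random_toy_hmm(rng, 3, 40)
            ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
            ref.startprob_ = model.initial
            ref.transmat_ = model.transition
            ref.means_ = model.means
            ref.covars_ = model.variances
            _, ref_path = ref.decode(obs.frames, algorithm="viterbi")
            np.testing.assert_array_equal(viterbi_decode(obs, model), ref_path)

    def test_uniform_everything_tie_breaks_low(self):
        n = 3
        model = PhaseHMM(("a", "b", "c"), np.full((n, n), 1 / n),
                         np.zeros((n, 1)), np.ones((n, 1)), np.full(n, 1 / n),
                         np.ones((n, n)), topology="full")
        obs = ObservationSequence(np.zeros((6, 1)), 10.0, np.arange(6) / 10.0)
        np.testing.assert_array_equal(viterbi_decode(obs, model), 0)

    def test_ring_never_skips_states(self, reference_model, default_mixture):
        clean, _ = preprocess(default_mixture.signal)
        obs = build_observations(clean)
        path = viterbi_decode(obs, reference_model)
        for a, b in zip(path, path[1:]):
            assert b == a or b == (a + 1) % 6


class TestAdaptHmm:
    def _sim(self, model, T, rng):
        s = 0
        frames = np.empty((T, model.means.shape[1]))
        for t in range(T):
            frames[t] = rng.normal(model.means[s], np.sqrt(model.variances[s]))
            s = rng.choice(model.n_states, p=model.transition[s])
        return ObservationSequence(frames, 40.0, np.arange(T) / 40.0)

    def _truth(self):
        means = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2], [2, 2, 0], [2, 0, 2]], dtype=float)
        return init_phase_hmm(np.array([0.5, 2.5, 0.6, 0.5, 1.6, 0.6]), 40.0,
                              emission_means=means, emission_variances=np.full((6, 3), 0.25),
                              n_reference_cycles=5)

    def test_zero_iterations_identity(self):
        truth = self._truth()
        obs = self._sim(truth, 50, np.random.default_rng(1))
        out = adapt_hmm(truth, obs, iterations=0)
        np.testing.assert_array_equal(out.transition, truth.transition)
        np.testing.assert_array_equal(out.means, truth.means)

    def test_infinite_prior_pins_transitions(self):
        truth = self._truth()
        strong = PhaseHMM(truth.states, truth.transition, truth.means, truth.variances,
                          truth.initial, truth.prior_counts * 1e9, truth.topology)
        obs = self._sim(truth, 120, np.random.default_rng(2))
        out = adapt_hmm(strong, obs, iterations=5)
        np.testing.assert_allclose(out.transition, truth.transition, atol=1e-6)

    def test_objective_non_decreasing(self):
        truth = self._truth()
        obs = self._sim(truth, 150, np.random.default_rng(3))
        out = adapt_hmm(truth, obs, iterations=15)
        h = np.asarray(out.objective_history_)
        assert np.all(np.diff(h) >= -1e-9)

    def test_self_transition_recovery(self):
        rng = np.random.default_rng(7)
        truth = self._truth()
        obs = self._sim(truth, 200, rng)
        pert = init_phase_hmm(
            np.array([0.5, 2.5, 0.6, 0.5, 1.6, 0.6]) * rng.uniform(0.6, 1.6, 6), 40.0,
            emission_means=truth.means + rng.normal(0, 0.3, (6, 3)),
            emission_variances=np.full((6, 3), 0.5), n_reference_cycles=5,
        )
        adapted = adapt_hmm(pert, obs, iterations=20)
        err = np.abs(np.diag(adapted.transition) - np.diag(truth.transition))
        assert err.max() < 0.05

    def test_structural_zeros_preserved(self):
        truth = self._truth()
        obs = self._sim(truth, 100, np.random.default_rng(4))
        out = adapt_hmm(truth, obs, iterations=10)
        allowed = truth.transition > 0
        assert np.all(out.transition[~allowed] == 0)


class TestStatesToCycles:
    def test_handwritten_ring_path(self):
        path = [0] * 3 + [1] * 5 + [2] * 2 + [3] * 2 + [4] * 4 + [5] * 3 + [0] * 2
        cycles = states_to_cycles(np.array(path), frame_rate=10.0)
        # the trailing state-0 entry never reaches expiration: dropped
        assert len(cycles) == 1
        complete = cycles[0]
        assert complete.s1_start_s == pytest.approx(0.0)
        assert complete.s2_start_s == pytest.approx(1.0)  # entry into state 3 at frame 10
        assert complete.cycle_end_s == pytest.approx(1.9)  # next state-0 entry

    def test_stuck_path_gives_nothing(self):
        assert states_to_cycles(np.full(50, 2), 10.0) == []

    def test_output_satisfies_ordering(self, reference_model, default_mixture):
        clean, _ = preprocess(default_mixture.signal)
        cycles = segment_hmm(clean, reference_model)
        for c in cycles:
            assert c.s1_start_s < c.s1_end_s <= c.s2_start_s < c.s2_end_s <= c.cycle_end_s


class TestRoutesAgree:
    def test_methods_close_on_synthetic_suite(self, reference_model):
        diffs = []
        for seed in range(5):
            m = mix_recording(BreathSpec(seed=seed), HeartSpec(seed=seed + 40),
                              NoiseSpec(), seed=seed + 80)
            clean, _ = preprocess(m.signal)
            p = segment_peaks(clean, pre_highpass_hz=150.0)
            h = segment_hmm(clean, reference_model)
            pairing = match_cycles(p, h)
            diffs += [
                abs(p[i].s1_start_s - h[j].s1_start_s) for i, j in pairing.pairs
            ]
        assert np.median(diffs) < 0.2

    def test_boundaries_invariant_to_gain(self):
        breath, _ = generate_breath(BreathSpec(seed=77))
        c1 = segment_peaks(breath)
        c2 = segment_peaks(AudioSignal(0.25 * breath.samples, RATE))
        assert len(c1) == len(c2)
        for a, b in zip(c1, c2):
            assert a.s1_start_s == pytest.approx(b.s1_start_s, abs=1e-9)
            assert a.s2_start_s == pytest.approx(b.s2_start_s, abs=1e-9)


class TestLabelConversions:
    def test_truth_round_trip(self, default_mixture):
        cycles = labels_to_cycles(default_mixture.labels, default_mixture.signal.duration_s)
        assert cycles
        track = cycles_to_labels(cycles)
        back = labels_to_cycles(track, default_mixture.signal.duration_s)
        for a, b in zip(cycles, back):
            assert a.s1_start_s == pytest.approx(b.s1_start_s)
            assert a.s2_end_s == pytest.approx(b.s2_end_s)

    def test_truth_cycles_satisfy_invariants(self, default_mixture):
        for c in labels_to_cycles(default_mixture.labels, default_mixture.signal.duration_s):
            assert c.s1_start_s < c.s1_end_s <= c.s2_start_s < c.s2_end_s <= c.cycle_end_s
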