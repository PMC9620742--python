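"""Bootstrap response classification: CI machinery, the combined
two-method test, bias assignment, bias types, spiking-unit variant."""

import numpy as np
import pytest

from motorpop.datatypes import Bias, Responsiveness
from motorpop.response_class import (
    EpochSpec,
    assign_bias_type,
    assign_responsiveness,
    bootstrap_ci,
    classify_bias,
    classify_response,
    classify_unit_firing,
    is_putative_pyramidal,
)

FR = 40.0
TIME_AXIS = np.arange(-60, 61) / FR          # -1.5 .. 1.5 s
EPOCHS = EpochSpec(peri=(-0.15, 0.79))
NOISE = 0.1


def _transient(amplitude, onset=0.0, rise=0.5, decay=1.5):
    t = np.clip(TIME_AXIS - onset, 0, None)
    h = np.exp(-t / decay) - np.exp(-t / rise)
    h[TIME_AXIS < onset] = 0
    return amplitude * h / h.max()


def _trials(amplitude, n=30, seed=0, onset=0.0):
    r = np.random.default_rng(seed)
    return _transient(amplitude, onset) + r.standard_normal((n, len(TIME_AXIS))) * NOISE


class TestBootstrapCI:
    def test_degenerate_constant_sample(self):
        lo, hi = bootstrap_ci(np.full(10, 2.5), n_boot=200)
        assert lo == hi == 2.5

    def test_brackets_the_sample_mean(self, rng):
        x = rng.normal(1.0, 2.0, 50)
        lo, hi = bootstrap_ci(x, n_boot=2000, rng=rng)
        assert lo <= x.mean() <= hi

    def test_width_close_to_normal_approximation(self, rng):
        p, n = 0.5, 200
        x = (rng.random(n) < p).astype(float)
        lo, hi = bootstrap_ci(x, n_boot=5000, rng=rng)
        analytic = 2 * 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs((hi - lo) - analytic) / analytic < 0.2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([]))


class TestClassifyResponse:
    def test_planted_increase_detected_with_positive_sign(self):
        res = classify_response(_trials(5 * NOISE, seed=1), TIME_AXIS, EPOCHS, FR,
                                rng=np.random.default_rng(1))
        assert res.significant and res.sign == 1

    def test_planted_suppression_detected_with_negative_sign(self):
        res = classify_response(_trials(-5 * NOISE, seed=2), TIME_AXIS, EPOCHS, FR,
                                rng=np.random.default_rng(2))
        assert res.significant and res.sign == -1

    def test_flat_noise_rarely_significant(self):
        # empirical false-positive calibration of the combined rule
        hits = 0
        n_rep = 60
        for s in range(n_rep):
            r = np.random.default_rng(5000 + s)
            trials = r.standard_normal((30, len(TIME_AXIS))) * NOISE
            hits += classify_response(trials, TIME_AXIS, EPOCHS, FR,
                                      n_boot=4000, rng=r).significant
        assert hits / n_rep <= 0.06

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="trials"):
            classify_response(_trials(0.5, n=4), TIME_AXIS, EPOCHS, FR)

    def test_epochs_outside_window_rejected(self):
        bad = EpochSpec(baseline=(-3.0, -2.5), peri=(-0.15, 0.79))
        with pytest.raises(ValueError):
            classify_response(_trials(0.5), TIME_AXIS, bad, FR)


class TestClassifyBias:
    def test_equal_amplitudes_usually_invariant(self):
        hits = 0
        n_rep = 40
        for s in range(n_rep):
            r = np.random.default_rng(7000 + s)
            push = _trials(0.5, seed=100 + s)
            pull = _trials(0.5, seed=200 + s)
            hits += classify_bias(push, pull, TIME_AXIS, EPOCHS, FR,
                                  n_boot=4000, rng=r) != Bias.INVARIANT
        assert hits / n_rep <= 0.15

    def test_stronger_push_response_gives_push_bias(self):
        push, pull = _trials(10 * NOISE, seed=3), _trials(5 * NOISE, seed=4)
        assert classify_bias(push, pull, TIME_AXIS, EPOCHS, FR,
                             rng=np.random.default_rng(3)) == Bias.PUSH

    def test_mirrored_case_gives_pull_bias(self):
        push, pull = _trials(5 * NOISE, seed=4), _trials(10 * NOISE, seed=3)
        assert classify_bias(push, pull, TIME_AXIS, EPOCHS, FR,
                             rng=np.random.default_rng(3)) == Bias.PULL

    def test_label_exchange_symmetry(self):
        push, pull = _trials(10 * NOISE, seed=5), _trials(2 * NOISE, seed=6)
        a = classify_bias(push, pull, TIME_AXIS, EPOCHS, FR, rng=np.random.default_rng(9))
        b = classify_bias(pull, push, TIME_AXIS, EPOCHS, FR, rng=np.random.default_rng(9))
        assert {a, b} == {Bias.PUSH, Bias.PULL}


class TestAssignment:
    def test_no_significance_is_non_responsive(self):
        assert assign_responsiveness(False, False, np.nan, 0.5) \
            is Responsiveness.NON_RESPONSIVE

    def test_late_onset_is_reward_phase(self):
        assert assign_responsiveness(True, False, 1.7, 0.5) \
            is Responsiveness.REWARD_PHASE

    def test_peri_movement_onset_is_movement_related(self):
        assert assign_responsiveness(True, True, -0.1, 0.5) \
            is Responsiveness.MOVEMENT_RELATED

    @pytest.mark.parametrize("flags,expected", [
        ((True, 1, True, 1), 1),
        ((True, 1, False, 0), 2),
        ((False, 0, True, 1), 2),
        ((True, -1, False, 0), 3),
        ((True, -1, True, -1), 4),
        ((True, 1, True, -1), None),
        ((False, 0, False, 0), None),
    ])
    def test_bias_type_taxonomy(self, flags, expected):
        assert assign_bias_type(*flags) == expected

    def test_significant_but_signless_rejected(self):
        with pytest.raises(ValueError):
            assign_bias_type(True, 0, False, 0)


class TestUnitFiring:
    def _session(self, push_rate, pull_rate, base_rate=5.0, n=8, seed=0):
        r = np.random.default_rng(seed)
        trains, types, cues, onsets, comps = [], [], [], [], []
        t = 5.0
        for k in range(2 * n):
            mv = "push" if k % 2 == 0 else "pull"
            cue, onset = t, t + 0.3
            comp = onset + 0.4
            rate = push_rate if mv == "push" else pull_rate
            spikes = np.sort(r.uniform(t - 2, onset, r.poisson(base_rate * (onset - t + 2))))
            burst = np.sort(r.uniform(onset, comp + 0.5, r.poisson(rate * (comp + 0.5 - onset))))
            trains.append(np.concatenate([spikes, burst]))
            types.append(mv); cues.append(cue); onsets.append(onset); comps.append(comp)
            t += 6.0
        return (trains, np.array(types), np.array(cues), np.array(onsets),
                np.array(comps))

    def test_rate_step_is_responsive(self):
        args = self._session(30.0, 30.0, seed=1)
        responsive, bias = classify_unit_firing(*args, n_boot=2000,
                                                rng=np.random.default_rng(1))
        assert responsive
        assert bias is None  # equal modulation: no push/pull bias

    def test_homogeneous_unit_usually_unresponsive(self):
        hits = 0
        for s in range(10):
            args = self._session(5.0, 5.0, seed=50 + s)
            responsive, _ = classify_unit_firing(*args, n_boot=2000,
                                                 rng=np.random.default_rng(s))
            hits += responsive
        assert hits <= 3

    def test_strong_push_modulation_gives_push_bias(self):
        args = self._session(60.0, 5.0, seed=2)
        responsive, bias = classify_unit_firing(*args, n_boot=2000,
                                                rng=np.random.default_rng(2))
        assert responsive and bias == Bias.PUSH

    def test_empty_spike_train_is_unresponsive_not_error(self):
        trains, types, cues, onsets, comps = self._session(5.0, 5.0, seed=3)
        trains = [np.array([]) for _ in trains]
        responsive, bias = classify_unit_firing(trains, types, cues, onsets, comps,
                                                n_boot=500)
        assert not responsive and bias is None


@pytest.mark.parametrize("width,expected", [(0.6, True), (0.3, False), (0.4, False)])
def test_pyramidal_spike_width_rule(width, expected):
    assert is_putative_pyramidal(width) is expected


def test_pyramidal_rejects_nonpositive_width():
    with pytest.raises(ValueError):
        is_putative_pyramidal(0.0)
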