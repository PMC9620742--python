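"""Pairwise correlations, distances, group medians, HDA time course,
trial-to-trial analyses and the spatial clustering mixed model."""

import numpy as np
import pandas as pd
import pytest

from motorpop.spatiotemporal import (
    fit_clustering_model,
    group_median_difference,
    hda_timecourse,
    mean_trial_pair_correlation,
    pairwise_activity_correlations,
    pairwise_distances,
    residual_diagnostics,
    trial_correlation_analyses,
)

FR = 40.0


def _aligned(n_neurons=4, n_trials=10, n_t=80, seed=0, noise=1.0):
    r = np.random.default_rng(seed)
    data = r.standard_normal((n_neurons, n_trials, n_t)) * noise
    labels = np.array(["push"] * (n_trials // 2) + ["pull"] * (n_trials - n_trials // 2))
    ta = (np.arange(n_t) - 20) / FR
    return data, labels, ta


def _null_pairs(n=2000, n_neurons=100, seed=0, slope=0.0):
    r = np.random.default_rng(seed)
    acc = r.uniform(0.4, 0.9, n_neurons)
    i = r.integers(0, n_neurons // 2, n)
    j = r.integers(n_neurons // 2, n_neurons, n)
    dist = r.uniform(0, 300, n)
    rr = r.normal(0.2, 0.1, n) + slope * (dist - dist.mean())
    pairs = pd.DataFrame({
        "neuron_i": i, "neuron_j": j, "pearson_r": rr, "distance_um": dist,
        "group_i": "HDA", "group_j": "LDA",
        "movement": r.choice(["push", "pull"], n),
        "animal_id": r.choice(["m1", "m2", "m3", "m4"], n),
    })
    return pairs, acc


class TestPairCorrelations:
    def test_identical_and_negated_traces(self):
        data, labels, ta = _aligned(3, seed=1)
        base = np.sin(np.linspace(0, 6, data.shape[2]))
        data[0] = base
        data[1] = base
        data[2] = -base
        xy = np.array([[0.0, 0.0], [30.0, 40.0], [100.0, 0.0]])
        pairs = pairwise_activity_correlations(
            data, ta, labels, xy, (-0.25, 1.0), FR)
        push = pairs[pairs["movement"] == "push"].set_index(["neuron_i", "neuron_j"])
        assert push.loc[(0, 1), "pearson_r"] == pytest.approx(1.0)
        assert push.loc[(0, 2), "pearson_r"] == pytest.approx(-1.0)
        assert push.loc[(0, 1), "distance_um"] == pytest.approx(50.0)

    def test_independent_noise_has_small_median_r(self):
        data, labels, ta = _aligned(12, n_trials=20, n_t=220, seed=2)
        xy = np.random.default_rng(0).uniform(0, 300, (12, 2))
        pairs = pairwise_activity_correlations(
            data, ta, labels, xy, (-0.5, 4.4), FR)
        assert np.median(np.abs(pairs["pearson_r"].dropna())) < 0.25

    def test_constant_trace_flagged(self):
        data, labels, ta = _aligned(2, seed=3)
        data[0] = 1.0
        xy = np.zeros((2, 2))
        pairs = pairwise_activity_correlations(data, ta, labels, xy, (-0.25, 1.0), FR)
        assert pairs["flagged"].all()

    def test_triangle_inequality_and_symmetry(self, rng):
        xy = rng.uniform(0, 300, (10, 2))
        D = pairwise_distances(xy)
        np.testing.assert_allclose(D, D.T)
        for a in range(10):
            for b in range(10):
                for c in range(10):
                    assert D[a, c] <= D[a, b] + D[b, c] + 1e-9


class TestGroupMedianDifference:
    def test_group_vs_itself_centred_at_zero(self):
        pairs, _ = _null_pairs(seed=4)
        pairs["group_j"] = "HDA"
        med, (lo, hi) = group_median_difference(pairs, "pearson_r", "HDA", "HDA",
                                                n_boot=2000,
                                                rng=np.random.default_rng(0))
        assert lo <= 0 <= hi
        assert abs(med) < 0.02

    def test_shift_recovered(self):
        pairs, _ = _null_pairs(seed=5)
        delta = 0.15
        pairs.loc[(pairs["group_i"] == "HDA") & (pairs["group_j"] == "LDA"),
                  "group_j"] = "HDA"   # make every pair an HDA pair
        shifted = pairs.copy()
        shifted["pearson_r"] += delta
        both = pd.concat([pairs.assign(group_i="LDA", group_j="LDA"), shifted])
        med, _ = group_median_difference(both, "pearson_r", "HDA", "LDA",
                                         n_boot=2000, rng=np.random.default_rng(0))
        assert med == pytest.approx(delta, abs=0.02)

    def test_deterministic_given_seed(self):
        pairs, _ = _null_pairs(seed=6)
        pairs["group_j"] = "HDA"
        a = group_median_difference(pairs, "distance_um", "HDA", "all",
                                    n_boot=500, rng=np.random.default_rng(3))
        b = group_median_difference(pairs, "distance_um", "HDA", "all",
                                    n_boot=500, rng=np.random.default_rng(3))
        assert a == b


class TestTrialCorrelations:
    def test_identical_trials_give_unit_mean_r(self):
        tr = np.tile(np.sin(np.linspace(0, 5, 50)), (6, 1))
        assert mean_trial_pair_correlation(tr) == pytest.approx(1.0)

    def test_independent_trials_near_zero(self, rng):
        tr = rng.standard_normal((10, 300))
        assert abs(mean_trial_pair_correlation(tr)) < 0.1

    def test_population_tracks_motion_index(self):
        # population signal is a deterministic function of the motion index
        r = np.random.default_rng(8)
        n_trials, n_t = 16, 120
        ta = (np.arange(n_t) - 20) / FR
        mi = np.abs(r.standard_normal((n_trials, 1))) * np.sin(np.linspace(0, np.pi, n_t))
        mi += 0.05 * r.standard_normal((n_trials, n_t))
        data = np.stack([mi * w for w in r.uniform(0.5, 1.5, 5)])
        labels = np.array(["push"] * 8 + ["pull"] * 8)
        out = trial_correlation_analyses(
            data, ta, labels, (-0.25, 2.0), FR,
            bias_class=np.array(["invariant"] * 5),
            motion_index_trials=mi, n_boot=500, n_bins=4,
            rng=np.random.default_rng(0),
        )
        binned = out["population_binned"].sort_values("mi_r_median")
        assert binned["pop_r_median"].is_monotonic_increasing

    def test_class_medians_present(self):
        data, labels, ta = _aligned(4, n_trials=8, seed=9)
        out = trial_correlation_analyses(
            data, ta, labels, (-0.25, 1.0), FR,
            bias_class=np.array(["invariant", "invariant", "push", "pull"]),
            n_boot=200, rng=np.random.default_rng(0),
        )
        assert ("push", "invariant") in out["class_medians"]


class TestHdaTimecourse:
    def test_never_significant_gives_zero(self):
        correct = [np.zeros((20, 10), bool) for _ in range(5)]
        tc = hda_timecourse(correct, 0.6, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(tc, 0.0)

    def test_all_significant_in_one_bin(self):
        correct = [np.zeros((20, 10), bool) for _ in range(5)]
        for c in correct:
            c[:, 4] = True
        tc = hda_timecourse(correct, 0.6, rng=np.random.default_rng(0))
        assert tc[4] == 1.0 and tc[0] == 0.0

    def test_peaks_at_planted_latencies(self):
        r = np.random.default_rng(10)
        early = [(r.random((30, 20)) < 0.5) for _ in range(10)]
        for c in early[:5]:
            c[:, 3:5] = True       # early informative
        for c in early[5:]:
            c[:, 14:16] = True     # late informative
        tc = hda_timecourse(early, 0.62, rng=r)
        assert tc[3] > tc[9] and tc[14] > tc[9]


class TestClusteringModel:
    def test_null_distance_slope_within_2se(self):
        pairs, acc = _null_pairs(seed=11)
        fit = fit_clustering_model(pairs, acc)
        assert abs(fit.params["dist_c"]) < 2 * fit.bse["dist_c"]

    def test_injected_slope_recovered(self):
        beta = 4e-4  # r per µm
        pairs, acc = _null_pairs(seed=12, slope=beta)
        fit = fit_clustering_model(pairs, acc)
        assert fit.params["dist_c"] > 0
        assert abs(fit.params["dist_c"] - beta) < 2 * fit.bse["dist_c"]

    def test_model_has_exactly_the_formula_terms(self):
        pairs, acc = _null_pairs(seed=13)
        fit = fit_clustering_model(pairs, acc)
        assert list(fit.params.index) == ["Intercept", "dist_c", "acc_z", "dist_c:acc_z"]

    def test_requires_two_animals_and_movements(self):
        pairs, acc = _null_pairs(seed=14)
        pairs["animal_id"] = "m1"
        with pytest.raises(ValueError):
            fit_clustering_model(pairs, acc)

    def test_residual_diagnostics_near_zero_for_null(self):
        pairs, acc = _null_pairs(seed=15)
        fit = fit_clustering_model(pairs, acc)
        diag = residual_diagnostics(fit, pairs)
        assert (diag["resid_correlation"].abs() < 0.1).all()
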