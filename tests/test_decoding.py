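"""Independent-Poisson decoder: likelihoods, cross-validation, pairwise
discrimination, direction and incorrect-trial decoding."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson
from sklearn.base import clone

from conftest import make_iid_ensemble
from speedcat.decoding import (PoissonPopulationDecoder,
                               accuracy_vs_population_size,
                               cross_validated_accuracy, decode_trial,
                               direction_decoding, equalize_trials,
                               estimate_tuning, incorrect_trial_decoding,
                               llr_pair_discrimination, log_likelihood,
                               normalized_accuracy)
from speedcat.synth import ScenarioSpec, build_scenario
from speedcat.task import TaskConfig


class TestLogLikelihood:
    def test_single_neuron_value(self):
        # r log f - f with f=2, r=3
        ll = log_likelihood([3], [[2.0]])
        assert ll[0] == pytest.approx(3 * math.log(2) - 2)

    def test_additive_over_neurons(self, rng):
        F = rng.uniform(1, 8, size=(1, 5))
        r = rng.integers(0, 10, size=1)
        single = log_likelihood(r, F)
        double = log_likelihood(np.tile(r, 2), np.tile(F, (2, 1)))
        np.testing.assert_allclose(double, 2 * single)

    def test_silent_population_prefers_lowest_total_tuning(self, rng):
        F = rng.uniform(1, 8, size=(4, 6))
        ll = log_likelihood(np.zeros(4, dtype=int), F)
        assert ll.argmax() == F.sum(axis=0).argmin()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            log_likelihood([1, 2], [[1.0, 2.0]])

    def test_zero_tuning_disqualified_once_spike_observed(self):
        F = np.array([[0.0, 2.0]])
        ll = log_likelihood([3], F)
        assert ll[0] == -np.inf and np.isfinite(ll[1])
        # no spikes: zero-mean class predicts perfectly (0 * log 0 = 0)
        ll0 = log_likelihood([0], F)
        assert ll0[0] == 0.0


class TestDecodeTrial:
    def test_argmax(self):
        assert decode_trial([-2.0, -3.0]) == 0

    def test_brute_force_two_class_example(self):
        # f=(1,5), r=5: class 2 wins since 5 ln5 - 5 > 5 ln1 - 1
        ll = log_likelihood([5], [[1.0, 5.0]])
        assert decode_trial(ll, seed=0) == 1
        assert ll[1] > ll[0]

    def test_tie_broken_uniformly(self):
        rng = np.random.default_rng(0)
        picks = np.array([decode_trial(np.zeros(16), seed=rng)
                          for _ in range(10000)])
        freqs = np.bincount(picks, minlength=16) / 10000
        se = math.sqrt((1 / 16) * (15 / 16) / 10000)
        assert np.all(np.abs(freqs - 1 / 16) < 4 * se)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            decode_trial([])


class TestOracleEquivalence:
    def test_matches_full_poisson_pmf_decoder(self):
        """Dropping the stimulus-independent log(r!) term never changes
        the argmax: exhaustive check against scipy's full log-pmf on
        small instances (<=3 neurons, <=4 classes, counts <=6)."""
        rng = np.random.default_rng(1)
        for n_neurons, n_classes in itertools.product((1, 2, 3), (2, 3, 4)):
            for _ in range(3):
                F = rng.uniform(0.5, 6.0, size=(n_neurons, n_classes))
                for r in itertools.product(range(7), repeat=n_neurons):
                    r = np.asarray(r)
                    fast = log_likelihood(r, F)
                    full = poisson.logpmf(r[:, None], F).sum(axis=0)
                    fast_best = set(np.flatnonzero(fast == fast.max()))
                    full_best = set(np.flatnonzero(
                        np.isclose(full, full.max(), atol=1e-10)))
                    assert fast_best == full_best


class TestEstimateTuning:
    def test_zero_training_counts_floored(self):
        table = estimate_tuning([np.array([0, 0]), np.array([2, 4])])
        np.testing.assert_allclose(table.class_means, [1.0, 3.0])
        assert table.floor_applied.tolist() == [True, False]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="equalization"):
            estimate_tuning([np.array([]), np.array([1])])


class TestSklearnDecoder:
    def test_fit_predict_separable(self, rng):
        means = np.array([[2.0, 20.0], [20.0, 2.0]])  # 2 neurons, 2 classes
        X, y = [], []
        for j, label in enumerate(["a", "b"]):
            X.append(rng.poisson(means[:, j], size=(50, 2)))
            y += [label] * 50
        X = np.vstack(X)
        clf = PoissonPopulationDecoder(random_state=0).fit(X, y)
        assert (clf.predict(X[:50]) == "a").mean() > 0.95
        assert (clf.predict(X[50:]) == "b").mean() > 0.95

    def test_floor_recorded(self):
        clf = PoissonPopulationDecoder(floor=1.0).fit(
            np.zeros((4, 2)), ["a", "a", "b", "b"])
        assert clf.floor_applied_.all()
        np.testing.assert_allclose(clf.tuning_, 1.0)

    def test_decision_function_permutes_with_classes(self, rng):
        X = rng.poisson(5, size=(40, 3))
        y = rng.integers(0, 4, size=40)
        clf = PoissonPopulationDecoder().fit(X, y)
        ll = clf.decision_function(X[:5])
        perm = rng.permutation(4)
        clf2 = PoissonPopulationDecoder().fit(X, perm[y])
        ll2 = clf2.decision_function(X[:5])
        # relabeling class j -> perm[j] permutes likelihood columns exactly
        np.testing.assert_allclose(ll2[:, perm], ll, rtol=1e-12)

    def test_clone_and_get_params(self):
        clf = PoissonPopulationDecoder(floor=0.5, random_state=3)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()


@pytest.fixture(scope="module")
def sessions():
    spec = ScenarioSpec(n_neurons=4, n_blocks=8, seed=5)
    return build_scenario(spec)[0]


class TestEqualize:
    def test_every_cell_has_exactly_n_eq_trials(self, sessions, task):
        ens = equalize_trials(sessions, "post_saccade", task, n_eq=10,
                              seed=0)
        assert ens.counts.shape[1:] == (16, 10)

    def test_surplus_subsampled_without_reconstruction(self, task):
        spec = ScenarioSpec(n_neurons=2, n_blocks=10, seed=6)
        sessions, _ = build_scenario(spec)
        ens = equalize_trials(sessions, "post_saccade", task, n_eq=3,
                              seed=1)
        assert not ens.reconstructed.any()

    def test_deficit_filled_with_poisson_surrogates(self, task):
        spec = ScenarioSpec(n_neurons=2, n_blocks=4, seed=7)
        sessions, _ = build_scenario(spec)
        ens = equalize_trials(sessions, "post_saccade", task, n_eq=12,
                              seed=2)
        assert ens.reconstructed.any()
        frac = ens.reconstructed_fraction()
        assert set(frac) == {"slow", "fast"}
        assert all(0 < v < 1 for v in frac.values())

    def test_neuron_with_empty_cell_excluded(self, task):
        # with a single block, easy speeds have no incorrect trials, so
        # demanding incorrect-only trials empties cells for every neuron
        spec = ScenarioSpec(n_neurons=3, n_blocks=1, seed=50)
        few, _ = build_scenario(spec)
        with pytest.raises(ValueError, match="no neurons survived"):
            equalize_trials(few, "post_saccade", task,
                            trial_filter="incorrect_only", seed=3)

    def test_subset_preserves_structure(self, sessions, task):
        ens = equalize_trials(sessions, "post_saccade", task, seed=4)
        sub = ens.subset([0, 2])
        assert sub.n_neurons == 2
        assert sub.classes == ens.classes


class TestCrossValidatedAccuracy:
    def test_flat_ensemble_decodes_at_chance(self):
        ens = make_iid_ensemble(5.0, n_neurons=20, seed=8)
        rep = cross_validated_accuracy(ens, n_draws=150, seed=9)
        # tolerance reflects the finite 10-trial pools frozen in the
        # ensemble, not just draw noise
        assert abs(rep.speed_accuracy - 0.125) < 0.025
        assert abs(rep.boundary_accuracy - 0.5) < 0.045
        assert rep.chance == {"speed": 0.125, "boundary": 0.5}

    def test_well_separated_tuning_decodes_almost_perfectly(self):
        means = np.full((20, 16), 2.0)
        for i in range(20):
            means[i, i % 16] = 60.0  # distinctive signature per class
        ens = make_iid_ensemble(means, seed=10)
        rep = cross_validated_accuracy(ens, n_draws=100, seed=11)
        assert rep.joint_accuracy > 0.95

    def test_accuracy_invariant_to_class_relabeling(self):
        means = np.full((10, 16), 3.0)
        means[:5, :8] += 6.0
        ens = make_iid_ensemble(means, seed=12)
        rep = cross_validated_accuracy(ens, n_draws=300, seed=13)
        perm = np.random.default_rng(14).permutation(16)
        ens_perm = make_iid_ensemble(means, seed=12)
        ens_perm.counts = ens_perm.counts[:, perm, :]
        ens_perm.classes = [ens.classes[j] for j in perm]
        rep_perm = cross_validated_accuracy(ens_perm, n_draws=300, seed=13)
        assert rep_perm.joint_accuracy == pytest.approx(
            rep.joint_accuracy, abs=0.02)

    def test_loo_scheme_beats_single_trial_training(self):
        means = np.full((12, 16), 2.0)
        means[:, 8:] += 3.0  # boundary signal
        ens = make_iid_ensemble(means, seed=15)
        single = cross_validated_accuracy(ens, n_draws=200,
                                          scheme="train_one", seed=16)
        loo = cross_validated_accuracy(ens, n_draws=200, scheme="loo",
                                       seed=17)
        # 9-trial training means are less noisy than single trials
        assert loo.boundary_accuracy >= single.boundary_accuracy

    def test_n_eq_below_two_rejected(self):
        ens = make_iid_ensemble(5.0, n_neurons=3, n_eq=1, seed=18)
        with pytest.raises(ValueError, match="n_eq"):
            cross_validated_accuracy(ens)

    def test_per_class_table_complete(self):
        ens = make_iid_ensemble(4.0, n_neurons=5, seed=19)
        rep = cross_validated_accuracy(ens, n_draws=20, seed=20)
        assert len(rep.per_class) == 16
        for col in ("joint_accuracy", "speed_accuracy",
                    "boundary_accuracy"):
            assert rep.per_class[col].between(0, 1).all()


class TestNormalizedAccuracy:
    @pytest.mark.parametrize("acc, chance, expected",
                             [(0.125, 0.125, 0.0), (1.0, 0.125, 1.0),
                              (0.5, 0.5, 0.0), (1.0, 0.5, 1.0)])
    def test_formula(self, acc, chance, expected):
        assert normalized_accuracy(acc, chance) == pytest.approx(expected)

    def test_bounds(self):
        assert normalized_accuracy(0.0, 0.125) == pytest.approx(
            -0.125 / 0.875)


class TestPopulationSize:
    def test_accuracy_nondecreasing_with_population_size(self):
        rng = np.random.default_rng(21)
        means = 3.0 + rng.uniform(0, 8, size=(24, 16))
        ens = make_iid_ensemble(means, seed=22)
        curve = accuracy_vs_population_size(ens, sizes=[2, 6, 12, 24],
                                            n_draws=80, seed=23)
        acc = curve["speed_normalized"].to_numpy()
        sem = curve["speed_accuracy_sem"].to_numpy() / (1 - 0.125)
        assert np.all(np.diff(acc) > -(sem[1:] + sem[:-1]))

    def test_boundary_code_saturates_before_speed_code(self):
        """Redundant boundary coding: every neuron carries the boundary
        signal but only a subset is speed tuned, so the boundary curve
        approaches its asymptote at smaller N."""
        rng = np.random.default_rng(24)
        n_neurons = 24
        means = np.full((n_neurons, 16), 3.0)
        means[:, 8:] += 4.0  # boundary signal in every neuron
        speeds = np.tile(np.arange(8), 2)
        for i in range(0, n_neurons, 3):  # a third are speed coders
            pref = rng.integers(0, 8)
            means[i] += 8.0 * np.exp(-0.5 * ((speeds - pref) / 1.0) ** 2)
        ens = make_iid_ensemble(means, seed=25)
        sizes = [2, 4, 8, 16, 24]
        curve = accuracy_vs_population_size(ens, sizes=sizes, n_draws=80,
                                            seed=26)

        def saturation_size(col):
            vals = curve[col].to_numpy()
            target = 0.8 * vals.max()
            return sizes[int(np.argmax(vals >= target))]

        assert (saturation_size("boundary_normalized")
                < saturation_size("speed_normalized"))

    def test_oversized_request_rejected(self):
        ens = make_iid_ensemble(5.0, n_neurons=4, seed=27)
        with pytest.raises(ValueError, match="sizes"):
            accuracy_vs_population_size(ens, sizes=[8])


class TestPairDiscrimination:
    def test_identical_tuning_discriminates_at_chance(self):
        ens = make_iid_ensemble(5.0, n_neurons=12, seed=28)
        tab = llr_pair_discrimination(ens, n_draws=150, seed=29)
        # per-pair deviations reflect each pair's frozen 10-trial pools;
        # the mean over the 14 pair/boundary cells averages pool luck out
        assert np.all(np.abs(tab["accuracy"] - 0.5) < 0.12)
        assert abs(tab["accuracy"].mean() - 0.5) < 0.03

    def test_pair_tags_follow_boundary_cues(self):
        ens = make_iid_ensemble(5.0, n_neurons=4, seed=30)
        tab = llr_pair_discrimination(ens, n_draws=5, seed=31)
        tag = {(r.s1, r.s2, r.boundary): r.category
               for r in tab.itertuples()}
        assert tag[(4.0, 6.0, "slow")] == "inter"   # straddles cue 5
        assert tag[(4.0, 6.0, "fast")] == "intra"
        assert tag[(12.0, 14.0, "fast")] == "inter"  # straddles cue 13
        assert tag[(12.0, 14.0, "slow")] == "intra"
        assert len(tab) == 14  # 7 pairs x 2 boundaries

    def test_llr_antisymmetric_in_pair_order(self, rng):
        F = rng.uniform(1, 6, size=(5, 2))
        r = rng.integers(0, 8, size=5)
        ll = log_likelihood(r, F)
        assert (ll[0] - ll[1]) == pytest.approx(-(ll[1] - ll[0]))

    def test_category_step_accentuates_inter_pairs(self):
        """Boundary accentuation: near-boundary pairs discriminate better
        when their members fall in different categories."""
        means = np.full((20, 16), 3.0)
        speeds = np.tile(np.arange(1, 9) * 2.0, 2)
        bounds = np.repeat(["slow", "fast"], 8)
        refs = np.where(bounds == "slow", 5.0, 13.0)
        means[:, speeds > refs] += 6.0  # step across the active boundary
        ens = make_iid_ensemble(means, seed=32)
        tab = llr_pair_discrimination(ens, n_draws=200, seed=33)
        near = tab[tab.apply(lambda r: (r["s1"], r["s2"])
                             in [(4.0, 6.0), (12.0, 14.0)], axis=1)]
        inter = near.loc[near["category"] == "inter", "accuracy"].mean()
        intra = near.loc[near["category"] == "intra", "accuracy"].mean()
        assert inter > intra + 0.2

    def test_direction_ensemble_rejected(self):
        ens = make_iid_ensemble(np.full((3, 32), 5.0), seed=34,
                                include_direction=True)
        with pytest.raises(ValueError, match="16-class"):
            llr_pair_discrimination(ens, n_draws=5, seed=35)


class TestDirectionDecoding:
    def test_thirty_two_classes_enumerated(self, task):
        classes = task.joint_classes(include_direction=True)
        assert len(classes) == 32
        assert len(set(classes)) == 32

    def test_direction_blind_tuning_at_chance(self):
        ens = make_iid_ensemble(np.full((15, 32), 5.0), seed=36,
                                include_direction=True)
        rep = direction_decoding(ens, n_draws=100, seed=37)
        assert abs(rep.direction_accuracy - 0.5) < 0.05

    def test_near_boundary_direction_suppression_detected(self):
        """A generator that silences direction modulation at speeds 6 and
        12 yields lower direction accuracy at those stimuli."""
        spec = ScenarioSpec(
            n_neurons=18, tuning_family="flat", tuning_amplitude_hz=2.0,
            direction_amplitude_hz=14.0, direction_suppression_near=0.0,
            include_direction=True, n_blocks=8, seed=38)
        sessions, _ = build_scenario(spec)
        ens = equalize_trials(sessions, "post_saccade", spec.task,
                              include_direction=True, seed=39)
        rep = direction_decoding(ens, n_draws=150, seed=40)
        pc = rep.per_class
        near = pc.loc[pc["speed"].isin([6.0, 12.0]),
                      "direction_accuracy"].mean()
        far = pc.loc[~pc["speed"].isin([6.0, 12.0]),
                     "direction_accuracy"].mean()
        assert near < far - 0.1

    def test_sixteen_class_ensemble_rejected(self):
        ens = make_iid_ensemble(5.0, n_neurons=3, seed=41)
        with pytest.raises(ValueError, match="include_direction"):
            direction_decoding(ens)


class TestIncorrectTrialDecoding:
    def test_subjective_trace_degrades_incorrect_trial_readout(self):
        """When incorrect trials carry spike counts reflecting the chosen
        (wrong) category, the decoder loses the stimulus identity on
        those trials."""
        spec = ScenarioSpec(
            n_neurons=16, tuning_family="speed_tuned",
            tuning_amplitude_hz=18.0, tuning_width=1.5,
            incorrect_spikes="chosen_category", n_blocks=14, seed=42)
        sessions, _ = build_scenario(spec)
        out = incorrect_trial_decoding(sessions, "post_saccade", spec.task,
                                       n_draws=150, seed=43)
        assert (out["incorrect_speed_accuracy"]
                < out["correct_speed_accuracy"] - 0.05)

    def test_no_incorrect_trials_raises_actionable_error(self, task):
        spec = ScenarioSpec(n_neurons=2, n_blocks=3, seed=44)
        sessions, _ = build_scenario(spec)
        # speeds 2/16 are nearly always correct: no incorrect trials
        with pytest.raises(ValueError, match="incorrect-trial ensemble"):
            incorrect_trial_decoding(sessions, "post_saccade", task,
                                     speeds=(2.0, 16.0), n_draws=5,
                                     seed=45)
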