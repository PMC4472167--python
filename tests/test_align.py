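"""Alignment model: tau mapping, pair likelihood, gap search, joint decoding,
representations, full-MLE and two-step estimation."""

import numpy as np
import pytest

from conftest import enum_joint_viterbi, enum_pair_loglik, random_params

from tcalign.align import (
    AlignmentMap,
    ProfilePair,
    average_profile,
    fit_full_mle,
    fit_two_step,
    gap_grid_search,
    joint_viterbi,
    pair_loglik,
    tau_from_gaps,
    total_loglik,
)
from tcalign.hmm import HMMParams, InputError, ParameterError, Profile, baum_welch_pooled
from tcalign import synthetic


def _pair(gene, w, c):
    return ProfilePair(gene, Profile(gene, "a", w), Profile(gene, "b", c))


class TestTauMapping:
    def test_estimated_grapevine_gaps(self):
        amap = tau_from_gaps(2, 11, 19)
        expected = [1, 3, 4, 5, 6, 7, 8, 9, 10, 12, 13, 14, 15, 16, 17, 18, 19]
        np.testing.assert_array_equal(amap.tau_short, expected)
        assert amap.gap_positions == (2, 11)

    def test_gaps_at_the_end_leave_prefix_unshifted(self):
        amap = tau_from_gaps(18, 19, 19)
        np.testing.assert_array_equal(amap.tau_short, np.arange(1, 18))

    def test_adjacent_gaps(self):
        amap = tau_from_gaps(2, 3, 19)
        np.testing.assert_array_equal(amap.tau_short, [1] + list(range(4, 20)))

    def test_matches_piecewise_formula(self):
        # tau[t] = t before g1, t+1 between the gaps, t+2 after g2
        for g1, g2 in [(2, 11), (3, 4), (5, 19), (2, 3)]:
            amap = tau_from_gaps(g1, g2, 19)
            for t in range(1, 18):
                if t <= g1 - 1:
                    assert amap.tau_short[t - 1] == t
                elif t <= g2 - 2:
                    assert amap.tau_short[t - 1] == t + 1
                else:
                    assert amap.tau_short[t - 1] == t + 2

    @pytest.mark.parametrize("g1,g2", [(1, 5), (5, 5), (7, 3), (2, 20)])
    def test_inadmissible_gaps_rejected(self, g1, g2):
        with pytest.raises(ParameterError):
            tau_from_gaps(g1, g2, 19)

    def test_tau_short_is_complement_of_gaps(self):
        amap = AlignmentMap.from_gap_set((3, 7, 12), 19)
        assert set(amap.tau_short) | set(amap.gap_positions) == set(range(1, 20))
        assert (np.diff(amap.tau_short) > 0).all()
        assert amap.tau_short[0] == 1


class TestPairLoglik:
    def test_single_state_all_at_mean(self):
        params = HMMParams([1.0], [[1.0]], [0.5], [0.25], variance_floor=0.001)
        amap = AlignmentMap.from_gap_set((2, 3), 3)
        pair = _pair("g", [0.5, 0.5, 0.5], [0.5])
        ll = pair_loglik(pair, params, amap)
        assert ll == pytest.approx(4 * np.log(1 / np.sqrt(2 * np.pi * 0.25)), abs=1e-6)

    @pytest.mark.parametrize("gaps", [(2, 3), (2, 4), (3, 4)])
    def test_matches_enumeration(self, gaps, rng):
        params = random_params(2, rng)
        amap = AlignmentMap.from_gap_set(gaps, 4)
        pair = _pair("g", rng.uniform(0, 1, 4), rng.uniform(0, 1, 2))
        ll = pair_loglik(pair, params, amap)
        ref = enum_pair_loglik(
            pair.profile_long.values, pair.profile_short.values, params, amap
        )
        assert ll == pytest.approx(ref, rel=1e-10)

    def test_length_mismatch_is_an_error(self, params2):
        amap = tau_from_gaps(2, 11, 19)
        with pytest.raises(InputError):
            pair_loglik(_pair("g", np.zeros(10), np.zeros(8)), params2, amap)


class TestTotalLoglik:
    def test_single_pair_equals_pair_loglik(self, params2, rng):
        pair = _pair("g", rng.uniform(0, 1, 19), rng.uniform(0, 1, 17))
        amap = tau_from_gaps(2, 11, 19)
        assert total_loglik([pair], params2, 2, 11) == pytest.approx(
            pair_loglik(pair, params2, amap), rel=1e-12
        )

    def test_additive_over_pairs(self, params3, rng):
        pairs = [
            _pair(f"g{i}", rng.uniform(0, 1, 19), rng.uniform(0, 1, 17))
            for i in range(10)
        ]
        amap = tau_from_gaps(3, 9, 19)
        total = total_loglik(pairs, params3, 3, 9)
        parts = sum(pair_loglik(p, params3, amap) for p in pairs)
        assert total == pytest.approx(parts, rel=1e-12)
        assert total_loglik(pairs * 2, params3, 3, 9) == pytest.approx(2 * total, rel=1e-12)

    def test_heterogeneous_lengths_rejected(self, params2):
        pairs = [
            _pair("g1", np.zeros(19), np.zeros(17)),
            _pair("g2", np.zeros(18), np.zeros(16)),
        ]
        with pytest.raises(InputError):
            total_loglik(pairs, params2, 2, 11)


class TestJointViterbi:
    def test_single_state_all_ones(self, rng):
        params = HMMParams([1.0], [[1.0]], [0.5], [0.1], variance_floor=0.001)
        amap = tau_from_gaps(2, 11, 19)
        pair = _pair("g", rng.uniform(0, 1, 19), rng.uniform(0, 1, 17))
        assert (joint_viterbi(pair, params, amap).states == 1).all()

    def test_matches_enumeration_argmax(self, rng):
        params = random_params(2, rng)
        amap = AlignmentMap.from_gap_set((2, 4), 4)
        pair = _pair("g", rng.uniform(0, 1, 4), rng.uniform(0, 1, 2))
        res = joint_viterbi(pair, params, amap)
        ref_path, ref_lp = enum_joint_viterbi(
            pair.profile_long.values, pair.profile_short.values, params, amap
        )
        np.testing.assert_array_equal(res.states - 1, ref_path)
        assert res.log_prob == pytest.approx(ref_lp, rel=1e-10)

    def test_joint_log_prob_bounded_by_pair_loglik(self, rng):
        params = random_params(3, rng)
        amap = tau_from_gaps(2, 11, 19)
        for _ in range(5):
            pair = _pair("g", rng.uniform(0, 1, 19), rng.uniform(0, 1, 17))
            assert joint_viterbi(pair, params, amap).log_prob <= pair_loglik(
                pair, params, amap
            ) + 1e-10

    def test_noiseless_consistency_with_individual_paths(self):
        from tcalign.hmm import viterbi

        params = synthetic.default_params(variance=1e-4, variance_floor=1e-4)
        amap = tau_from_gaps(2, 11, 19)
        gen = np.random.default_rng(3)
        states = synthetic._draw_states(params, 19, gen)
        w = params.emission_means[states]
        c = w[amap.tau_short - 1]
        pair = _pair("g", w, c)
        joint = joint_viterbi(pair, params, amap)
        np.testing.assert_array_equal(joint.states, states + 1)
        ind_long = viterbi(pair.profile_long, params)
        ind_short = viterbi(pair.profile_short, params)
        np.testing.assert_array_equal(joint.states[amap.tau_long - 1], ind_long.states)
        np.testing.assert_array_equal(joint.states[amap.tau_short - 1], ind_short.states)


class TestAverageProfile:
    def test_identical_profiles_average_to_themselves(self):
        amap = tau_from_gaps(2, 11, 19)
        w = np.linspace(0, 1, 19)
        pair = _pair("g", w, w[amap.tau_short - 1])
        np.testing.assert_allclose(average_profile(pair, amap), w)

    def test_opposite_constants(self):
        amap = tau_from_gaps(2, 11, 19)
        pair = _pair("g", np.zeros(19), np.ones(17))
        avg = average_profile(pair, amap)
        assert avg[1] == 0.0 and avg[10] == 0.0  # gap positions keep the long value
        mask = np.ones(19, bool)
        mask[[1, 10]] = False
        assert (avg[mask] == 0.5).all()

    def test_hand_computed_small_case(self):
        amap = AlignmentMap.from_gap_set((2, 3), 3)
        pair = _pair("g", [0.2, 0.4, 0.6], [0.8])
        np.testing.assert_allclose(average_profile(pair, amap), [0.5, 0.4, 0.6])


class TestGapGridSearch:
    def test_surface_size_and_argmax_consistency(self, rng):
        ds = synthetic.generate_dataset(K=50, seed=0)
        params = synthetic.default_params()
        res = gap_grid_search(ds.pairs, params)
        assert len(res.surface) == 153  # C(18, 2)
        assert res.surface[res.best_gaps] == max(res.surface.values())

    def test_noiseless_pairs_pin_the_generating_gaps(self):
        params = synthetic.default_params(variance=1e-4, variance_floor=1e-4)
        ds = synthetic.generate_dataset(
            K=200, params=params, true_gaps=(5, 12), seed=17
        )
        res = gap_grid_search(ds.pairs, params)
        assert res.best_gaps == (5, 12)
        best = res.surface[(5, 12)]
        others = [v for k, v in res.surface.items() if k != (5, 12)]
        assert best > max(others)

    def test_surface_invariant_to_pair_ordering(self, rng):
        ds = synthetic.generate_dataset(K=30, seed=2)
        params = synthetic.default_params()
        res1 = gap_grid_search(ds.pairs, params)
        res2 = gap_grid_search(ds.pairs[::-1], params)
        for k in res1.surface:
            assert res1.surface[k] == pytest.approx(res2.surface[k], rel=1e-12)

    def test_combinatorial_cap(self, rng):
        pairs = [_pair("g", rng.uniform(0, 1, 19), rng.uniform(0, 1, 10))]  # C(18,9) sets
        with pytest.raises(InputError):
            gap_grid_search(pairs, random_params(2, rng), max_candidates=100)


class TestFitFullMLE:
    def test_single_state_closed_form(self, rng):
        pairs = [
            _pair(f"g{i}", rng.uniform(0, 1, 19), rng.uniform(0, 1, 17))
            for i in range(10)
        ]
        fit = fit_full_mle(pairs, 2, 11, n_states=1)
        allv = np.concatenate(
            [p.profile_long.values for p in pairs] + [p.profile_short.values for p in pairs]
        )
        assert fit.params.emission_means[0] == pytest.approx(allv.mean(), abs=1e-9)
        assert fit.params.emission_variances[0] == pytest.approx(
            max(allv.var(), 0.001), abs=1e-9
        )

    def test_monotone_loglik_and_mean_recovery(self):
        ds = synthetic.generate_dataset(K=500, seed=21)
        fit = fit_full_mle(ds.pairs, 2, 11, n_states=5)
        assert (np.diff(fit.loglik_history) >= -1e-8).all()
        means = np.sort(fit.params.emission_means)
        np.testing.assert_allclose(means, ds.true_params.emission_means, atol=0.05)

    def test_dominates_two_step_estimate_at_same_gaps(self):
        ds = synthetic.generate_dataset(K=100, seed=8)
        pooled, search = fit_two_step(ds.pairs, n_states=5)
        g1, g2 = search.best_gaps
        full = fit_full_mle(ds.pairs, g1, g2, n_states=5)
        assert full.loglik >= total_loglik(ds.pairs, pooled.params, g1, g2) - 1e-6

    def test_contamination_inflates_variances(self):
        ds = synthetic.generate_dataset(K=300, contamination_fraction=0.5, seed=13)
        profiles = [p.profile_long for p in ds.pairs] + [p.profile_short for p in ds.pairs]
        pooled = baum_welch_pooled(profiles, n_states=5)
        full = fit_full_mle(ds.pairs, 2, 11, n_states=5)
        assert full.params.emission_variances.mean() > pooled.params.emission_variances.mean()


class TestFitTwoStep:
    def test_clean_simulation_recovers_gaps_across_seeds(self):
        # >= 95 % recovery on clean data at K = 200; here every seeded replicate
        for seed in range(5):
            ds = synthetic.generate_dataset(K=200, seed=100 + seed)
            _, search = fit_two_step(ds.pairs, n_states=5)
            assert search.best_gaps == (2, 11)

    def test_deterministic_under_seed(self):
        ds = synthetic.generate_dataset(K=80, seed=4)
        out = [fit_two_step(ds.pairs, n_states=4, seed=0) for _ in range(2)]
        np.testing.assert_array_equal(
            out[0][0].params.emission_means, out[1][0].params.emission_means
        )
        assert out[0][1].best_gaps == out[1][1].best_gaps
        assert out[0][1].surface == out[1][1].surface
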