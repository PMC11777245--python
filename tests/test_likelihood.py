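import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cjsclim as cc
from cjsclim.likelihood import SpeciesLikelihood, interval_covariate


def brute_force_history_prob(history, first, phi, p):
    """Exhaustive sum over latent death times: independent oracle."""
    y = np.asarray(history, dtype=int)
    T = len(y)
    detected = np.flatnonzero(y)
    total = 0.0
    for d in range(first, T):  # d = last occasion alive
        if d < detected[-1]:
            continue
        prob = 1.0
        for t in range(first, d):
            prob *= phi[t]
        if d < T - 1:
            prob *= 1 - phi[d]
        for t in range(first + 1, d + 1):
            prob *= p[t] if y[t] else 1 - p[t]
        total += prob
    return total


def random_instance(rng, T):
    phi = rng.uniform(0.05, 0.95, T - 1)
    p = rng.uniform(0.05, 0.95, T)
    return phi, p


class TestChiRecursion:
    def test_certain_detection(self):
        chi = cc.chi_recursion([0.5], [0.3, 1.0])
        assert chi[0] == pytest.approx(0.5)
        assert chi[1] == 1.0

    def test_partial_detection_arithmetic(self):
        chi = cc.chi_recursion([0.5], [0.3, 0.4])
        assert chi[0] == pytest.approx(0.5 + 0.5 * 0.6)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            cc.chi_recursion([1.5], [0.3, 0.4])

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=50)
    def test_equals_exhaustive_enumeration(self, seed):
        """chi_1 = P(never seen again) summed over death times and detections."""
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 6))
        phi, p = random_instance(rng, T)
        chi = cc.chi_recursion(phi, p)
        # individual alive at occasion 0, never detected afterwards =
        # all-zero continuation history
        history = np.zeros(T, dtype=int)
        history[0] = 1
        expected = brute_force_history_prob(history, 0, phi, p)
        assert chi[0] == pytest.approx(expected, rel=1e-12)


class TestHistoryLoglik:
    def test_simple_recapture(self):
        ll = cc.history_loglik([1, 1], 0, [0.5], [0.3, 0.4])
        assert ll == pytest.approx(np.log(0.2))

    def test_unsampled_middle_occasion(self):
        # occasion 2 unsampled (p = 0) contributes a factor of one:
        # phi1 * 1 * phi2 * p3 * chi3 = 0.5 * 1 * 0.5 * 0.4 * 1 = 0.1
        ll = cc.history_loglik([1, 0, 1], 0, [0.5, 0.5], [0.4, 0.0, 0.4])
        assert ll == pytest.approx(np.log(0.1))

    def test_all_zero_history_raises(self):
        with pytest.raises(ValueError):
            cc.history_loglik([0, 0], 0, [0.5], [0.4, 0.4])

    def test_detection_where_p_zero_raises(self):
        with pytest.raises(ValueError, match="p = 0"):
            cc.history_loglik([1, 1], 0, [0.5], [0.4, 0.0])

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=60)
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 7))
        phi, p = random_instance(rng, T)
        first = int(rng.integers(0, T))
        # random continuation
        y = np.zeros(T, dtype=int)
        y[first] = 1
        y[first + 1 :] = rng.random(T - first - 1) < 0.5
        ll = cc.history_loglik(y, first, phi, p)
        expected = brute_force_history_prob(y, first, phi, p)
        assert np.exp(ll) == pytest.approx(expected, rel=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=30)
    def test_histories_sum_to_one(self, seed):
        """Post-first-capture histories form a probability distribution."""
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 6))
        phi, p = random_instance(rng, T)
        first = int(rng.integers(0, T - 1))
        total = 0.0
        for tail in itertools.product([0, 1], repeat=T - first - 1):
            y = np.zeros(T, dtype=int)
            y[first] = 1
            y[first + 1 :] = tail
            total += np.exp(cc.history_loglik(y, first, phi, p))
        assert total == pytest.approx(1.0, rel=1e-10)

    def test_monotone_in_survival_for_all_ones(self):
        y = [1, 1, 1, 1]
        phi = np.array([0.5, 0.5, 0.5])
        p = np.array([0.5, 0.5, 0.5, 0.5])
        base = cc.history_loglik(y, 0, phi, p)
        for t in range(3):
            bumped = phi.copy()
            bumped[t] += 0.1
            assert cc.history_loglik(y, 0, bumped, p) > base


class TestDatasetLoglik:
    def test_additivity_and_identical_histories(self, small_calendar):
        det = np.tile([1, 0, 1, 0], (3, 1))
        m = cc.CaptureHistoryMatrix(
            individuals=np.array(["a", "b", "c"]),
            species=np.array(["A", "A", "A"]),
            detections=det,
            calendar=small_calendar,
        )
        params = {"A": cc.CJSParameters(phi=[0.6] * 3, p=[0.4] * 4)}
        total, per = cc.dataset_loglik(m, params)
        single = cc.history_loglik([1, 0, 1, 0], 0, [0.6] * 3, [0.4] * 4)
        assert total == pytest.approx(3 * single, rel=1e-12)
        np.testing.assert_allclose(per, single)

    def test_missing_species_raises(self, small_matrix):
        with pytest.raises(ValueError, match="missing parameters"):
            cc.dataset_loglik(
                small_matrix, {"A": cc.CJSParameters(phi=[0.5] * 3, p=[0.4] * 4)}
            )

    def test_random_histories_sum_of_singles(self):
        rng = np.random.default_rng(3)
        cfg = cc.SimulationConfig(
            n_species=2, n_occasions=6, start_year=2000, mean_releases_per_year=5.0
        )
        climate = cc.simulate_climate(cfg, rng)
        m, _ = cc.simulate_capture_histories(cfg, climate, rng)
        params = {
            sp: cc.CJSParameters(
                phi=rng.uniform(0.3, 0.9, 5), p=rng.uniform(0.2, 0.8, 6)
            )
            for sp in m.species_list()
        }
        total, per = cc.dataset_loglik(m, params)
        for i in range(m.n_individuals):
            pr = params[m.species[i]]
            expected = cc.history_loglik(
                m.detections[i], m.first_capture[i], pr.phi, pr.p
            )
            assert per[i] == pytest.approx(expected, rel=1e-10)
        assert total == pytest.approx(per.sum())

    def test_permutation_invariance(self, small_matrix):
        params = {
            "A": cc.CJSParameters(phi=[0.6] * 3, p=[0.4] * 4),
            "B": cc.CJSParameters(phi=[0.5] * 3, p=[0.3] * 4),
        }
        total, _ = cc.dataset_loglik(small_matrix, params)
        perm = np.random.default_rng(0).permutation(small_matrix.n_individuals)
        shuffled = small_matrix.subset(perm)
        total2, _ = cc.dataset_loglik(shuffled, params)
        assert total2 == pytest.approx(total, rel=1e-12)

    def test_unsampled_year_equals_merged_intervals(self):
        """p_t = 0 is equivalent to removing the occasion and multiplying
        the adjacent survival probabilities."""
        cal = cc.OccasionCalendar.with_unsampled([0, 1, 2, 3], [1])
        phi = np.array([0.8, 0.7, 0.9])
        p = np.array([0.5, 0.0, 0.6, 0.55])
        det = np.array([[1, 0, 1, 0], [1, 0, 0, 1], [1, 0, 1, 1]])
        m = cc.CaptureHistoryMatrix(
            individuals=np.array(["a", "b", "c"]),
            species=np.array(["A"] * 3),
            detections=det,
            calendar=cal,
        )
        total, _ = cc.dataset_loglik(m, {"A": cc.CJSParameters(phi=phi, p=p)})
        # merged 3-occasion version
        cal3 = cc.OccasionCalendar.all_sampled([0, 2, 3])
        phi3 = np.array([0.8 * 0.7, 0.9])
        p3 = np.array([0.5, 0.6, 0.55])
        det3 = det[:, [0, 2, 3]]
        m3 = cc.CaptureHistoryMatrix(
            individuals=np.array(["a", "b", "c"]),
            species=np.array(["A"] * 3),
            detections=det3,
            calendar=cal3,
        )
        total3, _ = cc.dataset_loglik(m3, {"A": cc.CJSParameters(phi=phi3, p=p3)})
        assert total == pytest.approx(total3, rel=1e-10)


class TestBuildPhi:
    def test_zero_slope_reduces_to_constant(self, small_calendar, small_climate):
        spec = cc.ModelSpec("temperature")
        phi = cc.build_phi(spec, alpha=0.3, beta=0.0, climate=small_climate,
                           calendar=small_calendar)
        const = cc.build_phi(cc.ModelSpec("constant"), alpha=0.3, beta=None,
                             climate=None, calendar=small_calendar)
        np.testing.assert_allclose(phi, const)

    def test_logistic_arithmetic(self, small_calendar, small_climate):
        spec = cc.ModelSpec("temperature")
        phi = cc.build_phi(spec, alpha=0.0, beta=1.0, climate=small_climate,
                           calendar=small_calendar)
        x = interval_covariate(spec, small_climate, small_calendar)
        np.testing.assert_allclose(phi, 1 / (1 + np.exp(-x)))
        assert 1 / (1 + np.exp(0.85)) == pytest.approx(0.2994, abs=1e-4)

    def test_missing_covariate_year_raises(self, small_calendar):
        short = cc.zscore_covariates(
            cc.ClimateSeries(
                years=np.array([2000, 2001]),
                temp_c=np.array([26.0, 27.0]),
                precip_mm=np.array([300.0, 290.0]),
            )
        )
        with pytest.raises(ValueError, match="missing"):
            cc.build_phi(cc.ModelSpec("temperature"), 0.0, 1.0, short, small_calendar)


class TestSufficientStatistics:
    """The O(T) sufficient-statistic path must agree with per-history sums."""

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=25)
    def test_species_loglik_matches_rowwise(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(3, 8))
        n = int(rng.integers(1, 12))
        det = np.zeros((n, T), dtype=int)
        for i in range(n):
            f = int(rng.integers(0, T))
            det[i, f] = 1
            det[i, f + 1 :] = rng.random(T - f - 1) < 0.5
        sl = SpeciesLikelihood(det, np.ones(T, dtype=bool))
        phi, p = random_instance(rng, T)
        fast = sl.loglik(phi, p)
        slow = sum(
            cc.history_loglik(det[i], int(np.argmax(det[i])), phi, p)
            for i in range(n)
        )
        assert fast == pytest.approx(slow, rel=1e-10)
        point = sl.pointwise_loglik(phi[None, :], p[None, :])[0]
        assert point.sum() == pytest.approx(slow, rel=1e-10)


def test_candidate_set_structure():
    specs = cc.candidate_models()
    names = {s.name for s in specs}
    assert names == {
        "phi(.)p(.)", "phi(.)p(t)", "phi(t)p(.)", "phi(t)p(t)",
        "phi(temp)p(.)", "phi(temp)p(t)", "phi(precip)p(.)", "phi(precip)p(t)",
    }
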