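import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sg

from optoflow import (GLMResult, SimulationConfig, ValidationError,
                      activation_decision, bh_adjust, block_average,
                      build_design_matrix, cnr, cohens_d, default_design,
                      method_correlation, paired_t_bh, prewhiten, robust_glm,
                      roi_max_metric, simulate_recording)
from conftest import FS


def bh_oracle(p):
    """Brute-force step-up BH: independent of the implementation path."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBlockAverage:
    def test_constant_series(self):
        onsets = (15.0, 40.0, 65.0)
        ba = block_average(np.full(400, 3.2), FS, onsets)
        assert np.allclose(ba.pre_samples, 3.2) and np.allclose(ba.dur_samples, 3.2)
        assert ba.n_blocks_used == 3

    def test_boxcar_in_dur_window(self):
        n = 400
        t = np.arange(n) / FS
        onsets = (20.0, 60.0)
        x = np.zeros(n)
        for o in onsets:
            x[(t >= o + 5) & (t < o + 15)] = 2.5
        ba = block_average(x, FS, onsets)
        assert ba.pre_samples.mean() == pytest.approx(0.0, abs=1e-12)
        assert ba.dur_samples.mean() == pytest.approx(2.5, rel=0.02)

    def test_early_onset_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped 1 block"):
            ba = block_average(np.zeros(300), FS, (2.0, 30.0))
        assert ba.n_blocks_used == 1 and ba.n_blocks_dropped == 1

    def test_no_usable_blocks(self):
        with pytest.raises(ValidationError):
            block_average(np.zeros(30), FS, (2.0,))


class TestBlockMetrics:
    def test_cohens_d_hand_value(self):
        # (3 − 1.5) / sd([1,2,1,2]) = 1.5/sqrt(1/3)
        assert cohens_d([1, 2, 1, 2], [3, 3, 3, 3]) == pytest.approx(2.598076, abs=1e-6)

    def test_cohens_d_antisymmetry_and_zero(self):
        pre, dur = [1.0, 2.0, 3.0], [4.0, 5.0]
        assert cohens_d(pre, dur) == pytest.approx(-cohens_d([-p for p in pre],
                                                             [-d for d in dur]))
        assert cohens_d([1, 2, 1, 2], [1, 2, 1, 2]) == 0.0

    def test_cnr_hand_value_and_shift_invariance(self):
        assert cnr([1, 2, 1, 2], [3, 3, 3, 3]) == pytest.approx(2.598076, abs=1e-6)
        assert cnr([1, 2, 1, 2], [3, 3, 3, 3]) == pytest.approx(
            cnr([11, 12, 11, 12], [13, 13, 13, 13]))
        assert cnr([1, 2, 1, 2], [1.5, 1.5, 1.5, 1.5]) == 0.0

    def test_degenerate_windows(self):
        with pytest.raises(ValidationError):
            cohens_d([2, 2, 2], [3, 3])
        with pytest.raises(ValidationError):
            cnr([1, 1], [2, 2])

    def test_roi_max_conventions(self):
        vals = {0: 0.2, 1: 0.9, 2: 0.5, 3: 0.1}
        assert roi_max_metric(vals, [0, 1, 2, 3], "d_hbo") == 0.9
        assert roi_max_metric({0: -0.3, 1: -0.8}, [0, 1], "d_hbr") == -0.8
        assert roi_max_metric({0: -3.0, 1: 2.0}, [0, 1], "cnr") == 3.0
        with pytest.raises(ValidationError):
            roi_max_metric(vals, [], "d_hbo")


class TestDesignMatrix:
    def test_column_count(self):
        design = default_design()
        X = build_design_matrix(design, FS, 1000, include_derivatives=False)
        assert X.shape[1] == 2
        X = build_design_matrix(design, FS, 1000, include_derivatives=True)
        assert X.shape[1] == 4

    def test_main_column_at_task_frequency(self):
        design = default_design()
        n = 1000
        X = build_design_matrix(design, FS, n)
        f, p = sg.periodogram(X[:, 1] - X[:, 1].mean(), fs=FS)
        assert f[np.argmax(p)] == pytest.approx(design.fundamental_hz, abs=0.005)
        assert design.fundamental_hz == pytest.approx(1.0 / 25.0)

    def test_derivatives_orthogonal_to_main(self):
        X = build_design_matrix(default_design(), FS, 1000)
        for col in (2, 3):
            assert abs(np.dot(X[:, col], X[:, 1])) < 1e-8


class TestPrewhiten:
    def test_white_noise_selects_low_order(self):
        design = default_design()
        X = build_design_matrix(design, FS, 977)
        low = 0
        for seed in range(100):
            y = np.random.default_rng(seed).standard_normal(977)
            _, _, phi = prewhiten(y, X, fs=FS)
            low += len(phi) <= 1
        assert low >= 90

    def test_ar1_phi_recovered(self):
        rng = np.random.default_rng(0)
        y = sg.lfilter([1.0], [1.0, -0.8], rng.standard_normal(1100))[100:]
        _, _, phi = prewhiten(y, np.ones((1000, 1)), max_ar_order=6)
        assert phi[0] == pytest.approx(0.8, abs=0.1)

    def test_whitened_residual_autocorrelation(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = sg.lfilter([1.0], [1.0, -0.8], rng.standard_normal(1100))[100:]
            y_w, _, _ = prewhiten(y, np.ones((1000, 1)), max_ar_order=6)
            r1 = np.corrcoef(y_w[1:], y_w[:-1])[0, 1]
            assert abs(r1) < 0.1


class TestRobustGlm:
    def test_recovers_known_amplitude(self):
        design = default_design()
        X = build_design_matrix(design, FS, 977)
        rng = np.random.default_rng(1)
        y = 2.0 * X[:, 1] + 0.1 * rng.standard_normal(977)
        r = robust_glm(y, X)
        assert r.beta_main == pytest.approx(2.0, abs=0.1)
        assert r.t_main > 10

    def test_type_one_error_calibrated(self):
        design = default_design()
        X = build_design_matrix(design, FS, 977)
        rej = 0
        n_seeds = 300
        for seed in range(n_seeds):
            y = np.random.default_rng(seed).standard_normal(977)
            rej += robust_glm(y, X).p < 0.05
        assert 0.025 <= rej / n_seeds <= 0.10

    def test_outlier_resistance_vs_ols(self):
        design = default_design()
        X = build_design_matrix(design, FS, 500)
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = 1.0 * X[:, 1] + 0.2 * rng.standard_normal(500)
            idx = rng.choice(500, size=25, replace=False)
            y[idx] += rng.choice([-1, 1], size=25) * 10.0
            beta_r = robust_glm(y, X).beta_main
            beta_ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
            wins += abs(beta_r - 1.0) < abs(beta_ols - 1.0)
        assert wins / n_seeds >= 0.8

    def test_rank_deficient_rejected(self):
        X = np.ones((100, 2))
        with pytest.raises(ValidationError):
            robust_glm(np.zeros(100), X)


class TestBhAdjust:
    def test_hand_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.2])
        np.testing.assert_allclose(q, [0.05, 0.05, 0.05, 0.05, 0.2], atol=1e-12)

    def test_single_and_degenerate(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=rng.integers(1, 60))
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestActivationDecision:
    def make_result(self, species, beta, q):
        return GLMResult(species=species, beta=np.asarray(beta, float),
                         t=np.zeros(len(beta)), p=np.asarray(q, float),
                         q=np.asarray(q, float))

    def test_sign_and_significance_rules(self):
        hbo = self.make_result("hbo", [1.0, 1.0, -1.0], [0.01, 0.30, 0.01])
        hbr = self.make_result("hbr", [-1.0, -1.0, -1.0], [0.30, 0.01, 0.01])
        d = activation_decision(hbo, hbr)
        np.testing.assert_array_equal(d.oxy_active, [True, False, False])
        np.testing.assert_array_equal(d.deoxy_active, [False, True, True])
        np.testing.assert_array_equal(d.combined_active, [False, False, False])

    def test_combined_requires_both(self):
        hbo = self.make_result("hbo", [2.0], [0.001])
        hbr = self.make_result("hbr", [-2.0], [0.001])
        d = activation_decision(hbo, hbr)
        assert d.combined_active[0]

    def test_combined_subset_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 12
            hbo = self.make_result("hbo", rng.standard_normal(n), rng.uniform(0, 1, n))
            hbr = self.make_result("hbr", rng.standard_normal(n), rng.uniform(0, 1, n))
            d = activation_decision(hbo, hbr)
            assert d.active_set("combined") <= d.active_set("oxy")
            assert d.active_set("combined") <= d.active_set("deoxy")


class TestPairedComparisons:
    def test_constant_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(16)
        pc = paired_t_bh([(a + 1.0, a)])
        assert pc[0] < 1e-6

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        families_with_hit = 0
        n_fam = 300
        for _ in range(n_fam):
            pairs = [(rng.standard_normal(16), rng.standard_normal(16))
                     for _ in range(3)]
            families_with_hit += np.any(paired_t_bh(pairs) < 0.05)
        assert families_with_hit / n_fam <= 0.10

    def test_single_comparison_uncorrected(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        pc = paired_t_bh([(a, b)])
        assert pc[0] == pytest.approx(stats.ttest_rel(a, b).pvalue)

    def test_method_correlation_basics(self):
        x = np.random.default_rng(4).standard_normal(500)
        assert method_correlation(x, x) == pytest.approx(1.0)
        assert method_correlation(x, -x) == pytest.approx(-1.0)
        with pytest.raises(ValidationError):
            method_correlation(x, np.zeros(500))


class TestGlmEndToEnd:
    def test_prewhitening_controls_type_one_on_ar1(self):
        design = default_design()
        from optoflow import build_design_matrix
        X = build_design_matrix(design, FS, 977)
        rej_pw = rej_plain = 0
        n_seeds = 120
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = sg.lfilter([1.0], [1.0, -0.8], rng.standard_normal(1077))[100:]
            y_w, X_w, _ = prewhiten(y, X, fs=FS)
            rej_pw += robust_glm(y_w, X_w).p < 0.05
            rej_plain += robust_glm(y, X).p < 0.05
        assert 0.025 <= rej_pw / n_seeds <= 0.10
        assert rej_pw < rej_plain
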