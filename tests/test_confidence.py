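"""Confidence readouts: probit posterior, logistic approximation, the
low-dimensional mapping, mixtures, heatmaps and posterior fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr
from scipy.stats import spearmanr

from ldcconf import (
    DDMParams,
    LDCParams,
    LDCPosteriorRegressor,
    balanced_design,
    bayes_p_correct,
    bayes_readout_mixture,
    build_heatmap,
    fit_lambda,
    fit_ldc_to_posterior,
    ldc_confidence,
    logistic_probit_approx,
    simulate_dataset,
)


class TestBayesPCorrect:
    def test_zero_evidence_is_half(self):
        assert bayes_p_correct(0.0, 2.0) == pytest.approx(0.5)

    def test_one_sd_of_evidence(self):
        # e = sigma * sqrt(t) puts the standardized evidence at exactly 1
        assert bayes_p_correct(0.1 * np.sqrt(2.0), 2.0) == pytest.approx(
            0.8413447, abs=1e-6
        )

    @given(st.floats(-5, 5), st.floats(0.01, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_complement_symmetry(self, e, t):
        assert bayes_p_correct(e, t) + bayes_p_correct(-e, t) == pytest.approx(1.0)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            bayes_p_correct(0.1, 0.0)


class TestLogisticApprox:
    def test_zero_is_half(self):
        assert logistic_probit_approx(0.0) == pytest.approx(0.5)

    def test_approximation_error_below_one_percent(self):
        z = np.linspace(-10, 10, 20001)
        dev = np.abs(ndtr(z) - logistic_probit_approx(z, 1.702))
        assert dev.max() < 0.01

    def test_fit_lambda_recovers_the_constant(self):
        lam, dev = fit_lambda()
        assert round(lam, 1) == 1.7
        assert dev == pytest.approx(0.0095, abs=5e-4)

    def test_fit_lambda_is_the_argmin_on_its_grid(self):
        lam, dev = fit_lambda(lam_step=1e-3, z_step=1e-2)
        z = np.arange(0, 10.005, 1e-2)
        phi = ndtr(z)
        for other in (lam - 0.1, lam + 0.1, 1.5, 2.0):
            other_dev = np.abs(phi - logistic_probit_approx(z, other)).max()
            assert other_dev >= dev

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_lambda(interval=(2.0, 1.5))


class TestLDCConfidence:
    def test_alpha_zero_beta_zero_always_half(self):
        p = LDCParams(alpha=0.0, beta=0.0)
        for e, t, x in [(0.5, 1.0, 1), (-2.0, 0.3, -1), (0.0, 5.0, 1)]:
            assert ldc_confidence(e, t, x, p) == pytest.approx(0.5)

    def test_known_scalar_value(self):
        p = LDCParams(alpha=17.0, beta=0.0, gamma=0.5)
        assert ldc_confidence(0.1, 1.0, 1, p) == pytest.approx(0.8455347, abs=1e-6)

    @given(st.floats(-1, 1), st.floats(0.05, 8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_logistic_symmetry_at_zero_beta(self, e, t):
        p = LDCParams(alpha=20.0, beta=0.0)
        c1 = ldc_confidence(e, t, 1, p)
        c2 = ldc_confidence(-e, t, 1, p)
        assert c1 + c2 == pytest.approx(1.0)

    def test_large_alpha_saturates(self):
        p = LDCParams(alpha=1e6, beta=0.0)
        assert ldc_confidence(0.01, 1.0, 1, p) > 0.999999

    def test_monotone_in_beta_and_fading_with_time(self):
        e, x = 0.05, 1
        for t in (0.5, 1.0, 4.0):
            lo = ldc_confidence(e, t, x, LDCParams(alpha=10, beta=-0.5))
            hi = ldc_confidence(e, t, x, LDCParams(alpha=10, beta=0.5))
            assert hi > lo
        gaps = [
            ldc_confidence(e, t, x, LDCParams(alpha=10, beta=0.5))
            - ldc_confidence(e, t, x, LDCParams(alpha=10, beta=0.0))
            for t in (0.5, 2.0, 8.0)
        ]
        assert gaps[0] > gaps[1] > gaps[2]

    def test_reduces_to_probit_approx_at_equivalence(self):
        """alpha = lam/sigma, beta = 0 recovers the logistic-probit readout
        to machine precision."""
        sigma = 0.1
        p = LDCParams(alpha=1.7 / sigma, beta=0.0, gamma=0.5, lam=1.7)
        e = np.linspace(-0.5, 0.5, 101)
        for t in (0.2, 1.0, 3.7):
            lhs = ldc_confidence(e, t, np.where(e >= 0, 1, -1) * 0 + 1, p)
            rhs = logistic_probit_approx(e / (sigma * np.sqrt(t)), 1.7)
            assert np.max(np.abs(lhs - rhs)) < 1e-12


class TestReadoutMixture:
    def test_zero_evidence_half(self):
        assert bayes_readout_mixture(0.0, 1.0, [0.1, 0.2, 0.3]) == pytest.approx(0.5)

    def test_single_drift_reduces_to_logistic_form(self):
        v, sigma = 0.2, 0.1
        e = np.linspace(-0.3, 0.3, 61)
        t = 1.3
        got = bayes_readout_mixture(e, np.full_like(e, t), [v], sigma)
        want = 1.0 / (1.0 + np.exp(-2.0 * v * e / sigma**2))
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_strictly_increasing_in_evidence(self):
        e = np.linspace(-0.4, 0.4, 81)
        p = bayes_readout_mixture(e, np.full_like(e, 0.7), [0.1, 0.3])
        assert np.all(np.diff(p) > 0)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            bayes_readout_mixture(0.1, 1.0, [0.1, 0.2], prior=[0.9, 0.5])


class TestHeatmap:
    @pytest.fixture(scope="class")
    def symmetric_pair_table(self):
        ddm = DDMParams(drift_rates=(0.2,), bound=0.1, non_decision_time=0.3)
        rng = np.random.default_rng(31)
        return simulate_dataset(
            ddm, LDCParams(alpha=18.0), {"baseline": {0: 60_000}}, rng=rng
        ), ddm

    def test_monotone_in_evidence_and_half_at_zero(self, symmetric_pair_table):
        table, _ = symmetric_pair_table
        hm = build_heatmap(table, n_bins=12, min_count=100)
        # row means (over time) should rise along the evidence axis
        rows = [np.nanmean(r) for r in hm.p_correct if not np.all(np.isnan(r))]
        assert np.all(np.diff(rows) > -0.05)
        centers = 0.5 * (hm.evidence_edges[:-1] + hm.evidence_edges[1:])
        defined = ~np.all(np.isnan(hm.p_correct), axis=1)
        nearest = np.argmin(np.abs(centers) + np.where(defined, 0, np.inf))
        if abs(centers[nearest]) < 0.03:
            assert abs(np.nanmean(hm.p_correct[nearest]) - 0.5) < 0.1

    def test_matches_closed_form_mixture(self, symmetric_pair_table):
        """Empirical cell frequencies converge to the exact signed-drift
        mixture posterior, within 3 binomial SEs.

        The posterior is averaged over the trials inside each cell (the
        cell-conditional expectation of accuracy) rather than evaluated at
        the cell midpoint, which would be biased where the posterior is
        steep across a cell.
        """
        table, ddm = symmetric_pair_table
        hm = build_heatmap(table, n_bins=10, min_count=200)
        e = (table["evidence_total"] * table["choice"]).to_numpy()
        t = table["acc_time"].to_numpy()
        p_trial = bayes_readout_mixture(e, t, ddm.drift_rates)
        psum, _, _ = np.histogram2d(
            e, t, bins=[hm.evidence_edges, hm.time_edges], weights=p_trial
        )
        n_viol = n_cells = 0
        for i in range(hm.p_correct.shape[0]):
            for j in range(hm.p_correct.shape[1]):
                if np.isnan(hm.p_correct[i, j]):
                    continue
                p = psum[i, j] / hm.counts[i, j]
                se = np.sqrt(max(p * (1 - p), 1e-4) / hm.counts[i, j])
                n_cells += 1
                if abs(hm.p_correct[i, j] - p) > 3 * se + 0.01:
                    n_viol += 1
        assert n_cells > 15
        assert n_viol / n_cells < 0.1

    def test_all_cells_undefined_raises(self, baseline_table):
        with pytest.raises(ValueError):
            build_heatmap(baseline_table, n_bins=5, min_count=10**9)


class TestPosteriorFit:
    def test_self_consistency_is_exact(self):
        # evidence kept small enough that the logistic never saturates past
        # float precision, so the logit-scale linear solve is exact
        rng = np.random.default_rng(0)
        u = rng.normal(0, 0.04, 500)
        t = rng.uniform(0.5, 3.0, 500)
        truth = LDCParams(alpha=22.0, beta=-0.7)
        conf = ldc_confidence(u, t, np.ones(500, dtype=int), truth)
        a, b = fit_ldc_to_posterior(u, t, conf)
        assert a == pytest.approx(22.0, abs=1e-8)
        assert b == pytest.approx(-0.7, abs=1e-8)

    def test_recovers_probit_equivalence_from_bayes_targets(self):
        # over the moderate standardized-evidence range where the logistic
        # tracks the probit, the fit lands at alpha = lam/sigma = 17, beta = 0
        rng = np.random.default_rng(1)
        u = rng.normal(0, 0.05, 4000)
        t = rng.uniform(0.5, 2.5, 4000)
        targets = bayes_p_correct(u, t, sigma=0.1)
        a, b = fit_ldc_to_posterior(u, t, targets)
        assert a == pytest.approx(17.0, rel=0.05)
        assert b == pytest.approx(0.0, abs=0.05)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_ldc_to_posterior([0.1, 0.1], [1.0, 1.0], [0.7, 0.7])

    def test_estimator_interface(self):
        from sklearn.base import clone

        rng = np.random.default_rng(2)
        X = np.column_stack([rng.normal(0, 0.05, 300), rng.uniform(0.5, 2, 300)])
        y = bayes_p_correct(X[:, 0], X[:, 1])
        est = LDCPosteriorRegressor()
        clone(est).fit(X, y)
        est.fit(X, y)
        assert est.alpha_ == pytest.approx(17.0, rel=0.05)
        pred = est.predict(X)
        assert spearmanr(pred, y).statistic > 0.999
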