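"""Trait estimators against independent grid / enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from rcirt import (
    GaussianPrior,
    GRMItemBank,
    QuadratureGrid,
    batch_estimate,
    eap_sumscore_table,
    estimate_eap,
    estimate_eap_sumscore,
    estimate_map,
    estimate_ml,
    estimate_wml,
    log_likelihood,
    simulate_responses,
)
from rcirt.estimators import sumscore_likelihood
from rcirt.grm import test_information as total_information

GRID_12001 = np.linspace(-6.0, 6.0, 12001)
PATTERNS = [[1, 2, 0, 3, 2], [0, 0, 1, 0, 0], [4, 3, 4, 4, 3], [2, 2, 2, 2, 2]]


def _grid_argmax(objective):
    vals = objective(GRID_12001)
    return GRID_12001[int(np.argmax(vals))]


class TestML:
    def test_symmetric_middle_pattern_scores_zero(self, symmetric_bank):
        est = estimate_ml(symmetric_bank, [2] * 5)
        assert est.theta_hat == pytest.approx(0.0, abs=1e-6)
        assert est.converged

    def test_extreme_patterns_diverge(self, symmetric_bank):
        hi = estimate_ml(symmetric_bank, [4] * 5)
        lo = estimate_ml(symmetric_bank, [0] * 5)
        assert not hi.converged and hi.theta_hat == 6.0
        assert not lo.converged and lo.theta_hat == -6.0

    @pytest.mark.parametrize("pattern", PATTERNS[:2])
    def test_matches_grid_search(self, toy_bank5, pattern):
        est = estimate_ml(toy_bank5, pattern)
        oracle = _grid_argmax(lambda t: log_likelihood(toy_bank5, pattern, t))
        assert est.theta_hat == pytest.approx(oracle, abs=1e-3)
        assert est.se == pytest.approx(
            total_information(toy_bank5, est.theta_hat) ** -0.5
        )


class TestWML:
    def test_symmetric_middle_pattern_scores_zero(self, symmetric_bank):
        assert estimate_wml(symmetric_bank, [2] * 5).theta_hat == pytest.approx(
            0.0, abs=1e-6
        )

    def test_extreme_pattern_stays_finite(self, symmetric_bank):
        est = estimate_wml(symmetric_bank, [4] * 5)
        assert est.converged
        assert -6.0 < est.theta_hat < 6.0

    @pytest.mark.parametrize("pattern", PATTERNS)
    def test_matches_grid_search(self, toy_bank5, pattern):
        def objective(t):
            return log_likelihood(toy_bank5, pattern, t) + 0.5 * np.log(
                total_information(toy_bank5, t)
            )

        est = estimate_wml(toy_bank5, pattern)
        assert est.theta_hat == pytest.approx(_grid_argmax(objective), abs=1e-3)

    def test_finite_for_all_patterns_of_small_bank(self, toy_bank3):
        for pattern in itertools.product(range(5), repeat=3):
            est = estimate_wml(toy_bank3, pattern)
            assert np.isfinite(est.theta_hat) and est.converged
            assert -6.0 < est.theta_hat < 6.0


class TestEAP:
    def test_no_data_returns_prior(self):
        prior = GaussianPrior(-0.4, 1.3)
        est = estimate_eap(GRMItemBank([]), [], prior)
        assert est.theta_hat == pytest.approx(prior.mean, abs=1e-8)
        assert est.se == pytest.approx(prior.sd, abs=1e-3)

    def test_tight_prior_dominates(self, toy_bank5):
        est = estimate_eap(toy_bank5, PATTERNS[0], GaussianPrior(0.7, 1e-8))
        assert est.theta_hat == pytest.approx(0.7, abs=1e-3)

    @pytest.mark.parametrize("pattern", PATTERNS)
    def test_matches_dense_grid_oracle(self, toy_bank5, pattern):
        prior = GaussianPrior(-0.5, 1.0)
        est = estimate_eap(toy_bank5, pattern, prior)
        # independent dense-grid integration of the posterior moments
        nodes = np.linspace(prior.mean - 6, prior.mean + 6, 10001)
        w = np.exp(log_likelihood(toy_bank5, pattern, nodes)
                   - 0.5 * (nodes - prior.mean) ** 2)
        w /= w.sum()
        mean = w @ nodes
        sd = math.sqrt(w @ (nodes - mean) ** 2)
        assert est.theta_hat == pytest.approx(mean, abs=1e-4)
        assert est.se == pytest.approx(sd, abs=1e-4)

    def test_single_node_grid_rejected(self, toy_bank5):
        with pytest.raises(ValueError):
            QuadratureGrid(np.array([0.0]), np.array([1.0]))

    def test_narrow_grid_rejected(self, toy_bank5):
        grid = QuadratureGrid(np.linspace(-2, 2, 41), np.ones(41))
        with pytest.raises(ValueError, match="6 prior SDs"):
            estimate_eap(toy_bank5, PATTERNS[0], GaussianPrior(0, 1), grid)

    def test_posterior_sd_never_exceeds_prior_sd(self, toy_bank3):
        prior = GaussianPrior(0.0, 1.0)
        for pattern in itertools.product(range(5), repeat=3):
            assert estimate_eap(toy_bank3, pattern, prior).se <= prior.sd + 1e-12

    def test_prior_variance_limits(self, toy_bank5):
        # flat-prior limit: the mean of the normalized likelihood itself,
        # computed by an independent dense integration
        pattern = PATTERNS[0]
        nodes = np.linspace(-6, 6, 24001)
        lik = np.exp(log_likelihood(toy_bank5, pattern, nodes))
        lik /= lik.sum()
        flat_mean = float(lik @ nodes)
        ml_mode = estimate_ml(toy_bank5, pattern).theta_hat
        assert flat_mean == pytest.approx(ml_mode, abs=0.1)  # same neighborhood
        gaps = []
        for var in (0.25, 1.0, 4.0, 25.0, 100.0):
            prior = GaussianPrior(0.8, var)
            # node count scaled with the prior SD so spacing stays fine
            grid = prior.default_grid(n_nodes=1 + 1200 * max(1, int(prior.sd)))
            eap = estimate_eap(toy_bank5, pattern, prior, grid)
            gaps.append(abs(eap.theta_hat - flat_mean))
        assert all(x > y for x, y in zip(gaps, gaps[1:]))
        assert gaps[-1] < 5e-3
        tight = estimate_eap(toy_bank5, pattern, GaussianPrior(0.8, 1e-6))
        assert tight.theta_hat == pytest.approx(0.8, abs=1e-3)


class TestMAP:
    def test_no_data_returns_prior_mean(self):
        est = estimate_map(GRMItemBank([]), [], GaussianPrior(0.3, 2.0))
        assert est.theta_hat == pytest.approx(0.3, abs=1e-6)

    def test_flat_prior_agrees_with_ml(self, toy_bank5):
        flat = estimate_map(toy_bank5, PATTERNS[0], GaussianPrior(0.0, 1e6))
        ml = estimate_ml(toy_bank5, PATTERNS[0])
        assert flat.theta_hat == pytest.approx(ml.theta_hat, abs=1e-2)

    @pytest.mark.parametrize("pattern", PATTERNS)
    def test_matches_grid_search(self, toy_bank5, pattern):
        prior = GaussianPrior(-0.5, 1.0)

        def objective(t):
            return log_likelihood(toy_bank5, pattern, t) + prior.logpdf(t)

        est = estimate_map(toy_bank5, pattern, prior)
        assert est.theta_hat == pytest.approx(_grid_argmax(objective), abs=1e-3)
        assert est.se > 0


class TestSumScoreEAP:
    def test_single_item_equals_per_category_eap(self):
        bank = GRMItemBank([(1.9, (-1.1, -0.2, 0.6, 1.3))])
        prior = GaussianPrior(0.0, 1.0)
        table = eap_sumscore_table(bank, prior)
        for k in range(5):
            direct = estimate_eap(bank, [k], prior)
            assert table.theta_hat[k] == pytest.approx(direct.theta_hat, abs=1e-10)
            assert table.se[k] == pytest.approx(direct.se, abs=1e-10)

    def test_score_probabilities_sum_to_one(self, toy_bank5):
        table = eap_sumscore_table(toy_bank5, GaussianPrior(-0.2, 1.0))
        assert table.prob.sum() == pytest.approx(1.0, abs=1e-10)
        assert len(table) == toy_bank5.max_score + 1

    def test_recursion_matches_pattern_enumeration(self, toy_bank3):
        nodes = np.linspace(-3, 3, 11)
        rec = sumscore_likelihood(toy_bank3, nodes)
        brute = np.zeros_like(rec)
        for pattern in itertools.product(range(5), repeat=3):
            brute[sum(pattern)] += np.exp(log_likelihood(toy_bank3, pattern, nodes))
        np.testing.assert_allclose(rec, brute, atol=1e-10)

    def test_theta_nondecreasing_in_score(self, toy_bank3, symmetric_bank):
        for bank in (toy_bank3, symmetric_bank):
            table = eap_sumscore_table(bank, GaussianPrior(0.0, 1.0))
            assert np.all(np.diff(table.theta_hat) >= 0)

    def test_pattern_scoring_uses_its_sum_score(self, toy_bank3):
        prior = GaussianPrior(0.0, 1.0)
        table = eap_sumscore_table(toy_bank3, prior)
        est = estimate_eap_sumscore(toy_bank3, [2, 1, 3], prior)
        assert est.theta_hat == pytest.approx(table.theta_hat[6])
        assert est.method == "EAP_sumscore"


class TestBatchScoring:
    def test_agrees_with_scalar_estimators(self, toy_bank5, rng):
        resp = simulate_responses(toy_bank5, rng.normal(0, 1, 30), rng)
        prior = GaussianPrior(-0.5, 1.0)
        for method, scalar in (
            ("wml", lambda p: estimate_wml(toy_bank5, p)),
            ("eap", lambda p: estimate_eap(toy_bank5, p, prior)),
            ("map", lambda p: estimate_map(toy_bank5, p, prior)),
        ):
            theta, se, conv = batch_estimate(toy_bank5, resp.values, method, prior)
            for i, row in enumerate(resp.values):
                ref = scalar(row)
                assert theta[i] == pytest.approx(ref.theta_hat, abs=2e-3)
                assert se[i] == pytest.approx(ref.se, rel=2e-2)

    def test_ml_flags_extreme_rows(self, symmetric_bank):
        rows = np.array([[0] * 5, [2] * 5, [4] * 5])
        theta, _, conv = batch_estimate(symmetric_bank, rows, "ml")
        assert list(conv) == [False, True, False]
        assert theta[0] == -6.0 and theta[2] == 6.0
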