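import numpy as np
import pytest
from scipy.special import logsumexp

from oracles import logml_conjugate, logml_grid_2d
from translatome.bayes import (
    ModelComparison,
    PriorSpec,
    classify_transcript,
    collapse_to_gene,
    compare_models,
    log_marginal_likelihood,
    posterior_probability,
    rank_metric,
    select_transcripts,
    _logml_and_beta_by_sigma,
)
from translatome.simulate import SimConfig, simulate_expression


def _mc(tid, log_bf, delta, p=0.1, gene=None):
    return ModelComparison(tid, 0.0, log_bf, delta, p, gene_id=gene)


class TestMarginalLikelihood:
    def test_matches_conjugate_closed_form_at_fixed_sigma(self, rng):
        """With sigma fixed, the beta integral has a closed-form Gaussian
        answer; the internal per-sigma evidence must reproduce it."""
        for _ in range(25):
            n = int(rng.integers(2, 9))
            k = int(rng.integers(1, min(n, 4) + 1))
            X = rng.normal(size=(n, k))
            y = rng.normal(0, 2, size=n)
            s = rng.uniform(0.01, 0.5, size=n)
            tau = rng.uniform(0.5, 5.0, size=k)
            sigma = float(rng.uniform(0.05, 2.0))
            got, _ = _logml_and_beta_by_sigma(y, s, X, tau, np.array([sigma]))
            assert got[0] == pytest.approx(logml_conjugate(y, s, X, tau, sigma), abs=1e-8)

    def test_matches_dense_grid_integration(self, rng):
        """Quadrature evidence agrees with brute-force 2-D integration
        over (coefficient, sigma) on one-column designs."""
        prior = PriorSpec(tau_coef=1.0)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            x = rng.normal(size=n)
            y = rng.normal(0, 1.5, size=n)
            s = rng.uniform(0.05, 0.5, size=n)
            # intercept-free single column: make it the "coefficient" prior
            X = x.reshape(-1, 1)
            got = log_marginal_likelihood(y, s, X, PriorSpec(tau_intercept=1.0))
            want = logml_grid_2d(y, s, x, tau=1.0)
            assert got == pytest.approx(want, abs=1e-3)

    def test_occam_penalty_on_constant_data(self, dod_pair):
        """Exactly constant observations with tiny SDs favour the model
        without the superfluous interaction column."""
        y = np.full(16, 5.0)
        s = np.full(16, 0.01)
        prior = PriorSpec()
        ml0 = log_marginal_likelihood(y, s, dod_pair.X0, prior)
        ml1 = log_marginal_likelihood(y, s, dod_pair.X1, prior)
        assert ml0 > ml1

    def test_rejects_bad_inputs(self, dod_pair):
        y = np.zeros(16)
        with pytest.raises(ValueError, match="non-negative"):
            log_marginal_likelihood(y, np.full(16, -0.1), dod_pair.X0)
        with pytest.raises(ValueError, match="singular"):
            X = np.column_stack([np.ones(16), np.ones(16)])
            log_marginal_likelihood(y, np.full(16, 0.1), X)
        with pytest.raises(ValueError, match="number of samples"):
            log_marginal_likelihood(y[:8], np.full(8, 0.1), dod_pair.X0)

    def test_shift_invariance_with_vague_intercept(self, rng, dod_pair):
        """With the intercept prior widened toward flat, adding a
        constant to all observations leaves the Bayes factor nearly
        unchanged."""
        prior = PriorSpec(tau_intercept=1e3)
        y = rng.normal(5, 0.5, 16)
        s = rng.uniform(0.05, 0.2, 16)
        bf = lambda yy: (
            log_marginal_likelihood(yy, s, dod_pair.X1, prior)
            - log_marginal_likelihood(yy, s, dod_pair.X0, prior)
        )
        b0, b1 = bf(y), bf(y + 100.0)
        assert b1 == pytest.approx(b0, rel=0.01, abs=1e-4)


class TestPosteriorProbability:
    def test_prior_recovered_at_unit_bayes_factor(self):
        assert posterior_probability(0.0, 0.1) == pytest.approx(0.1, abs=1e-12)

    def test_even_odds_at_bayes_factor_nine(self):
        assert posterior_probability(np.log(9.0), 0.1) == pytest.approx(0.5, abs=1e-12)

    def test_limits(self):
        assert posterior_probability(1e4, 0.1) == pytest.approx(1.0)
        assert posterior_probability(-1e4, 0.1) == pytest.approx(0.0)

    def test_model_probabilities_sum_to_one(self, rng):
        for log_bf in rng.normal(0, 5, size=20):
            p1 = posterior_probability(log_bf, 0.1)
            p0 = posterior_probability(-log_bf, 0.9)
            assert p0 + p1 == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_bayes_factor(self):
        ps = [posterior_probability(lb, 0.1) for lb in np.linspace(-10, 10, 41)]
        assert all(a < b for a, b in zip(ps, ps[1:]))


class TestCompareAndClassify:
    def test_planted_interaction_detected(self, rng, dod_pair):
        y = rng.normal(5, 0.1, 16)
        y[dod_pair.X1[:, dod_pair.delta_column] == 1] -= 2.0
        s = np.full(16, 0.1)
        res = compare_models(y, s, dod_pair, transcript_id="tx1")
        assert res.posterior_prob > 0.99
        assert res.delta_hat == pytest.approx(-2.0, abs=0.3)
        assert classify_transcript(res) == "dependent"

    @pytest.mark.parametrize(
        "p1, delta, expected",
        [
            (0.25, -0.5, "dependent"),
            (0.19, -0.5, "unclassified"),
            (0.25, +0.5, "independent"),
            (0.25, 0.0, "unclassified"),  # documented tie rule
        ],
    )
    def test_threshold_and_sign_rule(self, p1, delta, expected):
        log_bf = np.log(p1 / (1 - p1)) - np.log(0.1 / 0.9)
        res = _mc("t", log_bf, delta)
        assert res.posterior_prob == pytest.approx(p1, abs=1e-9)
        assert classify_transcript(res, threshold=0.2) == expected

    @pytest.mark.parametrize(
        "p1, delta, expected",
        [(0.8, -1.0, +0.8), (0.8, +1.0, -0.8), (0.5, 0.0, 0.0)],
    )
    def test_rank_metric_orientation(self, p1, delta, expected):
        log_bf = (
            np.log(p1 / (1 - p1)) - np.log(0.1 / 0.9) if 0 < p1 < 1 else 0.0
        )
        res = _mc("t", log_bf if p1 != 0.5 else np.log(9.0), delta)
        assert rank_metric(res) == pytest.approx(expected, abs=1e-9)


class TestCollapseToGene:
    def test_highest_posterior_wins(self):
        results = [
            _mc("txA", np.log(0.3 / 0.7) - np.log(1 / 9), -1, gene="g1"),
            _mc("txB", np.log(0.5 / 0.5) - np.log(1 / 9), -1, gene="g1"),
        ]
        kept = collapse_to_gene(results)
        assert [r.transcript_id for r in kept] == ["txB"]

    def test_tie_broken_by_transcript_id(self):
        results = [_mc("txB", 0.0, -1, gene="g1"), _mc("txA", 0.0, -1, gene="g1")]
        assert collapse_to_gene(results)[0].transcript_id == "txA"

    def test_single_transcript_gene_and_unmapped(self, caplog):
        results = [_mc("txA", 0.0, -1, gene="g1"), _mc("txZ", 0.0, -1)]
        with caplog.at_level("WARNING"):
            kept = collapse_to_gene(results)
        assert {r.transcript_id for r in kept} == {"txA", "txZ"}
        assert "lack a gene mapping" in caplog.text


class TestSelectTranscripts:
    def test_null_calibration(self):
        """Without planted interactions and with matched priors, at most
        ~the threshold fraction of transcripts clear the liberal 0.2
        posterior-probability cut."""
        cfg = SimConfig(n_transcripts=300, frac_interaction=0.0, seed=11)
        expr, design, _ = simulate_expression(cfg)
        res = select_transcripts(expr, design)
        assert (res["posterior_prob"] >= 0.2).mean() <= 0.2
        assert (res["class"] == "unclassified").mean() >= 0.8

    def test_wrong_sample_count_rejected(self, dod_design):
        cfg = SimConfig(n_transcripts=2, seed=0)
        expr, design, _ = simulate_expression(cfg)
        with pytest.raises(ValueError, match="expected 16 samples"):
            select_transcripts(expr.iloc[:-1], design)
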