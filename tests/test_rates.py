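"""Unit tests for rate estimation and exact Poisson testing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mnvkit.rates import (
    ClinvarExpectationModel,
    WattersonModel,
    clinvar_expected_mnvs,
    denovo_enrichment,
    denovo_rate,
    exact_poisson_test,
    mutator_probability,
    poisson_count_ci,
    polzeta_context_excess,
    snv_missense_rate_check,
    watterson_scaled_rate,
)


class TestWattersonScaling:
    def test_identity_when_counts_equal(self):
        assert watterson_scaled_rate(100, 100, 1.1e-8) == 1.1e-8

    def test_reproduces_mnv_rate_from_site_ratio(self):
        # the MNV/SNV segregating-site ratio of 1.618% scales the SNV
        # rate 1.1e-8 to the MNV rate 1.78e-10
        assert watterson_scaled_rate(1618, 100_000, 1.1e-8) == \
            pytest.approx(1.78e-10, rel=0.01)

    def test_linear_in_focal_count_and_reference_rate(self):
        base = watterson_scaled_rate(30, 1000, 1.1e-8)
        assert watterson_scaled_rate(60, 1000, 1.1e-8) == \
            pytest.approx(2 * base)
        assert watterson_scaled_rate(30, 1000, 2.2e-8) == \
            pytest.approx(2 * base)

    def test_zero_reference_errors(self):
        with pytest.raises(ZeroDivisionError):
            watterson_scaled_rate(10, 0, 1e-8)

    def test_model_bundles_harmonic_number(self):
        m = WattersonModel(k_snv=100, k_mnv=2, n_chromosomes=5)
        assert m.a_n == pytest.approx(1 + 1 / 2 + 1 / 3 + 1 / 4)
        assert m.theta_hat_snv == pytest.approx(100 / m.a_n)
        assert m.mu_mnv == pytest.approx(0.02 * m.mu_snv)

    def test_missense_rate_scaling(self):
        assert snv_missense_rate_check(70, 100, 1e-8) == \
            pytest.approx(0.7e-8)


class TestDeNovoRate:
    def test_zero_events(self):
        est = denovo_rate(0, 100, 1e6)
        assert est.rate == 0.0 and est.ci_low == 0.0 and est.ci_high > 0

    def test_rate_formula_and_ci_transformation(self):
        est = denovo_rate(10, 500, 3e7)
        denom = 2 * 500 * 3e7
        assert est.rate == pytest.approx(10 / denom)
        lo, hi = poisson_count_ci(10)
        assert est.ci_low == pytest.approx(lo / denom)
        assert est.ci_high == pytest.approx(hi / denom)
        assert est.ci_low < est.rate < est.ci_high

    @pytest.mark.parametrize("n", [0, 1, 3, 7, 15, 30])
    def test_count_ci_matches_tail_equation_root_finding(self, n):
        """The exact CI bounds solve P(X >= n) = 0.025 (lower) and
        P(X <= n) = 0.025 (upper) in lambda; recover them by bisection."""
        from scipy.optimize import brentq

        lo, hi = poisson_count_ci(n)
        if n > 0:
            root = brentq(lambda lam: stats.poisson.sf(n - 1, lam) - 0.025,
                          1e-12, 200)
            assert lo == pytest.approx(root, rel=1e-6)
        oracle_hi = brentq(lambda lam: stats.poisson.cdf(n, lam) - 0.025,
                           1e-12, 200)
        assert hi == pytest.approx(oracle_hi, rel=1e-6)


def _poisson_p_oracle(observed, expected, method):
    """Direct summation over k in [0, expected + 20 sqrt(expected)]."""
    hi = int(expected + 20 * np.sqrt(expected)) + observed + 20
    ks = np.arange(hi + 1)
    pmf = stats.poisson.pmf(ks, expected)
    lower = pmf[ks <= observed].sum()
    upper = pmf[ks >= observed].sum()
    if method == "doubling":
        return min(1.0, 2 * min(lower, upper))
    if method == "one_sided":
        return upper if observed >= expected else lower
    d = stats.poisson.pmf(observed, expected) * (1 + 1e-7)
    return min(1.0, pmf[pmf <= d].sum())


class TestExactPoisson:
    def test_observed_near_expected_is_nonsignificant(self):
        for method in ("minlik", "doubling", "one_sided"):
            assert exact_poisson_test(50, 50.2, method) >= 0.5

    def test_reproduces_clinvar_depletion_p(self):
        # 24 observed vs 51.94 expected reported pathogenic missense MNVs
        assert exact_poisson_test(24, 51.94, "minlik") == \
            pytest.approx(2.8e-5, rel=0.05)

    def test_reproduces_dd_enrichment_p(self):
        # 10 observed de novo MNVs at 3.7-fold enrichment
        assert exact_poisson_test(10, 10 / 3.7, "doubling") == \
            pytest.approx(1.03e-3, rel=0.05)

    @pytest.mark.parametrize("method", ["minlik", "doubling", "one_sided"])
    def test_matches_direct_summation_oracle(self, method, rng):
        for _ in range(25):
            expected = float(rng.uniform(0.5, 80))
            observed = int(rng.integers(0, 120))
            assert exact_poisson_test(observed, expected, method) == \
                pytest.approx(_poisson_p_oracle(observed, expected, method),
                              rel=1e-6, abs=1e-300)

    @given(st.integers(0, 200), st.floats(0.1, 100))
    def test_minlik_bounded_by_tails(self, observed, expected):
        """minlik is at least the one-sided tail and at most twice it,
        up to the probability mass of density ties on the far side (the
        same convention R's poisson.test follows, e.g. at (0, 1))."""
        one = exact_poisson_test(observed, expected, "one_sided")
        minlik = exact_poisson_test(observed, expected, "minlik")
        assert one - 1e-12 <= minlik
        d_obs = stats.poisson.pmf(observed, expected) * (1 + 1e-7)
        hi = int(expected + 40 * np.sqrt(expected)) + observed + 40
        pmf = stats.poisson.pmf(np.arange(hi + 1), expected)
        tie = pmf[np.isclose(pmf, d_obs, rtol=2e-7)].sum()
        assert minlik <= min(1.0, 2 * one + tie) + 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_poisson_test(5, 0.0)
        with pytest.raises(ValueError):
            exact_poisson_test(-1, 2.0)
        with pytest.raises(ValueError):
            exact_poisson_test(5, 2.0, "banana")


class TestEnrichment:
    def test_fold_one_when_observed_matches_expectation(self):
        res = denovo_enrichment(10, mu=1e-8, gene_bp=1e6, n_trios=500)
        assert res.expected == pytest.approx(10.0)
        assert res.fold == pytest.approx(1.0)
        assert res.p_value > 0.5

    def test_context_factor_scales_fold_exactly(self):
        a = denovo_enrichment(10, 1e-8, 1e6, 500, context_factor=1.0)
        b = denovo_enrichment(10, 1e-8, 1e6, 500, context_factor=1.02)
        assert a.fold / b.fold == pytest.approx(1.02)
        assert b.context_corrected and not a.context_corrected

    def test_bonferroni_family_threshold(self):
        res = denovo_enrichment(30, 1e-8, 1e6, 50)  # 3-fold excess
        assert res.significant == (res.p_value < 0.05 / 12)

    def test_simulation_recovery_of_injected_fold(self, rng):
        """De novos injected at 4x the expected rate in a gene set give a
        mean fold estimate near 4 over replicates."""
        mu, gene_bp, n_trios = 1.78e-10, 2e6, 3000
        lam = mu * 2 * n_trios * gene_bp * 4.0
        folds = [denovo_enrichment(int(rng.poisson(lam)), mu, gene_bp,
                                   n_trios).fold for _ in range(50)]
        se = np.std(folds, ddof=1) / np.sqrt(len(folds))
        assert abs(np.mean(folds) - 4.0) < 3 * se + 1e-9


class TestPolzetaContext:
    def test_identical_sets_fold_one(self):
        seqs = ["ACGTGCGATT", "TTGCAGAGGA"]
        out = polzeta_context_excess(seqs, list(seqs))
        assert out["fold"] == pytest.approx(1.0)

    def test_extreme_composition(self):
        out = polzeta_context_excess(["GC" * 200], ["AT" * 200])
        assert out["fold"] > 50
        assert out["p_value"] < 1e-10

    def test_reverse_complement_invariant(self):
        from mnvkit.spectra import revcomp

        a = ["ACGTGCGATTGGA", "TTGCAGAGGACCA"]
        b = ["TTTTACAGATTTT", "CCCCAGGGGTGGC"]
        fwd = polzeta_context_excess(a, b)
        rev = polzeta_context_excess([revcomp(s) for s in a],
                                     [revcomp(s) for s in b])
        assert fwd["fold"] == pytest.approx(rev["fold"])

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            polzeta_context_excess([], ["ACGT"])


class TestClinvarExpectation:
    def _model(self, **kw):
        defaults = dict(n_reported_snv_missense=100, coding_bp_sum=1e6,
                        mu_mnv=1e-9, mu_snv_missense=1e-8)
        defaults.update(kw)
        return ClinvarExpectationModel(**defaults)

    def test_toy_rate_ratio_arithmetic(self):
        # ratio mu_mnv*2/3*0.97 / mu_snv = 0.1 exactly when
        # mu_mnv/mu_snv = 0.1/(2/3*0.97)
        m = self._model(mu_mnv=1e-8 * 0.1 / (2 / 3 * 0.97))
        out = clinvar_expected_mnvs(m, observed=10)
        assert out["expected"] == pytest.approx(10.0)
        assert out["p_value"] > 0.5

    def test_depletion_significant_at_printed_level(self):
        # calibrated so the expectation is 51.94, as for the reported
        # pathogenic missense MNVs in DD-associated genes
        m = self._model(n_reported_snv_missense=100,
                        mu_mnv=51.94 / 100 / (2 / 3 * 0.97) * 1e-8)
        out = clinvar_expected_mnvs(m, observed=24)
        assert out["expected"] == pytest.approx(51.94, rel=1e-9)
        assert out["p_value"] == pytest.approx(2.8e-5, rel=0.05)

    def test_coding_bp_cancels_in_expectation(self):
        a = clinvar_expected_mnvs(self._model(coding_bp_sum=1e6), 10)
        b = clinvar_expected_mnvs(self._model(coding_bp_sum=5e7), 10)
        assert a["expected"] == pytest.approx(b["expected"])

    def test_zero_snv_rate_errors(self):
        with pytest.raises(ValueError):
            clinvar_expected_mnvs(self._model(mu_snv_missense=0.0), 5)


class TestMutatorProbability:
    def test_zero_rate_zero_probability(self):
        assert mutator_probability(1000, 0.0, 1) == 0.0

    def test_zero_threshold_certain(self):
        assert mutator_probability(1000, 0.5, 0) == 1.0

    def test_matches_monte_carlo_oracle(self, rng):
        n, lam, m = 1000, 0.02, 3
        p = mutator_probability(n, lam, m)
        draws = rng.poisson(lam, size=(1_000_000 // n * n,)).reshape(-1, n)
        multi = (draws >= 2).sum(axis=1)
        p_hat = float(np.mean(multi >= m))
        se = np.sqrt(max(p_hat * (1 - p_hat), 1e-7) / len(multi))
        assert abs(p - p_hat) < 4 * se + 1e-4
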