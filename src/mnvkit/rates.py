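"""Mutation-rate estimation and Poisson enrichment/depletion testing.

Two independent routes to the MNV mutation rate:

* **Segregating-site scaling.**  Rearranging Watterson's estimator
  ``theta = K / a_n = 4 N_e mu`` shows that for two variant classes
  ascertained in the same cohort, the unknown ``4 N_e a_n`` factor
  cancels, leaving ``mu_focal = (K_focal / K_ref) * mu_ref``.  With the
  reference SNV rate of 1.1e-8 per bp per generation and variant counts
  restricted to unconstrained genes (pLI < 0.1), this yields the MNV rate.

* **De novo counting.**  ``rate = n_events / (2 * n_trios * callable_bp)``
  with an exact Poisson confidence interval on the event count.

Enrichment of de novo events in a gene set is tested with an exact Poisson
test against ``lambda = mu * 2 * n_trios * gene_bp`` (optionally corrected
for the sequence-context excess of polymerase zeta dinucleotides); the
test family uses a Bonferroni threshold of 0.05/12.  Both two-sided exact
Poisson p-value conventions are implemented: *minlik* (sum of all outcome
probabilities no larger than the observed one) and tail *doubling*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import two_proportion_test

#: two-sided family size for the de novo enrichment analyses
BONFERRONI_FAMILY = 12
DEFAULT_MU_SNV = 1.1e-8
MU_SNV_SENSITIVITY = (1.0e-8, 1.1e-8, 1.2e-8)

#: polymerase zeta reference dinucleotide contexts (GC, GA + revcomp TC;
#: GC is its own reverse complement)
POLZETA_CONTEXTS = ("GC", "GA", "TC")


@dataclass
class WattersonModel:
    """Book-keeping for the segregating-site rate rearrangement."""

    k_snv: int
    k_mnv: int
    n_chromosomes: int
    mu_snv: float = DEFAULT_MU_SNV

    @property
    def a_n(self) -> float:
        return float(np.sum(1.0 / np.arange(1, self.n_chromosomes)))

    @property
    def theta_hat_snv(self) -> float:
        return self.k_snv / self.a_n

    @property
    def mu_mnv(self) -> float:
        return watterson_scaled_rate(self.k_mnv, self.k_snv, self.mu_snv)


@dataclass
class DeNovoRateEstimate:
    n_events: int
    n_trios: int
    callable_bp: float
    rate: float
    ci_low: float
    ci_high: float


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    fold: float
    p_value: float
    method: str
    context_corrected: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05 / BONFERRONI_FAMILY


@dataclass
class ClinvarExpectationModel:
    """Expected clinically reported missense MNVs from SNV report counts.

    ``p_in_codon = 2/3`` is the probability that an adjacent-base MNV falls
    within one codon (frame enumeration) and ``p_missense_given_in_codon =
    0.97`` is the observed probability that a within-codon MNV is missense
    (an empirical constant, deliberately not derived from codon-table
    enumeration).
    """

    n_reported_snv_missense: int
    coding_bp_sum: float
    mu_mnv: float
    mu_snv_missense: float
    p_in_codon: float = 2.0 / 3.0
    p_missense_given_in_codon: float = 0.97

    @property
    def mu_mnv_missense(self) -> float:
        return (self.mu_mnv * self.p_in_codon
                * self.p_missense_given_in_codon * self.coding_bp_sum)

    @property
    def mu_snv_missense_total(self) -> float:
        return self.mu_snv_missense * self.coding_bp_sum

    @property
    def expected_mnvs(self) -> float:
        return (self.n_reported_snv_missense
                * self.mu_mnv_missense / self.mu_snv_missense_total)


# ---------------------------------------------------------------------------
# rate estimators

def watterson_scaled_rate(k_focal: int, k_ref: int, mu_ref: float) -> float:
    """Scale a reference rate by the segregating-site ratio."""
    if k_ref <= 0:
        raise ZeroDivisionError("reference segregating-site count is zero")
    if k_focal < 0:
        raise ValueError("negative segregating-site count")
    return (k_focal / k_ref) * mu_ref


def snv_missense_rate_check(k_missense: int, k_all_snv: int,
                            mu_snv: float = DEFAULT_MU_SNV) -> float:
    """Missense SNV rate via the same segregating-site scaling."""
    return watterson_scaled_rate(k_missense, k_all_snv, mu_snv)


def poisson_count_ci(n_events: int, level: float = 0.95
                     ) -> tuple[float, float]:
    """Exact (Garwood) Poisson confidence interval for a count."""
    alpha = 1 - level
    lo = 0.0 if n_events == 0 else \
        float(stats.chi2.ppf(alpha / 2, 2 * n_events) / 2)
    hi = float(stats.chi2.ppf(1 - alpha / 2, 2 * n_events + 2) / 2)
    return lo, hi


def denovo_rate(n_events: int, n_trios: int,
                callable_bp: float) -> DeNovoRateEstimate:
    """Per-bp per-generation rate from de novo counts with exact CI."""
    if n_trios <= 0 or callable_bp <= 0:
        raise ValueError("n_trios and callable_bp must be positive")
    if n_events < 0:
        raise ValueError("negative event count")
    denom = 2.0 * n_trios * callable_bp
    lo, hi = poisson_count_ci(n_events)
    return DeNovoRateEstimate(n_events, n_trios, callable_bp,
                              n_events / denom, lo / denom, hi / denom)


# ---------------------------------------------------------------------------
# exact Poisson tests

def exact_poisson_test(observed: int, expected: float,
                       method: str = "minlik") -> float:
    """Exact Poisson p-value for an observed count against a mean.

    ``minlik``: the sum of probabilities of all outcomes whose density is
    no larger than the observed one (within relative tolerance 1 + 1e-7),
    matching R's ``poisson.test``.  ``doubling``: twice the smaller tail,
    capped at 1.  ``one_sided``: the tail in the direction of departure.
    """
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if method == "one_sided":
        if observed >= expected:
            return float(min(1.0, stats.poisson.sf(observed - 1, expected)))
        return float(stats.poisson.cdf(observed, expected))
    lower = float(stats.poisson.cdf(observed, expected))
    upper = float(stats.poisson.sf(observed - 1, expected))
    if method == "doubling":
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method != "minlik":
        raise ValueError("method must be minlik, doubling or one_sided")
    d_obs = stats.poisson.pmf(observed, expected) * (1 + 1e-7)
    hi = int(expected + 40.0 * np.sqrt(expected) + 40)
    hi = max(hi, observed + 1)
    ks = np.arange(0, hi + 1)
    pmf = stats.poisson.pmf(ks, expected)
    return float(min(1.0, pmf[pmf <= d_obs].sum()))


def denovo_enrichment(observed: int, mu: float, gene_bp: float,
                      n_trios: int, context_factor: float = 1.0,
                      method: str = "doubling") -> EnrichmentResult:
    """Poisson enrichment of de novo events in a gene set.

    The expectation is ``mu * 2 * n_trios * gene_bp * context_factor``;
    ``context_factor`` defaults to 1 and is set to the polymerase zeta
    dinucleotide-context excess for the context-corrected test.
    """
    expected = mu * 2.0 * n_trios * gene_bp * context_factor
    if expected <= 0:
        raise ValueError("expected count is zero")
    return EnrichmentResult(
        observed=observed, expected=expected, fold=observed / expected,
        p_value=exact_poisson_test(observed, expected, method=method),
        method=method, context_corrected=(context_factor != 1.0))


def polzeta_context_excess(gene_seqs_a: list[str],
                           gene_seqs_b: list[str]) -> dict:
    """Excess of polymerase zeta dinucleotide contexts between gene sets.

    Counts overlapping dinucleotide positions matching GC/GA/TC in each
    set of CDS sequences; returns the proportion in each set, the fold
    ratio a/b, and a two-proportion p-value.  Strand symmetric: the
    context set is closed under reverse complement.
    """
    def count(seqs: list[str]) -> tuple[int, int]:
        hits = total = 0
        for seq in seqs:
            seq = seq.upper()
            total += max(0, len(seq) - 1)
            for i in range(len(seq) - 1):
                if seq[i:i + 2] in POLZETA_CONTEXTS:
                    hits += 1
        return hits, total

    ha, na = count(gene_seqs_a)
    hb, nb = count(gene_seqs_b)
    if na == 0 or nb == 0:
        raise ValueError("empty sequence set")
    prop_a, prop_b = ha / na, hb / nb
    if prop_b == 0:
        fold = float("inf") if prop_a > 0 else float("nan")
    else:
        fold = prop_a / prop_b
    return dict(prop_a=prop_a, prop_b=prop_b, fold=fold,
                p_value=two_proportion_test(ha, na, hb, nb))


def clinvar_expected_mnvs(model: ClinvarExpectationModel,
                          observed: int) -> dict:
    """Expected reported missense MNVs and the depletion p-value."""
    if model.mu_snv_missense <= 0:
        raise ValueError("SNV missense rate must be > 0")
    expected = model.expected_mnvs
    return dict(expected=expected, observed=observed,
                p_value=exact_poisson_test(observed, expected,
                                           method="minlik"))


def mutator_probability(n_individuals: int, lambda_per_individual: float,
                        m_threshold: int) -> float:
    """P(at least m individuals carry more than one de novo MNV).

    Under independence each individual's de novo MNV count is Poisson with
    mean ``lambda_per_individual``; the probability of carrying more than
    one is ``1 - e^-lam - lam e^-lam``, and the number of such individuals
    is binomial.
    """
    if lambda_per_individual < 0 or m_threshold < 0:
        raise ValueError("lambda and m must be >= 0")
    if m_threshold == 0:
        return 1.0
    lam = lambda_per_individual
    p_multi = 1.0 - np.exp(-lam) - lam * np.exp(-lam)
    p_multi = max(0.0, float(p_multi))
    return float(stats.binom.sf(m_threshold - 1, n_individuals, p_multi))
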