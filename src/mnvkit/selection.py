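"""Purifying-selection metrics across variant classes.

Three complementary read-outs of selection strength, each computed per
variant class (e.g. missense SNV, one-step missense MNV, two-step missense
MNV, inter-codon MNV):

* depletion in highly constrained genes (pLI >= 0.9 by default),
* the singleton proportion (fraction with cohort allele count 1), a proxy
  for the shift toward rare alleles under stronger selection,
* the median deleteriousness score (e.g. CADD) with a percentile bootstrap.

All binomial proportions carry Wilson 95% confidence intervals; pLI and
deleteriousness scores are consumed as input annotations, never computed.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .spectra import two_proportion_test

logger = logging.getLogger(__name__)


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def _pairwise_tests(counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    rows = []
    for a, b in itertools.combinations(sorted(counts), 2):
        ka, na = counts[a]
        kb, nb = counts[b]
        rows.append(dict(class_a=a, class_b=b,
                         p_value=two_proportion_test(ka, na, kb, nb)))
    return pd.DataFrame(rows, columns=["class_a", "class_b", "p_value"])


def pli_depletion(variants_by_class: dict[str, pd.DataFrame],
                  gene_map: pd.DataFrame,
                  pli_threshold: float = 0.9) -> dict:
    """Per-class proportion of variants in highly constrained genes.

    ``variants_by_class`` maps a class label to a table with a ``gene``
    column; ``gene_map`` has columns ``gene`` and ``pLI``.  Variants in
    genes without a pLI value are excluded from the denominator (logged).
    """
    pli = gene_map.set_index("gene")["pLI"]
    per_class = {}
    counts = {}
    for label, df in variants_by_class.items():
        if len(df) == 0:
            logger.warning("class %s is empty, skipped", label)
            continue
        mapped = df["gene"].map(pli)
        n_dropped = int(mapped.isna().sum())
        if n_dropped:
            logger.info("class %s: %d variants without pLI dropped",
                        label, n_dropped)
        mapped = mapped.dropna()
        n = len(mapped)
        k = int((mapped >= pli_threshold).sum())
        lo, hi = wilson_ci(k, n)
        per_class[label] = dict(n_total=n, n_in_high_pli=k,
                                proportion=k / n, ci_low=lo, ci_high=hi,
                                n_dropped=n_dropped)
        counts[label] = (k, n)
    return dict(per_class=per_class, pairwise=_pairwise_tests(counts))


def singleton_proportion(allele_counts_by_class: dict[str, np.ndarray]
                         ) -> dict:
    """Per-class fraction of variants observed exactly once (AC == 1)."""
    per_class = {}
    counts = {}
    for label, acs in allele_counts_by_class.items():
        acs = np.asarray(acs)
        n = len(acs)
        if n == 0:
            logger.warning("class %s is empty, skipped", label)
            continue
        k = int((acs == 1).sum())
        lo, hi = wilson_ci(k, n)
        per_class[label] = dict(n_total=n, n_singletons=k,
                                proportion=k / n, ci_low=lo, ci_high=hi)
        counts[label] = (k, n)
    return dict(per_class=per_class, pairwise=_pairwise_tests(counts))


def singleton_to_score_interpolation(snv_bins: pd.DataFrame,
                                     query_proportion: float) -> float:
    """Invert a score-bin vs singleton-proportion curve.

    ``snv_bins`` has columns ``score`` (bin midpoint, strictly increasing)
    and ``proportion``.  The proportions are first made monotone
    non-decreasing by isotonic regression, then the query proportion is
    mapped back to a score by piecewise-linear interpolation; queries
    outside the fitted range return the boundary score with a warning.
    """
    scores = snv_bins["score"].to_numpy(dtype=float)
    props = snv_bins["proportion"].to_numpy(dtype=float)
    if not np.all(np.diff(scores) > 0):
        raise ValueError("score bins must be strictly increasing")
    from sklearn.isotonic import IsotonicRegression
    fitted = IsotonicRegression(increasing=True).fit_transform(scores, props)
    if not fitted[0] <= query_proportion <= fitted[-1]:
        logger.warning("query proportion %.3f outside fitted range "
                       "[%.3f, %.3f]; returning boundary score",
                       query_proportion, fitted[0], fitted[-1])
        return float(scores[0] if query_proportion < fitted[0]
                     else scores[-1])
    # np.interp needs strictly increasing x; isotonic fits can plateau
    keep = np.concatenate([[True], np.diff(fitted) > 0])
    return float(np.interp(query_proportion, fitted[keep], scores[keep]))


def median_score_compare(scores_by_class: dict[str, np.ndarray],
                         n_bootstrap: int = 1000,
                         rng: np.random.Generator | None = None) -> dict:
    """Median scores with percentile bootstrap CIs and rank-sum tests."""
    if rng is None:
        rng = np.random.default_rng()
    per_class = {}
    for label, scores in scores_by_class.items():
        scores = np.asarray(scores, dtype=float)
        med = float(np.median(scores)) if len(scores) else float("nan")
        if len(scores) < 2:
            logger.warning("class %s has < 2 scores; CI undefined", label)
            per_class[label] = dict(n=len(scores), median=med,
                                    ci_low=float("nan"),
                                    ci_high=float("nan"))
            continue
        boots = np.median(
            scores[rng.integers(0, len(scores),
                                size=(n_bootstrap, len(scores)))], axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        per_class[label] = dict(n=len(scores), median=med,
                                ci_low=float(lo), ci_high=float(hi))
    rows = []
    labels = sorted(scores_by_class)
    for a, b in itertools.combinations(labels, 2):
        xa = np.asarray(scores_by_class[a], dtype=float)
        xb = np.asarray(scores_by_class[b], dtype=float)
        if len(xa) and len(xb):
            p = float(stats.mannwhitneyu(xa, xb,
                                         alternative="two-sided").pvalue)
        else:
            p = float("nan")
        rows.append(dict(class_a=a, class_b=b, p_value=p))
    return dict(per_class=per_class,
                pairwise=pd.DataFrame(
                    rows, columns=["class_a", "class_b", "p_value"]))
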