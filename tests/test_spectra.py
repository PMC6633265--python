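"""Unit tests for spectrum keys, signature fractions and ordering tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mnvkit.spectra import (
    SpectrumTable,
    apobec_motif_test,
    canonical_key,
    compare_spectra,
    cpg_order_consistency,
    key_for_call,
    mutability_shift,
    polzeta_fraction,
    revcomp,
    tabulate_spectrum,
    two_proportion_test,
)

BASES = "ACGT"


def _pair_row(ref1, alt1, ref2, alt2, distance=1, ac=(5, 5),
              pos1=100, mnv_class="sim"):
    return dict(chrom="chr1", pos1=pos1, pos2=pos1 + distance,
                ref1=ref1, alt1=alt1, ref2=ref2, alt2=alt2,
                distance=distance, mnv_class=mnv_class,
                stratum={1: "d1", 2: "d2"}.get(distance, "d3_20"),
                AC1=ac[0], AC2=ac[1])


class TestCanonicalKey:
    def test_ga_tt_equals_its_reverse_complement(self):
        assert canonical_key("GA", "TT") == canonical_key("TC", "AA")

    def test_self_revcomp_ref_collapses_alt(self):
        # GC is its own reverse complement; AA and TT are each other's
        assert canonical_key("GC", "AA") == canonical_key("GC", "TT")

    def test_idempotent(self):
        key = canonical_key("CA", "TG")
        ref, alt = key.split(">")
        assert canonical_key(ref, alt) == key

    def test_exhaustive_revcomp_invariance_dinucleotides(self):
        """canonical_key(x) == canonical_key(revcomp(x)) for all 16 x 9
        double substitutions."""
        for r1, r2 in itertools.product(BASES, repeat=2):
            alts1 = [b for b in BASES if b != r1]
            alts2 = [b for b in BASES if b != r2]
            for a1, a2 in itertools.product(alts1, alts2):
                ref, alt = r1 + r2, a1 + a2
                assert canonical_key(ref, alt) == \
                    canonical_key(revcomp(ref), revcomp(alt))

    def test_placeholder_preserved_for_gapped_pairs(self):
        assert ">" in canonical_key("CnC", "TnT")
        assert canonical_key("CnC", "TnT") == canonical_key("GnG", "AnA")

    def test_identical_ref_alt_rejected(self):
        with pytest.raises(ValueError):
            canonical_key("GA", "GA")


class TestTabulate:
    def test_single_call_counted_once(self):
        calls = pd.DataFrame([_pair_row("G", "A", "C", "A")])
        table = tabulate_spectrum(calls, "d1", "sim")
        assert table.total == 1
        assert table.counts == {canonical_key("GC", "AA"): 1}

    def test_totals_partition_by_stratum_without_loss(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(10):
            d = int(rng.choice([1, 2, 5]))
            r1, r2 = rng.choice(list(BASES), 2)
            a1 = [b for b in BASES if b != r1][rng.integers(3)]
            a2 = [b for b in BASES if b != r2][rng.integers(3)]
            rows.append(_pair_row(r1, a1, r2, a2, distance=d,
                                  pos1=100 + 30 * i))
        calls = pd.DataFrame(rows)
        total = sum(tabulate_spectrum(calls, s, "sim").total
                    for s in ("d1", "d2", "d3_20"))
        assert total == len(calls)

    def test_polzeta_fraction_arithmetic(self):
        table = SpectrumTable("d1", "sim",
                              {"GC>AA": 2, "GA>TT": 1, "AT>CC": 7})
        assert polzeta_fraction(table) == pytest.approx(0.3)

    def test_polzeta_fraction_pure_signature(self):
        table = SpectrumTable("d1", "sim", {"GC>AA": 3, "GA>TT": 2})
        assert polzeta_fraction(table) == 1.0

    def test_polzeta_fraction_empty_table_errors(self):
        with pytest.raises(ValueError):
            polzeta_fraction(SpectrumTable("d1", "sim", {}))


class TestCompareSpectra:
    def test_identical_tables_nothing_significant(self):
        t = SpectrumTable("d1", "sim", {"GC>AA": 30, "GA>TT": 70})
        out = compare_spectra(t, t)
        assert not out["significant"].any()

    def test_extreme_difference_significant(self):
        a = SpectrumTable("d1", "sim", {"GC>AA": 50, "GA>TT": 50})
        b = SpectrumTable("d1", "con", {"GA>TT": 100})
        out = compare_spectra(a, b)
        row = out[out["key"] == "GC>AA"].iloc[0]
        assert row["significant"]

    def test_pvalues_match_fisher_oracle_on_small_tables(self, rng):
        for _ in range(20):
            x1, x2 = int(rng.integers(0, 50)), int(rng.integers(0, 50))
            n1, n2 = x1 + int(rng.integers(1, 50)), \
                x2 + int(rng.integers(1, 50))
            p = two_proportion_test(x1, n1, x2, n2, method="exact")
            oracle = stats.fisher_exact(
                [[x1, n1 - x1], [x2, n2 - x2]])[1]
            assert p == pytest.approx(oracle, rel=1e-9)


class TestApobecMotif:
    def test_tctc_to_tttt_is_motif_positive(self):
        ref = "AAATCTCAAA"
        calls = pd.DataFrame([dict(pos1=5, ref1="C", alt1="T",
                                   pos2=7, ref2="C", alt2="T")])
        out = apobec_motif_test(calls, calls, ref)
        assert out["prop_a"] == 1.0

    def test_non_deamination_context_is_negative(self):
        # mutated Cs preceded by A on both strands: not a TpC/CpC motif
        ref = "AAACACAAAA"
        calls = pd.DataFrame([dict(pos1=4, ref1="C", alt1="T",
                                   pos2=6, ref2="C", alt2="T")])
        out = apobec_motif_test(calls, calls, ref)
        assert out["prop_a"] == 0.0

    def test_strand_symmetric(self):
        ref = "AAATCTCAAA"
        calls = pd.DataFrame([dict(pos1=5, ref1="C", alt1="T",
                                   pos2=7, ref2="C", alt2="T")])
        rc = revcomp(ref)
        n = len(ref)
        rc_calls = pd.DataFrame([dict(
            pos1=n - 7 + 1, ref1="G", alt1="A",
            pos2=n - 5 + 1, ref2="G", alt2="A")])
        a = apobec_motif_test(calls, calls, ref)
        b = apobec_motif_test(rc_calls, rc_calls, rc)
        assert a["prop_a"] == b["prop_a"]

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError):
            apobec_motif_test(pd.DataFrame(), pd.DataFrame(), "")


class TestCpgOrdering:
    def test_ordered_call_counted(self):
        calls = pd.DataFrame([_pair_row("C", "T", "A", "G", ac=(3, 12),
                                        mnv_class="con")])
        out = cpg_order_consistency(calls)
        assert out == dict(ordered_fraction=1.0, n_ordered=1, n_total=1)

    def test_reverse_order_counted_as_violation(self):
        calls = pd.DataFrame([_pair_row("C", "T", "A", "G", ac=(12, 3),
                                        mnv_class="con")])
        assert cpg_order_consistency(calls)["ordered_fraction"] == 0.0

    def test_equal_counts_excluded(self):
        calls = pd.DataFrame([_pair_row("C", "T", "A", "G", ac=(5, 5),
                                        mnv_class="con")])
        assert cpg_order_consistency(calls)["n_total"] == 0

    def test_non_cpg_keys_ignored(self):
        calls = pd.DataFrame([_pair_row("A", "T", "A", "T", ac=(9, 2),
                                        mnv_class="con")])
        assert cpg_order_consistency(calls)["n_total"] == 0

    def test_shuffled_counts_give_half(self, rng):
        rows = []
        for i in range(2000):
            acs = (3, 12) if rng.random() < 0.5 else (12, 3)
            rows.append(_pair_row("C", "T", "A", "G", ac=acs,
                                  mnv_class="con", pos1=100 + 3 * i))
        out = cpg_order_consistency(pd.DataFrame(rows))
        assert abs(out["ordered_fraction"] - 0.5) < 3 * np.sqrt(
            0.25 / out["n_total"])


class TestMutabilityShift:
    def test_lookup_arithmetic(self):
        # 1-based reference: pos 8 is G, pos 11 is A
        ref = "AAAACTGGTAAAAAA"
        # first variant (higher AC) at pos 11 (A>T) sits inside the 7-mer
        # of the second at pos 8 (G>C): probability 0.001 -> 0.002
        table = {("CTGGTAA", "C"): 0.001, ("CTGGTAT", "C"): 0.002}
        calls = pd.DataFrame([dict(
            chrom="chr1", pos1=8, pos2=11, ref1="G", alt1="C",
            ref2="A", alt2="T", distance=3, mnv_class="con",
            stratum="d3_20", AC1=2, AC2=9)])
        out = mutability_shift(calls, table, ref)
        assert out["n"] == 1
        assert out["median_delta"] == pytest.approx(0.001)

    def test_calls_beyond_3bp_or_cpg_creating_excluded(self):
        ref = "AAAACTGGTAAAAAA"
        far = dict(chrom="chr1", pos1=8, pos2=13, ref1="G", alt1="C",
                   ref2="A", alt2="T", distance=5, mnv_class="con",
                   stratum="d3_20", AC1=2, AC2=9)
        cpg = dict(chrom="chr1", pos1=5, pos2=6, ref1="C", alt1="T",
                   ref2="A", alt2="G", distance=1, mnv_class="con",
                   stratum="d1", AC1=2, AC2=9)
        out = mutability_shift(pd.DataFrame([far, cpg]), {}, ref)
        assert out["n"] == 0 and out["n_skipped"] == 0

    def test_missing_context_skipped_with_count(self):
        ref = "AAAACTGGTAAAAAA"
        calls = pd.DataFrame([dict(
            chrom="chr1", pos1=8, pos2=11, ref1="G", alt1="C",
            ref2="A", alt2="T", distance=3, mnv_class="con",
            stratum="d3_20", AC1=2, AC2=9)])
        out = mutability_shift(calls, {}, ref)
        assert out["n"] == 0 and out["n_skipped"] == 1

    def test_signed_rank_p_matches_sign_flip_permutation_oracle(self, rng):
        deltas = rng.normal(0.0005, 0.001, size=30)
        ref = "A" * 400
        table = {}
        rows = []
        # 30 calls, each with a distinct context pair realising one delta;
        # the temporally first member (higher AC) is pos2 = pos1 + 2 here,
        # so the module's "second" variant is pos1
        for i, delta in enumerate(deltas):
            pos_second = 10 + i * 12
            pos_first = pos_second + 2
            before = ref[pos_second - 4:pos_second + 3]
            after = list(before)
            after[pos_first - (pos_second - 3)] = "T"
            table[(before, "C")] = 0.001
            table[("".join(after), "C")] = 0.001 + delta
            rows.append(dict(chrom="chr1", pos1=pos_second, pos2=pos_first,
                             ref1="A", alt1="C", ref2="A", alt2="T",
                             distance=2, mnv_class="con", stratum="d2",
                             AC1=2, AC2=9))
        out = mutability_shift(pd.DataFrame(rows), table, ref)
        assert out["n"] == 30
        # sign-flip permutation oracle for the signed-rank statistic
        ranks = stats.rankdata(np.abs(deltas))
        t_obs = abs(np.sum(np.sign(deltas) * ranks))
        flips = rng.choice([-1.0, 1.0], size=(10_000, 30))
        t_perm = np.abs((flips * ranks).sum(axis=1))
        p_perm = float(np.mean(t_perm >= t_obs - 1e-12))
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / 10_000)
        assert abs(out["p_value"] - p_perm) < max(5 * se, 0.02)
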