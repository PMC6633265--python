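"""Mutational spectra of MNVs: tabulation, signatures and ordering tests.

Dinucleotide (and trinucleotide) substitution keys are collapsed over
strands: a key and its reverse complement are the same mutation, and the
canonical representative is the lexicographically smaller ``REF>ALT``
string.  Intervening unmutated bases are written ``n`` (one base) or
``..`` (two or more), e.g. ``CnC>TnT`` for variants 2 bp apart.

The module provides the signature analyses used to attribute MNVs to
mutational processes: the polymerase zeta share (GC>AA / GA>TT tandem
substitutions), the APOBEC motif comparison (mutated cytosines in a
TpC/CpC context on either strand), the CpG-creation temporal-ordering
statistic for consecutive MNVs, and the heptanucleotide mutability shift
of the second variant of a con-MNV after the first has occurred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTn.", "TGCAn.")

POLZETA_KEYS = ("GA>TT", "GC>AA")   # canonical forms; revcomps collapse here

# CpG-creation con-MNV orientations (adjacent pairs): key -> index of the
# CpG-creating member (0 = left substitution, 1 = right); the other member
# is the C>T-like deamination.
CPG_CREATING_ORIENTATIONS = {
    "CA>TG": 1, "TG>CA": 0,
    "CC>TG": 1, "GG>CA": 0,
    "AG>CA": 0, "CT>TG": 1,
}


def revcomp(seq: str) -> str:
    """Reverse complement preserving ``n``/``.`` placeholders."""
    return seq.translate(_COMP)[::-1]


def canonical_key(ref_context: str, alt_context: str) -> str:
    """Strand-collapsed ``REF>ALT`` key.

    Returns the lexicographically smaller of the key and its reverse
    complement; idempotent and symmetric under reverse complementation.
    """
    if len(ref_context) != len(alt_context):
        raise ValueError("ref and alt contexts must have equal length")
    for r, a in zip(ref_context, alt_context):
        if (r in "n.") != (a in "n."):
            raise ValueError("placeholder positions must match")
    if all(r == a for r, a in zip(ref_context, alt_context)
           if r not in "n."):
        raise ValueError("ref and alt must differ at a mutated position")
    fwd = f"{ref_context}>{alt_context}"
    rev = f"{revcomp(ref_context)}>{revcomp(alt_context)}"
    return min(fwd, rev)


def _context_strings(ref1: str, ref2: str, alt1: str, alt2: str,
                     distance: int) -> tuple[str, str]:
    if distance == 1:
        gap = ""
    elif distance == 2:
        gap = "n"
    else:
        gap = ".."
    return ref1 + gap + ref2, alt1 + gap + alt2


def key_for_call(row) -> str:
    """Canonical spectrum key for one MNV call row (pair TSV schema)."""
    ref, alt = _context_strings(row["ref1"], row["ref2"], row["alt1"],
                                row["alt2"], int(row["distance"]))
    return canonical_key(ref, alt)


@dataclass
class SpectrumTable:
    stratum: str                 # d1 | d2 | d3_20
    mnv_class: str               # sim | con | de_novo
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, dtype=int).sort_index()


def tabulate_spectrum(calls: pd.DataFrame, stratum: str,
                      mnv_class: str) -> SpectrumTable:
    """Count canonical keys for calls of one distance stratum and class."""
    sub = calls[(calls["stratum"] == stratum)
                & (calls["mnv_class"] == mnv_class)]
    counts: dict[str, int] = {}
    for _, row in sub.iterrows():
        key = key_for_call(row)
        counts[key] = counts.get(key, 0) + 1
    return SpectrumTable(stratum, mnv_class, counts)


def two_proportion_test(x1: int, n1: int, x2: int, n2: int,
                        method: str = "auto") -> float:
    """Two-sided test that two binomial proportions are equal.

    ``auto`` uses Fisher's exact test whenever any expected cell is below
    5, otherwise the normal-approximation (score) test.
    """
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be auto, exact or normal")
    if min(n1, n2) < 1:
        raise ValueError("need at least one observation per group")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    use_exact = method == "exact"
    if method == "auto":
        expected = (table.sum(axis=1, keepdims=True)
                    * table.sum(axis=0, keepdims=True) / table.sum())
        use_exact = bool((expected < 5).any())
    if use_exact:
        return float(stats.fisher_exact(table.astype(int))[1])
    from statsmodels.stats.proportion import proportions_ztest
    _, p = proportions_ztest([x1, x2], [n1, n2])
    return float(p)


def compare_spectra(table_a: SpectrumTable, table_b: SpectrumTable,
                    alpha: float = 0.05,
                    n_tests: int | None = None) -> pd.DataFrame:
    """Per-key proportion comparison with a Bonferroni significance flag."""
    keys = sorted(set(table_a.counts) | set(table_b.counts))
    if n_tests is None:
        n_tests = len(keys)
    na, nb = table_a.total, table_b.total
    rows = []
    for key in keys:
        xa = table_a.counts.get(key, 0)
        xb = table_b.counts.get(key, 0)
        p = two_proportion_test(xa, na, xb, nb)
        rows.append(dict(key=key, count_a=xa, count_b=xb,
                         prop_a=xa / na, prop_b=xb / nb, p_value=p,
                         significant=bool(p < alpha / max(n_tests, 1))))
    return pd.DataFrame(rows)


def polzeta_fraction(table: SpectrumTable) -> float:
    """Share of polymerase zeta tandem signatures in a d1 spectrum."""
    if table.total == 0:
        raise ValueError("empty spectrum table")
    hits = sum(table.counts.get(k, 0) for k in POLZETA_KEYS)
    return hits / table.total


# ---------------------------------------------------------------------------
# APOBEC motif analysis

def _is_apobec_motif(reference: str, pos: int, ref: str, alt: str) -> bool:
    """Mutated C (either strand) in a TpC/CpC deamination context.

    ``reference`` is the chromosome sequence, ``pos`` 1-based.  A C>T (or
    any C>N) substitution qualifies when its 5' neighbour is T or C; a
    G-reference substitution is the reverse-strand case, qualifying when
    the base 3' of it is A or G.
    """
    if ref == "C":
        return pos >= 2 and reference[pos - 2] in "TC"
    if ref == "G":
        return pos < len(reference) and reference[pos] in "AG"
    return False


def apobec_motif_test(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                      reference: str) -> dict:
    """Compare the per-call fraction with BOTH variants in APOBEC motifs.

    ``reference`` is the full chromosome sequence the call coordinates
    refer to (e.g. ``str(pyfaidx.Fasta(path)[chrom][:])``).
    """
    if not reference:
        raise ValueError("reference sequence required for flanking context")

    def motif_count(calls: pd.DataFrame) -> int:
        n = 0
        for _, row in calls.iterrows():
            hit1 = _is_apobec_motif(reference, int(row["pos1"]),
                                    row["ref1"], row["alt1"])
            hit2 = _is_apobec_motif(reference, int(row["pos2"]),
                                    row["ref2"], row["alt2"])
            if hit1 and hit2:
                n += 1
        return n

    xa, na = motif_count(calls_a), len(calls_a)
    xb, nb = motif_count(calls_b), len(calls_b)
    p = two_proportion_test(xa, na, xb, nb)
    return dict(prop_a=xa / na if na else float("nan"),
                prop_b=xb / nb if nb else float("nan"),
                n_a=na, n_b=nb, p_value=p)


# ---------------------------------------------------------------------------
# CpG-creation ordering

def cpg_order_consistency(con_calls_d1: pd.DataFrame) -> dict:
    """Temporal-order statistic for CpG-creating adjacent con-MNVs.

    For each con-MNV whose key is a CpG-creating orientation (CA>TG,
    CC>TG, AG>CA or a reverse complement), checks whether the CpG-creating
    member's allele count strictly exceeds the deamination member's --
    the order expected if the CpG was created first and then mutated.
    Calls with equal counts would have been classified sim and are
    excluded.
    """
    n_ordered = 0
    n_total = 0
    for _, row in con_calls_d1.iterrows():
        if int(row["distance"]) != 1:
            continue
        key = f"{row['ref1']}{row['ref2']}>{row['alt1']}{row['alt2']}"
        creator_idx = CPG_CREATING_ORIENTATIONS.get(key)
        if creator_idx is None:
            continue
        ac = (int(row["AC1"]), int(row["AC2"]))
        if ac[0] == ac[1]:
            continue
        n_total += 1
        if ac[creator_idx] > ac[1 - creator_idx]:
            n_ordered += 1
    frac = n_ordered / n_total if n_total else float("nan")
    return dict(ordered_fraction=frac, n_ordered=n_ordered, n_total=n_total)


# ---------------------------------------------------------------------------
# heptanucleotide mutability shift

def load_hepta_table(path: str) -> dict[tuple[str, str], float]:
    """Read a 7-mer mutation-probability table.

    Two-column TSV: ``context_alt`` (7-mer, underscore, alt base of the
    central position, e.g. ``AACTGGT_G``) and ``probability``.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["context_alt", "probability"], header=0)
    table = {}
    for _, row in df.iterrows():
        context, alt = row["context_alt"].split("_")
        table[(context, alt)] = float(row["probability"])
    return table


def mutability_shift(con_calls: pd.DataFrame,
                     hepta_table: dict[tuple[str, str], float],
                     reference: str) -> dict:
    """Change in the second variant's mutability once the first exists.

    Restricted to consecutive MNVs 1-3 bp apart that are not CpG-creating.
    The temporally first variant is the member with the higher allele
    count.  For each call the 7-mer context of the second variant is
    looked up before and after applying the first variant; the deltas are
    summarised by their median and a one-sample Wilcoxon signed-rank test
    against zero shift.  Calls whose context is absent from the table are
    skipped (count logged and returned).
    """
    deltas = []
    n_skipped = 0
    for _, row in con_calls.iterrows():
        d = int(row["distance"])
        if not 1 <= d <= 3:
            continue
        key = f"{row['ref1']}{row['ref2']}>{row['alt1']}{row['alt2']}"
        if d == 1 and key in CPG_CREATING_ORIENTATIONS:
            continue
        if int(row["AC1"]) == int(row["AC2"]):
            continue
        first, second = (1, 2) if row["AC1"] > row["AC2"] else (2, 1)
        pos_f, ref_f, alt_f = (int(row[f"pos{first}"]), row[f"ref{first}"],
                               row[f"alt{first}"])
        pos_s, ref_s, alt_s = (int(row[f"pos{second}"]), row[f"ref{second}"],
                               row[f"alt{second}"])
        if pos_s - 4 < 0 or pos_s + 3 > len(reference):
            n_skipped += 1
            continue
        before = list(reference[pos_s - 4:pos_s + 3])
        after = list(before)
        offset = pos_f - (pos_s - 3)
        if 0 <= offset < 7:
            after[offset] = alt_f
        key_before = ("".join(before), alt_s)
        key_after = ("".join(after), alt_s)
        if key_before not in hepta_table or key_after not in hepta_table:
            n_skipped += 1
            continue
        deltas.append(hepta_table[key_after] - hepta_table[key_before])
    if n_skipped:
        logger.info("mutability_shift: skipped %d calls without context",
                    n_skipped)
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        return dict(median_delta=float("nan"), p_value=float("nan"),
                    n=0, n_skipped=n_skipped)
    if np.allclose(deltas, 0.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(deltas).pvalue)
    return dict(median_delta=float(np.median(deltas)), p_value=p,
                n=int(deltas.size), n_skipped=n_skipped)
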