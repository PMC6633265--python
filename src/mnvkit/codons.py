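"""Codon-level joint annotation of MNVs and missense step classification.

An MNV inside one codon must be annotated jointly: translating the two
substitutions one at a time can mis-state the consequence (e.g. CGG with
C>T and G>A separately gives a missense and a synonymous call, while the
joint codon TGA is a stop gain).  Intra-codon missense MNVs split into

* **one-step**: the resulting amino acid is also reachable from the
  reference codon by a single-base substitution, and
* **two-step**: the amino acid can only be reached by changing two bases.

Amino-acid changes reachable *only* by a single-base change are the
*exclusive-SNV* class.  Physicochemical divergence of a change is the
Euclidean distance between packaged five-dimensional amino-acid
descriptors derived from multidimensional scaling of 237 physical-chemical
properties.

Translation uses the standard genetic code (autosomal exome analysis).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

BASES = "ACGT"
STOP = "*"

_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = STOP
SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TO_AA.items()
                            if aa != STOP))
AMINO_ACIDS = tuple(sorted(set(CODON_TO_AA.values()) - {STOP}))

SEVERITY = {"synonymous": 0, "stop_retained": 0, "missense": 1,
            "stop_lost": 1, "stop_gained": 2}


@dataclass
class CodonChange:
    ref_codon: str
    alt_codon: str
    n_changed: int
    joint_class: str
    ref_aa: str
    alt_aa: str
    step_class: str       # one_step | two_step | not_applicable
    distance: float = float("nan")


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a codon: {codon!r}")
    return CODON_TO_AA[codon]


def _classify(ref_aa: str, alt_aa: str) -> str:
    if ref_aa == STOP and alt_aa == STOP:
        return "stop_retained"
    if ref_aa == STOP:
        return "stop_lost"
    if alt_aa == STOP:
        return "stop_gained"
    return "synonymous" if ref_aa == alt_aa else "missense"


def joint_consequence(ref_codon: str, positions_changed: tuple[int, ...],
                      alt_bases: tuple[str, ...],
                      matrix: pd.DataFrame | None = None) -> CodonChange:
    """Annotate all substitutions of one codon as a single event.

    ``positions_changed`` are 1-based positions within the codon.  The
    reference codon must be a sense codon (stop-loss annotation beyond the
    bare class is out of scope).
    """
    ref_codon = ref_codon.upper()
    if translate_codon(ref_codon) == STOP:
        raise ValueError("reference stop codons are not supported")
    if len(positions_changed) != len(alt_bases) or not positions_changed:
        raise ValueError("positions and alt bases must align")
    alt = list(ref_codon)
    for p, b in zip(positions_changed, alt_bases):
        if p not in (1, 2, 3):
            raise ValueError("codon positions are 1..3")
        if ref_codon[p - 1] == b.upper():
            raise ValueError(f"alt equals ref at codon position {p}")
        alt[p - 1] = b.upper()
    alt_codon = "".join(alt)
    ref_aa, alt_aa = translate_codon(ref_codon), translate_codon(alt_codon)
    joint = _classify(ref_aa, alt_aa)
    n_changed = sum(a != b for a, b in zip(ref_codon, alt_codon))
    step = "not_applicable"
    if joint == "missense" and n_changed == 2:
        step = classify_step(ref_codon, alt_codon)
    dist = float("nan")
    if joint == "missense" and matrix is not None:
        dist = aa_distance(ref_aa, alt_aa, matrix)
    return CodonChange(ref_codon, alt_codon, n_changed, joint,
                       ref_aa, alt_aa, step, dist)


def compare_joint_vs_separate(joint_class: str,
                              snv_classes: tuple[str, ...]) -> str:
    """Compare joint severity against the worst separately annotated SNV."""
    joint = SEVERITY[joint_class]
    sep = max(SEVERITY[c] for c in snv_classes)
    if joint == sep:
        return "same"
    return "joint_more_severe" if joint > sep else "joint_less_severe"


def _substituted(codon: str, n_sub: int):
    """All codons at exact Hamming distance n_sub from ``codon``."""
    for positions in itertools.combinations(range(3), n_sub):
        alts = [[b for b in BASES if b != codon[p]] for p in positions]
        for repl in itertools.product(*alts):
            out = list(codon)
            for p, b in zip(positions, repl):
                out[p] = b
            yield "".join(out)


def one_step_missense_set(codon: str) -> set[str]:
    """Amino acids reachable from a sense codon by one substitution.

    Excludes the reference amino acid (synonymous) and stops.
    """
    codon = codon.upper()
    ref_aa = translate_codon(codon)
    if ref_aa == STOP:
        raise ValueError("sense codon required")
    return {translate_codon(c) for c in _substituted(codon, 1)} \
        - {ref_aa, STOP}


def two_step_missense_sets(codon: str) -> tuple[set[str], set[str], set[str]]:
    """(reachable by two substitutions, two-step-only, exclusive-SNV)."""
    codon = codon.upper()
    ref_aa = translate_codon(codon)
    if ref_aa == STOP:
        raise ValueError("sense codon required")
    one = one_step_missense_set(codon)
    two = {translate_codon(c) for c in _substituted(codon, 2)} \
        - {ref_aa, STOP}
    return two, two - one, one - two


def classify_step(ref_codon: str, alt_codon: str) -> str:
    """one_step vs two_step for an intra-codon double-substitution missense.

    Classification is by amino-acid reachability, not the particular codon
    path: the change is one-step iff the resulting amino acid is also in
    the single-substitution missense set of the reference codon.
    """
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    n = sum(a != b for a, b in zip(ref_codon, alt_codon))
    if n != 2:
        raise ValueError("step classification needs Hamming distance 2")
    ref_aa, alt_aa = translate_codon(ref_codon), translate_codon(alt_codon)
    if ref_aa == STOP or alt_aa in (STOP, ref_aa):
        raise ValueError("step classification applies to missense changes")
    return ("one_step" if alt_aa in one_step_missense_set(ref_codon)
            else "two_step")


# ---------------------------------------------------------------------------
# physicochemical distance

def load_aa_descriptors() -> pd.DataFrame:
    """Packaged five-dimensional amino-acid descriptor table (E1..E5)."""
    with resources.files("mnvkit.data").joinpath(
            "aa_descriptors.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return df.set_index("aa")


def aa_distance_matrix(descriptors: pd.DataFrame | None = None
                       ) -> pd.DataFrame:
    """20x20 Euclidean distance matrix over the descriptor space."""
    if descriptors is None:
        descriptors = load_aa_descriptors()
    x = descriptors.to_numpy(dtype=float)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    return pd.DataFrame(d, index=descriptors.index,
                        columns=descriptors.index)


def load_aa_distance_matrix(path: str | None = None) -> pd.DataFrame:
    """Distance matrix from a TSV (rows/cols one-letter codes) or packaged."""
    if path is None:
        return aa_distance_matrix()
    m = pd.read_csv(path, sep="\t", index_col=0)
    if not np.allclose(m.values, m.values.T):
        raise ValueError("distance matrix must be symmetric")
    return m


def aa_distance(aa_from: str, aa_to: str, matrix: pd.DataFrame) -> float:
    if aa_from not in matrix.index or aa_to not in matrix.columns:
        raise ValueError(f"non-standard amino acid: {aa_from}/{aa_to}")
    return float(matrix.loc[aa_from, aa_to])


def distance_distributions(matrix: pd.DataFrame | None = None,
                           per: str = "amino_acid") -> dict:
    """Physicochemical distance distributions of the three missense classes.

    Enumerates all 61 sense codons.  ``per="amino_acid"`` (default) adds
    one entry per (codon, distinct reachable amino acid); ``per="path"``
    weights by the number of substitution paths reaching the amino acid.
    Returns the three distance lists, their medians, and two-sided
    rank-sum p-values for two-step vs one-step and one-step vs
    exclusive-SNV.
    """
    if per not in ("amino_acid", "path"):
        raise ValueError("per must be 'amino_acid' or 'path'")
    if matrix is None:
        matrix = aa_distance_matrix()
    dists: dict[str, list[float]] = {"exclusive_snv": [], "one_step": [],
                                     "two_step": []}
    for codon in SENSE_CODONS:
        ref_aa = translate_codon(codon)
        one = one_step_missense_set(codon)
        two, additional, exclusive = two_step_missense_sets(codon)
        if per == "amino_acid":
            groups = {"exclusive_snv": exclusive, "one_step": one & two,
                      "two_step": additional}
            for label, aas in groups.items():
                dists[label] += [aa_distance(ref_aa, aa, matrix)
                                 for aa in aas]
        else:
            for alt in _substituted(codon, 1):
                aa = translate_codon(alt)
                if aa in (ref_aa, STOP):
                    continue
                label = "exclusive_snv" if aa in exclusive else "one_step"
                dists[label].append(aa_distance(ref_aa, aa, matrix))
            for alt in _substituted(codon, 2):
                aa = translate_codon(alt)
                if aa in (ref_aa, STOP):
                    continue
                label = "one_step" if aa in one else "two_step"
                dists[label].append(aa_distance(ref_aa, aa, matrix))
    from scipy import stats
    medians = {k: float(np.median(v)) for k, v in dists.items()}
    p_two_vs_one = float(stats.mannwhitneyu(
        dists["two_step"], dists["one_step"],
        alternative="two-sided").pvalue)
    p_one_vs_excl = float(stats.mannwhitneyu(
        dists["one_step"], dists["exclusive_snv"],
        alternative="two-sided").pvalue)
    return dict(distances=dists, medians=medians,
                p_two_step_vs_one_step=p_two_vs_one,
                p_one_step_vs_exclusive=p_one_vs_excl)


# ---------------------------------------------------------------------------
# coordinate-level annotation

def intra_codon_probability(distance: int) -> float:
    """Probability two variants ``distance`` bp apart share a codon.

    By enumeration of the three reading-frame offsets of the first
    variant: the pair is intra-codon for offsets o with o + distance <= 2,
    so adjacent pairs land in one codon with probability 2/3.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    return max(0, 3 - distance) / 3.0


@dataclass
class CodingContext:
    """Concatenated CDS of one transcript (1-based inclusive intervals)."""

    transcript: str
    chrom: str
    intervals: list[tuple[int, int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        last = 0
        for s, e in self.intervals:
            if s <= last or e < s:
                raise ValueError("CDS intervals must be ordered and "
                                 "non-overlapping")
            last = e
        if self.cds_length % 3:
            raise ValueError("CDS length must be divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def cds_coordinate(self, pos: int) -> int | None:
        """0-based CDS offset of a genomic position, or None if outside."""
        off = 0
        for s, e in self.intervals:
            if s <= pos <= e:
                fwd = off + (pos - s)
                if self.strand == "+":
                    return fwd
                return self.cds_length - 1 - fwd
            off += e - s + 1
        return None


def load_cds_model(path: str) -> list[CodingContext]:
    """BED-like TSV: chrom, start, end, strand, transcript (1-based)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for tx, grp in df.groupby("transcript"):
        out.append(CodingContext(
            transcript=tx, chrom=grp["chrom"].iloc[0],
            intervals=[(int(r.start), int(r.end))
                       for r in grp.itertuples()],
            strand=grp["strand"].iloc[0]))
    return out


_RC = str.maketrans("ACGT", "TGCA")


def annotate_mnv(ctx: CodingContext, reference: str, pos1: int, alt1: str,
                 pos2: int, alt2: str,
                 matrix: pd.DataFrame | None = None) -> dict:
    """Joint and separate consequences of a two-variant MNV in one CDS.

    Both substitutions are applied to the transcript CDS, which is then
    diffed codon-by-codon, so inter-codon MNVs get one consequence per
    affected codon; the reported joint class is the most severe.
    """
    cds = []
    for s, e in ctx.intervals:
        cds.append(reference[s - 1:e])
    seq = "".join(cds)
    if ctx.strand == "-":
        seq = seq.translate(_RC)[::-1]
    positions = []
    for pos, alt in ((pos1, alt1), (pos2, alt2)):
        c = ctx.cds_coordinate(pos)
        if c is None:
            raise ValueError(f"position {pos} outside CDS of "
                             f"{ctx.transcript}")
        a = alt if ctx.strand == "+" else alt.translate(_RC)
        positions.append((c, a))
    codon_idx = {c // 3 for c, _ in positions}
    intra = len(codon_idx) == 1

    def consequence(subs) -> str:
        worst = "synonymous"
        for ci in sorted({c // 3 for c, _ in subs}):
            ref_codon = seq[3 * ci:3 * ci + 3]
            alt = list(ref_codon)
            for c, b in subs:
                if c // 3 == ci:
                    alt[c % 3] = b
            cls = _classify(translate_codon(ref_codon),
                            translate_codon("".join(alt)))
            if SEVERITY[cls] > SEVERITY[worst]:
                worst = cls
        return worst

    joint = consequence(positions)
    separate = tuple(consequence([p]) for p in positions)
    step = "not_applicable"
    distance = float("nan")
    if intra:
        ci = codon_idx.pop()
        ref_codon = seq[3 * ci:3 * ci + 3]
        alt = list(ref_codon)
        for c, b in positions:
            alt[c % 3] = b
        alt_codon = "".join(alt)
        n_changed = sum(a != b for a, b in zip(ref_codon, alt_codon))
        if joint == "missense" and n_changed == 2:
            step = classify_step(ref_codon, alt_codon)
        if joint == "missense" and matrix is not None:
            distance = aa_distance(translate_codon(ref_codon),
                                   translate_codon(alt_codon), matrix)
    return dict(joint_class=joint, separate_classes=separate,
                intra_codon=intra, step_class=step, aa_distance=distance,
                severity_compare=compare_joint_vs_separate(joint, separate))


def annotate_calls(calls: pd.DataFrame, contexts: list[CodingContext],
                   reference: str,
                   matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Annotate an MNV call table against the first overlapping CDS."""
    if matrix is None:
        matrix = aa_distance_matrix()
    rows = []
    for _, row in calls.iterrows():
        ann = dict(joint_class="", separate_classes="", intra_codon=None,
                   step_class="", aa_distance=float("nan"),
                   severity_compare="")
        for ctx in contexts:
            if ctx.chrom != row["chrom"]:
                continue
            c1 = ctx.cds_coordinate(int(row["pos1"]))
            c2 = ctx.cds_coordinate(int(row["pos2"]))
            if c1 is None or c2 is None:
                continue
            res = annotate_mnv(ctx, reference, int(row["pos1"]),
                               row["alt1"], int(row["pos2"]), row["alt2"],
                               matrix)
            ann = dict(joint_class=res["joint_class"],
                       separate_classes=";".join(res["separate_classes"]),
                       intra_codon=res["intra_codon"],
                       step_class=res["step_class"],
                       aa_distance=res["aa_distance"],
                       severity_compare=res["severity_compare"])
            break
        rows.append({**row.to_dict(), **ann})
    return pd.DataFrame(rows)
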