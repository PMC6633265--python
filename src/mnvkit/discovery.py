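"""MNV discovery from cohort genotypes via trio-based phasing.

A candidate MNV is a pair of heterozygous SNVs observed within
``max_candidate_dist`` (default 100) bp of each other in at least one
individual, with read depth >= 20 at both sites.  Each candidate is phased
in every carrier trio by parent-of-origin logic: two nearby variants
transmitted by the same parent must sit on the same child haplotype
(recombination between sites <= 100 bp apart is negligible).  Pairs on the
same haplotype in more than 99% of phase-determined carriers, at distance
<= 20 bp, are called MNVs; trios whose phase cannot be determined count
toward neither numerator nor denominator.

Called MNVs are classified *sim* (one simultaneous mutational event --
members share an identical cohort allele count) or *con* (consecutive
events -- allele counts differ, the older variant being the more frequent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

MATERNAL = "maternal"
PATERNAL = "paternal"


@dataclass
class Variant:
    """One biallelic SNV site with cohort genotypes."""

    chrom: str
    pos: int                 # 1-based
    ref: str
    alt: str
    allele_count: int
    gt: np.ndarray           # per-sample dosage 0/1/2, -1 missing
    dp: np.ndarray           # per-sample read depth

    def __post_init__(self) -> None:
        if self.ref == self.alt or len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("Variant must be a biallelic SNV with ref != alt")


@dataclass
class CandidatePair:
    first: Variant
    second: Variant
    phaseable_trios: int = 0
    same_haplotype_trios: int = 0

    @property
    def distance(self) -> int:
        return self.second.pos - self.first.pos

    @property
    def same_fraction(self) -> float:
        if self.phaseable_trios == 0:
            return float("nan")
        return self.same_haplotype_trios / self.phaseable_trios


def stratum_of(distance: int) -> str:
    if distance == 1:
        return "d1"
    if distance == 2:
        return "d2"
    return "d3_20"


@dataclass
class MnvCall:
    pair: CandidatePair
    mnv_class: str           # sim | con
    carriers: list[str] = field(default_factory=list)

    @property
    def distance(self) -> int:
        return self.pair.distance

    @property
    def stratum(self) -> str:
        return stratum_of(self.pair.distance)


@dataclass
class Pedigree:
    """Trio structure as indices into the VCF sample list."""

    samples: list[str]
    trios: list[tuple[int, int, int]]    # (child, mother, father)

    @classmethod
    def from_file(cls, path: str, samples: list[str]) -> "Pedigree":
        ped = pd.read_csv(path, sep="\t")
        index = {s: i for i, s in enumerate(samples)}
        trios = []
        for _, row in ped.iterrows():
            try:
                trios.append((index[row["child"]], index[row["mother"]],
                              index[row["father"]]))
            except KeyError as exc:
                raise ValueError(f"pedigree sample {exc} missing from VCF")
        return cls(samples=list(samples), trios=trios)


def read_cohort_vcf(path: str) -> tuple[list[Variant], list[str]]:
    """Load biallelic SNVs from a multi-sample VCF.

    Multi-allelic records and indels are skipped (count logged).  The
    cohort allele count is taken from INFO/AC when present, otherwise
    recomputed from the genotypes.
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    variants: list[Variant] = []
    n_skipped = 0
    for rec in vf:
        if len(rec.alts or ()) != 1 or len(rec.ref) != 1 \
                or len(rec.alts[0]) != 1:
            n_skipped += 1
            continue
        n = len(samples)
        gt = np.full(n, -1, dtype=np.int16)
        dp = np.zeros(n, dtype=np.int32)
        for i, sample in enumerate(rec.samples.values()):
            alleles = sample.get("GT")
            if alleles is not None and None not in alleles:
                gt[i] = sum(alleles)
            d = sample.get("DP")
            dp[i] = d if d is not None else 0
        ac = rec.info.get("AC")
        ac = int(ac[0]) if ac is not None else int(gt[gt > 0].sum())
        variants.append(Variant(rec.chrom, rec.pos, rec.ref, rec.alts[0],
                                ac, gt, dp))
    if n_skipped:
        logger.info("skipped %d multi-allelic/indel records", n_skipped)
    return variants, samples


def find_candidate_pairs(variants: list[Variant], max_dist: int = 100,
                         min_dp: int = 20) -> list[CandidatePair]:
    """All within-sample het pairs at 1..max_dist bp with DP >= min_dp.

    ``variants`` must be position-sorted within each chromosome.  Pairs are
    unique cohort-wide by site, regardless of how many individuals carry
    them.
    """
    if max_dist < 1:
        raise ValueError("max_dist must be >= 1")
    pairs: list[CandidatePair] = []
    for i, v1 in enumerate(variants):
        het1 = (v1.gt == 1) & (v1.dp >= min_dp)
        for v2 in variants[i + 1:]:
            if v2.chrom != v1.chrom:
                break
            if v2.pos <= v1.pos:
                raise ValueError("variants must be sorted by position")
            if v2.pos - v1.pos > max_dist:
                break
            het2 = (v2.gt == 1) & (v2.dp >= min_dp)
            if np.any(het1 & het2):
                pairs.append(CandidatePair(v1, v2))
    return pairs


def phase_site_in_trio(child_gt: int, mother_gt: int, father_gt: int) -> str | None:
    """Parent of origin of the child's alt allele at a heterozygous site.

    Returns ``"maternal"``, ``"paternal"``, or ``None`` when phase cannot
    be determined: both parents heterozygous, neither parent carrying the
    alt (apparent de novo), a missing genotype, or a Mendelian
    inconsistency.
    """
    if child_gt != 1:
        raise ValueError("child must be heterozygous at the site")
    if mother_gt < 0 or father_gt < 0:
        return None
    # scenario A: mother transmits alt, father transmits ref
    a = mother_gt > 0 and father_gt < 2
    # scenario B: father transmits alt, mother transmits ref
    b = father_gt > 0 and mother_gt < 2
    if a and not b:
        return MATERNAL
    if b and not a:
        return PATERNAL
    return None


def pair_same_haplotype(origin1: str | None, origin2: str | None) -> str:
    """Combine two parent-of-origin verdicts for a variant pair."""
    if origin1 is None or origin2 is None:
        return "undetermined"
    return "same" if origin1 == origin2 else "different"


def phase_candidate_pairs(pairs: list[CandidatePair], pedigree: Pedigree,
                          min_dp: int = 20) -> None:
    """Tally same-haplotype evidence for every candidate pair, in place.

    Only trios whose child is heterozygous at both sites with sufficient
    depth are examined; undetermined trios are discarded from both the
    numerator and the denominator.
    """
    for pair in pairs:
        v1, v2 = pair.first, pair.second
        pair.phaseable_trios = 0
        pair.same_haplotype_trios = 0
        for ci, mi, fi in pedigree.trios:
            if v1.gt[ci] != 1 or v2.gt[ci] != 1:
                continue
            if v1.dp[ci] < min_dp or v2.dp[ci] < min_dp:
                continue
            o1 = phase_site_in_trio(1, int(v1.gt[mi]), int(v1.gt[fi]))
            o2 = phase_site_in_trio(1, int(v2.gt[mi]), int(v2.gt[fi]))
            verdict = pair_same_haplotype(o1, o2)
            if verdict == "same":
                pair.phaseable_trios += 1
                pair.same_haplotype_trios += 1
            elif verdict == "different":
                pair.phaseable_trios += 1


def classify_sim_con(ac1: int, ac2: int) -> str:
    """sim if the two members share an identical cohort allele count."""
    return "sim" if ac1 == ac2 else "con"


def call_mnvs(pairs: list[CandidatePair], threshold: float = 0.99,
              max_dist: int = 20, min_phaseable: int = 1) -> list[MnvCall]:
    """Keep pairs on one haplotype in more than ``threshold`` of carriers.

    The inequality is strict: at the default 0.99, a pair with 99/100
    same-haplotype carriers is *not* called.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    calls = []
    for pair in pairs:
        if pair.distance > max_dist:
            continue
        if pair.phaseable_trios < max(min_phaseable, 1):
            continue
        if pair.same_fraction > threshold:
            calls.append(MnvCall(
                pair,
                classify_sim_con(pair.first.allele_count,
                                 pair.second.allele_count)))
    return calls


def find_trinucleotide_mnvs(calls: list[MnvCall],
                            max_span: int = 20) -> pd.DataFrame:
    """Triples of same-haplotype variants with identical allele counts.

    Built from called pairs: positions a < b < c form a trinucleotide MNV
    when (a,b), (b,c) and (a,c) are all called on one haplotype, the span
    c - a is within ``max_span``, and all three allele counts agree.
    ``adjacent`` flags triples at three consecutive bases.
    """
    by_sites: dict[tuple, MnvCall] = {}
    for call in calls:
        key = (call.pair.first.chrom, call.pair.first.pos,
               call.pair.second.pos)
        by_sites[key] = call
    rows = []
    for (chrom, a, b), call_ab in by_sites.items():
        for (chrom2, b2, c), call_bc in by_sites.items():
            if chrom2 != chrom or b2 != b or c - a > max_span:
                continue
            call_ac = by_sites.get((chrom, a, c))
            if call_ac is None:
                continue
            acs = {call_ab.pair.first.allele_count,
                   call_ab.pair.second.allele_count,
                   call_bc.pair.second.allele_count}
            if len(acs) != 1:
                continue
            rows.append(dict(
                chrom=chrom, pos1=a, pos2=b, pos3=c,
                ref=call_ab.pair.first.ref + call_ab.pair.second.ref
                    + call_bc.pair.second.ref,
                alt=call_ab.pair.first.alt + call_ab.pair.second.alt
                    + call_bc.pair.second.alt,
                allele_count=acs.pop(),
                adjacent=(c - a == 2),
            ))
    return pd.DataFrame(
        rows, columns=["chrom", "pos1", "pos2", "pos3", "ref", "alt",
                       "allele_count", "adjacent"])


def call_de_novo_mnvs(dnms: pd.DataFrame, max_dist: int = 20) -> pd.DataFrame:
    """Pair de novo SNVs of one child into de novo MNVs.

    ``dnms`` needs columns child, chrom, pos, ref, alt, evidence; the
    evidence column carries external haplotype support (read-backed phase
    in real data, the truth haplotype label in synthetic cohorts).  A pair
    is retained when both members fall within ``max_dist`` bp and share
    the same haplotype evidence; records with missing evidence are
    excluded.  All retained de novo MNVs are by definition simultaneous.
    """
    rows = []
    for (child, chrom), grp in dnms.groupby(["child", "chrom"]):
        grp = grp.sort_values("pos")
        recs = grp.to_dict("records")
        for i, r1 in enumerate(recs):
            for r2 in recs[i + 1:]:
                d = r2["pos"] - r1["pos"]
                if d > max_dist:
                    break
                if d < 1:
                    continue
                e1, e2 = r1.get("evidence"), r2.get("evidence")
                if not e1 or not e2 or pd.isna(e1) or pd.isna(e2):
                    continue   # undetermined, excluded
                if e1 != e2:
                    continue
                rows.append(dict(
                    child=child, chrom=chrom, pos1=r1["pos"], pos2=r2["pos"],
                    ref1=r1["ref"], alt1=r1["alt"],
                    ref2=r2["ref"], alt2=r2["alt"],
                    distance=d, haplotype=e1,
                ))
    return pd.DataFrame(
        rows, columns=["child", "chrom", "pos1", "pos2", "ref1", "alt1",
                       "ref2", "alt2", "distance", "haplotype"])


def ascertained_site_counts(variants: list[Variant], pedigree: Pedigree,
                            calls: list[MnvCall],
                            min_dp: int = 20) -> tuple[int, int]:
    """Segregating-site counts for the Watterson rate scaling.

    Returns ``(k_snv, k_sim_mnv)``: the number of called two-variant
    sim-MNVs, and the number of SNV sites under the same ascertainment --
    at least one trio child heterozygous with adequate depth whose
    parental transmission can be phased.  Member sites of any called MNV
    (sim or con) are excluded from the SNV count so one mutational event
    is never counted in both classes, and the three sub-pairs of a
    trinucleotide MNV are excluded from the sim count (trinucleotide
    events are a separate variant class, tallied elsewhere).
    """
    members = set()
    for call in calls:
        members.add((call.pair.first.chrom, call.pair.first.pos))
        members.add((call.pair.second.chrom, call.pair.second.pos))
    tri = find_trinucleotide_mnvs(calls)
    tri_pairs = set()
    for _, row in tri.iterrows():
        a, b, c = row["pos1"], row["pos2"], row["pos3"]
        tri_pairs |= {(row["chrom"], a, b), (row["chrom"], b, c),
                      (row["chrom"], a, c)}
    k_sim = sum(
        1 for c in calls
        if c.mnv_class == "sim"
        and (c.pair.first.chrom, c.pair.first.pos,
             c.pair.second.pos) not in tri_pairs)
    k_snv = 0
    for v in variants:
        if (v.chrom, v.pos) in members:
            continue
        for ci, mi, fi in pedigree.trios:
            if v.gt[ci] != 1 or v.dp[ci] < min_dp:
                continue
            if phase_site_in_trio(1, int(v.gt[mi]), int(v.gt[fi])):
                k_snv += 1
                break
    return k_snv, k_sim


def calls_to_dataframe(calls: list[MnvCall]) -> pd.DataFrame:
    """Flatten MNV calls to the tabular output format."""
    rows = []
    for c in calls:
        p = c.pair
        rows.append(dict(
            chrom=p.first.chrom, pos1=p.first.pos, pos2=p.second.pos,
            ref1=p.first.ref, alt1=p.first.alt,
            ref2=p.second.ref, alt2=p.second.alt,
            distance=c.distance, mnv_class=c.mnv_class, stratum=c.stratum,
            n_phaseable=p.phaseable_trios, n_same=p.same_haplotype_trios,
            AC1=p.first.allele_count, AC2=p.second.allele_count,
        ))
    return pd.DataFrame(
        rows, columns=["chrom", "pos1", "pos2", "ref1", "alt1", "ref2",
                       "alt2", "distance", "mnv_class", "stratum",
                       "n_phaseable", "n_same", "AC1", "AC2"])


def discover(vcf_path: str, ped_path: str, max_candidate_dist: int = 100,
             max_mnv_dist: int = 20, threshold: float = 0.99,
             min_dp: int = 20, min_phaseable: int = 1) -> pd.DataFrame:
    """End-to-end discovery: VCF + pedigree to an MNV call table."""
    variants, samples = read_cohort_vcf(vcf_path)
    pedigree = Pedigree.from_file(ped_path, samples)
    pairs = find_candidate_pairs(variants, max_dist=max_candidate_dist,
                                 min_dp=min_dp)
    phase_candidate_pairs(pairs, pedigree, min_dp=min_dp)
    calls = call_mnvs(pairs, threshold=threshold, max_dist=max_mnv_dist,
                      min_phaseable=min_phaseable)
    return calls_to_dataframe(calls)
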