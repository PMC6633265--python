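"""Synthetic trio exome cohort generator with known MNV ground truth.

Emulates the statistical structure that the MNV analysis downstream assumes:

* segregating SNVs with a neutral (1/k) site-frequency spectrum placed on
  random parental haplotypes,
* simultaneous MNVs (sim-MNVs): two substitutions sharing one mutational
  event, hence one carrier haplotype set and one allele count,
* consecutive MNVs (con-MNVs): an older substitution and a younger one that
  arose later on a subset of the older variant's haplotypes, including the
  CpG-creation pathway (e.g. CA > CG > TG) with configurable temporal
  ordering,
* de novo SNVs and MNVs in children, absent from both parents, with optional
  "mutator" individuals carrying a multiplied de novo MNV rate.

The cohort is modelled as ``4 * n_trios`` parental haplotypes (two diploid
parents per trio); each child inherits one haplotype from each parent,
uniformly at random, with no recombination inside the simulated CDS --
events are at most 20 bp apart, where recombination is negligible.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from ``CohortConfig.seed``; outputs are byte-identical for a given seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")

#: distance mixture (d=1, d=2, d in 3..20) for simultaneous MNVs
SIM_DISTANCE_MIX = (0.51, 0.12, 0.37)
#: distance mixture for consecutive MNVs
CON_DISTANCE_MIX = (0.10, 0.07, 0.83)
#: fraction of adjacent con-MNVs driven by CpG creation
CON_CPG_FRACTION_1BP = 0.24
#: fraction of trinucleotide MNVs at three adjacent bases
TRINUCLEOTIDE_ADJACENT_FRACTION = 0.128

#: polymerase zeta tandem signatures, both strands: GC>AA / GA>TT and
#: their reverse complements GC>TT / TC>AA
POLZETA_SIGNATURES = (("GC", "AA"), ("GA", "TT"), ("GC", "TT"), ("TC", "AA"))

# CpG-creation con-MNV orientations.  Each entry: planted reference
# dinucleotide, (alt0, alt1), index of the CpG-creating member, relative
# sampling weight.  The creating member mutates first; the other member is
# the subsequent deamination (C>T on one strand).
_CPG_CON_TYPES = (
    ("CA", ("T", "G"), 1, 0.35),   # CA > CG > TG
    ("TG", ("C", "A"), 0, 0.35),   # reverse complement of the above
    ("CC", ("T", "G"), 1, 0.075),  # CC > CG > TG
    ("GG", ("C", "A"), 0, 0.075),
    ("AG", ("C", "A"), 0, 0.075),  # AG > CG > CA
    ("CT", ("T", "G"), 1, 0.075),
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort.

    Rates are per base pair per generation. Defaults mirror the cohort the
    analysis is designed for: an SNV rate of 1.1e-8, a sim-MNV rate of
    1.78e-10 (~1.6% of the SNV rate), 53% of adjacent MNVs being
    simultaneous, a 22% polymerase zeta share of adjacent sim-MNVs, and a
    96% temporal-ordering probability for CpG-creating con-MNVs.
    """

    n_trios: int = 6688
    coding_bp: int = 300_000
    mu_snv: float = 1.1e-8
    mu_mnv: float = 1.78e-10
    sim_fraction_1bp: float = 0.53
    con_cpg_order_prob: float = 0.96
    polzeta_fraction: float = 0.22
    apobec_fraction: float = 0.08
    n_mutator_individuals: int = 0
    seed: int = 0
    # secondary knobs
    mutator_multiplier: float = 10.0
    denovo_polzeta_fraction: float = 0.18
    trinucleotide_fraction: float = 0.0127
    effective_population_size: float = 10_000.0
    denovo_callable_bp: float = 30_000_000.0
    cpg_enrichment: float = 0.02
    default_dp: int = 50
    low_dp_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_trios <= 0:
            raise ValueError("n_trios must be positive")
        if self.coding_bp <= 0 or self.coding_bp % 3:
            raise ValueError("coding_bp must be positive and divisible by 3")
        if self.mu_snv <= 0 or self.mu_mnv <= 0:
            raise ValueError("mutation rates must be > 0")
        for name in ("sim_fraction_1bp", "con_cpg_order_prob",
                     "polzeta_fraction", "apobec_fraction",
                     "trinucleotide_fraction", "denovo_polzeta_fraction",
                     "low_dp_fraction", "cpg_enrichment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_mutator_individuals < 0:
            raise ValueError("n_mutator_individuals must be >= 0")
        if self.n_mutator_individuals > self.n_trios:
            raise ValueError("more mutator individuals than trios")

    @property
    def mu_con_mnv(self) -> float:
        """Consecutive-MNV rate implied by the sim rate and mixtures.

        Chosen so that among adjacent MNVs the simultaneous fraction equals
        ``sim_fraction_1bp`` given the sim/con distance mixtures; with the
        defaults this puts the sim share of all MNVs near 19%.
        """
        sim_d1 = self.mu_mnv * SIM_DISTANCE_MIX[0]
        con_d1 = sim_d1 * (1.0 - self.sim_fraction_1bp) / self.sim_fraction_1bp
        return con_d1 / CON_DISTANCE_MIX[0]

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class SiteRecord:
    """One biallelic SNV record plus its ground-truth provenance."""

    pos: int                     # 1-based
    ref: str
    alt: str
    carriers: np.ndarray         # parental haplotype ids, sorted
    event_id: int
    kind: str                    # snv | sim_mnv | con_mnv | trinucleotide |
                                 # de_novo_snv | de_novo_mnv
    role: int = 0                # member index within the event
    signature: str = ""
    is_older: bool = False       # con-MNVs: temporally first member
    denovo_child: int = -1
    denovo_hap: int = -1         # 0 maternal, 1 paternal


def harmonic_number(m: int) -> float:
    """H_m = sum_{i=1..m} 1/i (the Watterson a_n for n = m + 1)."""
    if m < 1:
        return 0.0
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def sample_sfs_count(n_chromosomes: int, rng: np.random.Generator,
                     size: int | None = None, min_count: int = 1):
    """Draw derived-allele counts from a neutral site-frequency spectrum.

    Returns k in ``[min_count, n_chromosomes - 1]`` with P(k) proportional
    to 1/k, the expected spectrum for neutral segregating sites.
    """
    if n_chromosomes < 2:
        raise ValueError("need at least two chromosomes")
    if not 1 <= min_count <= n_chromosomes - 1:
        raise ValueError("min_count out of range")
    ks = np.arange(min_count, n_chromosomes)
    p = 1.0 / ks
    p /= p.sum()
    out = rng.choice(ks, size=size, p=p)
    return int(out) if size is None else out


class _Placer:
    """Tracks occupied reference positions and plants signature contexts."""

    def __init__(self, reference: np.ndarray, rng: np.random.Generator):
        self.ref = reference
        self.rng = rng
        self.used: set[int] = set()

    def claim(self, span: int, plant: str | None = None,
              margin: int = 3) -> int:
        """Reserve a free window and return its 1-based start position.

        ``span`` is the window width in bp; ``plant`` optionally overwrites
        the reference inside the window.  ``margin`` extra bases on both
        sides are kept variant-free so flanking context stays unambiguous.
        """
        L = len(self.ref)
        for _ in range(10_000):
            start = int(self.rng.integers(margin + 1, L - span - margin))
            window = range(start - margin, start + span + margin)
            if any(p in self.used for p in window):
                continue
            self.used.update(range(start, start + span))
            if plant is not None:
                self.ref[start - 1:start - 1 + span] = list(plant)
            return start
        raise RuntimeError("no free positions left on the reference")


def _make_reference(length: int, cpg_enrichment: float,
                    rng: np.random.Generator) -> np.ndarray:
    seq = rng.choice(BASES, size=length)
    if cpg_enrichment > 0:
        n_plant = rng.poisson(cpg_enrichment * length / 2)
        pos = rng.integers(0, length - 1, size=n_plant)
        seq[pos] = "C"
        seq[pos + 1] = "G"
    return seq


def _sample_distance(mix, rng: np.random.Generator) -> int:
    u = rng.random()
    if u < mix[0]:
        return 1
    if u < mix[0] + mix[1]:
        return 2
    return int(rng.integers(3, 21))


def _random_alt(ref_base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != ref_base]
    return choices[int(rng.integers(0, 3))]


class Cohort:
    """In-memory synthetic cohort: reference, sites, pedigree structure."""

    def __init__(self, config: CohortConfig, reference: np.ndarray,
                 sites: list[SiteRecord], child_mat: np.ndarray,
                 child_pat: np.ndarray, mutator_children: np.ndarray):
        self.config = config
        self.reference = reference
        self.sites = sorted(sites, key=lambda s: s.pos)
        self.child_mat = child_mat     # 0/1: which maternal haplotype
        self.child_pat = child_pat
        self.mutator_children = mutator_children
        self.chrom = "chr1"

    # ---- pedigree -------------------------------------------------------
    @property
    def n_trios(self) -> int:
        return self.config.n_trios

    def sample_names(self) -> list[str]:
        out = []
        for i in range(self.n_trios):
            out += [f"t{i:05d}_c", f"t{i:05d}_m", f"t{i:05d}_f"]
        return out

    # ---- genotypes ------------------------------------------------------
    def dosages(self, site: SiteRecord):
        """Per-trio diploid dosages ``(child, mother, father)``.

        Maternal haplotypes of trio *i* are ids ``4i`` and ``4i+1``,
        paternal ``4i+2`` and ``4i+3``.
        """
        n = self.n_trios
        hap = np.zeros(4 * n, dtype=np.int8)
        hap[site.carriers] = 1
        h = hap.reshape(n, 4)
        mother = h[:, 0] + h[:, 1]
        father = h[:, 2] + h[:, 3]
        idx = np.arange(n)
        child = h[idx, self.child_mat] + h[idx, 2 + self.child_pat]
        if site.denovo_child >= 0:
            child = child.copy()
            child[site.denovo_child] += 1
        return child, mother, father

    def allele_count(self, site: SiteRecord) -> int:
        """Alt allele count over all emitted genotypes (AC in the VCF)."""
        c, m, f = self.dosages(site)
        return int(c.sum() + m.sum() + f.sum())

    # ---- truth tables ---------------------------------------------------
    def truth_variants(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(dict(
                chrom=self.chrom, pos=s.pos, ref=s.ref, alt=s.alt,
                event_id=s.event_id, kind=s.kind, role=s.role,
                signature=s.signature, n_carrier_haps=len(s.carriers),
                allele_count=self.allele_count(s),
                is_older=int(s.is_older),
                child=(f"t{s.denovo_child:05d}_c" if s.denovo_child >= 0
                       else ""),
                haplotype=("maternal" if s.denovo_hap == 0 else
                           "paternal" if s.denovo_hap == 1 else ""),
            ))
        return pd.DataFrame(rows)

    def truth_events(self) -> pd.DataFrame:
        var = self.truth_variants().sort_values(["event_id", "pos"])
        var["pos_str"] = var["pos"].astype(str)
        var["ac_str"] = var["allele_count"].astype(str)
        g = var.groupby("event_id", sort=True)
        out = pd.DataFrame({
            "kind": g["kind"].first(),
            "positions": g["pos_str"].agg(";".join),
            "ref": g["ref"].agg(";".join),
            "alt": g["alt"].agg(";".join),
            "distance": g["pos"].last() - g["pos"].first(),
            "signature": g["signature"].first(),
            "allele_counts": g["ac_str"].agg(";".join),
            "child": g["child"].first(),
            "haplotype": g["haplotype"].first(),
        })
        older = (var.loc[var["is_older"] == 1]
                 .groupby("event_id")["pos"].first())
        out["older_pos"] = older.reindex(out.index).fillna(-1).astype(int)
        return out.reset_index()

    def denovo_table(self) -> pd.DataFrame:
        """De novo candidate table (child, chrom, pos, ref, alt, evidence).

        The evidence column carries the truth haplotype label, standing in
        for external read-backed phase evidence.
        """
        rows = []
        for s in self.sites:
            if s.denovo_child < 0:
                continue
            rows.append(dict(
                child=f"t{s.denovo_child:05d}_c", chrom=self.chrom,
                pos=s.pos, ref=s.ref, alt=s.alt,
                evidence=("maternal" if s.denovo_hap == 0 else "paternal"),
            ))
        return pd.DataFrame(
            rows, columns=["child", "chrom", "pos", "ref", "alt", "evidence"]
        ).sort_values(["child", "pos"]).reset_index(drop=True)

    # ---- in-memory bridge to discovery ---------------------------------
    def to_variants(self):
        """Sites as :class:`mnvkit.discovery.Variant` objects (VCF-free).

        Genotype columns follow :meth:`sample_names` order; depth is the
        configured default everywhere (low-DP injection applies only to
        written VCFs).
        """
        from .discovery import Variant

        out = []
        for s in self.sites:
            child, mother, father = self.dosages(s)
            gt = np.empty(3 * self.n_trios, dtype=np.int16)
            gt[0::3], gt[1::3], gt[2::3] = child, mother, father
            dp = np.full(gt.size, self.config.default_dp, dtype=np.int32)
            out.append(Variant(self.chrom, s.pos, s.ref, s.alt,
                               int(gt.sum()), gt, dp))
        return out

    def pedigree(self):
        from .discovery import Pedigree

        trios = [(3 * i, 3 * i + 1, 3 * i + 2)
                 for i in range(self.n_trios)]
        return Pedigree(samples=self.sample_names(), trios=trios)

    # ---- writers --------------------------------------------------------
    def write_vcf(self, path: str) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 987_654_321)  # DP noise only
        samples = self.sample_names()
        an = 2 * len(samples)
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={self.chrom},length={cfg.coding_bp}>\n")
            fh.write('##INFO=<ID=AC,Number=A,Type=Integer,'
                     'Description="Alt allele count">\n')
            fh.write('##INFO=<ID=AN,Number=1,Type=Integer,'
                     'Description="Total alleles">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                     'Description="Read depth">\n')
            fh.write(f"##mnvkit_seed={cfg.seed}\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            for s in self.sites:
                child, mother, father = self.dosages(s)
                ac = int(child.sum() + mother.sum() + father.sum())
                dp = cfg.default_dp
                if cfg.low_dp_fraction and rng.random() < cfg.low_dp_fraction:
                    dp = 10
                cells = []
                for i in range(self.n_trios):
                    for g in (child[i], mother[i], father[i]):
                        cells.append(f"{gt_str[int(g)]}:{dp}")
                fh.write(f"{self.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t"
                         f"PASS\tAC={ac};AN={an}\tGT:DP\t"
                         + "\t".join(cells) + "\n")

    def write_fasta(self, path: str) -> None:
        seq = "".join(self.reference)
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    def write_pedigree(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("child\tmother\tfather\n")
            for i in range(self.n_trios):
                fh.write(f"t{i:05d}_c\tt{i:05d}_m\tt{i:05d}_f\n")


# ---------------------------------------------------------------------------
# event placement

def place_sim_mnv(placer: _Placer, n_hap: int, distance: int,
                  signature_key: tuple[str, str] | None,
                  rng: np.random.Generator, event_id: int,
                  kind: str = "sim_mnv") -> list[SiteRecord]:
    """Place one simultaneous MNV: two substitutions, one carrier set.

    ``signature_key`` is an optional (ref, alt) pair of the two mutated
    bases (e.g. ``("GC", "AA")``); the reference is planted to match.
    """
    if not 1 <= distance <= 20:
        raise ValueError("distance must lie in [1, 20]")
    span = distance + 1
    if signature_key is not None:
        r, a = signature_key
        plant = r if distance == 1 else None
        pos = placer.claim(span, plant=plant)
        if distance > 1:
            placer.ref[pos - 1] = r[0]
            placer.ref[pos - 1 + distance] = r[1]
        refs, alts = (r[0], r[1]), (a[0], a[1])
    else:
        pos = placer.claim(span)
        r0 = str(placer.ref[pos - 1])
        r1 = str(placer.ref[pos - 1 + distance])
        refs, alts = (r0, r1), (_random_alt(r0, rng), _random_alt(r1, rng))
    k = sample_sfs_count(n_hap, rng)
    carriers = np.sort(rng.choice(n_hap, size=k, replace=False))
    sig = f"{signature_key[0]}>{signature_key[1]}" if signature_key else ""
    return [
        SiteRecord(pos + j * distance, refs[j], alts[j], carriers,
                   event_id, kind, role=j, signature=sig)
        for j in (0, 1)
    ]


def place_con_mnv_cpg(placer: _Placer, n_hap: int, order_prob: float,
                      rng: np.random.Generator,
                      event_id: int) -> list[SiteRecord]:
    """Place a CpG-creating consecutive MNV at adjacent bases.

    The CpG-creating substitution happens first; the deamination (C>T on
    one strand) follows on a subset of its haplotypes, so the creator's
    allele count is strictly greater.  With probability ``1 - order_prob``
    the roles are swapped, emulating the minority of events where the
    deamination-like member is in fact the older variant.
    """
    weights = np.array([t[3] for t in _CPG_CON_TYPES])
    idx = rng.choice(len(_CPG_CON_TYPES), p=weights / weights.sum())
    ref2, alts, creator_idx, _ = _CPG_CON_TYPES[idx]
    pos = placer.claim(2, plant=ref2)
    k_old = sample_sfs_count(n_hap, rng, min_count=2)
    k_young = int(rng.integers(1, k_old))
    old_carriers = np.sort(rng.choice(n_hap, size=k_old, replace=False))
    young_carriers = np.sort(rng.choice(old_carriers, size=k_young,
                                        replace=False))
    older_idx = creator_idx if rng.random() < order_prob else 1 - creator_idx
    sig = f"{ref2}>{alts[0]}{alts[1]}"
    sites = []
    for j in (0, 1):
        carriers = old_carriers if j == older_idx else young_carriers
        sites.append(SiteRecord(pos + j, ref2[j], alts[j], carriers,
                                event_id, "con_mnv", role=j, signature=sig,
                                is_older=(j == older_idx)))
    return sites


def place_con_mnv_random(placer: _Placer, n_hap: int, distance: int,
                         rng: np.random.Generator,
                         event_id: int) -> list[SiteRecord]:
    """Place a non-CpG consecutive MNV: younger nested in older carriers."""
    span = distance + 1
    pos = placer.claim(span)
    r0 = str(placer.ref[pos - 1])
    r1 = str(placer.ref[pos - 1 + distance])
    a0, a1 = _random_alt(r0, rng), _random_alt(r1, rng)
    k_old = sample_sfs_count(n_hap, rng, min_count=2)
    k_young = int(rng.integers(1, k_old))
    old_carriers = np.sort(rng.choice(n_hap, size=k_old, replace=False))
    young_carriers = np.sort(rng.choice(old_carriers, size=k_young,
                                        replace=False))
    older_idx = int(rng.integers(0, 2))
    refs, alts = (r0, r1), (a0, a1)
    sites = []
    for j in (0, 1):
        carriers = old_carriers if j == older_idx else young_carriers
        sites.append(SiteRecord(pos + j * distance, refs[j], alts[j],
                                carriers, event_id, "con_mnv", role=j,
                                is_older=(j == older_idx)))
    return sites


def place_trinucleotide(placer: _Placer, n_hap: int, adjacent: bool,
                        rng: np.random.Generator,
                        event_id: int) -> list[SiteRecord]:
    """Three same-haplotype substitutions, pairwise within 20 bp."""
    if adjacent:
        plant = "AAA" if rng.random() < 0.5 else "TTT"
        pos = placer.claim(3, plant=plant)
        offsets = (0, 1, 2)
        refs = tuple(plant)
        alts = tuple("TTT" if plant == "AAA" else "AAA")
    else:
        d1 = int(rng.integers(1, 10))
        d2 = int(rng.integers(1, 10))
        offsets = (0, d1, d1 + d2)
        pos = placer.claim(offsets[-1] + 1)
        refs = tuple(str(placer.ref[pos - 1 + o]) for o in offsets)
        alts = tuple(_random_alt(r, rng) for r in refs)
    k = sample_sfs_count(n_hap, rng)
    carriers = np.sort(rng.choice(n_hap, size=k, replace=False))
    return [
        SiteRecord(pos + o, refs[j], alts[j], carriers, event_id,
                   "trinucleotide", role=j)
        for j, o in enumerate(offsets)
    ]


def generate_de_novos(placer: _Placer, child: int, lam_snv: float,
                      lam_mnv: float, cfg: CohortConfig,
                      rng: np.random.Generator,
                      next_event_id: int) -> tuple[list[SiteRecord], int]:
    """De novo SNVs and sim-MNVs for one child.

    Counts are Poisson with the given per-child means; every de novo MNV
    places both members on the same child haplotype and neither parent
    carries them.
    """
    sites: list[SiteRecord] = []
    eid = next_event_id
    for _ in range(rng.poisson(lam_snv)):
        pos = placer.claim(1)
        r = str(placer.ref[pos - 1])
        sites.append(SiteRecord(pos, r, _random_alt(r, rng),
                                np.empty(0, dtype=int), eid, "de_novo_snv",
                                denovo_child=child,
                                denovo_hap=int(rng.integers(0, 2))))
        eid += 1
    for _ in range(rng.poisson(lam_mnv)):
        d = _sample_distance(SIM_DISTANCE_MIX, rng)
        sig = None
        if d == 1 and rng.random() < cfg.denovo_polzeta_fraction:
            sig = POLZETA_SIGNATURES[int(rng.integers(0, 4))]
        hap = int(rng.integers(0, 2))
        if sig is not None:
            span = d + 1
            pos = placer.claim(span, plant=sig[0])
            refs, alts = sig[0], sig[1]
        else:
            pos = placer.claim(d + 1)
            refs = str(placer.ref[pos - 1]) + str(placer.ref[pos - 1 + d])
            alts = "".join(_random_alt(r, rng) for r in refs)
        for j in (0, 1):
            sites.append(SiteRecord(pos + j * d, refs[j], alts[j],
                                    np.empty(0, dtype=int), eid,
                                    "de_novo_mnv", role=j,
                                    signature=(f"{refs}>{alts}" if sig else ""),
                                    denovo_child=child, denovo_hap=hap))
        eid += 1
    return sites, eid


# ---------------------------------------------------------------------------
# whole-cohort simulation

def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort in memory.

    Segregating event counts follow Watterson's expectation
    ``E[K] = 4 N_e mu L a_n`` with ``n = 4 n_trios`` parental chromosomes,
    so the ratio of MNV to SNV segregating sites recovers the rate ratio.
    De novo counts per child are Poisson with mean ``2 mu callable_bp``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_hap = 4 * cfg.n_trios
    a_n = harmonic_number(n_hap - 1)
    scale = 4.0 * cfg.effective_population_size * a_n * cfg.coding_bp

    ref = _make_reference(cfg.coding_bp, cfg.cpg_enrichment, rng)
    placer = _Placer(ref, rng)
    sites: list[SiteRecord] = []
    eid = 0

    # segregating SNVs
    for _ in range(rng.poisson(scale * cfg.mu_snv)):
        pos = placer.claim(1)
        r = str(ref[pos - 1])
        k = sample_sfs_count(n_hap, rng)
        carriers = np.sort(rng.choice(n_hap, size=k, replace=False))
        sites.append(SiteRecord(pos, r, _random_alt(r, rng), carriers,
                                eid, "snv"))
        eid += 1

    # simultaneous MNVs
    for _ in range(rng.poisson(scale * cfg.mu_mnv)):
        d = _sample_distance(SIM_DISTANCE_MIX, rng)
        sig = None
        if d == 1 and rng.random() < cfg.polzeta_fraction:
            sig = POLZETA_SIGNATURES[int(rng.integers(0, 4))]
        elif d == 2 and rng.random() < cfg.apobec_fraction:
            # APOBEC: CnC>TnT in a TCTC/CCTC context (or reverse strand)
            lead = "T" if rng.random() < 0.5 else "C"
            carriers = np.sort(rng.choice(
                n_hap, size=sample_sfs_count(n_hap, rng), replace=False))
            if rng.random() < 0.5:
                pos = placer.claim(4, plant=lead + "CTC")
                members = ((pos + 1, "C", "T"), (pos + 3, "C", "T"))
            else:
                pos = placer.claim(4, plant=revcomp(lead + "CTC"))
                members = ((pos, "G", "A"), (pos + 2, "G", "A"))
            for j, (p, r, a) in enumerate(members):
                sites.append(SiteRecord(p, r, a, carriers, eid, "sim_mnv",
                                        role=j, signature="CnC>TnT"))
            eid += 1
            continue
        sites += place_sim_mnv(placer, n_hap, d, sig, rng, eid)
        eid += 1

    # consecutive MNVs
    for _ in range(rng.poisson(scale * cfg.mu_con_mnv)):
        d = _sample_distance(CON_DISTANCE_MIX, rng)
        if d == 1 and rng.random() < CON_CPG_FRACTION_1BP:
            sites += place_con_mnv_cpg(placer, n_hap, cfg.con_cpg_order_prob,
                                       rng, eid)
        else:
            sites += place_con_mnv_random(placer, n_hap, d, rng, eid)
        eid += 1

    # trinucleotide MNVs
    for _ in range(rng.poisson(scale * cfg.mu_mnv
                               * cfg.trinucleotide_fraction)):
        adjacent = rng.random() < TRINUCLEOTIDE_ADJACENT_FRACTION
        sites += place_trinucleotide(placer, n_hap, adjacent, rng, eid)
        eid += 1

    # pedigree structure and de novos
    child_mat = rng.integers(0, 2, size=cfg.n_trios)
    child_pat = rng.integers(0, 2, size=cfg.n_trios)
    mutators = (np.sort(rng.choice(cfg.n_trios, cfg.n_mutator_individuals,
                                   replace=False))
                if cfg.n_mutator_individuals else np.empty(0, dtype=int))
    lam_snv = 2.0 * cfg.mu_snv * cfg.denovo_callable_bp
    lam_mnv0 = 2.0 * cfg.mu_mnv * cfg.denovo_callable_bp
    mut = set(mutators.tolist())
    for child in range(cfg.n_trios):
        lam_mnv = lam_mnv0 * (cfg.mutator_multiplier if child in mut else 1.0)
        new, eid = generate_de_novos(placer, child, lam_snv, lam_mnv, cfg,
                                     rng, eid)
        sites += new

    return Cohort(cfg, ref, sites, child_mat, child_pat, mutators)


def write_cohort(config: CohortConfig, out_dir: str) -> dict[str, str]:
    """Simulate and write VCF, reference FASTA, pedigree and truth tables.

    Deterministic: the same config (including seed) yields byte-identical
    files.
    """
    cohort = simulate_cohort(config)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "fasta": os.path.join(out_dir, "reference.fa"),
        "pedigree": os.path.join(out_dir, "pedigree.tsv"),
        "truth_variants": os.path.join(out_dir, "truth_variants.tsv"),
        "truth_events": os.path.join(out_dir, "truth_events.tsv"),
        "denovo": os.path.join(out_dir, "denovo.tsv"),
        "config": os.path.join(out_dir, "config.yaml"),
    }
    cohort.write_vcf(paths["vcf"])
    cohort.write_fasta(paths["fasta"])
    cohort.write_pedigree(paths["pedigree"])
    cohort.truth_variants().to_csv(paths["truth_variants"], sep="\t",
                                   index=False)
    cohort.truth_events().to_csv(paths["truth_events"], sep="\t", index=False)
    cohort.denovo_table().to_csv(paths["denovo"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# independent-pair phasing experiment

def independent_pair_same_haplotype(n_trios: int, n_pairs: int,
                                    min_dist: int = 15, max_dist: int = 20,
                                    seed: int = 0,
                                    require_different_ac: bool = True):
    """Fraction of independently placed variant pairs phasing together.

    Places ``n_pairs`` pairs of segregating variants ``min_dist..max_dist``
    bp apart on random parental haplotypes of an ``n_trios`` cohort, with
    each member drawn independently from the neutral spectrum, then
    trio-phases both sites in every carrier child that is heterozygous at
    both.  Because the two variants are unlinked by construction, each
    phase-determined carrier lands on the same haplotype with probability
    1/2 -- the asymptote expected for consecutive (different allele
    frequency) variant pairs.

    Returns ``(fraction_same, n_same, n_phaseable)``.
    """
    from . import discovery

    rng = np.random.default_rng(seed)
    n_hap = 4 * n_trios
    child_mat = rng.integers(0, 2, size=n_trios)
    child_pat = rng.integers(0, 2, size=n_trios)
    idx = np.arange(n_trios)
    n_same = 0
    n_det = 0
    made = 0
    while made < n_pairs:
        k1 = sample_sfs_count(n_hap, rng)
        k2 = sample_sfs_count(n_hap, rng)
        if require_different_ac and k1 == k2:
            continue
        made += 1
        dosages = []
        for k in (k1, k2):
            hap = np.zeros(n_hap, dtype=np.int8)
            hap[rng.choice(n_hap, size=k, replace=False)] = 1
            h = hap.reshape(n_trios, 4)
            mother = h[:, 0] + h[:, 1]
            father = h[:, 2] + h[:, 3]
            child = h[idx, child_mat] + h[idx, 2 + child_pat]
            dosages.append((child, mother, father))
        (c1, m1, f1), (c2, m2, f2) = dosages
        both_het = np.flatnonzero((c1 == 1) & (c2 == 1))
        for t in both_het:
            o1 = discovery.phase_site_in_trio(int(c1[t]), int(m1[t]),
                                              int(f1[t]))
            o2 = discovery.phase_site_in_trio(int(c2[t]), int(m2[t]),
                                              int(f2[t]))
            verdict = discovery.pair_same_haplotype(o1, o2)
            if verdict == "same":
                n_same += 1
                n_det += 1
            elif verdict == "different":
                n_det += 1
    frac = n_same / n_det if n_det else float("nan")
    return frac, n_same, n_det
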