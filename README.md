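# mnvkit

Discovery, classification and population-genetic analysis of
**multinucleotide variants (MNVs)** — pairs (or triples) of single-nucleotide
variants that sit on one haplotype within a short distance (≤ 20 bp) — from
parent–offspring trio exome cohorts.

MNVs matter because standard pipelines annotate their member SNVs
separately, which can mis-state the protein consequence (two substitutions
inside one codon must be translated jointly: `CGG` with `C>T` and `G>A`
separately reads as missense + synonymous, jointly as the stop codon `TGA`),
and because an intra-codon MNV can reach amino acids no single-base change
can ("two-step" missense), which are on average more physicochemically
divergent and more deleterious.

`mnvkit` is a library for geneticists working with trio cohorts and for
methodologists studying clustered mutation. It provides:

* **`mnvkit.simulate`** — a synthetic trio cohort generator with full MNV
  ground truth: neutral-spectrum segregating SNVs on parental haplotypes,
  simultaneous MNVs (one mutational event, one shared allele count),
  consecutive MNVs with CpG-creation temporal ordering (CA > CG > TG),
  de novo events, and optional mutator individuals.
* **`mnvkit.discovery`** — trio-phasing MNV calling: candidate heterozygous
  pairs within 100 bp at read depth ≥ 20 are called MNVs when they phase to
  the same child haplotype in > 99 % of phase-determined carrier trios;
  identical cohort allele counts classify a call *sim* (simultaneous),
  different counts *con* (consecutive).
* **`mnvkit.spectra`** — strand-collapsed substitution spectra and signature
  tests: polymerase ζ (GC→AA / GA→TT tandem errors), APOBEC deamination
  motifs (TpC/CpC), CpG-creation ordering, heptanucleotide mutability shift.
* **`mnvkit.codons`** — joint codon-level consequence annotation;
  one-step / two-step / exclusive-SNV missense classification; a packaged
  20×20 physicochemical distance matrix built from five MDS-derived
  amino-acid descriptors.
* **`mnvkit.selection`** — constraint depletion (pLI ≥ 0.9), singleton
  proportions with Wilson CIs, median score comparisons with bootstrap CIs.
* **`mnvkit.rates`** — the Watterson rearrangement
  `μ_MNV = (K_MNV / K_SNV) · μ_SNV` (the unknown `4 N_e a_n` cancels in the
  segregating-site ratio), de novo rate estimates with exact Poisson CIs,
  exact Poisson enrichment/depletion tests (minlik and tail-doubling
  conventions), and the mutator-phenotype binomial tail.

## Worked example

```bash
python examples/discover_mnvs.py
```

```
candidate het pairs within 100 bp : 239
MNVs called (<=20 bp, >99% same)  : 45

calls by class and distance stratum:
mnv_class  stratum
con        d1          5
           d2          2
           d3_20      32
sim        d1          4
           d3_20       2

injected sim-MNV events: 6; called sim: 6
```

Every injected simultaneous MNV with a phase-determined carrier is
recovered; consecutive MNVs dominate the longer distance strata, as in real
cohorts. The rate machinery reproduces the published arithmetic exactly
(`python examples/rates_and_enrichment.py`):

```
sim-MNV mutation rate: 1.78e-10 per bp per generation (1.6% of the SNV rate)
de novo MNV enrichment: 10 observed vs 2.70 expected = 3.7-fold, p = 1.01e-03
reported pathogenic missense MNVs: 24 observed vs 51.94 expected, depletion p = 2.8e-05
```

and the codon combinatorics (`python examples/codon_consequences.py`) show
that for histidine `CAC` a single-base change reaches 7 amino acids, a
two-base change reaches 10 more that no SNV can, and the median
physicochemical distance ranks two-step > one-step > exclusive-SNV
(0.708 > 0.662 > 0.604).

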