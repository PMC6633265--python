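# Methods

## The analysis

A multinucleotide variant (MNV) is defined operationally: two heterozygous
SNVs within 20 bp that appear on the same haplotype in more than 99 % of the
individuals in which both are phase-determined. Phasing is trio-based:
at a site where the child is heterozygous, the parent of origin of the alt
allele is determined whenever exactly one transmission scenario is
Mendelian-consistent (both parents heterozygous, apparent de novo alleles,
missing genotypes and inconsistencies are all *undetermined* and count
toward neither numerator nor denominator). Two nearby variants transmitted
by the same parent necessarily sit on the same child haplotype, because
recombination between sites ≤ 100 bp apart is negligible.

MNV calls split by the cohort allele counts of their members:

* **sim** — identical integer allele counts: the two variants have always
  co-occurred, so they almost certainly arose in a single mutational event;
* **con** — different counts: one variant arose first, the second later on a
  haplotype already carrying the first, so the older member is the more
  frequent and the younger member's carriers are a subset of the older's.

"Identical allele frequencies" is operationalised as identical integer
cohort allele counts (AC), not floating AF: counts are what a cohort VCF
records, and integer equality avoids denominator noise.

Downstream, the package computes substitution spectra with strand-collapsed
keys, joint codon-level consequences, selection metrics per variant class,
and two independent mutation-rate estimates with a Poisson testing suite.

## Synthetic cohorts

Real trio cohorts of this kind are access-controlled, so the package ships
a generator that emulates the statistical structure the analysis assumes.
A cohort of `n_trios` families is modelled as `4 n_trios` parental
haplotypes (two diploid parents each); every child inherits one haplotype
per parent uniformly at random, with **no recombination** inside the
simulated CDS — events of interest are ≤ 20 bp apart, where crossover
probability per generation is ~10⁻⁷.

Segregating events are placed as follows:

* event counts follow Watterson's expectation `E[K] = 4 N_e μ L a_n` with
  `a_n` the (n−1)th harmonic number of the parental chromosome count, so
  the ratio of MNV to SNV segregating sites recovers the rate ratio by
  construction;
* each event's derived-allele count is drawn from the neutral spectrum
  `P(k) ∝ 1/k`, and assigned to that many random parental haplotypes;
* sim-MNVs place both substitutions on one carrier set; con-MNVs draw the
  older member's count `k_old ≥ 2`, the younger's uniformly in
  `[1, k_old − 1]`, and nest the younger's carriers inside the older's;
* CpG-creating con-MNVs (CA>TG, CC>TG, AG>CA and reverse complements) put
  the CpG-creating substitution first with probability
  `con_cpg_order_prob`; the reference is locally overwritten ("planted") so
  signature events have the sequence context they claim;
* de novo counts per child are Poisson with mean `2 μ · callable_bp`
  (optionally multiplied for designated mutator children); members of a
  de novo MNV share one child haplotype and are absent from both parents.

The reference sequence is i.i.d. uniform over A/C/G/T with a small CpG
enrichment knob; it is not a real ORF, so in-frame stop codons occur and
codon-level annotation of synthetic calls includes occasional
stop-lost/stop-retained classes — harmless for the statistics tested.

### Defaults (per bp per generation unless noted)

| parameter | default | rationale |
|---|---|---|
| `mu_snv` | 1.1 × 10⁻⁸ | consensus germline SNV rate; sensitivity presets 1.0/1.2 × 10⁻⁸ |
| `mu_mnv` | 1.78 × 10⁻¹⁰ | simultaneous-MNV rate, ~1.6 % of the SNV rate |
| `sim_fraction_1bp` | 0.53 | share of adjacent MNVs that are simultaneous |
| sim distance mix | 0.51 / 0.12 / 0.37 | d = 1 / 2 / 3–20 shares among sim-MNVs |
| con distance mix | 0.10 / 0.07 / 0.83 | same for consecutive MNVs |
| `con_cpg_order_prob` | 0.96 | fraction of CpG-creating con-MNVs in creation order |
| `polzeta_fraction` | 0.22 | polymerase ζ share of adjacent sim-MNVs (`denovo_polzeta_fraction` 0.18 for de novo) |
| `apobec_fraction` | 0.08 | CnC>TnT share of 2-bp sim-MNVs |
| `trinucleotide_fraction` | 0.0127 | trinucleotide events relative to sim pairs (12.8 % adjacent) |
| `n_trios` | 6688 | cohort size of the study design emulated; tests use smaller cohorts |
| `coding_bp` | 300 000 | simulated CDS width; a free problem-size parameter |
| `denovo_callable_bp` | 3 × 10⁷ | exome-scale de novo exposure (see below) |
| `effective_population_size` | 10 000 | sets segregating-site density via `4 N_e μ L a_n` |

The consecutive-MNV rate is not a free knob: it is derived from `mu_mnv`,
`sim_fraction_1bp` and the two distance mixes, which makes the sim share of
all MNVs come out near one-fifth — internally consistent with the other
defaults.

De novo event counts use a separate exposure, `denovo_callable_bp`, rather
than the simulated CDS width: at realistic rates a desk-scale CDS would
essentially never produce a de novo MNV, while the de novo *rate estimator*
divides by the same exposure, so the estimate is unbiased regardless of the
value chosen. Events are placed uniformly on the simulated CDS.

### What the generator does not emulate

Sequencing error, genotyping error, indels, multi-allelic sites,
recombination, linkage disequilibrium beyond exact co-segregation,
population structure, X-chromosome inheritance, and selection (all sites
are neutral-frequency). Passing tests therefore demonstrate correctness of
the *inference machinery* under the stated model, not robustness to
real-data artefacts; the DP ≥ 20 filter is exercised via an explicit
low-depth injection option rather than a read-level error model.

## Rate estimation

**Segregating-site scaling.** From Watterson's estimator
`θ̂ = K / a_n = 4 N_e μ`, the unknown `4 N_e a_n` cancels between two
variant classes ascertained identically in one cohort, leaving
`μ_MNV = (K_MNV / K_SNV) · μ_SNV`. The package counts `K_MNV` as called
two-variant sim-MNVs and `K_SNV` as SNV sites under the same
ascertainment — at least one phase-determined heterozygous carrier child
with adequate depth — excluding member sites of any called MNV (one
mutational event is never counted in both classes) and excluding the three
sub-pairs of a trinucleotide MNV (a separate variant class, tallied by its
own routine). With matched ascertainment the transmission and phasing
losses of numerator and denominator cancel: on 20 replicate 400-trio
cohorts the estimator recovers the configured rate with no detectable bias.

**De novo counting.** `rate = n_events / (2 · n_trios · callable_bp)` with
a Garwood (exact chi-square) Poisson CI on the count, transformed to the
rate scale.

## Poisson testing

Both exact two-sided conventions are implemented because published
"Poisson test" p-values are reproducible only jointly: **minlik** (the sum
of probabilities of all outcomes whose density does not exceed the observed
one, within relative tolerance 1 + 10⁻⁷ — the R `poisson.test` convention)
reproduces the reported-variant depletion value 2.8 × 10⁻⁵ at
(24, 51.94), while **tail-doubling** reproduces the de novo enrichment
value 1.0 × 10⁻³ at (10, 10/3.7). Neither is asserted as "the" method;
enrichment defaults to doubling, depletion to minlik. Note that
`minlik ≤ 2 × one-sided` can fail at density ties (e.g. observed 0,
expected 1 gives minlik = 1.0), which R shares; the property tests allow
the tie mass explicitly. The enrichment family uses a Bonferroni threshold
of 0.05/12 (three gene sets × four consequence classes).

The de novo enrichment expectation `λ = μ · 2 · n_trios · gene_bp` accepts
a context-correction factor — the fold-excess of polymerase ζ dinucleotide
contexts (GC/GA/TC) in the tested gene set — which rescales λ and hence the
fold exactly.

## Codon-level classification

Translation uses the standard genetic code only (autosomal exome analysis).
For an intra-codon double substitution, the step class is decided by
*amino-acid reachability*, not the codon path: the change is one-step iff
the resulting amino acid is also in the codon's single-substitution
missense set. The three classes per codon — exclusive-SNV (one-step only),
one-step (reachable both ways), two-step (two-substitution only) — exclude
the reference amino acid and stops throughout.

The packaged distance matrix is the Euclidean distance between
five-dimensional amino-acid descriptors obtained by multidimensional
scaling of 237 physicochemical properties, shipped as a TSV so an
alternative (e.g. Grantham) can be swapped in. Distance distributions over
all 61 sense codons default to one entry per (codon, distinct reachable
amino acid); path-weighted enumeration (one entry per substitution path) is
available, and the two-step > one-step median ordering holds under both.
Unpaired distribution comparisons use the two-sided rank-sum test; the
signed-rank test is reserved for the genuinely paired heptanucleotide
mutability-shift analysis.

MNVs spanning two codons are annotated by applying both substitutions to
the transcript CDS and diffing codon-by-codon; the reported joint class is
the most severe, under the severity order
synonymous < missense < stop-gained.

## Numerical and design choices

* Strand collapsing of spectrum keys takes the lexicographically smaller of
  `REF>ALT` and its reverse complement — any fixed deterministic rule
  suffices for counting; placeholders (`n` for one intervening base, `..`
  for more) are preserved.
* The > 99 % same-haplotype threshold is strict: 99/100 fails. The minimum
  number of phase-determined carriers defaults to 1.
* Two-proportion comparisons use Fisher's exact test whenever any expected
  cell is below 5, else the normal-approximation test.
* All proportions carry Wilson score intervals (the score-test inversion).
* The singleton-proportion-to-score inverse lookup first applies isotonic
  regression (proportions need not be monotone in the score bins), then
  piecewise-linear interpolation; out-of-range queries return the boundary
  score with a warning.
* The 0.97 missense-given-intra-codon constant of the reported-variant
  expectation model is an empirical constant supplied to the model, not
  derived from codon-table enumeration (uniform enumeration gives a
  different number and must not silently replace it).
* All generator randomness flows from one seeded `numpy` generator; written
  cohorts are byte-identical for a given configuration, and the seed is
  recorded in the VCF header.

## Problem sizes used by the test-suite and acceptance script

Unit tests run on cohorts of 20–300 trios and CDS widths of 30–150 kb;
signature-fraction checks widen the CDS to 6–9 Mb so spectra hold a few
hundred events; the rate-recovery experiment uses 20 replicate cohorts of
400 trios × 1 Mb; the phasing-asymptote experiment uses 1,000–1,200 trios
and 2,000–2,500 independent variant pairs. These sizes give the Monte Carlo
tolerances quoted in each test (typically three standard errors) while the
whole suite completes in well under a minute.

## Known limitations

* Phase is inferred from parental genotypes only; read-backed phasing and
  BAM-level evidence are out of scope (de novo MNV haplotype support is an
  abstract evidence column — the truth haplotype in synthetic mode).
* Transcript handling takes the first overlapping CDS; no splice/UTR logic,
  no transcript selection policy, no alternate genetic codes.
* pLI and deleteriousness scores are consumed as annotations, never
  computed.
* The con-MNV generative model plants consecutive events directly rather
  than deriving them from the SNV process, so con-MNV *rates* are a
  modelling convenience (their internal structure — nesting, ordering,
  spectra — is what the analyses consume).
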