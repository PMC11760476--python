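# Methods

## Classification model

The package infers whole-genome ploidy of a blastocyst biopsy from three
per-marker quantities of a SNP beadchip assay: the genotype call
(AA/AB/BB/NC), the B-allele frequency (BAF — the fraction of signal
attributable to the B allele) and the log R ratio (LRR — log-scaled total
intensity relative to a diploid reference, a copy-number proxy).

**Heterozygosity (AB) rate.** For 0PN/1PN samples the statistic is the
fraction of called markers genotyped AB, over all chromosomes by default
(`scope` makes autosome-only available). A haploid genome has no true
heterozygotes, so its apparent AB rate equals roughly half the mis-call
rate (a mis-call replaces a genotype with one of the two wrong genotypes
uniformly, so about half of the mis-calls on a homozygous background land
on AB). With the platform noise floor at 5% mis-calls, the haploid bound
is `ab_rate <= 0.05`; diploids on an informative-marker chip sit near
2·E[p(1−p)] ≈ 0.4 and the diploid bound is `ab_rate >= 0.18`. Both
comparisons are inclusive, exactly as the thresholds are stated; the open
interval between them is reported as `indeterminate` and never coerced.

**3PN decision tree.** Routing is by chrY signal: `y_homozygosity` is true
iff at least `y_min_called` (default 10) chrY markers are called and at
least `y_hom_min_fraction` (default 0.80) of them are homozygous. The
called-count floor protects against stray calls in Y-less samples; the
homozygous-fraction test protects against residual cross-hybridization
noise (true single-copy Y markers can only be called homozygous, up to
mis-calls).

- Y-homozygous samples are tested for 69XXY by the chrX mean LRR (the
  arithmetic mean over non-missing chrX LRR): values at or below the
  one-copy bound mean one X (46XY), at or above the two-copy bound two X
  (69XXY), strictly between the bounds `indeterminate`. The bounds are the
  euploid-library extrema — max over 46XY samples and min over 46XX
  samples — and `calibrate_x_lrr` fails loudly if the two distributions
  overlap. The shipped defaults are the published operating points
  −1.0750221 / −1.0396700.
- All other samples are tested for 69XXX by the autosomal BAF windows
  [0.2, 0.3] and [0.7, 0.8] (closed intervals; the boundary convention is
  a package choice and both windows are configurable). A triploid genome
  places heterozygote BAF clusters at 1/3 and 2/3, so both window
  proportions rise well above euploid levels. Strictly below both
  cut-offs (defaults 5.89% and 4.31%, the published euploid-library
  values) means 46XX; both at or above means 69XXX; a mixed outcome is
  `indeterminate`. `calibrate_baf_cutoffs` offers max-over-library window
  proportions as a library-specific alternative to the shipped cut-offs.

Only the routed branch determines the class; the other branch's
statistics are still computed and reported for diagnostics. A sample that
is Y-homozygous but X-indeterminate is reported `indeterminate` rather
than guessed.

**Cohort statistics.** Percentages are computed by one centralized rule:
half-up rounding to one decimal (`round_half_up`), which reproduces the
published per-PN proportions (e.g. 6/291 → 2.1, 14/172 → 8.1). The FET
table's spontaneous-miscarriage row is a known printed-rounding
inconsistency in the source table: 3/74 = 4.054% rounds to 4.1 under any
standard rule but is printed as 4.0; the package reports the computed
4.1. Group age comparisons use the two-sided unpaired pooled-variance
Student t-test for two groups and one-way ANOVA for more, per standard
practice for cohort age contrasts.

## Synthetic-data generator

The simulator draws, per marker, one allele per chromosome copy
independently with the marker's population B-allele frequency
(Hardy–Weinberg), so the B-allele dosage is Binomial(copies, p). Copy
configurations: 23X (1 copy everywhere, no Y), 46XX (2, XX), 46XY (2
autosomal, 1 X, 1 Y), 69XXX (3, XXX), 69XXY (3 autosomal, 2 X, 1 Y). The
digynic/diandric distinction is metadata only; no classifier uses parent
of origin. BAF expectation is dosage/copies, perturbed by N(0, `baf_sd`)
truncated to [0, 1]; LRR is N(mean, `lrr_sd`) with mean 0 except on chrX,
where it encodes the X copy number. Noise applies in the fixed order
allele dropout (AB collapses to a random homozygote) → mis-call (uniform
wrong genotype) → no-call; each stage draws a full-length random vector,
so at a fixed seed raising one rate only enlarges that stage's affected
set — this coupling is what makes the monotonicity properties (haploid AB
rate non-decreasing in mis-call rate, diploid AB rate non-increasing in
ADO) hold exactly, not just in expectation.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `miscall_rate` | 0.05 | the platform noise floor that motivates the 5% haploid bound |
| `ado_rate` | 0.05 | typical whole-genome-amplified biopsy dropout |
| `nocall_rate` | 0.02 | high-quality beadchip call rates ≈ 98% |
| `baf_sd` | 0.05 | cluster spread wide enough that triploid 1/3–2/3 clusters shed mass into the detection windows, as on real arrays |
| `lrr_sd` | 0.25 | per-marker LRR noise typical of beadchips |
| `chrx_lrr_mean_1copy` / `2copy` / `3copy` | −1.20 / −0.90 / −0.70 | bracket the published one-/two-copy bounds so the shipped thresholds separate simulated states |
| `y_stray_call_rate` | 0.01 | false-signal floor for the Y gate |
| population B-freq | Uniform[0.2, 0.8] | the assay targets *informative* (high-MAF) markers; this MAF-enriched default gives diploid heterozygosity ≈ 0.44 and triploid window mass ≈ 7–8%, comfortably separated from both the 18% diploid bound and the euploid BAF cut-offs. A flat [0, 1]-wide spectrum would put triploid window mass near the cut-offs themselves, which real informative-marker data does not do. The spectrum is fully configurable (`pop_b_freq_sampler`). |

Stray chrY calls in Y-less samples are uniform over AA/AB/BB, so their
homozygous fraction sits near 2/3, below the 0.80 gate — the gate is thus
doubly protected (count floor and fraction) and remains correct even on
manifests with thousands of chrY markers.

What the simulator does **not** emulate: linkage disequilibrium and
per-chromosome MAF structure, segmental or whole-chromosome aneuploidy
signal (aneuploidy enters as an external PGT-A label only), mosaicism,
GC-wave LRR artefacts, per-sample normalization batch effects, and
parent-of-origin signal. Passing recovery tests therefore demonstrate
that the decision rules are implemented correctly and separate the ploidy
states under realistic marker-level noise — not that the published
thresholds are optimal for any particular real platform.

## Calibrated vs shipped LRR bounds

The library-extrema calibration has an inherent property worth stating:
when a new sample is drawn from the same distribution as the n library
samples of its sex, its mean LRR falls beyond the library extremum with
probability 1/(n+1) regardless of noise level, so with a 37-sample 46XY
library about 2.6% of true 46XY samples are expected to land above the
calibrated one-copy bound and be reported indeterminate. The decision
tree therefore uses the shipped published bounds by default — the
simulator's state means bracket them with ~9σ margins, giving
deterministic recovery — and applies library calibration only when a
library is passed to `fit` (or `--bounds` on the CLI). On real data the
same caveat applies to any freshly calibrated library: expect an
indeterminate rate of order 1/(library size per sex) at the boundaries.

## Numerical and interface choices

- Degenerate inputs (no called markers in scope, no chrX LRR, no
  autosomal BAF) raise a dedicated error; they are never silently scored.
- Missing BAF/LRR are excluded from every mean and proportion
  (denominators are non-missing counts); NC markers carry missing
  BAF/LRR by convention.
- Hierarchical clustering of biopsies uses per-chromosome AB-rate feature
  vectors (24 features, Euclidean, average linkage), which makes the
  haploid/diploid separation marker-count independent; leaf order is
  deterministic given input order.
- VCF interchange stores BAF/LRR as FORMAT floats (~6 significant digits
  on disk), so round trips preserve BAF to 1e-6 and LRR to ~1e-5 at
  magnitude 1; manifests round-trip exactly via 17-digit TSV floats.
- QC ADO/mis-call estimation requires a truth or replicate call vector
  (dropout = truly-AB markers read homozygous; mis-call = discordance on
  truly homozygous markers); on field data only the call rate is checked.
- Every stochastic stage derives child seeds from one run seed via
  `numpy.random.SeedSequence`, so pipelines are byte-reproducible.

## Problem sizes

The test suite and the acceptance script use manifests of ~5,400 markers
(5,000 autosomal + 300 X + 120 Y) with 200 simulated samples per ploidy
state for recovery checks, and ≤100-marker fixtures for brute-force
oracle equivalence. At these sizes the statistical margins of every
decision boundary exceed 6 binomial/Gaussian standard errors, so recovery
is deterministic across seeds while the full suite runs in seconds;
full-scale ~300,000-marker manifests are supported and differ only in
runtime.

## Known limitations

- Uniparental diploidy and parent-of-origin assignment are out of scope;
  the assay's statistics cannot distinguish them without parental
  genotypes.
- Aneuploidy is an input label (from NGS PGT-A), not inferred from the
  marker data.
- The 69XXY branch assumes the triploid two-X state lands in the
  library's two-copy LRR regime; platforms whose LRR normalization
  shifts triploid intensities should recalibrate bounds on triploid
  reference material before trusting the 46XY/69XXY split.
- 2PN records pass through tabulation unchanged; no 2PN-specific analysis
  is provided.
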