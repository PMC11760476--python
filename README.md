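# ploidyscope

SNP-array molecular ploidy calling for zygotes with abnormal pronuclear
numeration (0PN/1PN/3PN), for embryology and PGT laboratories that want to
rescue viable diploid blastocysts that conventional fertilization checks
would discard.

At fertilization check, a zygote is scored by its number of pronuclei (PN):
2PN is normal, while 0PN, 1PN and 3PN are "alternate" numerations usually
assumed abnormal. Whole-genome SNP-beadchip data (per-marker genotype call,
B-allele frequency and log R ratio) can resolve the true ploidy of the
resulting blastocyst:

- **0PN/1PN — haploid vs diploid.** A haploid genome has no heterozygous
  loci, so its apparent heterozygosity (AB) rate sits at the platform
  mis-call noise floor. Samples with overall AB rate ≤ 5% are called
  haploid (23X), ≥ 18% diploid; the gap is reported as indeterminate.
- **3PN — triploidy decision tree.** Samples showing homozygous chrY calls
  are tested for 69XXY by comparing the chrX mean LRR against bounds
  calibrated from a euploid library (≤ max over 46XY samples → one X copy
  → 46XY; ≥ min over 46XX samples → two copies → 69XXY). All other samples
  are tested for 69XXX via the autosomal BAF windows [0.2, 0.3] and
  [0.7, 0.8]: a triploid genome places its heterozygote BAF clusters at
  1/3 and 2/3, shedding mass into both windows, while a diploid
  (clusters at 0, 1/2, 1) does not. Proportions strictly below the euploid
  cut-offs 5.89% / 4.31% mean 46XX; both at or above mean 69XXX.
- **Cohort tabulation.** Per-PN ploidy/aneuploidy composition tables,
  frozen-embryo-transfer (FET) outcome tables, and unpaired t-test / ANOVA
  group age comparisons.

A synthetic beadchip simulator (Hardy–Weinberg genotypes per marker,
allele dropout, mis-call and no-call noise, copy-number-dependent BAF and
LRR) generates samples for every ploidy state — 23X, 46XX, 46XY, 69XXX,
69XXY — so the full pipeline is testable without any proprietary array
data. Interchange formats are open: VCF with `GT`/`BAF`/`LRR` FORMAT
fields (the gtc2vcf convention) and TSV manifests/metadata.

## Worked example

```python
from ploidyscope import (make_manifest, simulate_sample, NoiseModel,
                         HeterozygosityPloidyClassifier,
                         TriploidyDecisionTree, compute_ab_rate)

manifest = make_manifest(n_autosomal=5000, n_x=300, n_y=120, seed=1)
noise = NoiseModel()          # 5% mis-call floor, 5% ADO, 2% no-call

# --- a 1PN blastocyst that turns out haploid -------------------------
zygote = simulate_sample(manifest, "23X", noise, seed=2)
res = compute_ab_rate(zygote)
print(f"AB rate: {res.ab_rate:.4f} ({res.n_ab}/{res.n_called} called markers)")
clf = HeterozygosityPloidyClassifier().fit()
print("class:", clf.predict([zygote])[0])

# --- a 3PN blastocyst through the decision tree ----------------------
tri = TriploidyDecisionTree().fit()   # published chrX LRR bounds
row = tri.decision_table([simulate_sample(manifest, "69XXY", noise, seed=3)]).iloc[0]
print(f"y_homozygous={row.y_homozygous} (n_y_called={row.n_y_called})")
print(f"chrX mean LRR: {row.chrx_mean_lrr:.4f} -> x_copies={row.x_copies}")
print("class:", row.ploidy_class)
```

prints

```
AB rate: 0.0291 (152/5217 called markers)
class: haploid
y_homozygous=True (n_y_called=114)
chrX mean LRR: -0.8989 -> x_copies=2
class: 69XXY
```

The AB rate 2.9% sits below the 5% noise floor, so the sample is haploid.
The 3PN sample carries Y signal, and its chrX mean LRR of −0.90 lies above
the two-copy bound (−1.03967): two X chromosomes plus a Y means 69XXY.
`TriploidyDecisionTree().fit(library_samples, sex_labels)` instead
calibrates the LRR bounds from your own euploid library, erroring if the
two sex distributions overlap.

The same pipeline is scriptable from the shell:

```bash
ploidyscope simulate --state 69XXX --n-markers 6000 --seed 7 \
    --out sample.vcf --manifest-out manifest.tsv
ploidyscope classify-3pn sample.vcf --manifest manifest.tsv --out call.tsv
ploidyscope run --out demo_run/        # simulate -> QC -> calibrate ->
                                       # classify -> tabulate
```

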