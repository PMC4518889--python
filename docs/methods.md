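# Methods

## Masking model

A probe is removed when its genomic footprint shares at least one base
with the footprint of any variant, on the same chromosome, irrespective
of strand and of where inside the probe the variant falls. This is a
deliberately conservative, purely positional rule: the hybridization cost
of a mismatch depends on its position within the probe (edge mismatches
matter less), but position-weighted scoring would require a
thermodynamic model and tissue-specific validation, so any overlap
disqualifies the probe. The overlap count is recorded in the mask report
but never thresholded.

Variant footprints come from the VCF REF allele: an SNV occupies one
base, a deletion the full REF span, an insertion its single anchor base.
Indels are included by default (they disrupt hybridization at least as
much as SNVs); `--snv-only` restricts to single-base substitutions.

VCF handling: records failing FILTER are skipped by default
(`--keep-filtered` disables this); multi-allelic sites are one variant —
any alternate allele makes the site untrusted; the minor allele frequency
is the folded site-level non-reference frequency, taken from the AF INFO
field when present, else counted from GT columns excluding missing calls,
else the record is skipped (and tallied) when an MAF threshold is in
force. The threshold is inclusive and defaults to 5 %.

A probeset survives masking iff at least one member probe survives
(`--min-probes` raises that bar). Masking is conservative in the
accounting sense — probes kept + probes removed = probes before, same
for probesets — and idempotent. Even heavily reduced probesets (e.g. 3
of 12 probes) are kept: fewer unbiased probes beat many biased ones.

## eQTL scan

Per probeset and locus, ordinary least squares of log2 expression on the
additive genotype code, intercept included, missing genotypes dropped
pairwise per locus (not by whole-sample deletion). The slope's two-sided
t-test with n − 2 degrees of freedom supplies the p-value; for a binary
code it equals the pooled two-sample t-test exactly, which the suite
asserts to 1e−10. Loci that are constant after pairwise dropping, or
leave fewer than 3 pairs, are not testable and are skipped; a perfect fit
with nonzero slope is reported at the smallest positive double and
flagged degenerate.

The candidate eQTL is the locus with the smallest p; exact ties break by
(chromosome, position, locus id) so results are deterministic. cis mode
keeps loci with |position − TSS| ≤ 1,000,000 bp, boundary inclusive.
Benjamini–Hochberg q-values are computed across the emitted best-locus
p-values (the procedure is the standard step-up; the suite checks it
against a literal implementation of the definition).

The allele effect d = mean(expression | code 0) − mean(expression |
code > 0) groups all carriers together so one definition covers both the
backcross (0 vs 1) and the population (0 vs 1/2) designs; its sign is
positive when reference-strain homozygotes express higher. The bias test
is the exact two-sided binomial under the minimal-likelihood convention
(sum of all outcomes no more probable than the observed one); ties
(d exactly 0) are excluded from the trials and tallied separately.

For run comparisons, delta = −log10 p(corrected) − (−log10 p(uncorrected))
per shared probeset; "decreased in significance" means delta < 0 (exact
zeros count as not decreased). The reported Pearson correlation is
between uncorrected −log10 p and −delta, i.e. between how strong a
result was and how much of that strength masking took away. Whether the
correlation should instead use the signed delta is genuinely open; this
choice is documented here rather than asserted as canonical, and the
quantity is exposed so users can recompute alternatives from the
per-probeset table.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not raw
array physics. Geometry: loci every 5 Mb, ten per synthetic chromosome;
each probeset is anchored to the locus `index mod n_loci`, its TSS
placed 10 kb + a per-probeset 2 kb block downstream of that locus (so
every TSS is cis to exactly one locus); members are 25-bp probes spaced
40 bp apart. Layouts that would push a TSS out of its locus's cis
territory raise a geometry error. Exactly round(p_probe_hit × probes)
probes, chosen uniformly, receive one SNV at a uniform offset; the
emitted BED/VCF re-read through the real parsers reproduce that truth
table bit for bit (tested).

Genotypes: backcross cells are iid Bernoulli(0.5) in {0, 1}, the
expectation for an F1 × parental cross; the population design draws a
per-locus MAF uniformly from `maf_range` (default 0.05–0.5) and codes
from Binomial(2, MAF) (Hardy–Weinberg).

Probe intensity for probe p of probeset s in sample i:

    x = mu_s + beta_s · g_i · [s true eQTL]
        − bias_delta · [p hit] · [g_i > 0] + Normal(0, noise_sd)

with mu_s ~ Normal(8, 1) (a typical log2 intensity scale), beta_s =
±effect_size with random sign, and g_i the code at the probeset's cis
locus. Defaults: n_samples 100, n_loci 20, probes_per_probeset 12 (a
standard expression-array probeset size), effect_size 1.0 log2 units,
noise_sd 1.0 at the probe level (≈0.29 after averaging 12 probes),
bias_delta ≥ 0 in log2 units. Attenuation applies at full strength to
any carrier by default — in a backcross every carrier is heterozygous,
and no dose–response model is assumed —
with `dosage_proportional_bias` available for the 0/1/2 case.

Probeset summarization is the arithmetic mean of member log2 probe
values. Production normalizers (RMA's median polish etc.) are
deliberately out of scope: the mean preserves the attenuation arithmetic
exactly, which is what the correction tests rely on. Consequently the
generator does not emulate background correction, quantile
normalization, spatial artifacts, batch effects, or sequence-dependent
affinity — passing tests demonstrate the masking and scanning logic, not
robustness to those real-data phenomena.

All randomness descends from a single seed through independent
per-operation child generators, so each artifact is byte-reproducible
and insensitive to the order in which operations run.

## Calibration checks

`scripts/acceptance.py` recomputes three quantities whose expected
values follow from the design: the null direction fraction (no effects,
no bias → 50 % of candidate eQTL with d > 0; 1000 probesets, 100
samples, 20 loci), the post-masking direction fraction under injected
bias (30 % of probes hit, 1 log2 unit attenuation → the uncorrected run
must show a strong excess, the corrected run returns to 50 %), and the
backcross heterozygosity (50 % over 500 × 100 cells). Problem sizes were
chosen so each check resolves a 3-standard-error band of a few percent
while the whole script completes in seconds.

## Numerical and design notes

- p-values are clamped to [tiny, 1]; −log10 p is finite for every
  emitted result.
- Intersection uses an interval tree per chromosome; the contract is
  exact agreement with a brute-force all-pairs oracle, enforced on
  random inputs at 1000 × 500 scale.
- Annotation output ordering is deterministic (probesets lexicographic,
  members in stored order) so original-vs-masked diffs are reviewable.
- Unknown probe ids in a hit table warn instead of failing, so one hit
  list can serve annotation subsets.
- Chromosome naming ("chr1" vs "1") is reconciled by an explicit
  strip/add option rather than guessed.
- The simplified PGF/CLF dialect keeps the probeset→probe hierarchy and
  probe coordinates and flattens vendor atom/block levels; binary CDF
  files are out of scope.

## Limitations

Masking only removes probes for *known* variants: private or unsequenced
variation, copy-number changes and systematic strain-level expression
differences remain uncorrected, so real datasets may retain residual
direction bias after masking. The scan fits no covariates, permutation
thresholds, or mixed models; it is the minimal additive model, intended
for bias quantification and for studies where that model is adequate.
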