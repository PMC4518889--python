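# arrayqtl

SNP-aware masking of microarray probe annotations, plus a
linear-regression eQTL scanner with a direction-of-effect diagnostic.

## The problem

Expression microarrays measure mRNA with short (~25 nt) probes designed
against a reference genome. When a sample carries a sequence variant under
a probe, hybridization weakens and the probe reports artificially low
expression. In genetic studies — a mouse backcross segregating a divergent
strain, or human cohorts with population-specific SNPs — the variant
travels with the local genotype, so this purely technical attenuation
looks exactly like a *cis*-acting expression QTL. The artifact inflates
false positives in one allelic direction and can also hide genuine eQTL.

Because founder and population genomes are sequenced, affected probes can
be identified *a priori*: intersect every probe's genomic footprint with
the variants in one or more VCF files, remove intersecting probes from
their probesets, drop probesets left with no probes, and write a new,
internally consistent annotation that any downstream normalization can
use. `arrayqtl` implements that workflow end to end, together with the
eQTL scan used to quantify the bias before and after correction.

## The statistics

For each probeset with expression vector $y$ (log2) and genotype codes
$g \in \{0,1\}$ (backcross: 0 = homozygous reference strain, 1 =
heterozygous) or $g \in \{0,1,2\}$ (additive population coding), the scan
fits OLS $y = \alpha + \beta g + \varepsilon$ at every eligible locus and
reports the locus with the smallest two-sided $t$ p-value ($n-2$ df) as
the candidate eQTL; for binary $g$ this is exactly the pooled-variance
two-sample t-test. *cis* mode restricts loci to a 1 Mb window (inclusive)
around the probeset's transcription start site. FDR across probesets is
Benjamini–Hochberg.

The bias diagnostic is the allele effect
$d = \bar y_{g=0} - \bar y_{g>0}$ at the candidate locus. Absent bias and
systematic strain effects, $d > 0$ for ~50 % of probesets; variants under
probes depress carrier ($g>0$) signal and push the fraction above 50 %.
An exact two-sided binomial test against 0.5 quantifies the excess, and a
run comparison reports, per probeset, the change in $-\log_{10} p$ after
masking and the correlation between uncorrected strength and loss of
significance.

## Worked example

The built-in generator simulates the whole study — probes laid along
synthetic chromosomes, variants planted under a chosen fraction of
probes, backcross genotypes, probe-level expression with injectable
attenuation — so the pipeline runs with no external data:

```python
from arrayqtl import SimConfig, EqtlScan
from arrayqtl.synthetic import simulate_study

cfg = SimConfig(n_samples=100, n_loci=20, n_probesets=500, p_true_eqtl=0.1,
                effect_size=1.0, p_probe_hit=0.3, bias_delta=1.0, seed=11)
study = simulate_study(cfg)
print(EqtlScan(study.expression, study.genotypes).fit().summary())
```

```
eQTL scan results
=================
mode:                    genomewide
probesets tested:        500
samples:                 100
loci:                    20
significant (FDR<=0.05):  476
allele effect d > 0:     451/500 (90.2 %)
binomial P vs 50 %:      1.76e-82
```

Only 10 % of probesets carry a real effect, yet 90 % of candidate eQTL
point the same way — the signature of probe bias. Masking and rescanning
in one step:

```python
from arrayqtl import run_bias_eval
print(run_bias_eval(SimConfig(n_probesets=200, p_probe_hit=0.3,
                              bias_delta=1.0, seed=7)).summary())
```

```
probe-bias evaluation
=====================
probes removed:      720/2400
probesets dropped:   0/200
d > 0 before:        91.5 % (binomial P = 2.51e-36)
d > 0 after:         46.0 % (binomial P = 0.289)
lost significance:   90.5 % of shared probesets
strength vs loss r:  0.994 (P = 2.57e-190)
```

After removing the 720 variant-intersecting probes the direction fraction
returns to the null (binomial P = 0.29), and the probesets that lose the
most significance are precisely those with the strongest uncorrected
signal.

The same workflow is available from the shell: `arrayqtl equalize`
(BED + VCF + annotation → masked annotation + report), `arrayqtl eqtl`
(TSV matrices → results + bias summary), `arrayqtl simulate` and
`arrayqtl bias-eval` (config file → full synthetic experiment); every
command writes a `manifest.json` with parameters and input checksums.

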