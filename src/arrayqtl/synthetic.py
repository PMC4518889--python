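"""Synthetic study generator: platform, variants, genotypes, expression.

Emulates the structure a backcross (or outbred-population) eQTL study
assumes, with the probe-level failure mode the masking workflow corrects:
a variant under a probe attenuates that probe's signal in every sample
carrying the variant allele, which — because the variant travels with the
local genotype — masquerades as a cis-eQTL.

The generative model, per probe p of probeset s in sample i:

    x = mu_s + beta_s * g_i * 1[s is a true eQTL]
        − bias_delta * 1[p overlaps a variant] * 1[g_i > 0]
        + Normal(0, noise_sd)

with mu_s ~ Normal(8, 1) on the log2 scale, beta_s = ±effect_size, and
g_i the sample's genotype code at the probeset's cis locus.  Probeset
summaries are plain means of member probes, so masking attenuated probes
removes the artifact arithmetically.

All randomness flows from ``SimConfig.seed`` through per-operation child
generators, so each output is byte-reproducible and independent of the
order operations are called in.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import IntegrityError
from .eqtl import ExpressionMatrix, GenotypeMatrix
from .probes import AnnotationSet, Probe, Probeset, write_probe_bed
from .variants import GenomeInterval, Variant

__all__ = [
    "SimConfig",
    "SimPlatform",
    "ProbeExpression",
    "simulate_platform",
    "simulate_genotypes",
    "simulate_probe_expression",
    "summarize_probesets",
    "cis_locus_map",
    "write_vcf",
    "simulate_study",
]

PROBE_LEN = 25          # nt, standard Affymetrix probe length
_PROBE_SPACING = 40     # bp between member probe starts (non-overlapping)
_BLOCK_BP = 2_000       # bp reserved per probeset
_LOCI_PER_CHROM = 10
_LOCUS_SPACING = 5_000_000
_TSS_OFFSET = 10_000    # first probeset block starts this far from its locus
_MAX_TSS_DIST = 900_000  # every tss must stay cis to its locus (1 Mb window)


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for the generator; defaults are the backcross design."""

    n_samples: int = 100
    n_loci: int = 20
    n_probesets: int = 1000
    probes_per_probeset: int = 12
    p_probe_hit: float = 0.0
    bias_delta: float = 0.0       # log2 attenuation of hit probes in carriers
    p_true_eqtl: float = 0.0
    effect_size: float = 1.0      # true slope, log2 units per coded allele
    noise_sd: float = 1.0
    design: str = "backcross"     # or "population"
    maf_range: tuple[float, float] = (0.05, 0.5)
    dosage_proportional_bias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_probe_hit", "p_true_eqtl"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_samples", "n_loci", "n_probesets", "probes_per_probeset"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.bias_delta < 0:
            raise ValueError("bias_delta must be >= 0")
        if self.design not in ("backcross", "population"):
            raise ValueError(f"unknown design {self.design!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _locus_layout(n_loci: int) -> list[tuple[str, int]]:
    """(chrom, 1-based position) per locus: 10 loci per chromosome, 5 Mb apart."""
    out = []
    for j in range(n_loci):
        chrom = f"chr{j // _LOCI_PER_CHROM + 1}"
        pos = (j % _LOCI_PER_CHROM) * _LOCUS_SPACING + 1_000_000
        out.append((chrom, pos))
    return out


@dataclass
class SimPlatform:
    annotation: AnnotationSet
    variants: list[Variant]
    truth: dict[str, int]  # probe_id -> number of variants placed in it
    tss: dict[str, tuple[str, int]]
    bed_path: str | None = None
    vcf_path: str | None = None


def write_vcf(variants: list[Variant], path: str | os.PathLike) -> None:
    """Write variants as a minimal sorted VCF 4.2 text file with AF INFO."""
    def chrom_key(c: str) -> tuple[int, str]:
        tail = c[3:] if c.startswith("chr") else c
        return (int(tail), "") if tail.isdigit() else (10**9, tail)

    ordered = sorted(variants, key=lambda v: (chrom_key(v.chrom), v.pos_1based))
    chroms = sorted({v.chrom for v in ordered}, key=chrom_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in ordered:
            af = 0.5 if v.maf is None else v.maf
            fh.write(
                f"{v.chrom}\t{v.pos_1based}\t.\t{v.ref}\t{','.join(v.alts)}"
                f"\t.\tPASS\tAF={af:g}\n"
            )


def simulate_platform(cfg: SimConfig, out_dir: str | os.PathLike | None = None) -> SimPlatform:
    """Lay out probes along synthetic chromosomes and plant variants in some.

    Exactly ``round(p_probe_hit × total probes)`` probes receive one SNV
    at a uniform-random offset.  When ``out_dir`` is given, the probe BED
    and variant VCF are written there; re-reading them through the real
    readers reproduces the truth table exactly (tested).
    """
    rng = cfg._rng(1)
    loci = _locus_layout(cfg.n_loci)
    blocks_per_locus = math.ceil(cfg.n_probesets / cfg.n_loci)
    block_bp = max(_BLOCK_BP, cfg.probes_per_probeset * _PROBE_SPACING + 100)
    if _TSS_OFFSET + blocks_per_locus * block_bp > _MAX_TSS_DIST:
        raise ValueError(
            f"geometry impossible: {blocks_per_locus} probeset blocks of "
            f"{block_bp} bp per locus exceed the cis territory"
        )

    probes: dict[str, Probe] = {}
    probesets: dict[str, Probeset] = {}
    tss_map: dict[str, tuple[str, int]] = {}
    width = len(str(cfg.n_probesets))
    for s in range(cfg.n_probesets):
        ps_id = f"PS{s + 1:0{width}d}"
        locus_idx = s % cfg.n_loci
        block = s // cfg.n_loci
        chrom, locus_pos = loci[locus_idx]
        tss = locus_pos + _TSS_OFFSET + block * block_bp
        tss_map[ps_id] = (chrom, tss)
        member_ids = []
        for k in range(cfg.probes_per_probeset):
            probe_id = f"{ps_id}_P{k + 1:02d}"
            start0 = (tss - 1) + k * _PROBE_SPACING
            probes[probe_id] = Probe(
                probe_id, ps_id, GenomeInterval(chrom, start0, start0 + PROBE_LEN), "+"
            )
            member_ids.append(probe_id)
        probesets[ps_id] = Probeset(ps_id, tuple(member_ids), None, (chrom, tss))

    annotation = AnnotationSet("synthetic-array", probesets, probes)

    all_probe_ids = sorted(probes)
    n_hit = round(cfg.p_probe_hit * len(all_probe_ids))
    hit_ids = rng.choice(len(all_probe_ids), size=n_hit, replace=False)
    truth: dict[str, int] = {}
    variants: list[Variant] = []
    maf = 0.5 if cfg.design == "backcross" else None
    for idx in sorted(hit_ids):
        pid = all_probe_ids[idx]
        iv = probes[pid].interval
        offset = int(rng.integers(0, PROBE_LEN))
        pos_1based = iv.start0 + offset + 1
        variants.append(
            Variant(iv.chrom, pos_1based, "A", ("G",), maf=maf, population_tag="SIM")
        )
        truth[pid] = 1

    platform = SimPlatform(annotation, variants, truth, tss_map)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        platform.bed_path = str(out / "probes.bed")
        platform.vcf_path = str(out / "variants.vcf")
        write_probe_bed(probes.values(), platform.bed_path)
        write_vcf(variants, platform.vcf_path)
    return platform


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw genotype codes for every (sample, locus) cell.

    backcross: iid Bernoulli(0.5) codes in {0, 1} — each locus is an even
    split of heterozygotes and reference-strain homozygotes in
    expectation.  population: per-locus minor allele frequency uniform in
    ``maf_range``, codes 0/1/2 drawn Binomial(2, maf) (Hardy–Weinberg).
    """
    rng = cfg._rng(2)
    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    locus_ids = [f"L{j + 1:04d}" for j in range(cfg.n_loci)]
    positions = _locus_layout(cfg.n_loci)
    if cfg.design == "backcross":
        codes = rng.integers(0, 2, size=(cfg.n_loci, cfg.n_samples)).astype(float)
    else:
        lo, hi = cfg.maf_range
        mafs = rng.uniform(lo, hi, size=cfg.n_loci)
        codes = rng.binomial(2, mafs[:, None], size=(cfg.n_loci, cfg.n_samples)).astype(float)
    return GenotypeMatrix(sample_ids, locus_ids, positions, codes, cfg.design)


def cis_locus_map(geno: GenotypeMatrix, tss: dict[str, tuple[str, int]]) -> dict[str, int]:
    """Nearest locus (row index) to each probeset's TSS on the same chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j, (chrom, pos) in enumerate(geno.positions):
        by_chrom.setdefault(chrom, []).append((pos, j))
    out: dict[str, int] = {}
    for ps_id, (chrom, pos) in tss.items():
        cands = by_chrom.get(chrom)
        if cands:
            out[ps_id] = min(cands, key=lambda t: (abs(t[0] - pos), t[0]))[1]
    return out


@dataclass
class ProbeExpression:
    """Probe-level log2 intensities, pre-summarization.

    ``true_beta`` records the signed slope actually injected per probeset
    (0 for non-eQTL probesets), for parameter-recovery checks.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_probes, n_samples)
    true_beta: dict[str, float] = field(default_factory=dict)


def simulate_probe_expression(
    cfg: SimConfig,
    geno: GenotypeMatrix,
    annotation: AnnotationSet,
    truth: dict[str, int],
    tss: dict[str, tuple[str, int]] | None = None,
) -> ProbeExpression:
    """Generate probe intensities under the model in the module docstring.

    Both the true cis effect and the probe attenuation act through the
    genotype at the probeset's cis locus (nearest locus to its TSS), the
    linkage structure that makes attenuation look like a cis-eQTL.
    """
    rng = cfg._rng(3)
    if tss is None:
        tss = {ps.probeset_id: ps.tss for ps in annotation.probesets.values() if ps.tss}
    locus_of = cis_locus_map(geno, tss)

    ps_ids = sorted(annotation.probesets)
    n_true = round(cfg.p_true_eqtl * len(ps_ids))
    true_idx = set(rng.choice(len(ps_ids), size=n_true, replace=False).tolist())
    mu = rng.normal(8.0, 1.0, size=len(ps_ids))
    sign = rng.choice([-1.0, 1.0], size=len(ps_ids))

    probe_ids: list[str] = []
    rows: list[np.ndarray] = []
    betas: dict[str, float] = {}
    for s, ps_id in enumerate(ps_ids):
        ps = annotation.probesets[ps_id]
        j = locus_of.get(ps_id)
        if j is None:
            raise IntegrityError(f"probeset {ps_id} has no cis locus on its chromosome")
        g = np.nan_to_num(geno.codes[j], nan=0.0)
        beta = sign[s] * cfg.effect_size if s in true_idx else 0.0
        betas[ps_id] = beta
        base = mu[s] + beta * g
        carrier = (g > 0).astype(float)
        dose = g if cfg.dosage_proportional_bias else carrier
        for pid in ps.probe_ids:
            attenuation = cfg.bias_delta * dose if truth.get(pid, 0) else 0.0
            noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples)
            rows.append(base - attenuation + noise)
            probe_ids.append(pid)
    return ProbeExpression(probe_ids, list(geno.sample_ids), np.vstack(rows), betas)


def summarize_probesets(
    probe_expr: ProbeExpression, annotation: AnnotationSet
) -> ExpressionMatrix:
    """Probeset value per sample = arithmetic mean of member probe values.

    Member probes missing from the matrix are an integrity error; probes
    present in the matrix but absent from the annotation are ignored —
    that is exactly the post-masking case, where the summary must use
    only the surviving members.
    """
    row_of = {pid: i for i, pid in enumerate(probe_expr.probe_ids)}
    ps_ids = sorted(annotation.probesets)
    values = np.empty((len(ps_ids), len(probe_expr.sample_ids)))
    for i, ps_id in enumerate(ps_ids):
        ps = annotation.probesets[ps_id]
        missing = [pid for pid in ps.probe_ids if pid not in row_of]
        if missing:
            raise IntegrityError(
                f"probeset {ps_id} members absent from probe matrix: {missing[:5]}"
            )
        idx = [row_of[pid] for pid in ps.probe_ids]
        values[i] = probe_expr.values[idx].mean(axis=0)
    return ExpressionMatrix(ps_ids, list(probe_expr.sample_ids), values)


@dataclass
class SimStudy:
    """Everything one simulated experiment produces, pre-summarized."""

    config: SimConfig
    platform: SimPlatform
    genotypes: GenotypeMatrix
    probe_expr: ProbeExpression
    expression: ExpressionMatrix  # summarized over the FULL annotation


def simulate_study(cfg: SimConfig, out_dir: str | os.PathLike | None = None) -> SimStudy:
    """Run the full generator: platform → genotypes → probes → summaries."""
    platform = simulate_platform(cfg, out_dir)
    geno = simulate_genotypes(cfg)
    probe_expr = simulate_probe_expression(
        cfg, geno, platform.annotation, platform.truth, platform.tss
    )
    expr = summarize_probesets(probe_expr, platform.annotation)
    if out_dir is not None:
        out = Path(out_dir)
        geno.to_tsv(out / "genotypes.tsv")
        expr.to_tsv(out / "expression.tsv")
    return SimStudy(cfg, platform, geno, probe_expr, expr)
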