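"""Linear-regression eQTL scanning and direction-of-effect diagnostics.

The scan regresses each probeset's log2 expression on genotype codes at
every eligible locus (genome-wide, or cis within a window around the
transcription start site), reports the statistically strongest locus as
the candidate eQTL, and controls the FDR across probesets with
Benjamini–Hochberg.

Genotype coding is additive in the non-reference-strain (or ALT) allele:
a backcross has codes {0 = homozygous reference strain, 1 = heterozygous},
an outbred human design has {0, 1, 2}.  The allele-effect statistic

    d = mean(expression | code 0) − mean(expression | code > 0)

is the diagnostic for hybridization bias: with no bias and no consistent
strain effect, d should be positive for ~50 % of candidate eQTL, while
variants under probes depress the signal of variant-carrying (code > 0)
samples and push the positive fraction well above 50 %.  An exact binomial
test against 0.5 quantifies the excess.

Model/Results surface: build an :class:`EqtlScan` from an expression and a
genotype matrix, call ``fit()``, and work with the returned
:class:`EqtlScanResults` (per-probeset table, ``summary()``,
``direction_bias()``, ``compare_to()``).
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "RegressResult",
    "NotTestable",
    "EqtlResult",
    "BiasSummary",
    "RunComparison",
    "regress",
    "scan",
    "bh_fdr",
    "direction_bias",
    "compare_runs",
    "EqtlScan",
    "EqtlScanResults",
]


# ---------------------------------------------------------------------------
# matrices

@dataclass
class GenotypeMatrix:
    """Genotype codes per (locus, sample); NaN marks a missing call.

    codes count non-reference-strain (ALT) alleles: {0, 1} for a backcross,
    {0, 1, 2} for an outbred additive design.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    positions: list[tuple[str, int]]  # (chrom, 1-based position) per locus
    codes: np.ndarray  # shape (n_loci, n_samples), float, NaN = missing
    design: str = "backcross"  # or "population"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise ValueError("codes shape does not match locus/sample ids")
        if len(self.sample_ids) < 2:
            raise ValueError("a genotype matrix needs >= 2 samples")
        if len(self.positions) != len(self.locus_ids):
            raise ValueError("one (chrom, pos) per locus required")
        vmax = 1 if self.design == "backcross" else 2
        observed = self.codes[~np.isnan(self.codes)]
        if observed.size and (observed.min() < 0 or observed.max() > vmax):
            raise ValueError(
                f"genotype codes outside [0, {vmax}] for design {self.design!r}"
            )

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, design: str = "backcross") -> "GenotypeMatrix":
        """Rows = loci: columns locus_id, chrom, pos, then one per sample; NA = missing."""
        try:
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        except Exception as exc:
            raise ParseError(f"cannot read genotype TSV {path}: {exc}") from exc
        required = ["locus_id", "chrom", "pos"]
        if list(df.columns[:3]) != required:
            raise ParseError(
                f"genotype TSV must start with columns {required}, got {list(df.columns[:3])}", 1
            )
        samples = list(df.columns[3:])
        codes = df[samples].to_numpy(dtype=float)
        return cls(
            sample_ids=samples,
            locus_ids=df["locus_id"].astype(str).tolist(),
            positions=list(zip(df["chrom"], df["pos"].astype(int))),
            codes=codes,
            design=design,
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.codes, columns=self.sample_ids)
        df.insert(0, "pos", [p for _, p in self.positions])
        df.insert(0, "chrom", [c for c, _ in self.positions])
        df.insert(0, "locus_id", self.locus_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class ExpressionMatrix:
    """log2 expression per (probeset, sample)."""

    probeset_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_probesets, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probeset_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match probeset/sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ExpressionMatrix":
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:
            raise ParseError(f"cannot read expression TSV {path}: {exc}") from exc
        if df.columns[0] != "probeset_id":
            raise ParseError(
                f"expression TSV must start with column probeset_id, got {df.columns[0]!r}", 1
            )
        samples = list(df.columns[1:])
        return cls(
            probeset_ids=df["probeset_id"].astype(str).tolist(),
            sample_ids=samples,
            values=df[samples].to_numpy(dtype=float),
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "probeset_id", self.probeset_ids)
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# single regression

@dataclass(frozen=True)
class RegressResult:
    slope: float
    se: float
    t: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class NotTestable:
    reason: str


def regress(y: Sequence[float], g: Sequence[float]) -> RegressResult | NotTestable:
    """OLS of expression on genotype code, with intercept.

    Pairs with a missing genotype (NaN) are dropped.  The p-value is the
    two-sided t test on the slope with n − 2 degrees of freedom; for a
    binary genotype it coincides exactly with the pooled-variance
    two-sample t-test.  A perfect fit with nonzero slope (zero residual
    variance) is reported at the smallest positive float and flagged
    degenerate.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~(np.isnan(g) | np.isnan(y))
    y, g = y[keep], g[keep]
    n = y.size
    if n < 3:
        return NotTestable(f"only {n} complete pairs")
    gc = g - g.mean()
    sxx = float(gc @ gc)
    if sxx == 0.0:
        return NotTestable("constant genotype")
    slope = float(gc @ (y - y.mean())) / sxx
    resid = y - y.mean() - slope * gc
    sse = float(resid @ resid)
    df = n - 2
    if sse <= 0.0 or math.isclose(sse, 0.0, abs_tol=1e-300):
        if slope == 0.0:
            return RegressResult(0.0, 0.0, 0.0, 1.0, n)
        return RegressResult(slope, 0.0, math.inf, float(np.finfo(float).tiny), n, degenerate=True)
    se = math.sqrt(sse / df / sxx)
    t = slope / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    return RegressResult(slope, se, t, p, n)


# ---------------------------------------------------------------------------
# results containers

@dataclass(frozen=True)
class EqtlResult:
    """Best-locus association for one probeset."""

    probeset_id: str
    best_locus_id: str
    slope: float
    p_value: float
    neglog10p: float
    allele_effect_d: float
    q_value: float | None = None


@dataclass(frozen=True)
class BiasSummary:
    """Direction-of-effect accounting and its exact binomial test."""

    n_eqtl: int
    n_positive_d: int
    fraction_positive: float
    binomial_p: float
    n_ties_excluded: int


@dataclass(frozen=True)
class RunComparison:
    """Change in eQTL strength between an uncorrected and a corrected run."""

    n_shared: int
    deltas: dict[str, float]  # probeset -> neglog10p(corrected) − neglog10p(uncorrected)
    fraction_decreased: float
    pearson_r: float | None  # None when a correlate has zero variance
    pearson_p: float | None


# ---------------------------------------------------------------------------
# statistics

def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q(i) = min over ranks j >= rank(i) of m·p(j)/j, capped at 1; monotone
    in p and invariant under permutation of the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def direction_bias(
    results: Sequence[EqtlResult], fdr_max: float | None = None
) -> BiasSummary:
    """Count candidate eQTL with positive allele effect d and test vs 0.5.

    d > 0 means reference-strain homozygotes express higher.  Ties (d == 0
    exactly) are excluded from the binomial trials and tallied.  The test
    is the exact two-sided binomial (minimal-likelihood convention).
    """
    rows = list(results)
    if fdr_max is not None:
        rows = [r for r in rows if r.q_value is not None and r.q_value <= fdr_max]
    if not rows:
        raise ValueError("no eQTL results left after FDR filtering")
    n_pos = sum(1 for r in rows if r.allele_effect_d > 0)
    n_ties = sum(1 for r in rows if r.allele_effect_d == 0)
    n_trials = len(rows) - n_ties
    if n_trials == 0:
        raise ValueError("all allele effects are exactly zero")
    binom_p = float(stats.binomtest(n_pos, n_trials, 0.5).pvalue)
    return BiasSummary(
        n_eqtl=len(rows),
        n_positive_d=n_pos,
        fraction_positive=n_pos / n_trials,
        binomial_p=min(binom_p, 1.0),
        n_ties_excluded=n_ties,
    )


def compare_runs(
    uncorrected: Sequence[EqtlResult], corrected: Sequence[EqtlResult]
) -> RunComparison:
    """Per-probeset change in −log10 p between two runs.

    delta = neglog10p(corrected) − neglog10p(uncorrected); negative delta
    means the probeset lost significance after correction.  pearson_r
    correlates the uncorrected strength with −delta (the loss), asking
    whether stronger uncorrected signals lost more.
    """
    unc = {r.probeset_id: r for r in uncorrected}
    cor = {r.probeset_id: r for r in corrected}
    shared = sorted(set(unc) & set(cor))
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} probesets shared between runs")
    deltas = {ps: cor[ps].neglog10p - unc[ps].neglog10p for ps in shared}
    frac_dec = sum(1 for d in deltas.values() if d < 0) / len(shared)
    x = np.array([unc[ps].neglog10p for ps in shared])
    y = np.array([-deltas[ps] for ps in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r_val, p_val = None, None
    else:
        r = stats.pearsonr(x, y)
        r_val, p_val = float(r.statistic), float(r.pvalue)
    return RunComparison(
        n_shared=len(shared),
        deltas=deltas,
        fraction_decreased=frac_dec,
        pearson_r=r_val,
        pearson_p=p_val,
    )


# ---------------------------------------------------------------------------
# the scan

def _allele_effect(y: np.ndarray, g: np.ndarray) -> float:
    """mean(y | code 0) − mean(y | code > 0); NaN if a group is empty."""
    keep = ~np.isnan(g)
    y, g = y[keep], g[keep]
    ref = y[g == 0]
    alt = y[g > 0]
    if ref.size == 0 or alt.size == 0:
        return float("nan")
    return float(ref.mean() - alt.mean())


def scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    mode: str = "genomewide",
    cis_window_bp: int = 1_000_000,
    tss: Mapping[str, tuple[str, int]] | None = None,
) -> list[EqtlResult]:
    """Best-locus association scan over all probesets.

    cis mode restricts each probeset to loci within ``cis_window_bp``
    (inclusive) of its transcription start site, on the same chromosome.
    The best locus has the smallest p; exact ties break by genomic order
    (chrom, position, locus_id).  Probesets with no testable locus are
    omitted with a logged reason.  q-values are BH-adjusted across the
    emitted best-locus p-values.
    """
    if mode not in ("genomewide", "cis"):
        raise ValueError(f"mode must be 'genomewide' or 'cis', got {mode!r}")
    if mode == "cis" and tss is None:
        raise ValueError("cis mode requires per-probeset tss anchors")

    shared = [s for s in geno.sample_ids if s in set(expr.sample_ids)]
    if not shared:
        raise ValueError("expression and genotype matrices share no samples")
    e_idx = [expr.sample_ids.index(s) for s in shared]
    g_idx = [geno.sample_ids.index(s) for s in shared]
    E = expr.values[:, e_idx]
    G = geno.codes[:, g_idx]

    n_loci = len(geno.locus_ids)
    # tie-break order: genomic position then locus id
    order_key = [
        (geno.positions[j][0], geno.positions[j][1], geno.locus_ids[j])
        for j in range(n_loci)
    ]

    results: list[EqtlResult] = []
    for i, ps_id in enumerate(expr.probeset_ids):
        if mode == "cis":
            anchor = tss.get(ps_id)
            if anchor is None:
                logger.info("probeset %s skipped: no TSS anchor", ps_id)
                continue
            chrom, pos = anchor
            eligible = [
                j for j in range(n_loci)
                if geno.positions[j][0] == chrom
                and abs(geno.positions[j][1] - pos) <= cis_window_bp
            ]
        else:
            eligible = range(n_loci)

        y = E[i]
        best = None  # (p, order_key, j, RegressResult)
        for j in eligible:
            res = regress(y, G[j])
            if isinstance(res, NotTestable):
                continue
            cand = (res.p_value, order_key[j], j, res)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            logger.info("probeset %s skipped: no testable locus", ps_id)
            continue
        p, _, j, res = best
        results.append(
            EqtlResult(
                probeset_id=ps_id,
                best_locus_id=geno.locus_ids[j],
                slope=res.slope,
                p_value=p,
                neglog10p=-math.log10(p),
                allele_effect_d=_allele_effect(E[i], G[j]),
            )
        )

    if results:
        q = bh_fdr([r.p_value for r in results])
        results = [replace(r, q_value=float(qi)) for r, qi in zip(results, q)]
    return results


# ---------------------------------------------------------------------------
# model / results surface

_RESULT_COLUMNS = [
    "probeset_id", "best_locus_id", "slope", "p_value",
    "neglog10p", "allele_effect_d", "q_value",
]


class EqtlScan:
    """eQTL scan model: expression and genotypes plus the scan design.

    Parameters
    ----------
    expr, geno
        Aligned-by-sample-id expression and genotype matrices.
    mode
        "genomewide" (every locus eligible for every probeset) or "cis"
        (loci within ``cis_window_bp`` of the probeset's TSS).
    cis_window_bp
        Inclusive half-window around the TSS, default 1 Mb.
    tss
        probeset_id -> (chrom, 1-based position), required for cis mode.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        geno: GenotypeMatrix,
        mode: str = "genomewide",
        cis_window_bp: int = 1_000_000,
        tss: Mapping[str, tuple[str, int]] | None = None,
    ):
        self.expr = expr
        self.geno = geno
        self.mode = mode
        self.cis_window_bp = cis_window_bp
        self.tss = tss

    @classmethod
    def from_files(
        cls,
        expr_path: str | os.PathLike,
        geno_path: str | os.PathLike,
        design: str = "backcross",
        **kwargs,
    ) -> "EqtlScan":
        return cls(
            ExpressionMatrix.from_tsv(expr_path),
            GenotypeMatrix.from_tsv(geno_path, design=design),
            **kwargs,
        )

    def fit(self) -> "EqtlScanResults":
        results = scan(
            self.expr, self.geno, self.mode, self.cis_window_bp, self.tss
        )
        return EqtlScanResults(self, results)


class EqtlScanResults:
    """Fitted scan: one best-locus association per testable probeset."""

    def __init__(self, model: EqtlScan, results: list[EqtlResult]):
        self.model = model
        self.results = results

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(r, c) for c in _RESULT_COLUMNS] for r in self.results],
            columns=_RESULT_COLUMNS,
        )

    def direction_bias(self, fdr_max: float | None = None) -> BiasSummary:
        return direction_bias(self.results, fdr_max)

    def compare_to(self, corrected: "EqtlScanResults") -> RunComparison:
        """Treat self as the uncorrected run and ``corrected`` as the re-run."""
        return compare_runs(self.results, corrected.results)

    def n_significant(self, fdr_max: float = 0.05) -> int:
        return sum(1 for r in self.results if r.q_value is not None and r.q_value <= fdr_max)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self, fdr_max: float = 0.05) -> str:
        bias = self.direction_bias()
        lines = [
            "eQTL scan results",
            "=================",
            f"mode:                    {self.model.mode}"
            + (f" (window {self.model.cis_window_bp:,} bp)" if self.model.mode == "cis" else ""),
            f"probesets tested:        {len(self.results)}",
            f"samples:                 {len(set(self.model.expr.sample_ids) & set(self.model.geno.sample_ids))}",
            f"loci:                    {len(self.model.geno.locus_ids)}",
            f"significant (FDR<={fdr_max:g}):  {self.n_significant(fdr_max)}",
            f"allele effect d > 0:     {bias.n_positive_d}/{bias.n_eqtl - bias.n_ties_excluded}"
            f" ({100 * bias.fraction_positive:.1f} %)",
            f"binomial P vs 50 %:      {bias.binomial_p:.3g}",
        ]
        return "\n".join(lines)
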