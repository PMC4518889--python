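"""End-to-end workflows tying masking and scanning together.

`run_bias_eval` is the whole experiment in one call: simulate a study with
injectable probe bias, scan it as-is, equalize the annotation against the
simulated variants, re-summarize and re-scan, and report the
direction-of-effect bias before and after together with the per-probeset
change in eQTL strength.
"""

from __future__ import annotations

from dataclasses import dataclass

from .eqtl import (
    BiasSummary,
    EqtlScan,
    EqtlScanResults,
    RunComparison,
    compare_runs,
)
from .equalize import MaskReport, equalize_annotation
from .intersect import build_index, probes_hit
from .synthetic import SimConfig, SimStudy, simulate_study, summarize_probesets

__all__ = ["BiasEvalResult", "run_bias_eval"]


@dataclass
class BiasEvalResult:
    study: SimStudy
    mask_report: MaskReport
    uncorrected: EqtlScanResults
    corrected: EqtlScanResults
    bias_before: BiasSummary
    bias_after: BiasSummary
    comparison: RunComparison

    def summary(self) -> str:
        b, a = self.bias_before, self.bias_after
        lines = [
            "probe-bias evaluation",
            "=====================",
            f"probes removed:      {self.mask_report.probes_removed}/{self.mask_report.probes_total}",
            f"probesets dropped:   {self.mask_report.probesets_dropped}/{self.mask_report.probesets_total}",
            f"d > 0 before:        {100 * b.fraction_positive:.1f} % (binomial P = {b.binomial_p:.3g})",
            f"d > 0 after:         {100 * a.fraction_positive:.1f} % (binomial P = {a.binomial_p:.3g})",
            f"lost significance:   {100 * self.comparison.fraction_decreased:.1f} % of shared probesets",
        ]
        if self.comparison.pearson_r is not None:
            lines.append(
                f"strength vs loss r:  {self.comparison.pearson_r:.3f}"
                f" (P = {self.comparison.pearson_p:.3g})"
            )
        return "\n".join(lines)


def run_bias_eval(cfg: SimConfig, mode: str = "genomewide") -> BiasEvalResult:
    """Simulate, scan, mask, re-scan; quantify the bias correction."""
    study = simulate_study(cfg)
    annotation = study.platform.annotation

    index = build_index(study.platform.variants)
    hits = probes_hit(annotation.probes.values(), index)
    masked, report = equalize_annotation(annotation, hits)

    tss = study.platform.tss if mode == "cis" else None
    uncorrected = EqtlScan(study.expression, study.genotypes, mode=mode, tss=tss).fit()
    expr_after = summarize_probesets(study.probe_expr, masked)
    corrected = EqtlScan(expr_after, study.genotypes, mode=mode, tss=tss).fit()

    return BiasEvalResult(
        study=study,
        mask_report=report,
        uncorrected=uncorrected,
        corrected=corrected,
        bias_before=uncorrected.direction_bias(),
        bias_after=corrected.direction_bias(),
        comparison=compare_runs(uncorrected.results, corrected.results),
    )
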