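"""Remove variant-hit probes from their probesets and account for it.

Any probe overlapping at least one variant footprint is removed from its
probeset; a probeset whose every member is removed disappears from the
annotation entirely.  The accompanying report records, per probeset, how
many probes it had and how many were taken away, so the scale of the edit
is auditable.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping

from .errors import ParseError
from .probes import AnnotationSet, Probeset

logger = logging.getLogger(__name__)

__all__ = ["MaskReport", "equalize_annotation", "write_report", "read_report"]


@dataclass(frozen=True)
class MaskReport:
    """Per-probeset removal accounting plus conserved totals.

    rows: probeset_id -> (n_probes_before, n_probes_removed)
    """

    rows: dict[str, tuple[int, int]]
    probes_total: int
    probes_removed: int
    probesets_total: int
    probesets_dropped: int
    min_probes: int = 1

    def __post_init__(self) -> None:
        before = sum(b for b, _ in self.rows.values())
        removed = sum(r for _, r in self.rows.values())
        dropped = sum(1 for b, r in self.rows.values() if b - r < self.min_probes)
        if before != self.probes_total or removed != self.probes_removed:
            raise ValueError("report totals do not match per-probeset rows")
        if len(self.rows) != self.probesets_total or dropped != self.probesets_dropped:
            raise ValueError("probeset totals do not match per-probeset rows")
        for ps_id, (b, r) in self.rows.items():
            if not (0 <= r <= b):
                raise ValueError(f"impossible removal count for {ps_id}: {r}/{b}")


def equalize_annotation(
    aset: AnnotationSet,
    hits: Mapping[str, int],
    min_probes: int = 1,
) -> tuple[AnnotationSet, MaskReport]:
    """Drop every hit probe; prune probesets left with < ``min_probes``.

    ``hits`` is the probe_id -> overlap-count table from the intersection
    stage; the count is reported but never thresholded — one overlap is
    enough to distrust a probe.  Hit ids unknown to the annotation are
    ignored with a warning so one hit list can serve annotation subsets.
    Surviving probesets keep their members in the original order.
    """
    unknown = set(hits) - set(aset.probes)
    if unknown:
        logger.warning(
            "%d hit probe ids are not in the annotation (e.g. %s); ignoring",
            len(unknown), sorted(unknown)[:5],
        )

    new_probes = {}
    new_probesets = {}
    rows: dict[str, tuple[int, int]] = {}
    dropped = 0
    for ps_id, ps in aset.probesets.items():
        survivors = tuple(pid for pid in ps.probe_ids if pid not in hits)
        n_before = len(ps.probe_ids)
        n_removed = n_before - len(survivors)
        rows[ps_id] = (n_before, n_removed)
        if len(survivors) == 0 or len(survivors) < min_probes:
            dropped += 1
            continue
        new_probesets[ps_id] = Probeset(ps_id, survivors, ps.gene_symbol, ps.tss)
        for pid in survivors:
            new_probes[pid] = aset.probes[pid]

    report = MaskReport(
        rows=rows,
        probes_total=aset.n_probes,
        probes_removed=sum(r for _, r in rows.values()),
        probesets_total=aset.n_probesets,
        probesets_dropped=aset.n_probesets - len(new_probesets),
        min_probes=min_probes,
    )
    out = AnnotationSet(aset.platform_name, new_probesets, new_probes)
    return out, report


def write_report(report: MaskReport, path: str | os.PathLike) -> None:
    """Serialize the report as TSV: one row per probeset, #TOTAL footer."""
    with open(path, "w") as fh:
        fh.write("probeset_id\tn_probes_before\tn_probes_removed\tn_probes_after\n")
        for ps_id in sorted(report.rows):
            b, r = report.rows[ps_id]
            fh.write(f"{ps_id}\t{b}\t{r}\t{b - r}\n")
        fh.write(f"#TOTAL probes\t{report.probes_total}\t{report.probes_removed}"
                 f"\t{report.probes_total - report.probes_removed}\n")
        fh.write(f"#TOTAL probesets\t{report.probesets_total}\t{report.probesets_dropped}"
                 f"\t{report.probesets_total - report.probesets_dropped}\n")
        if report.min_probes != 1:
            fh.write(f"#TOTAL min_probes\t{report.min_probes}\n")


def read_report(path: str | os.PathLike) -> MaskReport:
    rows: dict[str, tuple[int, int]] = {}
    totals: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("probeset_id\t"):
            raise ParseError("not a mask report TSV", 1)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if line.startswith("#TOTAL"):
                totals[cols[0]] = tuple(int(c) for c in cols[1:3])
                continue
            rows[cols[0]] = (int(cols[1]), int(cols[2]))
    pt, pr = totals.get("#TOTAL probes", (0, 0))
    st, sd = totals.get("#TOTAL probesets", (0, 0))
    mp = totals.get("#TOTAL min_probes", (1,))[0]
    return MaskReport(rows, pt, pr, st, sd, mp)
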