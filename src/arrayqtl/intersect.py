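"""Probe-vs-variant interval intersection.

A probe is compromised when its genomic footprint shares at least one base
with the footprint of any variant, regardless of strand or of where within
the probe the variant falls.  The engine is an interval tree per
chromosome; its contract is exact agreement with a brute-force all-pairs
scan, which the test suite enforces on random inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .probes import Probe, write_probe_bed
from .variants import Variant, variant_interval

logger = logging.getLogger(__name__)

__all__ = ["VariantIndex", "build_index", "probes_hit", "write_hit_bed"]


@dataclass
class VariantIndex:
    """Per-chromosome interval trees over variant footprints."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)
    n_variants: int = 0

    def chromosomes(self) -> set[str]:
        return set(self.trees)

    def count_overlaps(self, chrom: str, start0: int, end0: int) -> int:
        tree = self.trees.get(chrom)
        if tree is None:
            return 0
        return len(tree.overlap(start0, end0))


def build_index(variants: Iterable[Variant]) -> VariantIndex:
    """Index variant footprints for overlap queries.

    The index stores exactly what it is given; deduplication of identical
    records across sources happens upstream (merge_variant_sources).
    """
    index = VariantIndex()
    for n, v in enumerate(variants, start=1):
        iv = variant_interval(v)
        tree = index.trees.setdefault(iv.chrom, IntervalTree())
        # data=n keeps duplicate-footprint variants distinct in the tree
        tree.addi(iv.start0, iv.end0, n)
        index.n_variants = n
    return index


def probes_hit(probes: Iterable[Probe], index: VariantIndex) -> dict[str, int]:
    """Map probe_id -> number of variant footprints it overlaps.

    Probes overlapping nothing are absent from the result, so the mapping
    doubles as the set of probes to remove.  Overlap is half-open interval
    intersection on the same chromosome; strand never matters.
    """
    hits: dict[str, int] = {}
    for p in probes:
        n = index.count_overlaps(p.interval.chrom, p.interval.start0, p.interval.end0)
        if n:
            hits[p.probe_id] = n
    return hits


def write_hit_bed(
    probes: Iterable[Probe], hits: Mapping[str, int], path: str
) -> None:
    """Audit trail: the hit probes as BED, for inspection with genome tools."""
    write_probe_bed([p for p in probes if p.probe_id in hits], path)
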