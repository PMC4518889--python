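"""Genome variants: VCF reading, MAF filtering and genomic footprints.

A variant is reduced to the minimum the probe-masking workflow needs: its
genomic footprint (the reference bases it occupies), a folded minor allele
frequency when one can be determined, and a free-text population tag naming
the strain or population the variant set describes.

Coordinate conventions: VCF positions are 1-based; probe coordinates (BED)
are 0-based half-open.  :func:`variant_interval` performs the conversion, so
everything downstream works in 0-based half-open intervals.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from cyvcf2 import VCF

from .errors import InputError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeInterval",
    "Variant",
    "read_vcf",
    "variant_interval",
    "merge_variant_sources",
    "normalize_chrom",
]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A 0-based half-open genomic interval [start0, end0) on one chromosome."""

    chrom: str
    start0: int
    end0: int

    def __post_init__(self) -> None:
        if self.start0 < 0:
            raise ValueError(f"negative interval start: {self.start0}")
        if self.end0 <= self.start0:
            raise ValueError(
                f"empty or inverted interval [{self.start0}, {self.end0})"
            )

    def __len__(self) -> int:
        return self.end0 - self.start0

    def overlaps(self, other: "GenomeInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start0 < other.end0
            and other.start0 < self.end0
        )


@dataclass(frozen=True)
class Variant:
    """One VCF record reduced to footprint + minor allele frequency.

    ``maf`` is the folded non-reference allele frequency (min of the
    non-REF frequency and its complement), in [0, 0.5], or None when the
    record carried neither an AF INFO field nor genotype columns.
    """

    chrom: str
    pos_1based: int
    ref: str
    alts: tuple[str, ...]
    maf: float | None = None
    population_tag: str = ""

    def __post_init__(self) -> None:
        if self.pos_1based < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos_1based}")
        if not self.ref:
            raise ValueError("REF allele must be non-empty")
        if not self.alts:
            raise ValueError("ALT allele list must be non-empty")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"folded MAF must lie in [0, 0.5], got {self.maf}")

    @property
    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        """Identity used for deduplication across variant sources."""
        return (self.chrom, self.pos_1based, self.ref, self.alts)

    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


def normalize_chrom(name: str, style: str | None) -> str:
    """Reconcile 'chr1' vs '1' naming between VCF and BED inputs.

    style: None (exact match), "strip_chr", or "add_chr".
    """
    if style is None:
        return name
    if style == "strip_chr":
        return name[3:] if name.lower().startswith("chr") else name
    if style == "add_chr":
        return name if name.lower().startswith("chr") else "chr" + name
    raise ValueError(f"unknown chromosome style {style!r}")


def _fold(freq: float) -> float:
    """Fold a non-reference allele frequency to the minor allele: [0, 0.5]."""
    return min(freq, 1.0 - freq)


def _af_from_info(rec) -> float | None:
    """Site-level non-REF frequency from the AF INFO tag, if present.

    Multi-allelic records report one AF per ALT; the site-level non-REF
    frequency is their sum (any ALT under a probe is disqualifying, so the
    site is treated as one variant).
    """
    raw = rec.INFO.get("AF")
    if raw is None:
        return None
    if isinstance(raw, (tuple, list)):
        vals = [float(x) for x in raw]
    elif isinstance(raw, (bytes, str)):
        s = raw.decode() if isinstance(raw, bytes) else raw
        vals = [float(x) for x in s.split(",")]
    else:
        vals = [float(raw)]
    return min(sum(vals), 1.0)

def _af_from_genotypes(rec) -> float | None:
    """Non-REF allele frequency by allele counting over GT columns.

    Missing calls (./.) are excluded from the denominator.  Returns None
    when the record has no sample columns or every call is missing.
    """
    gts = rec.genotypes
    if not gts:
        return None
    non_ref = 0
    total = 0
    for gt in gts:
        for allele in gt[:-1]:  # last element is the phasing flag
            if allele is None or allele < 0:
                continue
            total += 1
            if allele > 0:
                non_ref += 1
    if total == 0:
        return None
    return non_ref / total


def read_vcf(
    path: str | os.PathLike,
    maf_min: float = 0.0,
    population_tag: str = "",
    *,
    keep_filtered: bool = False,
    snv_only: bool = False,
    chrom_style: str | None = None,
    tally: dict | None = None,
) -> Iterator[Variant]:
    """Stream variants from a VCF 4.x file (plain or gzipped).

    Records are kept when their folded MAF is >= ``maf_min`` (inclusive
    threshold).  MAF is taken from the AF INFO field when present, else
    computed from GT sample columns; records offering neither are skipped
    whenever ``maf_min > 0`` and counted under ``tally['no_maf']``.

    Records whose FILTER is neither PASS nor "." are skipped unless
    ``keep_filtered`` is set.  ``snv_only`` drops indels and other
    multi-base footprints.  ``tally`` (a dict, mutated in place) receives
    counts under keys kept / below_maf / filtered / no_maf / not_snv.
    """
    if not (0.0 <= maf_min <= 1.0):
        raise ValueError(f"maf_min must lie in [0, 1], got {maf_min}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"VCF file not found: {path}")
    if tally is None:
        tally = {}
    for k in ("kept", "below_maf", "filtered", "no_maf", "not_snv"):
        tally.setdefault(k, 0)

    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib refuses the header
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    n_header = vcf.raw_header.count("\n")
    n_records = 0
    records = iter(vcf)
    while True:
        try:
            rec = next(records)
        except StopIteration:
            break
        except Exception as exc:
            raise ParseError(
                f"malformed VCF record in {path}: {exc}",
                line_number=n_header + n_records + 1,
            ) from exc
        n_records += 1
        # cyvcf2 reports FILTER=None for both PASS and "."
        if rec.FILTER is not None and not keep_filtered:
            tally["filtered"] += 1
            continue
        alts = tuple(rec.ALT)
        if not alts:
            continue
        ref = rec.REF
        if snv_only and (len(ref) != 1 or any(len(a) != 1 for a in alts)):
            tally["not_snv"] += 1
            continue
        freq = _af_from_info(rec)
        if freq is None:
            freq = _af_from_genotypes(rec)
        if freq is None:
            if maf_min > 0:
                tally["no_maf"] += 1
                continue
            maf = None
        else:
            maf = _fold(freq)
            if maf < maf_min:
                tally["below_maf"] += 1
                continue
        tally["kept"] += 1
        yield Variant(
            chrom=normalize_chrom(rec.CHROM, chrom_style),
            pos_1based=rec.POS,
            ref=ref,
            alts=alts,
            maf=maf,
            population_tag=population_tag,
        )


def variant_interval(v: Variant) -> GenomeInterval:
    """The 0-based half-open footprint of a variant's REF allele.

    SNVs occupy one base; deletions span the full REF length; insertions
    anchor at the single REF base they are reported on.
    """
    start0 = v.pos_1based - 1
    return GenomeInterval(v.chrom, start0, start0 + len(v.ref))


def merge_variant_sources(sources: list[Iterable[Variant]]) -> Iterator[Variant]:
    """Union of several variant streams, deduplicated on (chrom, pos, ref, alts).

    The first occurrence wins, keeping its population tag.  Two records at
    the same position with different ALT alleles are both kept.
    """
    if not sources:
        raise ValueError("merge_variant_sources requires at least one source")
    seen: set = set()
    for source in sources:
        for v in source:
            if v.key in seen:
                continue
            seen.add(v.key)
            yield v
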