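"""Platform annotation model: probes, probesets and their file dialects.

An Affymetrix-style expression array reports one value per *probeset*, a
small ensemble of ~25-nt *probes* whose signals are summarized together.
The annotation — which probes exist, where they sit on the genome, and
which probeset owns each — is what the masking workflow edits.

Two on-disk dialects are supported:

* ``generic_tsv`` — a single TSV with one row per probe and columns
  ``probeset_id  probe_id  chrom  start0  end0  strand  gene_symbol  tss``
  (the last two optional, ``tss`` written as ``chrom:pos1``).
* ``pgf_clf`` — a simplified text rendering of the vendor's PGF/CLF pair:
  the PGF carries the probeset→probe hierarchy (vendor atom/block levels
  flattened), the CLF carries probe coordinates.  The binary CDF dialect
  is out of scope.

Both dialects round-trip: ``read(write(A)) == A`` field for field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InputError, IntegrityError, ParseError
from .variants import GenomeInterval

__all__ = [
    "Probe",
    "Probeset",
    "AnnotationSet",
    "read_probe_bed",
    "write_probe_bed",
    "read_annotation",
    "write_annotation",
]

STRANDS = ("+", "-", ".")  # "." = unknown


@dataclass(frozen=True)
class Probe:
    probe_id: str
    probeset_id: str
    interval: GenomeInterval
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class Probeset:
    probeset_id: str
    probe_ids: tuple[str, ...]
    gene_symbol: str | None = None
    tss: tuple[str, int] | None = None  # (chrom, 1-based position)

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError(f"probeset {self.probeset_id} has no probes")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError(f"probeset {self.probeset_id} has duplicate members")


@dataclass
class AnnotationSet:
    """A complete, internally consistent platform description.

    Invariants (checked on construction): every probe's owning probeset
    exists and lists it as a member; every member id resolves to a probe;
    no probeset is empty.
    """

    platform_name: str
    probesets: dict[str, Probeset]
    probes: dict[str, Probe]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        orphans = [
            p.probe_id for p in self.probes.values()
            if p.probeset_id not in self.probesets
        ]
        if orphans:
            raise IntegrityError(
                f"probes reference unknown probesets: {sorted(orphans)[:10]}"
            )
        for ps in self.probesets.values():
            for pid in ps.probe_ids:
                if pid not in self.probes:
                    raise IntegrityError(
                        f"probeset {ps.probeset_id} lists unknown probe {pid}"
                    )
                if self.probes[pid].probeset_id != ps.probeset_id:
                    raise IntegrityError(
                        f"probe {pid} owned by {self.probes[pid].probeset_id} "
                        f"but listed in {ps.probeset_id}"
                    )
        listed = {pid for ps in self.probesets.values() for pid in ps.probe_ids}
        unlisted = set(self.probes) - listed
        if unlisted:
            raise IntegrityError(
                f"probes present but listed in no probeset: {sorted(unlisted)[:10]}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_probesets(self) -> int:
        return len(self.probesets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.platform_name == other.platform_name
            and self.probesets == other.probesets
            and self.probes == other.probes
        )


# ---------------------------------------------------------------------------
# BED


def read_probe_bed(
    path: str | os.PathLike,
    membership: Mapping[str, str] | None = None,
) -> list[Probe]:
    """Read probe locations from a BED file (>= 4 columns).

    The name column (4) encodes membership as ``probesetID:probeID``; a
    bare probe id is resolved through ``membership`` (probe_id →
    probeset_id), typically derived from a sidecar annotation.  Strand is
    taken from column 6 when present.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"BED file not found: {path}")
    probes: list[Probe] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(
                    f"BED line has {len(cols)} columns, need >= 4", lineno
                )
            chrom, start_s, end_s, name = cols[:4]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"non-integer BED coordinate: {exc}", lineno)
            if start0 >= end0:
                raise ParseError(
                    f"BED interval start >= end ({start0} >= {end0})", lineno
                )
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
            if ":" in name:
                probeset_id, probe_id = name.split(":", 1)
            else:
                probe_id = name
                if membership is None or probe_id not in membership:
                    raise IntegrityError(
                        f"line {lineno}: probe {probe_id!r} carries no probeset "
                        "and no membership table was provided"
                    )
                probeset_id = membership[probe_id]
            if probe_id in seen:
                raise IntegrityError(f"duplicate probe id {probe_id!r} in {path}")
            seen.add(probe_id)
            probes.append(
                Probe(probe_id, probeset_id, GenomeInterval(chrom, start0, end0), strand)
            )
    return probes


def write_probe_bed(probes: Iterable[Probe], path: str | os.PathLike) -> None:
    """Write probes as 6-column BED with ``probesetID:probeID`` names."""
    with open(path, "w") as fh:
        for p in sorted(probes, key=lambda p: (p.interval.chrom, p.interval.start0, p.probe_id)):
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start0}\t{p.interval.end0}"
                f"\t{p.probeset_id}:{p.probe_id}\t0\t{p.strand}\n"
            )


# ---------------------------------------------------------------------------
# generic TSV dialect

_TSV_HEADER = [
    "probeset_id", "probe_id", "chrom", "start0", "end0",
    "strand", "gene_symbol", "tss",
]


def _format_tss(tss: tuple[str, int] | None) -> str:
    return f"{tss[0]}:{tss[1]}" if tss else ""


def _parse_tss(text: str, lineno: int) -> tuple[str, int] | None:
    if not text:
        return None
    try:
        chrom, pos = text.rsplit(":", 1)
        return (chrom, int(pos))
    except ValueError:
        raise ParseError(f"cannot parse tss field {text!r}", lineno)


def _read_generic_tsv(path: str, platform_name: str) -> AnnotationSet:
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = _TSV_HEADER[:6]
        if header[: len(required)] != required:
            raise ParseError(
                f"unexpected TSV header {header!r}, expected to start with {required}", 1
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if line:
                rows.append((lineno, line.split("\t")))

    probes: dict[str, Probe] = {}
    members: dict[str, list[str]] = {}
    meta: dict[str, tuple[str | None, tuple[str, int] | None]] = {}
    for lineno, cols in rows:
        if len(cols) < 6:
            raise ParseError(f"row has {len(cols)} columns, need >= 6", lineno)
        ps_id, probe_id, chrom = cols[0], cols[1], cols[2]
        try:
            start0, end0 = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise ParseError(f"non-integer coordinate: {exc}", lineno)
        strand = cols[5] if cols[5] in ("+", "-") else "."
        gene = cols[6] if len(cols) > 6 and cols[6] else None
        tss = _parse_tss(cols[7], lineno) if len(cols) > 7 else None
        if probe_id in probes:
            raise IntegrityError(f"duplicate probe id {probe_id!r}")
        probes[probe_id] = Probe(probe_id, ps_id, GenomeInterval(chrom, start0, end0), strand)
        members.setdefault(ps_id, []).append(probe_id)
        prev = meta.get(ps_id)
        if prev is not None and prev != (gene, tss):
            raise IntegrityError(
                f"probeset {ps_id} has conflicting gene_symbol/tss across rows"
            )
        meta[ps_id] = (gene, tss)

    probesets = {
        ps_id: Probeset(ps_id, tuple(pids), meta[ps_id][0], meta[ps_id][1])
        for ps_id, pids in members.items()
    }
    return AnnotationSet(platform_name, probesets, probes)


def _write_generic_tsv(aset: AnnotationSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for ps_id in sorted(aset.probesets):
            ps = aset.probesets[ps_id]
            for pid in ps.probe_ids:
                p = aset.probes[pid]
                fh.write(
                    "\t".join(
                        [
                            ps_id, pid, p.interval.chrom,
                            str(p.interval.start0), str(p.interval.end0),
                            p.strand, ps.gene_symbol or "", _format_tss(ps.tss),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# simplified PGF/CLF dialect

def _pgf_clf_paths(path: str | os.PathLike) -> tuple[Path, Path]:
    """Resolve a base path (or explicit .pgf/.clf path) to the file pair."""
    p = Path(path)
    if p.suffix in (".pgf", ".clf"):
        p = p.with_suffix("")
    return p.with_suffix(".pgf"), p.with_suffix(".clf")


def _read_pgf_clf(path: str, platform_name: str) -> AnnotationSet:
    pgf_path, clf_path = _pgf_clf_paths(path)
    for fp in (pgf_path, clf_path):
        if not fp.exists():
            raise InputError(f"annotation file not found: {fp}")

    # PGF: probeset lines at column 0, member probe lines indented one tab.
    members: dict[str, list[str]] = {}
    meta: dict[str, tuple[str | None, tuple[str, int] | None]] = {}
    owner: dict[str, str] = {}
    current: str | None = None
    name = platform_name
    with open(pgf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#%platform="):
                name = line.split("=", 1)[1]
                continue
            if line.startswith("#"):
                continue
            if line.startswith("\t"):
                if current is None:
                    raise ParseError("probe line before any probeset", lineno)
                probe_id = line.strip()
                if probe_id in owner:
                    raise IntegrityError(f"duplicate probe id {probe_id!r} in PGF")
                owner[probe_id] = current
                members[current].append(probe_id)
            else:
                cols = line.split("\t")
                current = cols[0]
                if current in members:
                    raise IntegrityError(f"duplicate probeset id {current!r} in PGF")
                gene = cols[1] if len(cols) > 1 and cols[1] else None
                tss = _parse_tss(cols[2], lineno) if len(cols) > 2 else None
                members[current] = []
                meta[current] = (gene, tss)

    # CLF: one coordinate line per probe.
    coords: dict[str, tuple[GenomeInterval, str]] = {}
    with open(clf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(f"CLF line has {len(cols)} columns, need >= 4", lineno)
            probe_id, chrom = cols[0], cols[1]
            try:
                start0, end0 = int(cols[2]), int(cols[3])
            except ValueError as exc:
                raise ParseError(f"non-integer CLF coordinate: {exc}", lineno)
            strand = cols[4] if len(cols) > 4 and cols[4] in ("+", "-") else "."
            if probe_id in coords:
                raise IntegrityError(f"duplicate probe id {probe_id!r} in CLF")
            coords[probe_id] = (GenomeInterval(chrom, start0, end0), strand)

    only_pgf = sorted(set(owner) - set(coords))
    only_clf = sorted(set(coords) - set(owner))
    if only_pgf or only_clf:
        raise IntegrityError(
            f"PGF/CLF mismatch: in hierarchy only {only_pgf[:10]}, "
            f"in coordinates only {only_clf[:10]}"
        )

    probes = {
        pid: Probe(pid, owner[pid], coords[pid][0], coords[pid][1]) for pid in owner
    }
    probesets = {
        ps_id: Probeset(ps_id, tuple(pids), meta[ps_id][0], meta[ps_id][1])
        for ps_id, pids in members.items()
    }
    return AnnotationSet(name, probesets, probes)


def _write_pgf_clf(aset: AnnotationSet, path: str) -> None:
    pgf_path, clf_path = _pgf_clf_paths(path)
    with open(pgf_path, "w") as fh:
        fh.write(f"#%platform={aset.platform_name}\n")
        for ps_id in sorted(aset.probesets):
            ps = aset.probesets[ps_id]
            fh.write(f"{ps_id}\t{ps.gene_symbol or ''}\t{_format_tss(ps.tss)}\n")
            for pid in ps.probe_ids:
                fh.write(f"\t{pid}\n")
    with open(clf_path, "w") as fh:
        fh.write(f"#%platform={aset.platform_name}\n")
        for ps_id in sorted(aset.probesets):
            for pid in aset.probesets[ps_id].probe_ids:
                p = aset.probes[pid]
                fh.write(
                    f"{pid}\t{p.interval.chrom}\t{p.interval.start0}"
                    f"\t{p.interval.end0}\t{p.strand}\n"
                )


# ---------------------------------------------------------------------------
# dispatch

DIALECTS = ("generic_tsv", "pgf_clf")


def read_annotation(
    path: str | os.PathLike,
    dialect: str = "generic_tsv",
    platform_name: str = "platform",
) -> AnnotationSet:
    """Read a platform annotation; see module docstring for the dialects."""
    path = os.fspath(path)
    if dialect == "generic_tsv":
        if not os.path.exists(path):
            raise InputError(f"annotation file not found: {path}")
        return _read_generic_tsv(path, platform_name)
    if dialect == "pgf_clf":
        return _read_pgf_clf(path, platform_name)
    raise ValueError(f"unknown annotation dialect {dialect!r}; choose from {DIALECTS}")


def write_annotation(
    aset: AnnotationSet, path: str | os.PathLike, dialect: str = "generic_tsv"
) -> None:
    """Write an annotation so that re-reading reproduces it exactly.

    Output ordering is deterministic (probesets lexicographic by id,
    member probes in their stored order), so a diff between the original
    and an equalized annotation is reviewable.
    """
    path = os.fspath(path)
    if dialect == "generic_tsv":
        _write_generic_tsv(aset, path)
    elif dialect == "pgf_clf":
        _write_pgf_clf(aset, path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}; choose from {DIALECTS}")
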