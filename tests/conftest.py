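import numpy as np
import pytest

from arrayqtl.probes import AnnotationSet, Probe, Probeset
from arrayqtl.variants import GenomeInterval, Variant


def make_annotation(spec: dict[str, list[tuple[str, str, int, int]]],
                    platform: str = "test") -> AnnotationSet:
    """Build an AnnotationSet from {probeset: [(probe_id, chrom, start0, end0), ...]}."""
    probes = {}
    probesets = {}
    for ps_id, rows in spec.items():
        member_ids = []
        for probe_id, chrom, start0, end0 in rows:
            probes[probe_id] = Probe(probe_id, ps_id, GenomeInterval(chrom, start0, end0))
            member_ids.append(probe_id)
        probesets[ps_id] = Probeset(ps_id, tuple(member_ids))
    return AnnotationSet(platform, probesets, probes)


def random_annotation(rng: np.random.Generator,
                      n_probesets: int = 5,
                      max_probes: int = 6,
                      with_meta: bool = True) -> AnnotationSet:
    """A random but valid AnnotationSet on two small chromosomes."""
    probes = {}
    probesets = {}
    for s in range(n_probesets):
        ps_id = f"PS{s}"
        chrom = f"chr{rng.integers(1, 3)}"
        n = int(rng.integers(1, max_probes + 1))
        member_ids = []
        for k in range(n):
            pid = f"PS{s}_P{k}"
            start0 = int(rng.integers(0, 10_000))
            probes[pid] = Probe(
                pid, ps_id,
                GenomeInterval(chrom, start0, start0 + 25),
                str(rng.choice(["+", "-", "."])),
            )
            member_ids.append(pid)
        gene = f"Gene{s}" if with_meta and rng.random() < 0.5 else None
        tss = (chrom, int(rng.integers(1, 10_000))) if with_meta and rng.random() < 0.5 else None
        probesets[ps_id] = Probeset(ps_id, tuple(member_ids), gene, tss)
    return AnnotationSet("random-platform", probesets, probes)


def random_variants(rng: np.random.Generator, n: int = 50,
                    span: int = 10_200) -> list[Variant]:
    out = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, 3)}"
        pos = int(rng.integers(1, span))
        ref_len = int(rng.choice([1, 1, 1, 2, 3]))  # mostly SNVs, some deletions
        out.append(Variant(chrom, pos, "A" * ref_len, ("G",), maf=0.5, population_tag="T"))
    return out


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
    '##FILTER=<ID=q10,Description="low qual">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf_text(path, records: list[str], samples: list[str] | None = None) -> str:
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + "".join(r + "\n" for r in records))
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
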