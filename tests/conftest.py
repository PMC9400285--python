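"""Shared fixtures: synthetic allele databases, read sets and tiny BAMs.

All fixtures are generated programmatically; BAM files are built at test
time from in-memory alignments via pysam and indexed in the tmp directory.
"""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from kirgeno import (
    EmConfig,
    GeneRegion,
    make_synthetic_database,
)


@pytest.fixture(scope="session")
def small_db():
    """3 genes x 6 coding variants, 1000 bp, pairwise divergent by >= 20."""
    return make_synthetic_database(
        n_genes=3, alleles_per_gene=6, allele_length=1000, divergence=20, seed=42
    )


@pytest.fixture(scope="session")
def sibling_db():
    """Same shape but every coding group has 2 synonymous siblings."""
    return make_synthetic_database(
        n_genes=3,
        alleles_per_gene=6,
        allele_length=1000,
        divergence=20,
        synonymous_siblings=2,
        seed=42,
    )


@pytest.fixture
def default_config():
    return EmConfig(alpha=1e-5, n_boot=100, p=0.5, t_threshold=0.25, seed=0)


def make_bam(
    path: Path,
    reads: list[tuple[str, str, int, bool]],
    contig: str = "chr19",
    contig_length: int = 200_000,
    index: bool = True,
) -> Path:
    """Write a coordinate-sorted, indexed BAM from (name, seq, pos, flags).

    ``reads`` entries are (query_name, sequence, 0-based position,
    is_duplicate).  All reads are primary, forward-strand, fully matched
    (CIGAR <len>M).
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": contig, "LN": contig_length}]}
    unsorted = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as out:
        for name, seq, pos, is_dup in sorted(reads, key=lambda r: r[2]):
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = pos
            a.cigarstring = f"{len(seq)}M"
            a.mapping_quality = 60
            a.flag = 1024 if is_dup else 0
            out.write(a)
    pysam.sort("-o", str(path), str(unsorted))
    unsorted.unlink()
    if index:
        pysam.index(str(path))
    return path


@pytest.fixture
def tiny_bam(tmp_path):
    """5 primary reads: 3 inside [1000, 2000), 2 far away."""
    inside = [(f"in{i}", "ACGT" * 25, 1200 + 50 * i, False) for i in range(3)]
    outside = [(f"out{i}", "TTTT" * 25, 50_000 + 200 * i, False) for i in range(2)]
    return make_bam(tmp_path / "tiny.bam", inside + outside)


@pytest.fixture
def kir_region():
    return GeneRegion(gene="KIR2DL1", chrom="chr19", start=1000, end=2000)
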