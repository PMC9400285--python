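"""Extraction of WES reads overlapping the KIR gene loci from BAM/CRAM.

Reads are harvested per gene region (BED coordinates, 0-based half-open) and
written to one read collection per gene, mirroring the per-gene processing of
the genotyping workflow.  Mate pairs are treated as independent reads; a mate
suffix keeps identifiers unique within a set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam

from .alleles import KIR_GENES


class RegionConfigError(ValueError):
    """A region refers to a contig absent from the alignment header."""


@dataclass(frozen=True)
class GeneRegion:
    """A KIR gene locus: contig plus 0-based half-open coordinates."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region for {self.gene}: {self.start}>={self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadSet:
    """The reads assigned to one gene: (read_id, sequence) pairs."""

    gene: str
    reads: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


def load_regions_bed(bed_path: str | Path) -> list[GeneRegion]:
    """Read a 4-column BED (chrom, start, end, gene) of KIR gene regions."""
    regions: list[GeneRegion] = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"BED line needs 4 columns: {line!r}")
            chrom, start, end, gene = fields[:4]
            if gene not in KIR_GENES:
                raise ValueError(f"unknown KIR gene in BED: {gene!r}")
            regions.append(GeneRegion(gene=gene, chrom=chrom, start=int(start), end=int(end)))
    return regions


def _open_alignment(path: str | Path) -> pysam.AlignmentFile:
    p = str(path)
    mode = "rc" if p.endswith(".cram") else "rb"
    try:
        af = pysam.AlignmentFile(p, mode)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot open alignment file {p}: {exc}") from exc
    if not af.has_index():
        af.close()
        raise IOError(f"alignment file {p} is not indexed (run samtools index)")
    return af


def _check_contigs(af: pysam.AlignmentFile, regions: Iterable[GeneRegion]) -> None:
    known = set(af.references)
    for region in regions:
        if region.chrom not in known:
            raise RegionConfigError(
                f"contig {region.chrom!r} (gene {region.gene}) absent from alignment header"
            )


def extract_kir_reads(
    alignment_path: str | Path,
    regions: list[GeneRegion],
    min_mapped_overlap: int = 1,
    exclude_duplicates: bool = False,
) -> dict[str, ReadSet]:
    """Collect primary-alignment reads overlapping each gene region.

    A read enters a gene's :class:`ReadSet` iff its aligned reference span
    overlaps the region by at least ``min_mapped_overlap`` bp; a read
    straddling two regions appears in both.  Unmapped, secondary and
    supplementary alignments are excluded; duplicate-marked reads are kept
    unless ``exclude_duplicates``.  Sequences are emitted as stored in the
    file (no reverse-complementing).  Output is sorted by read id and mate
    suffix, so it is independent of file iteration order.
    """
    out: dict[str, ReadSet] = {}
    with _open_alignment(alignment_path) as af:
        _check_contigs(af, regions)
        for region in regions:
            collected: list[tuple[str, str]] = []
            for aln in af.fetch(region.chrom, region.start, region.end):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if exclude_duplicates and aln.is_duplicate:
                    continue
                overlap = min(aln.reference_end, region.end) - max(
                    aln.reference_start, region.start
                )
                if overlap < min_mapped_overlap:
                    continue
                seq = aln.query_sequence
                if not seq:
                    continue
                mate = "/2" if aln.is_read2 else "/1"
                collected.append((f"{aln.query_name}{mate}", seq))
            collected.sort()
            out[region.gene] = ReadSet(gene=region.gene, reads=collected)
    return out


def mean_region_coverage(alignment_path: str | Path, region: GeneRegion) -> float:
    """Mean per-base depth over a region, primary alignments only."""
    with _open_alignment(alignment_path) as af:
        _check_contigs(af, [region])
        total = 0
        for aln in af.fetch(region.chrom, region.start, region.end):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            total += min(aln.reference_end, region.end) - max(
                aln.reference_start, region.start
            )
    return total / region.length


def write_readsets_fasta(
    readsets: dict[str, ReadSet], out_dir: str | Path, sample: str
) -> list[Path]:
    """Write one FASTA per gene, named ``<sample>.<gene>.fasta``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for gene in sorted(readsets):
        path = out_dir / f"{sample}.{gene}.fasta"
        with open(path, "w") as fh:
            for read_id, seq in readsets[gene].reads:
                fh.write(f">{read_id}\n{seq}\n")
        written.append(path)
    return written


def read_readset_fasta(fasta_path: str | Path, gene: str) -> ReadSet:
    """Load a per-gene read FASTA back into a :class:`ReadSet`."""
    reads: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    with open(fasta_path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    reads.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if name is not None:
            reads.append((name, "".join(chunks)))
    return ReadSet(gene=gene, reads=reads)
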