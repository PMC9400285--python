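"""Synthetic allele databases and WES-like read sets with known truth.

The generator emulates the inputs of the genotyping workflow without any
download: a multi-gene allele database in which coding variants of a gene
differ at dedicated blocks of substituted positions (so pairwise divergence
is guaranteed by construction), optionally with "synonymous sibling" alleles
that differ from their group founder only at reserved tail positions —
standing in for non-exonic or silent differences, and collapsing to the same
coding group; plus read sets tiling one or two truth alleles at a target
depth with i.i.d. substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .alleles import AlleleRecord, KirAlleleDatabase, KIR_GENES, build_coding_groups
from .reads import ReadSet

_BASES = np.array(list("ACGT"))

#: Fraction of the allele carrying variant-distinguishing sites; the rest is
#: conserved across variants (reads from it are uninformative), echoing the
#: concentration of KIR polymorphism in particular domains.
POLYMORPHIC_FRACTION = 0.6


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for one simulated gene: alleles, depth, error model."""

    gene: str
    truth_alleles: tuple[str, ...]
    depth: float = 30.0
    read_length: int = 100
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.truth_alleles) <= 2:
            raise ValueError("truth_alleles must name one or two alleles")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def _substitute(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(3)]


def variant_positions(
    index: int,
    alleles_per_gene: int,
    allele_length: int,
    divergence: int,
    reserved: int = 0,
) -> list[int]:
    """Positions substituted in coding variant ``index`` (0-based).

    The ``divergence * alleles_per_gene`` substituted sites form an evenly
    spaced grid (interleaved between variants) over the polymorphic span —
    the first ``POLYMORPHIC_FRACTION`` of the allele — mirroring real genes
    where allele-distinguishing sites concentrate in particular exons: a
    read overlapping a variant's sites at interior offsets has no long
    identical window left and so discriminates between variants, while
    reads from the conserved remainder match every variant.  The last
    ``reserved`` bases are kept substitution-free for synonymous-sibling
    edits.
    """
    total = divergence * alleles_per_gene
    span = min(
        round(POLYMORPHIC_FRACTION * allele_length), allele_length - reserved
    )
    stride = span // total
    if stride < 1:
        raise ValueError(
            "divergence * alleles_per_gene (+ sibling positions) exceeds allele_length"
        )
    offset = stride // 2
    return [offset + stride * (j * alleles_per_gene + index) for j in range(divergence)]


def make_synthetic_database(
    n_genes: int = 3,
    alleles_per_gene: int = 6,
    allele_length: int = 1000,
    divergence: int = 20,
    synonymous_siblings: int = 0,
    seed: int = 0,
) -> KirAlleleDatabase:
    """Build a deterministic synthetic KIR-style allele database.

    Per gene, a random root sequence is drawn and each of the
    ``alleles_per_gene`` coding variants substitutes every base at its own
    ``divergence`` grid positions (evenly interleaved along the allele, see
    :func:`variant_positions`), so any two variants of a gene differ at
    ``2 * divergence`` scattered positions (Hamming distance >= divergence
    guaranteed).  Each coding group additionally receives
    ``synonymous_siblings`` members that differ from the founder only at
    reserved tail positions; they share the founder's 3-digit coding group
    by naming.  Gene symbols are the first ``n_genes`` of the real 15-gene
    universe so downstream invariants hold unchanged.
    """
    if min(n_genes, alleles_per_gene, allele_length) < 1 or divergence < 1:
        raise ValueError("all counts must be >= 1")
    if n_genes > len(KIR_GENES):
        raise ValueError(f"at most {len(KIR_GENES)} genes supported")
    reserved = alleles_per_gene * max(synonymous_siblings, 0)
    positions = [
        variant_positions(i, alleles_per_gene, allele_length, divergence, reserved)
        for i in range(alleles_per_gene)
    ]

    rng = np.random.default_rng(seed)
    records: dict[str, list[AlleleRecord]] = {}
    for g in range(n_genes):
        gene = KIR_GENES[g]
        root = rng.choice(_BASES, size=allele_length)
        gene_records: list[AlleleRecord] = []
        for i in range(alleles_per_gene):
            variant = root.copy()
            for pos in positions[i]:
                variant[pos] = _substitute(variant[pos], rng)
            group_digits = f"{i + 1:03d}"
            founder_name = f"{gene}*{group_digits}01"
            gene_records.append(
                AlleleRecord(
                    full_name=founder_name,
                    gene=gene,
                    sequence="".join(variant),
                    coding_group=f"{gene}*{group_digits}",
                )
            )
            for j in range(synonymous_siblings):
                sibling = variant.copy()
                pos = allele_length - 1 - (i * synonymous_siblings + j)
                sibling[pos] = _substitute(sibling[pos], rng)
                gene_records.append(
                    AlleleRecord(
                        full_name=f"{gene}*{group_digits}{j + 2:02d}",
                        gene=gene,
                        sequence="".join(sibling),
                        coding_group=f"{gene}*{group_digits}",
                    )
                )
        records[gene] = gene_records
    db = KirAlleleDatabase(version=f"synthetic-seed{seed}", records=records)
    db.groups = build_coding_groups(db)
    return db


def simulate_reads(
    truth: SimulationTruth,
    db: KirAlleleDatabase,
    reverse_half: bool = False,
) -> ReadSet:
    """Tile reads over the truth allele(s) at the target depth.

    Emits ``ceil(depth * allele_length / read_length)`` reads in total for
    the genotype; a heterozygous truth draws half from each allele.  Each
    read is a uniformly positioned substring of its source allele with
    i.i.d. substitution errors at ``error_rate``.  Read ids encode source
    allele and start position for oracle checks.  With ``reverse_half``,
    every other read is emitted reverse-complemented to exercise strand
    handling.
    """
    by_name = {rec.full_name: rec for rec in db.alleles_for(truth.gene)}
    sources = []
    for name in truth.truth_alleles:
        if name not in by_name:
            raise ValueError(f"truth allele {name} not in database for {truth.gene}")
        sources.append(by_name[name])
    for rec in sources:
        if truth.read_length > len(rec.sequence):
            raise ValueError("read_length exceeds allele length")

    rng = np.random.default_rng(truth.seed)
    L = len(sources[0].sequence)
    n_total = ceil(truth.depth * L / truth.read_length)
    if len(sources) == 1:
        counts = [n_total]
    else:
        counts = [n_total - n_total // 2, n_total // 2]

    comp = str.maketrans("ACGT", "TGCA")
    reads: list[tuple[str, str]] = []
    idx = 0
    for rec, n_reads in zip(sources, counts):
        seq_len = len(rec.sequence)
        for _ in range(n_reads):
            pos = int(rng.integers(0, seq_len - truth.read_length + 1))
            read = list(rec.sequence[pos : pos + truth.read_length])
            if truth.error_rate > 0:
                errs = rng.random(truth.read_length) < truth.error_rate
                for k in np.flatnonzero(errs):
                    read[k] = _substitute(read[k], rng)
            seq = "".join(read)
            if reverse_half and idx % 2 == 1:
                seq = seq.translate(comp)[::-1]
            reads.append((f"{rec.full_name}|{pos}|{idx}", seq))
            idx += 1
    return ReadSet(gene=truth.gene, reads=reads)
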