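"""Bootstrapped expectation-maximization over read-to-allele alignments.

For one gene, the m alleles x n reads alignment matrix M starts with each
read's column distributing unit mass uniformly over the x_r alleles the read
matched exactly.  EM alternates

    E_a      = sum_r M[a, r]                       (expectation)
    M'[a, r] = M[a, r] * E_a / sum_a(M[a, r] E_a)  (Bayesian reweighting)

until the sum of squared changes in M drops to the convergence threshold
alpha.  The final expectation vector, divided by the read count n, is the
allele probability estimate.  Because a single EM run tends to collapse
ambiguous evidence onto a homozygous local optimum, the estimate is averaged
over n_boot bootstraps, each run on a random subsample of fraction p of the
reads.  Probabilities above the calling threshold t yield the genotype:
exactly one such allele is a homozygote, exactly two a heterozygote,
anything else no call.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from math import ceil
from pathlib import Path
from typing import Mapping

import numpy as np

from .align import DEFAULT_MIN_ALIGNMENT_LENGTH, ReadAlignments, align_readset
from .alleles import KirAlleleDatabase, collapse_probabilities
from .reads import GeneRegion, ReadSet, extract_kir_reads


class NoReadsError(ValueError):
    """The gene has no usable exact-match alignments."""


@dataclass(frozen=True)
class EmConfig:
    """Runtime hyperparameters of the genotyper.

    alpha
        EM convergence threshold on the sum of squared matrix changes.
    n_boot
        Number of bootstrap subsamples averaged per gene.
    p
        Fraction of reads drawn per bootstrap, in (0, 1].
    t_threshold
        Probability cutoff converting allele probabilities into calls.
    """

    alpha: float = 1e-5
    n_boot: int = 100
    p: float = 0.5
    t_threshold: float = 0.25
    seed: int = 0
    max_iterations: int = 1000
    min_reads: int = 1
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        if not 0 < self.t_threshold < 1:
            raise ValueError("t_threshold must be in (0, 1)")


@dataclass
class AlignmentMatrix:
    """Ordered allele/read index plus the column-stochastic matrix M."""

    alleles: list[str]
    reads: list[str]
    M: np.ndarray
    iteration_index: int = 0


@dataclass
class AlleleProbabilities:
    """Normalized per-allele probability estimate for one gene."""

    gene: str
    probs: dict[str, float]
    n_reads: int
    converged: bool = True
    iterations: int = 0


@dataclass
class GenotypeCall:
    """Zygosity plus called coding-group alleles, or a reasoned no-call."""

    gene: str
    zygosity: str  # homozygous | heterozygous | no_call
    alleles: tuple[str, ...] = ()
    no_call_reason: str = "none"  # none | no_reads | none_above_threshold |
    #                               more_than_two_above_threshold | not_converged
    probabilities: AlleleProbabilities | None = None

    def key(self) -> tuple:
        """Order-free identity used for concordance and entropy counting."""
        return (self.zygosity, tuple(sorted(set(self.alleles))), self.no_call_reason)


def gene_rng(seed: int, gene: str) -> np.random.Generator:
    """Per-gene RNG substream, stable under gene-order changes."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(gene.encode())])
    )


def initialize_alignment_matrix(alignments: ReadAlignments) -> AlignmentMatrix:
    """Build M with column r holding 1/x_r on each allele read r matched."""
    if alignments.n_reads == 0:
        raise NoReadsError(f"no alignments for gene {alignments.gene}")
    alleles = alignments.allele_universe
    reads = sorted(alignments.entries)
    a_index = {a: i for i, a in enumerate(alleles)}
    M = np.zeros((len(alleles), len(reads)))
    for j, read_id in enumerate(reads):
        matched = alignments.entries[read_id]
        w = 1.0 / len(matched)
        for a in matched:
            M[a_index[a], j] = w
    return AlignmentMatrix(alleles=alleles, reads=reads, M=M)


def em_iterate(
    M0: AlignmentMatrix, alpha: float = 1e-5, max_iterations: int = 1000
) -> AlleleProbabilities:
    """Run EM to convergence and return the normalized expectation vector.

    Each update multiplies a read's column by the current per-allele
    expectations and renormalizes the column, so column stochasticity is
    preserved and the expectations always sum to the read count.  Hitting
    ``max_iterations`` returns ``converged=False`` rather than raising.
    """
    M = M0.M.copy()
    n = M.shape[1]
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        E = M.sum(axis=1)
        W = M * E[:, None]
        M_new = W / W.sum(axis=0, keepdims=True)
        delta = float(((M_new - M) ** 2).sum())
        M = M_new
        if delta <= alpha:
            converged = True
            break
    E = M.sum(axis=1) / n
    probs = {a: float(E[i]) for i, a in enumerate(M0.alleles)}
    return AlleleProbabilities(
        gene="", probs=probs, n_reads=n, converged=converged, iterations=iterations
    )


def bootstrap_probabilities(
    alignments: ReadAlignments,
    config: EmConfig,
    rng: np.random.Generator | None = None,
) -> AlleleProbabilities:
    """Average EM probability estimates over bootstrap subsamples.

    Each bootstrap draws ``ceil(p * N)`` reads — without replacement by
    default (subsampling), with replacement behind the config flag — runs
    EM on the subsample, and contributes a normalized probability vector;
    alleles absent from a subsample contribute zero.  Deterministic for a
    given seed.
    """
    N = alignments.n_reads
    if N < max(config.min_reads, 1):
        raise NoReadsError(
            f"gene {alignments.gene}: {N} reads < min_reads={config.min_reads}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    read_ids = sorted(alignments.entries)
    k = ceil(config.p * N)
    alleles = alignments.allele_universe
    a_pos = {a: i for i, a in enumerate(alleles)}
    acc = np.zeros(len(alleles))
    all_converged = True
    total_iter = 0
    for _ in range(config.n_boot):
        chosen = rng.choice(N, size=k, replace=config.with_replacement)
        sub = ReadAlignments(
            gene=alignments.gene,
            entries={
                f"{read_ids[i]}#{j}": alignments.entries[read_ids[i]]
                for j, i in enumerate(chosen)
            },
        )
        res = em_iterate(
            initialize_alignment_matrix(sub), config.alpha, config.max_iterations
        )
        all_converged &= res.converged
        total_iter += res.iterations
        for a, v in res.probs.items():
            acc[a_pos[a]] += v
    acc /= config.n_boot
    return AlleleProbabilities(
        gene=alignments.gene,
        probs={a: float(acc[i]) for i, a in enumerate(alleles)},
        n_reads=N,
        converged=all_converged,
        iterations=total_iter,
    )


def call_genotype(
    probs: AlleleProbabilities,
    t_threshold: float,
    groups: Mapping[str, str] | None = None,
    require_convergence: bool = True,
) -> GenotypeCall:
    """Threshold (collapsed) allele probabilities into a genotype call.

    ``groups`` maps full allele names to coding groups; when given, the
    probabilities are collapsed before thresholding.  Comparison with t is
    strict: a probability exactly at t is below threshold.
    """
    collapsed = (
        collapse_probabilities(probs.probs, groups) if groups is not None else probs.probs
    )
    collapsed_probs = AlleleProbabilities(
        gene=probs.gene,
        probs=dict(collapsed),
        n_reads=probs.n_reads,
        converged=probs.converged,
        iterations=probs.iterations,
    )
    if require_convergence and not probs.converged:
        return GenotypeCall(
            gene=probs.gene,
            zygosity="no_call",
            no_call_reason="not_converged",
            probabilities=collapsed_probs,
        )
    above = sorted(a for a, v in collapsed.items() if v > t_threshold)
    if len(above) == 1:
        return GenotypeCall(
            gene=probs.gene,
            zygosity="homozygous",
            alleles=(above[0], above[0]),
            probabilities=collapsed_probs,
        )
    if len(above) == 2:
        return GenotypeCall(
            gene=probs.gene,
            zygosity="heterozygous",
            alleles=tuple(above),
            probabilities=collapsed_probs,
        )
    reason = "none_above_threshold" if not above else "more_than_two_above_threshold"
    return GenotypeCall(
        gene=probs.gene,
        zygosity="no_call",
        no_call_reason=reason,
        probabilities=collapsed_probs,
    )


def genotype_alignments(
    alignments: ReadAlignments,
    config: EmConfig,
    groups: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> GenotypeCall:
    """Bootstrap-EM one gene's alignments and threshold into a call."""
    try:
        probs = bootstrap_probabilities(alignments, config, rng=rng)
    except NoReadsError:
        return GenotypeCall(
            gene=alignments.gene, zygosity="no_call", no_call_reason="no_reads"
        )
    return call_genotype(probs, config.t_threshold, groups=groups)


def genotype_readsets(
    readsets: Mapping[str, ReadSet],
    db: KirAlleleDatabase,
    config: EmConfig,
    min_alignment_length: int = DEFAULT_MIN_ALIGNMENT_LENGTH,
) -> dict[str, GenotypeCall]:
    """Align each gene's reads against its alleles and call genotypes."""
    calls: dict[str, GenotypeCall] = {}
    for gene in sorted(readsets):
        readset = readsets[gene]
        alleles = db.alleles_for(gene)
        if not readset.reads or not alleles:
            calls[gene] = GenotypeCall(
                gene=gene, zygosity="no_call", no_call_reason="no_reads"
            )
            continue
        alignments = align_readset(readset, alleles, min_alignment_length)
        calls[gene] = genotype_alignments(
            alignments, config, db.groups, rng=gene_rng(config.seed, gene)
        )
    return calls


def genotype_sample(
    alignment_path: str | Path,
    db: KirAlleleDatabase,
    regions: list[GeneRegion],
    config: EmConfig,
    min_alignment_length: int = DEFAULT_MIN_ALIGNMENT_LENGTH,
    min_mapped_overlap: int = 1,
    exclude_duplicates: bool = False,
) -> dict[str, GenotypeCall]:
    """Full per-sample workflow: extract, align, bootstrap-EM, call.

    Genes with zero extracted reads yield ``no_call(no_reads)``; I/O and
    configuration errors propagate.
    """
    readsets = extract_kir_reads(
        alignment_path,
        regions,
        min_mapped_overlap=min_mapped_overlap,
        exclude_duplicates=exclude_duplicates,
    )
    return genotype_readsets(readsets, db, config, min_alignment_length)


def with_hyperparameters(config: EmConfig, **kwargs) -> EmConfig:
    """Return a copy of the config with selected fields replaced."""
    return replace(config, **kwargs)
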