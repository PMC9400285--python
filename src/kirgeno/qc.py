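"""Internal quality-control instruments for the genotyper.

Covers the consistency and robustness checks used to characterize the
caller: Shannon entropies of allele-probability vectors and of repeated
genotype calls, hyperparameter (p, t) entropy grids, replicate concordance
with normal-approximation confidence intervals, coverage-vs-entropy
profiles, and pseudo read sets — negative controls built by mixing reads
from several donors so that no coherent single genotype exists.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import ReadAlignments
from .em import EmConfig, GenotypeCall, bootstrap_probabilities, call_genotype, with_hyperparameters
from .reads import ReadSet


@dataclass
class EntropyGrid:
    """log2 Shannon entropies of genotype calls over a (p, t) grid."""

    p_values: list[float]
    t_values: list[float]
    entropy: np.ndarray  # |p| x |t|
    iterations_per_cell: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entropy, index=self.p_values, columns=self.t_values)


def shannon_entropy(values: Iterable) -> float:
    """log2 Shannon entropy of weights or of a categorical multiset.

    Numeric input is treated as non-negative weights and normalized to a
    probability vector; non-numeric input is counted as categorical
    outcomes.  By convention 0*log(0) = 0.  An unambiguous homozygous
    probability vector (1, 0, ...) gives 0 bits and a clean heterozygous
    vector (0.5, 0.5, 0, ...) gives 1 bit.
    """
    items = list(values)
    if not items:
        raise ValueError("entropy of empty input is undefined")
    try:
        w = np.asarray(items, dtype=float)
    except (TypeError, ValueError):
        w = np.asarray(list(Counter(items).values()), dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    q = w[w > 0] / total
    return float(-(q * np.log2(q)).sum()) + 0.0  # normalize -0.0


def allele_probability_entropy(probs: Mapping[str, float]) -> float:
    """Entropy (bits) of one gene's allele-probability vector."""
    return shannon_entropy(probs.values())


def genotype_entropy_grid(
    alignments: ReadAlignments,
    p_values: Sequence[float],
    t_values: Sequence[float],
    iterations: int,
    config: EmConfig,
    groups: Mapping[str, str] | None = None,
) -> EntropyGrid:
    """Empirical genotype-call entropy across a (p, t) hyperparameter grid.

    Each cell reruns the bootstrap-EM caller ``iterations`` times with
    distinct cell-derived seeds and takes the entropy of the resulting
    genotype distribution (no-calls are a category; heterozygous calls
    compare as unordered pairs).  An ideal, self-consistent caller gives 0
    everywhere.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    groups = groups if groups is not None else {a: a for a in alignments.allele_universe}
    grid = np.zeros((len(p_values), len(t_values)))
    for i, p in enumerate(p_values):
        for j, t in enumerate(t_values):
            cfg = with_hyperparameters(config, p=p, t_threshold=t)
            keys = []
            for k in range(iterations):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed & 0x7FFFFFFF, i, j, k])
                )
                probs = bootstrap_probabilities(alignments, cfg, rng=rng)
                call = call_genotype(probs, cfg.t_threshold, groups=groups)
                keys.append(call.key())
            grid[i, j] = shannon_entropy(keys)
    return EntropyGrid(
        p_values=list(p_values),
        t_values=list(t_values),
        entropy=grid,
        iterations_per_cell=iterations,
    )


def _calls_identical(a: GenotypeCall, b: GenotypeCall) -> bool:
    return a.key() == b.key()


def replicate_concordance(
    calls_a: Mapping[str, Mapping[str, GenotypeCall]],
    calls_b: Mapping[str, Mapping[str, GenotypeCall]],
    pairing: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Fraction of replicate pairs with identical calls, per gene + overall.

    Calls compare on zygosity plus unordered collapsed allele names;
    no-call matches no-call.  Pairs missing a gene in either table are
    skipped with a warning row count.  The confidence interval is the
    normal approximation p_hat +/- 1.96 * sqrt(p_hat (1 - p_hat) / n).
    """
    if not pairing:
        raise ValueError("pairing must be non-empty")
    per_gene: dict[str, list[bool]] = {}
    for sa, sb in pairing:
        genes = set(calls_a.get(sa, {})) & set(calls_b.get(sb, {}))
        for gene in genes:
            per_gene.setdefault(gene, []).append(
                _calls_identical(calls_a[sa][gene], calls_b[sb][gene])
            )
    rows = []
    pooled: list[bool] = []
    for gene in sorted(per_gene):
        flags = per_gene[gene]
        pooled.extend(flags)
        rows.append((gene, flags))
    rows.append(("overall", pooled))
    out = []
    for label, flags in rows:
        n = len(flags)
        phat = sum(flags) / n if n else float("nan")
        half = 1.96 * np.sqrt(phat * (1 - phat) / n) if n else float("nan")
        out.append(
            {
                "gene": label,
                "n_pairs": n,
                "concordance": phat,
                "ci_low": max(0.0, phat - half),
                "ci_high": min(1.0, phat + half),
            }
        )
    return pd.DataFrame(out)


def make_pseudo_readset(
    donor_readsets: Sequence[ReadSet], seed: int = 0
) -> ReadSet:
    """Mix donors' reads into a negative-control read set.

    Draws reads uniformly without replacement from the pooled donors until
    the output size equals the rounded mean donor read count, so the
    mixture's depth is commensurate with its constituents.  Requires at
    least two donors; deterministic under seed.
    """
    if len(donor_readsets) < 2:
        raise ValueError("need at least 2 donor read sets")
    gene = donor_readsets[0].gene
    if any(rs.gene != gene for rs in donor_readsets):
        raise ValueError("all donors must cover the same gene")
    pool = [read for rs in donor_readsets for read in rs.reads]
    if not pool:
        raise ValueError("donors contain no reads")
    target = int(round(sum(len(rs) for rs in donor_readsets) / len(donor_readsets)))
    target = min(target, len(pool))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=target, replace=False)
    reads = [
        (f"pseudo{i}|{pool[j][0]}", pool[j][1]) for i, j in enumerate(sorted(chosen))
    ]
    return ReadSet(gene=gene, reads=reads)


def coverage_entropy_profile(
    samples: Sequence[tuple[float, float]], bin_width: float
) -> pd.DataFrame:
    """Bin samples by coverage; per-bin median and IQR of entropies.

    Empty bins are omitted.  Mirrors the observation that probability
    entropies rise only at very low coverage.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not samples:
        raise ValueError("no samples")
    binned: dict[int, list[float]] = {}
    for cov, ent in samples:
        binned.setdefault(int(cov // bin_width), []).append(ent)
    rows = []
    for b in sorted(binned):
        ents = np.asarray(binned[b])
        q1, med, q3 = np.percentile(ents, [25, 50, 75])
        rows.append(
            {
                "bin_low": b * bin_width,
                "bin_high": (b + 1) * bin_width,
                "n": len(ents),
                "median_entropy": med,
                "iqr_low": q1,
                "iqr_high": q3,
            }
        )
    return pd.DataFrame(rows)
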