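"""Downstream statistics on called KIR genotypes.

Allele frequency tabulation, the copy-number "KIR-space" encoding, carrier
association tests (two-sided Fisher's exact for binary traits, two-sided
Mann-Whitney U for continuous ones) with multiple-testing correction, and
dominant / semi-dominant / recessive genetic effect models for a continuous
phenotype, ranked by BIC.

Carrier status means possession of at least one copy of an allele; samples
without a call at the relevant gene are excluded pairwise.  The genetic
encodings map copy counts {0,1,2} to a covariate x:

    dominant       2 -> 1, 1 -> 1, 0 -> 0
    semi-dominant  2 -> 2, 1 -> 1, 0 -> 0
    recessive      2 -> 1, 1 -> 0, 0 -> 0

and the phenotype is modeled as y = m*x + b by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .em import GenotypeCall

ENCODINGS: dict[str, dict[int, float]] = {
    "dominant": {0: 0.0, 1: 1.0, 2: 1.0},
    "semidominant": {0: 0.0, 1: 1.0, 2: 2.0},
    "recessive": {0: 0.0, 1: 0.0, 2: 1.0},
}


@dataclass
class AssociationResult:
    allele: str
    trait: str
    test: str  # fisher_exact | mann_whitney_u
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    odds_ratio: float | None = None
    table: tuple[int, int, int, int] | None = None
    direction: str = ""
    degenerate: bool = False


@dataclass
class EffectModelFit:
    model: str
    slope: float
    intercept: float
    n: int
    rss: float
    bic: float
    skipped: bool = False


def genotype_table(calls: Mapping[str, Mapping[str, GenotypeCall]]) -> pd.DataFrame:
    """Flatten nested sample -> gene -> call maps into a long table."""
    rows = []
    for sample in sorted(calls):
        for gene in sorted(calls[sample]):
            call = calls[sample][gene]
            a1, a2 = (call.alleles + (None, None))[:2]
            rows.append(
                {
                    "sample_id": sample,
                    "gene": gene,
                    "zygosity": call.zygosity,
                    "allele1": a1,
                    "allele2": a2,
                }
            )
    return pd.DataFrame(rows)


def allele_frequencies(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-gene allele frequencies from called genotypes.

    Every called sample contributes two allele copies per gene (a
    homozygote contributes two of one allele); no-call rows are excluded
    from numerator and denominator.  Genes with zero called samples are
    omitted.  Per-gene frequencies sum to 1.
    """
    if table.empty:
        raise ValueError("genotype table is empty")
    out: dict[str, dict[str, float]] = {}
    called = table[table["zygosity"].isin(["homozygous", "heterozygous"])]
    for gene, sub in called.groupby("gene"):
        counts: dict[str, int] = {}
        for _, row in sub.iterrows():
            counts[row["allele1"]] = counts.get(row["allele1"], 0) + 1
            counts[row["allele2"]] = counts.get(row["allele2"], 0) + 1
        total = sum(counts.values())
        out[gene] = {a: c / total for a, c in sorted(counts.items())}
    return out


def encode_kir_space(
    table: pd.DataFrame, allele_universe: Sequence[str]
) -> pd.DataFrame:
    """Samples x alleles copy-number matrix (0/1/2).

    A homozygote places 2 in one column, a heterozygote 1 in each of two;
    genes without a call contribute zeros, so each row sums to twice the
    number of called genes for that sample.
    """
    universe = list(allele_universe)
    pos = {a: i for i, a in enumerate(universe)}
    samples = sorted(table["sample_id"].unique())
    M = np.zeros((len(samples), len(universe)), dtype=int)
    srow = {s: i for i, s in enumerate(samples)}
    for _, row in table.iterrows():
        if row["zygosity"] not in ("homozygous", "heterozygous"):
            continue
        for allele in (row["allele1"], row["allele2"]):
            if allele not in pos:
                raise ValueError(f"allele {allele!r} outside the given universe")
            M[srow[row["sample_id"]], pos[allele]] += 1
    return pd.DataFrame(M, index=samples, columns=universe)


def carrier_association_fisher(
    carrier: Sequence[bool],
    trait: Sequence[bool],
    allele: str = "",
    trait_name: str = "",
) -> AssociationResult:
    """Two-sided Fisher's exact test of carrier status vs a binary trait.

    The two-sided p-value sums hypergeometric probabilities of all tables
    (at fixed margins) no more likely than the observed one.  The sample
    odds ratio ad/bc may be 0 or infinite.  A degenerate margin (all-true
    or all-false vector) gives p = 1 with the odds ratio undefined.
    """
    carrier = np.asarray(carrier, dtype=bool)
    trait = np.asarray(trait, dtype=bool)
    if carrier.shape != trait.shape or carrier.size < 2:
        raise ValueError("carrier and trait must be equal-length vectors (n >= 2)")
    a = int((carrier & trait).sum())
    b = int((carrier & ~trait).sum())
    c = int((~carrier & trait).sum())
    d = int((~carrier & ~trait).sum())
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        return AssociationResult(
            allele=allele,
            trait=trait_name,
            test="fisher_exact",
            statistic=float("nan"),
            p_value=1.0,
            odds_ratio=None,
            table=(a, b, c, d),
            degenerate=True,
        )
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        sample_or = float("inf") if a * d > 0 else 0.0
    else:
        sample_or = a * d / (b * c)
    return AssociationResult(
        allele=allele,
        trait=trait_name,
        test="fisher_exact",
        statistic=float(odds),
        p_value=float(p),
        odds_ratio=sample_or,
        table=(a, b, c, d),
        direction="positive" if sample_or > 1 else "negative",
    )


def carrier_association_mwu(
    carrier: Sequence[bool],
    values: Sequence[float],
    allele: str = "",
    trait_name: str = "",
) -> AssociationResult:
    """Two-sided Mann-Whitney U of a continuous trait between carriers and
    non-carriers.

    Exact p by enumeration when the smaller group has <= 8 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    carrier = np.asarray(carrier, dtype=bool)
    values = np.asarray(values, dtype=float)
    x = values[carrier]
    y = values[~carrier]
    if x.size == 0 or y.size == 0:
        raise ValueError("both carrier and non-carrier groups must be non-empty")
    ties = len(np.unique(values)) < values.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    med_x, med_y = float(np.median(x)), float(np.median(y))
    return AssociationResult(
        allele=allele,
        trait=trait_name,
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction="higher_in_carriers" if med_x > med_y else "lower_in_carriers",
    )


def adjust_pvalues(
    p_values: Sequence[float], method: str = "bonferroni"
) -> list[float]:
    """Multiple-testing correction: ``bonferroni`` or ``benjamini_hochberg``.

    Bonferroni is min(1, p*m); Benjamini-Hochberg is the step-up procedure
    with monotonicity enforcement.  Input order is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh"}[method]
    return list(multipletests(p, method=key)[1])


def fit_effect_models(
    copies: Sequence[int],
    phenotype: Sequence[float],
) -> tuple[list[EffectModelFit], EffectModelFit]:
    """Fit the three genetic encodings by OLS and rank them by BIC.

    BIC = n*ln(rss/n) + k*ln(n) with k = 3 (slope, intercept, error
    variance); only BIC differences and ranks are meaningful.  An encoding
    whose covariate is constant in the data is skipped (flagged); the best
    model minimizes BIC among those actually fit.
    """
    copies = np.asarray(copies, dtype=int)
    y = np.asarray(phenotype, dtype=float)
    if copies.shape != y.shape or copies.size < 3:
        raise ValueError("need matched copies/phenotype vectors with n >= 3")
    if not np.isin(copies, [0, 1, 2]).all():
        raise ValueError("copy counts must be 0, 1 or 2")
    n = copies.size
    fits: list[EffectModelFit] = []
    for model, enc in ENCODINGS.items():
        x = np.array([enc[c] for c in copies])
        if np.unique(x).size < 2:
            fits.append(
                EffectModelFit(model, np.nan, np.nan, n, np.nan, np.inf, skipped=True)
            )
            continue
        X = np.column_stack([x, np.ones(n)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        rss = float(resid @ resid)
        if rss <= 0:
            # exact fit: -inf BIC dominates, as it should
            bic = -np.inf
        else:
            bic = n * np.log(rss / n) + 3 * np.log(n)
        fits.append(EffectModelFit(model, float(coef[0]), float(coef[1]), n, rss, bic))
    usable = [f for f in fits if not f.skipped]
    if not usable:
        raise ValueError("no encoding produced a non-constant covariate")
    best = min(usable, key=lambda f: f.bic)
    return fits, best


def association_scan_fisher(
    kir_space: pd.DataFrame,
    traits: pd.DataFrame,
    min_allele_freq: float = 0.01,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Test every (allele, binary trait) carrier pair; adjust jointly."""
    results: list[AssociationResult] = []
    shared = kir_space.index.intersection(traits.index)
    X = kir_space.loc[shared]
    T = traits.loc[shared]
    n2 = 2 * len(shared)
    for allele in X.columns:
        if X[allele].sum() / n2 < min_allele_freq:
            continue
        carrier = X[allele].to_numpy() >= 1
        for trait in T.columns:
            mask = T[trait].notna().to_numpy()
            results.append(
                carrier_association_fisher(
                    carrier[mask],
                    T[trait].to_numpy()[mask].astype(bool),
                    allele=allele,
                    trait_name=trait,
                )
            )
    return _finalize(results, adjust)


def association_scan_mwu(
    kir_space: pd.DataFrame,
    traits: pd.DataFrame,
    min_allele_freq: float = 0.01,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Test every (allele, continuous trait) carrier pair; adjust jointly."""
    results: list[AssociationResult] = []
    shared = kir_space.index.intersection(traits.index)
    X = kir_space.loc[shared]
    T = traits.loc[shared]
    n2 = 2 * len(shared)
    for allele in X.columns:
        if X[allele].sum() / n2 < min_allele_freq:
            continue
        carrier = X[allele].to_numpy() >= 1
        for trait in T.columns:
            mask = T[trait].notna().to_numpy()
            if carrier[mask].all() or not carrier[mask].any():
                continue
            results.append(
                carrier_association_mwu(
                    carrier[mask],
                    T[trait].to_numpy()[mask],
                    allele=allele,
                    trait_name=trait,
                )
            )
    return _finalize(results, adjust)


def _finalize(results: list[AssociationResult], adjust: str) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(
            columns=["allele", "trait", "test", "statistic", "p_value", "adjusted_p"]
        )
    adjusted = adjust_pvalues([r.p_value for r in results], method=adjust)
    for r, q in zip(results, adjusted):
        r.adjusted_p = q
    return pd.DataFrame(
        {
            "allele": [r.allele for r in results],
            "trait": [r.trait for r in results],
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "direction": [r.direction for r in results],
        }
    )
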