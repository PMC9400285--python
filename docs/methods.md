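# Methods

## Model and procedure

`kirgeno` types the 15 expressed KIR genes (KIR2DL1–3, KIR2DL4, KIR2DL5A/B,
KIR3DL1–3, KIR2DS1–5, KIR3DS1; the pseudogenes KIR2DP1 and KIR3DP1 are
dropped at database load) one gene at a time. The model is deliberately
simple: every extracted read is assumed to originate from one of the gene's
two allele copies, read-to-allele compatibility is binary (100% identity or
nothing), and the EM estimates a probability vector over alleles that the
thresholding step converts into a genotype.

**Exact-match alignment.** A read matches an allele when the read or its
reverse complement shares a contiguous, gapless, mismatch-free substring of
length ≥ `min(len(read), min_alignment_length)` with it. The length floor
(default 50 nt, conservative for ~100 bp WES reads) suppresses spurious
short exact seeds; short reads must match end-to-end. Reads containing N
never match — N equals no base under strict identity. The implementation
contract is brute-force substring scanning; an optional external backend
drives `blastn` (`-perc_identity 100 -ungapped -xdrop_ungap 0`, so HSPs are
pure exact runs, with the e-value cutoff relaxed because the length floor
is the only intended filter) and agrees with the internal matcher on clean
reads. Reads matching no allele are dropped before EM.

**EM.** The alignment matrix column for read r distributes mass 1/x_r over
the x_r alleles it matched. Each iteration computes per-allele expectations
(row sums), multiplies each column elementwise by them, renormalizes the
column, and stops when the sum of squared matrix changes is ≤ α. Column
stochasticity is preserved exactly, so expectations always sum to the read
count n; the reported probabilities are the final expectations divided by n
(the raw expectation vector lives on the scale of read counts; dividing by
n makes it a probability vector comparable with the threshold t). Reaching
`max_iterations` (default 1000) returns `converged=False` instead of
raising; by default a non-converged gene becomes a no-call with reason
`not_converged`, configurable to call anyway.

**Bootstrap.** Ambiguous evidence makes plain EM collapse onto homozygous
local optima. Each of `n_boot` bootstraps draws ⌈p·N⌉ reads uniformly
*without* replacement (subsampling; a with-replacement mode sits behind a
flag) and runs EM on the subsample; the per-gene estimate is the arithmetic
mean of the normalized bootstrap vectors, with alleles absent from a
subsample contributing zero. Averaging normalized (rather than raw)
vectors keeps every bootstrap on the same probability scale regardless of
subsample size.

**Coding-region collapse.** WES cannot see non-exonic differences, and
silent differences do not change the receptor, so alleles are merged into
protein-level groups named by the gene plus the first three designation
digits (KIR nomenclature encodes protein identity in digits 1–3).
Collapse is nomenclature truncation, not sequence re-translation — the
nucleotide FASTA carries no exon annotations — and group probabilities are
the sums of their members'. Designations shorter than three digits are
right-padded with zeros and logged. An optional homogeneity check flags
groups whose members differ at >5% of aligned positions.

**Thresholding.** After collapse, the groups with probability strictly
greater than t are counted: one → homozygous (the allele counted twice),
two → heterozygous, zero or more than two → no-call with reason
`none_above_threshold` / `more_than_two_above_threshold`. Ties at exactly
t fall below threshold. Raising t can only shrink the above-threshold set,
so it never turns a `none_above_threshold` no-call into a call.

## Hyperparameters

| name | meaning | default |
|---|---|---|
| α | EM convergence threshold on Σ(ΔM)² | 1e−5 |
| n_boot | bootstrap count per gene | 100 |
| p | read fraction per bootstrap, (0, 1] | 0.5 |
| t | calling threshold on collapsed probabilities | 0.25 |
| min_alignment_length | exact-match length floor, nt | 50 |
| max_iterations | EM iteration cap | 1000 |
| min_reads | minimum usable alignments per gene | 1 |

Randomness: one integer seed per run; per-gene substreams are derived from
the CRC-32 of the gene name so results do not depend on gene processing
order, and the entropy-grid cells use cell-index-derived substreams so
cells are independent and reproducible.

## Validation instruments

*Genotype entropy* is the log2 Shannon entropy of the empirical
distribution of calls over repeated reruns (distinct derived seeds);
no-calls are a category of their own — excluding them would understate
ambiguity — and heterozygous calls compare as unordered pairs. A perfectly
self-consistent caller scores 0 everywhere on the (p, t) grid.
*Allele-probability entropy* is the entropy of one run's collapsed
probability vector: 0 for a certain homozygote, 1 bit for a clean
heterozygote, higher when mass spreads over many groups. *Replicate
concordance* is the fraction of sample pairs with identical calls
(zygosity plus unordered collapsed alleles; no-call matches no-call), with
normal-approximation intervals p̂ ± 1.96·√(p̂(1−p̂)/n). *Pseudo read sets*
mix reads drawn uniformly without replacement from ≥2 donors' pools, sized
to the rounded mean donor read count, so the mixture's depth is
commensurate with its constituents while no coherent genotype exists —
their probability entropies should exceed those of pure samples.
*Coverage–entropy profiles* bin samples by mean locus coverage and report
per-bin median and IQR of entropies.

## Synthetic data

The generator emulates the workflow's inputs without any download. Per
gene, a random root sequence is drawn; each of the `alleles_per_gene`
coding variants substitutes the bases at its own `divergence` positions on
an evenly spaced grid confined to the first 60% of the allele
(`POLYMORPHIC_FRACTION`), so any two variants differ at 2·divergence
scattered sites while the remainder of the gene is identical across
variants. This mirrors two features of real KIR data: allele-distinguishing
sites scattered along particular domains rather than clustered at sequence
edges, and long conserved stretches whose reads are uninformative. Each
coding group can additionally receive "synonymous sibling" alleles that
differ from their founder only at reserved tail positions — standing in
for non-exonic or silent differences — and collapse to the same 3-digit
group. Reads tile one or two truth alleles at a target depth (heterozygous
truths draw half from each copy), with uniform start positions and i.i.d.
substitution errors; the error model is substitution-only because the
identity-based matcher turns indels into dropped matches rather than a
distinct signal. Read ids encode source allele and position for oracle
checks.

What passing tests on this generator do **not** show: robustness to the
real KIR locus's inter-gene homology (reads mis-mapped between paralogs),
to alignment artifacts, to copy-number variation (gene presence/absence
haplotypes), or to base-quality structure. The generator's truth model is
exactly two copies per gene.

Default study conditions used by the tests and the acceptance script: a
3-gene × 6-allele database of 1000 bp alleles at divergence 20, 30× depth,
100 bp error-free reads, default hyperparameters. The depth-degradation
check uses divergence 3 — closely related alleles whose few distinguishing
sites are often uncovered at 2× — where both the no-call fraction and the
probability entropy rise relative to 30×.

## Association statistics

Called genotypes flatten into a samples × alleles copy-number matrix
(0/1/2; genes without a call contribute zeros). Carrier status means ≥1
copy; samples without a call at the relevant gene are excluded pairwise,
and a homozygote-only indicator supports recessive-style contrasts.
Binary traits use the two-sided Fisher's exact test (scipy's
hypergeometric-sum definition; the sample odds ratio ad/bc may be 0 or
infinite, and degenerate margins return p = 1 flagged). Continuous traits
use the two-sided Mann-Whitney U — exact by enumeration when the smaller
group has ≤8 observations and no ties, otherwise the tie- and
continuity-corrected normal approximation. Both Bonferroni (default) and
Benjamini–Hochberg corrections are available.

The genetic effect models regress a continuous phenotype on an encoded
genotype covariate x — dominant (2→1, 1→1), semi-dominant (2→2, 1→1),
recessive (2→1, 1→0) — by ordinary least squares and rank the encodings by
BIC = n·ln(rss/n) + k·ln(n) with k = 3 (slope, intercept, error variance).
Because k is identical across encodings, only BIC differences and ranks
are meaningful, and selection reduces to minimum residual sum of squares;
an encoding constant in the data is skipped and flagged. A note on
attainable accuracy: with n = 500, slope 5 and noise sd 10, the hardest
confusion (dominant truth vs the semi-dominant encoding) has a population
lack-of-fit of 1.5625 at genotype weights (¼, ½, ¼) — the optimum over all
genotype distributions — giving a noncentrality of ~7.8 and a ceiling of
roughly 93% correct selection; the acceptance script reports the measured
rates under Hardy–Weinberg genotype draws at allele frequency 0.5, chosen
so all three genotype classes are well populated.

## Numerical and design choices

- Coordinates are BED-style 0-based half-open throughout; the shipped
  region file is a labeled template because gene boundaries are
  reference-build specific and must be supplied build-matched.
- Mate pairs are treated as independent reads (a /1–/2 suffix keeps ids
  unique); duplicate-marked reads are kept unless excluded by flag;
  secondary/supplementary/unmapped alignments are always excluded.
- Extraction output is sorted by read id, so results are independent of
  file iteration order; a read overlapping two gene regions enters both.
- TSV floats are written with 6 significant digits and outputs are written
  atomically, so a rerun with identical inputs and seed is byte-identical.
- The threshold comparison is strict (>); probabilities exactly at t do
  not call.
- Collapse conserves probability mass to the last floating-point unit and
  is idempotent on already-collapsed vectors.

## Known limitations

- No gene copy-number inference: every gene is modeled as two copies, so
  deleted or duplicated genes (common in real KIR haplotypes) are called
  as if diploid.
- No gapped or mismatch-tolerant alignment; sequencing errors at a
  distinguishing site simply delete evidence.
- Association analyses are univariate with no covariate adjustment or
  population-structure correction beyond cohort subsetting.
- The 3-digit collapse trusts nomenclature; alleles mis-grouped upstream
  would be mis-merged here (the homogeneity check only flags gross cases).
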