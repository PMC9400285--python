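"""Expectation-maximization core: initialization, iteration, bootstrap
averaging and threshold calling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kirgeno.align import ReadAlignments
from kirgeno.em import (
    AlleleProbabilities,
    EmConfig,
    NoReadsError,
    bootstrap_probabilities,
    call_genotype,
    em_iterate,
    genotype_readsets,
    initialize_alignment_matrix,
)
from kirgeno.reads import ReadSet


def make_alignments(entries: dict[str, set[str]], gene="KIR2DL1") -> ReadAlignments:
    return ReadAlignments(
        gene=gene, entries={r: frozenset(s) for r, s in entries.items()}
    )


def brute_force_em(entries: dict[str, set[str]], alpha: float, max_iter: int = 1000):
    """Independent direct iteration of the EM recurrences with plain dicts.

    Initialization puts 1/x_r on each allele a read matches; each step
    computes per-allele expectations as row sums, reweights each read's
    column by them, renormalizes the column, and stops when the sum of
    squared matrix changes is at most alpha.  Returns expectations / n.
    """
    alleles = sorted({a for s in entries.values() for a in s})
    reads = sorted(entries)
    M = {
        (a, r): (1.0 / len(entries[r]) if a in entries[r] else 0.0)
        for a in alleles
        for r in reads
    }
    for _ in range(max_iter):
        E = {a: sum(M[(a, r)] for r in reads) for a in alleles}
        M_new = {}
        for r in reads:
            denom = sum(M[(a, r)] * E[a] for a in alleles)
            for a in alleles:
                M_new[(a, r)] = M[(a, r)] * E[a] / denom
        delta = sum((M_new[k] - M[k]) ** 2 for k in M)
        M = M_new
        if delta <= alpha:
            break
    E = {a: sum(M[(a, r)] for r in reads) for a in alleles}
    n = len(reads)
    return {a: E[a] / n for a in alleles}


class TestInitialization:
    def test_split_column_for_ambiguous_read(self):
        am = initialize_alignment_matrix(make_alignments({"r1": {"A", "B"}}))
        col = am.M[:, 0]
        assert list(am.alleles) == ["A", "B"]
        assert col == pytest.approx([0.5, 0.5])

    def test_unit_column_for_unique_read(self):
        am = initialize_alignment_matrix(make_alignments({"r1": {"A"}}))
        assert am.M[:, 0] == pytest.approx([1.0])

    def test_disjoint_reads_give_identity_like_matrix(self):
        am = initialize_alignment_matrix(
            make_alignments({"r1": {"A"}, "r2": {"B"}})
        )
        assert am.M.sum(axis=0) == pytest.approx([1.0, 1.0])
        assert am.M.sum() == pytest.approx(2.0)

    def test_empty_alignments_raise_no_reads(self):
        with pytest.raises(NoReadsError):
            initialize_alignment_matrix(make_alignments({}))


class TestEmIterate:
    def test_single_unique_read_is_certain(self):
        res = em_iterate(initialize_alignment_matrix(make_alignments({"r1": {"A"}})))
        assert res.probs["A"] == pytest.approx(1.0)
        assert res.converged

    def test_symmetric_disjoint_reads_are_a_fixed_point(self):
        res = em_iterate(
            initialize_alignment_matrix(make_alignments({"r1": {"A"}, "r2": {"B"}}))
        )
        assert res.probs["A"] == pytest.approx(0.5)
        assert res.probs["B"] == pytest.approx(0.5)

    def test_unique_evidence_pulls_ambiguous_read(self):
        # r1 only matches A; r2 is ambiguous between A and B: EM resolves to A
        res = em_iterate(
            initialize_alignment_matrix(
                make_alignments({"r1": {"A"}, "r2": {"A", "B"}})
            ),
            alpha=1e-12,
        )
        assert res.probs["A"] == pytest.approx(1.0, abs=1e-4)
        assert res.probs["B"] == pytest.approx(0.0, abs=1e-4)

    def test_fully_ambiguous_reads_stay_symmetric(self):
        res = em_iterate(
            initialize_alignment_matrix(
                make_alignments({"r1": {"A", "B"}, "r2": {"A", "B"}})
            )
        )
        assert res.probs["A"] == pytest.approx(0.5)
        assert res.probs["B"] == pytest.approx(0.5)

    def test_max_iterations_reports_nonconvergence_without_raising(self):
        res = em_iterate(
            initialize_alignment_matrix(
                make_alignments({"r1": {"A"}, "r2": {"A", "B"}})
            ),
            alpha=1e-300,
            max_iterations=3,
        )
        assert not res.converged
        assert res.iterations == 3

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 7))
        n = int(rng.integers(1, 51))
        alleles = [f"A{i}" for i in range(m)]
        entries = {
            f"r{j}": set(
                rng.choice(alleles, size=int(rng.integers(1, m + 1)), replace=False)
            )
            for j in range(n)
        }
        res = em_iterate(
            initialize_alignment_matrix(make_alignments(entries)), alpha=1e-8
        )
        expected = brute_force_em(entries, alpha=1e-8)
        for a in expected:
            assert res.probs[a] == pytest.approx(expected[a], abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_column_stochasticity_and_mass_conservation(self, seed):
        rng = np.random.default_rng(seed)
        alleles = ["A", "B", "C"]
        entries = {
            f"r{j}": set(rng.choice(alleles, size=int(rng.integers(1, 4)), replace=False))
            for j in range(int(rng.integers(1, 20)))
        }
        am = initialize_alignment_matrix(make_alignments(entries))
        M = am.M
        n = M.shape[1]
        for _ in range(5):
            E = M.sum(axis=1)
            assert E.sum() == pytest.approx(n)  # sum of expectations = read count
            W = M * E[:, None]
            M = W / W.sum(axis=0, keepdims=True)
            assert M.sum(axis=0) == pytest.approx(np.ones(n))


class TestBootstrap:
    def test_degenerate_bootstrap_equals_plain_em(self):
        entries = {"r1": {"A"}, "r2": {"A", "B"}, "r3": {"B"}}
        cfg = EmConfig(n_boot=1, p=1.0, seed=5)
        boot = bootstrap_probabilities(make_alignments(entries), cfg)
        plain = em_iterate(
            initialize_alignment_matrix(make_alignments(entries)), cfg.alpha
        )
        for a in plain.probs:
            assert boot.probs[a] == pytest.approx(plain.probs[a])

    @pytest.mark.parametrize("seed,p", [(0, 0.3), (1, 0.5), (2, 1.0)])
    def test_unanimous_evidence_is_seed_invariant(self, seed, p):
        entries = {f"r{i}": {"A"} for i in range(10)}
        cfg = EmConfig(n_boot=20, p=p, seed=seed)
        boot = bootstrap_probabilities(make_alignments(entries), cfg)
        assert boot.probs["A"] == pytest.approx(1.0)

    def test_symmetric_input_gives_symmetric_average(self):
        entries = {"r1": {"A"}, "r2": {"B"}, "r3": {"A", "B"}}
        # per-bootstrap outcomes are one of (.5,.5), (1,0), (0,1), so the
        # mean difference has sd ~ sqrt(2/3)/sqrt(n_boot); 2000 bootstraps
        # put the 0.05 tolerance at ~2.7 sigma
        cfg = EmConfig(n_boot=2000, p=0.5, seed=7)
        boot = bootstrap_probabilities(make_alignments(entries), cfg)
        assert abs(boot.probs["A"] - boot.probs["B"]) < 0.05

    def test_invariant_under_read_relabeling(self):
        entries = {"r1": {"A"}, "r2": {"B"}, "r3": {"A", "B"}, "r4": {"B"}}
        relabeled = {f"z{k[1:]}": v for k, v in entries.items()}
        cfg = EmConfig(n_boot=100, p=0.5, seed=3)
        a = bootstrap_probabilities(make_alignments(entries), cfg)
        b = bootstrap_probabilities(make_alignments(relabeled), cfg)
        for k in a.probs:
            assert a.probs[k] == pytest.approx(b.probs[k])

    def test_fewer_than_min_reads_raises(self):
        cfg = EmConfig(min_reads=5)
        with pytest.raises(NoReadsError):
            bootstrap_probabilities(make_alignments({"r1": {"A"}}), cfg)

    def test_deterministic_given_seed(self):
        entries = {"r1": {"A"}, "r2": {"A", "B"}, "r3": {"B"}}
        cfg = EmConfig(n_boot=50, p=0.5, seed=11)
        a = bootstrap_probabilities(make_alignments(entries), cfg)
        b = bootstrap_probabilities(make_alignments(entries), cfg)
        assert a.probs == b.probs


def probs_of(d: dict[str, float]) -> AlleleProbabilities:
    return AlleleProbabilities(gene="KIR2DL2", probs=d, n_reads=10)


class TestCalling:
    def test_single_allele_above_threshold_is_homozygous(self):
        call = call_genotype(probs_of({"A": 0.90, "B": 0.10}), 0.5)
        assert call.zygosity == "homozygous"
        assert call.alleles == ("A", "A")

    def test_two_alleles_above_threshold_is_heterozygous(self):
        call = call_genotype(probs_of({"A": 0.55, "B": 0.40, "C": 0.05}), 0.25)
        assert call.zygosity == "heterozygous"
        assert call.alleles == ("A", "B")

    def test_three_above_threshold_is_no_call(self):
        call = call_genotype(probs_of({"A": 0.40, "B": 0.35, "C": 0.25}), 0.2)
        assert call.zygosity == "no_call"
        assert call.no_call_reason == "more_than_two_above_threshold"

    def test_none_above_threshold_is_no_call(self):
        call = call_genotype(probs_of({"A": 0.4, "B": 0.3, "C": 0.3}), 0.5)
        assert call.no_call_reason == "none_above_threshold"

    def test_threshold_comparison_is_strict(self):
        call = call_genotype(probs_of({"A": 0.75, "B": 0.25}), 0.25)
        assert call.zygosity == "homozygous"  # B at exactly t is below threshold

    def test_collapse_applied_before_thresholding(self):
        groups = {"KIRX*00501": "KIRX*005", "KIRX*00502": "KIRX*005"}
        call = call_genotype(
            probs_of({"KIRX*00501": 0.3, "KIRX*00502": 0.3}), 0.5, groups=groups
        )
        assert call.zygosity == "homozygous"
        assert call.alleles == ("KIRX*005", "KIRX*005")

    def test_nonconverged_probabilities_yield_no_call_by_default(self):
        p = probs_of({"A": 1.0})
        p.converged = False
        assert call_genotype(p, 0.25).no_call_reason == "not_converged"
        assert (
            call_genotype(p, 0.25, require_convergence=False).zygosity == "homozygous"
        )

    @given(
        st.dictionaries(
            st.sampled_from("ABCDE"),
            st.floats(min_value=0, max_value=1),
            min_size=1,
            max_size=5,
        ),
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.01, max_value=0.99),
    )
    @settings(deadline=None, max_examples=60)
    def test_raising_t_never_rescues_a_none_above_threshold(self, probs, t1, t2):
        lo, hi = sorted((t1, t2))
        call_lo = call_genotype(probs_of(probs), lo)
        call_hi = call_genotype(probs_of(probs), hi)
        if call_lo.no_call_reason == "none_above_threshold":
            assert call_hi.no_call_reason == "none_above_threshold"


def test_gene_with_no_reads_yields_no_call(small_db):
    gene = small_db.genes[0]
    calls = genotype_readsets(
        {gene: ReadSet(gene=gene, reads=[])}, small_db, EmConfig(seed=0)
    )
    assert calls[gene].zygosity == "no_call"
    assert calls[gene].no_call_reason == "no_reads"
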