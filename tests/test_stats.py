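"""Statistics core: overlap tests, FDR, Wilcoxon, KS, motif scanner."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from clipscan.intervals import ValidationError
from clipscan.stats import (
    MotifSpec,
    OverlapSpec,
    bh_fdr,
    fisher_exact,
    hypergeom_overlap_report,
    hypergeom_tail,
    ks_one_sided,
    log_hypergeom_tail,
    motif_scan,
    qvalues,
    wilcoxon_paired,
)


class TestHypergeom:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_tail(OverlapSpec(100, 50, 10, 0)).p == 1.0

    def test_small_case_full_enumeration(self):
        # N=10, K=5, n=4, k=4: C(5,4)C(5,0)/C(10,4) = 5/210
        res = hypergeom_tail(OverlapSpec(10, 5, 4, 4))
        assert res.p == pytest.approx(5 / 210, rel=1e-12)

    def test_matches_exhaustive_enumeration_small_populations(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            exact = sum(
                math.comb(K, i) * math.comb(N - K, n - i)
                for i in range(k, min(K, n) + 1)
                if n - i <= N - K
            ) / math.comb(N, n)
            assert hypergeom_tail(OverlapSpec(N, K, n, k)).p == pytest.approx(exact, rel=1e-10)

    @pytest.mark.parametrize(
        "N,K,n,k,printed",
        [
            (14_737, 8_681, 538, 500, 6.5e-74),
            (14_737, 8_681, 1_978, 1_835, 2.3e-287),
            (12_242, 952, 327, 51, 1.3e-6),
            (12_659, 1_920, 502, 349, 1.3e-175),
        ],
    )
    def test_published_overlap_anchors(self, N, K, n, k, printed):
        """Deeply significant gene-list overlaps reproduce the reported
        p-values within 10% relative error on the log10 scale."""
        log10p = log_hypergeom_tail(OverlapSpec(N, K, n, k)) / np.log(10)
        assert np.isfinite(log10p)
        assert log10p == pytest.approx(np.log10(printed), rel=0.10)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            OverlapSpec(10, 11, 5, 2)
        with pytest.raises(ValidationError):
            OverlapSpec(10, 5, 4, 5)

    def test_overlap_report(self):
        pop = [f"g{i}" for i in range(100)]
        spec, res = hypergeom_overlap_report(pop[:10], pop[5:20], pop)
        assert (spec.N, spec.K, spec.n, spec.k) == (100, 15, 10, 5)
        with pytest.raises(ValidationError):
            hypergeom_overlap_report(["absent"], pop[:5], pop)

    def test_disjoint_lists_p_one(self):
        pop = [f"g{i}" for i in range(50)]
        spec, res = hypergeom_overlap_report(pop[:10], pop[40:], pop)
        assert spec.k == 0 and res.p == 1.0


class TestFisher:
    def test_diagonal_table_enumeration(self):
        # [[10,0],[0,10]]: only the two extreme tables are as improbable
        res = fisher_exact([[10, 0], [0, 10]])
        assert res.p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_balanced_table_is_null(self):
        assert fisher_exact([[1, 1], [1, 1]]).p == 1.0

    def test_zero_margin_flagged(self):
        res = fisher_exact([[0, 0], [3, 5]])
        assert res.p == 1.0 and "zero-margin" in res.flags

    def test_one_sided_equals_hypergeometric_tail(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            res = fisher_exact([[a, b], [c, d]], sidedness="greater")
            spec = OverlapSpec(N=a + b + c + d, K=a + b, n=a + c, k=a)
            assert res.p == pytest.approx(hypergeom_tail(spec).p, rel=1e-8)


class TestWilcoxon:
    def test_all_positive_unit_differences_exact(self):
        # ten pairs, all shifted by +1: P = 1/2^10 under sign-flip null
        x = np.arange(10.0)
        res = wilcoxon_paired(x, x + 1, alternative="greater")
        assert res.p == pytest.approx(1 / 2**10, rel=1e-12)

    def test_identical_vectors_flagged(self):
        res = wilcoxon_paired([1.0, 2.0], [1.0, 2.0])
        assert res.p == 1.0 and "all-zero-differences" in res.flags

    def test_exact_agrees_with_scipy_no_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=12)
            y = x + rng.normal(0.3, 1.0, size=12)
            for alt in ("greater", "less", "two-sided"):
                ours = wilcoxon_paired(x, y, alternative=alt)
                ref = sps.wilcoxon(y, x, alternative=alt, method="exact")
                assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_close_to_normal_approximation_at_boundary(self):
        # moderate-p regime, where the normal approximation is accurate
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = x + rng.normal(0.2, 1.0, size=25)
        exact = wilcoxon_paired(x, y, alternative="greater", exact_max_n=25)
        approx = wilcoxon_paired(x, y, alternative="greater", exact_max_n=0)
        assert approx.p == pytest.approx(exact.p, rel=0.10)

    def test_antisymmetry_of_sides(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=15), rng.normal(size=15)
        g = wilcoxon_paired(x, y, alternative="greater").p
        l = wilcoxon_paired(y, x, alternative="greater").p
        assert g == pytest.approx(wilcoxon_paired(y, x, alternative="less").p, rel=1e-9)


class TestKS:
    def test_identical_samples(self):
        a = np.arange(50.0)
        res = ks_one_sided(a, a)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_shift_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=100)
        res = ks_one_sided(a, a - 10)  # b stochastically smaller -> D+ large
        assert res.statistic > 0.9 and res.p < 0.01

    def test_statistic_equals_brute_force_ecdf_gap(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=40), rng.normal(0.3, 1.2, size=60)
        grid = np.concatenate([a, b])
        dplus = max((b <= x).mean() - (a <= x).mean() for x in grid)
        assert ks_one_sided(a, b).statistic == pytest.approx(dplus, abs=1e-12)


class TestFDR:
    def test_all_ones(self):
        q, pi0 = qvalues(np.ones(200))
        assert np.all(q == 1.0) and pi0 == 1.0

    def test_uniform_null_pi0_near_one(self):
        rng = np.random.default_rng(7)
        q, pi0 = qvalues(rng.random(10_000))
        assert pi0 == pytest.approx(1.0, abs=0.05)

    def test_qvalues_bounded_by_bh_under_signal(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.random(5_000), rng.beta(0.1, 10, 5_000)])
        q, pi0 = qvalues(p)
        assert pi0 < 1.0
        assert np.all(q <= bh_fdr(p) + 1e-12)

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(9)
        p = rng.random(500)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert adj.max() <= 1.0 and np.all(adj >= p - 1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestMotif:
    def test_basic_matches(self):
        assert motif_scan("TTTTTT") == [0]
        assert motif_scan("TTTGTT") == [0]
        assert motif_scan("TTGGTT") == []
        assert motif_scan("") == []
        assert motif_scan("NTTTTT") == []

    def test_u6_with_one_g_accepts_exactly_seven_hexamers(self):
        spec = MotifSpec()
        accepted = {
            "".join(w) for w in itertools.product("ACGT", repeat=6)
            if motif_scan("".join(w), spec)
        }
        assert len(accepted) == 7
        assert accepted == spec.accepted_kmers()

    def test_rna_alphabet_accepted(self):
        assert motif_scan("UUUGUU") == [0]

    def test_scan_equals_declarative_oracle_on_random_sequences(self):
        spec = MotifSpec()
        kmers = spec.accepted_kmers()
        rng = np.random.default_rng(10)
        bases = np.array(list("ACGTN"))
        for _ in range(300):
            seq = "".join(rng.choice(bases, size=60, p=[0.1, 0.1, 0.2, 0.55, 0.05]))
            oracle = [i for i in range(55) if seq[i:i + 6] in kmers]
            assert motif_scan(seq, spec) == oracle

    def test_relaxed_modes(self):
        five = MotifSpec(length=5)
        assert motif_scan("TTGTT", five) == [0]
        ac = MotifSpec(allowed="A")
        assert motif_scan("TTTATT", ac) == [0]
        assert motif_scan("TTTGTT", ac) == []
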