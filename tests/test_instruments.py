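"""Instrument selection, clumping and strength arithmetic."""

import numpy as np
import pytest

from mrpipe import (
    ConfigurationError,
    DomainError,
    InstrumentSet,
    LDMatrix,
    SyntheticTruth,
    harmonize,
    ld_clump,
    overall_f,
    per_snp_f,
    per_snp_r2,
    retained,
    significance_filter,
    simulate_pair,
)
from conftest import make_instruments


def _records(pvals):
    from mrpipe import VariantAssociation

    return [
        VariantAssociation(f"rs{i}", "A", "G", 0.1, 0.01, p, 1000, eaf=0.3)
        for i, p in enumerate(pvals)
    ]


class TestSignificanceFilter:
    def test_threshold(self):
        kept = significance_filter(_records([1e-9, 1e-7, 1e-4]), 5e-8)
        assert [r.variant_id for r in kept] == ["rs0"]

    def test_identity_near_one(self):
        records = _records([1e-9, 1e-7, 1e-4])
        assert significance_filter(records, 1.0 - 1e-12) == records

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        pvals = 10.0 ** rng.uniform(-12, 0, 100)
        records = _records(pvals)
        kept = significance_filter(records, 5e-8)
        assert len(kept) == int(np.sum(pvals < 5e-8))
        assert [r.variant_id for r in kept] == [
            r.variant_id for r in records if r.pval < 5e-8
        ]

    def test_idempotent(self):
        records = _records([1e-9, 1e-10, 0.2])
        once = significance_filter(records, 5e-8)
        assert significance_filter(once, 5e-8) == once

    def test_bad_threshold_raises(self):
        with pytest.raises(DomainError):
            significance_filter(_records([0.5]), 1.5)


class TestLDClump:
    def test_greedy_example(self):
        records = _records([1e-20, 1e-10, 1e-9])
        r2 = np.array([[1.0, 0.5, 0.001], [0.5, 1.0, 0.002], [0.001, 0.002, 1.0]])
        ld = LDMatrix(("rs0", "rs1", "rs2"), r2)
        kept = ld_clump(records, ld, 0.01, 10_000)
        assert [r.variant_id for r in kept] == ["rs0", "rs2"]

    def test_identity_matrix_keeps_all(self):
        records = _records([1e-20, 1e-10, 1e-9])
        kept = ld_clump(records, LDMatrix.identity(["rs0", "rs1", "rs2"]), 0.01, 10_000)
        assert len(kept) == 3

    def test_perfect_ld_keeps_smallest_p(self):
        records = _records([1e-10, 1e-20, 1e-9])
        ld = LDMatrix(("rs0", "rs1", "rs2"), np.ones((3, 3)))
        kept = ld_clump(records, ld, 0.01, 10_000)
        assert [r.variant_id for r in kept] == ["rs1"]

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        records = _records(10.0 ** rng.uniform(-15, -8, 12))
        a = rng.uniform(0, 1, (12, 12))
        r2 = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(tuple(f"rs{i}" for i in range(12)), r2)
        kept = ld_clump(records, ld, 0.3, 10_000)
        for seed in range(3):
            shuffled = list(records)
            np.random.default_rng(seed).shuffle(shuffled)
            assert [r.variant_id for r in ld_clump(shuffled, ld, 0.3, 10_000)] == [
                r.variant_id for r in kept
            ]
        # all pairwise kept r2 below the threshold
        idx = [ld.variant_ids.index(r.variant_id) for r in kept]
        for i in idx:
            for j in idx:
                if i != j:
                    assert r2[i, j] < 0.3

    def test_window_semantics_with_positions(self):
        # perfectly correlated pair, but 20 Mb apart: outside a 10 Mb window
        records = _records([1e-20, 1e-10])
        ld = LDMatrix(
            ("rs0", "rs1"),
            np.array([[1.0, 1.0], [1.0, 1.0]]),
            positions={"rs0": ("1", 1_000_000), "rs1": ("1", 21_000_000)},
        )
        kept = ld_clump(records, ld, 0.01, 10_000)
        assert len(kept) == 2
        # same pair within the window is clumped
        ld2 = LDMatrix(
            ("rs0", "rs1"),
            np.array([[1.0, 1.0], [1.0, 1.0]]),
            positions={"rs0": ("1", 1_000_000), "rs1": ("1", 2_000_000)},
        )
        assert len(ld_clump(records, ld2, 0.01, 10_000)) == 1

    def test_missing_variant_raises(self):
        records = _records([1e-10, 1e-9])
        with pytest.raises(ConfigurationError, match="rs1"):
            ld_clump(records, LDMatrix.identity(["rs0"]), 0.01, 10_000)


class TestStrengthArithmetic:
    @pytest.mark.parametrize(
        "beta,se,expected", [(0.1, 0.05, 4.0), (0.0, 0.1, 0.0), (-0.3, 0.1, 9.0)]
    )
    def test_per_snp_f(self, beta, se, expected):
        assert per_snp_f(beta, se) == pytest.approx(expected)

    def test_per_snp_f_domain(self):
        with pytest.raises(DomainError):
            per_snp_f(0.1, 0.0)

    def test_per_snp_r2_hand_evaluation(self):
        # 2*eaf*(1-eaf) cancels: beta^2 / (beta^2 + n se^2) = 0.01 / 1.01
        assert per_snp_r2(0.5, 0.1, 0.01, 10_000) == pytest.approx(0.01 / 1.01, rel=1e-12)

    def test_per_snp_r2_null_and_symmetry(self):
        assert per_snp_r2(0.3, 0.0, 0.01, 1000) == 0.0
        assert per_snp_r2(0.3, -0.2, 0.01, 1000) == per_snp_r2(0.3, 0.2, 0.01, 1000)

    @pytest.mark.parametrize("eaf", [0.0, 1.0, -0.1])
    def test_per_snp_r2_domain(self, eaf):
        with pytest.raises(DomainError):
            per_snp_r2(eaf, 0.1, 0.01, 1000)

    # published instrument panels: (k SNPs, exposure n, R2 %, F)
    TABLE = [
        (39, 335_394, 0.54, 46.69), (17, 461_053, 0.15, 40.74), (34, 452_236, 0.31, 41.36),
        (44, 441_640, 0.45, 45.37), (73, 451_486, 0.62, 38.58), (44, 428_860, 0.73, 71.67),
        (17, 448_651, 0.14, 37.00), (46, 421_764, 0.45, 41.44), (58, 446_462, 0.59, 45.68),
        (33, 460_006, 0.29, 40.54), (12, 460_880, 0.11, 42.29), (73, 460_443, 0.69, 43.82),
        (14, 460_162, 0.12, 39.49), (9, 461_900, 0.06, 30.81), (24, 461_981, 0.20, 38.57),
        (21, 435_435, 0.18, 37.39), (124, 462_630, 1.30, 49.13), (50, 447_485, 0.63, 56.73),
    ]

    @pytest.mark.parametrize("k,n,r2_pct,f_expected", TABLE)
    def test_overall_f_reproduces_published_panels(self, k, n, r2_pct, f_expected):
        assert round(overall_f(n, k, r2_pct / 100.0), 2) == f_expected

    def test_overall_f_null(self):
        assert overall_f(1000, 10, 0.0) == 0.0

    @pytest.mark.parametrize("n,k,r2", [(10, 9, 0.1), (1000, 10, 1.0), (1000, 0, 0.1)])
    def test_overall_f_domain(self, n, k, r2):
        with pytest.raises(DomainError):
            overall_f(n, k, r2)


class TestInstrumentSet:
    def test_strong_synthetic_instruments_pass_f_bar(self):
        """Default synthetic data yields only strong (F >= 10) instruments."""
        exposure, outcome, _ld, _ledger = simulate_pair(SyntheticTruth(seed=11))
        insts = retained(harmonize(significance_filter(exposure), outcome))
        iset = InstrumentSet.from_instruments(insts)
        assert min(iset.f_per_snp) >= 10.0
        assert iset.f_overall > 10.0 and not iset.weak
        assert 0.0 <= iset.r2_total < 1.0

    def test_r2_total_sums_members(self):
        insts = make_instruments(5, seed=1)
        iset = InstrumentSet.from_instruments(insts, n=300_000)
        expected = sum(per_snp_r2(i.eaf, i.beta_exp, i.se_exp, i.n_exp) for i in insts)
        assert iset.r2_total == pytest.approx(expected, rel=1e-12)


def test_ld_matrix_validation():
    with pytest.raises(ConfigurationError):
        LDMatrix(("a", "b"), np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
    with pytest.raises(ConfigurationError):
        LDMatrix(("a", "b"), np.array([[1.0, 2.0], [2.0, 1.0]]))  # out of range
    with pytest.raises(ConfigurationError):
        LDMatrix(("a", "b"), np.array([[0.9, 0.1], [0.1, 1.0]]))  # diagonal
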