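"""Causal estimators against hand arithmetic and an independent WLS oracle."""

import dataclasses
import math

import numpy as np
import pytest

from mrpipe import (
    CollinearityError,
    DegenerateInstrumentError,
    HarmonizedInstrument,
    InsufficientInstrumentsError,
    cochran_q,
    egger,
    ivw,
    to_odds_scale,
    wald_ratio,
    weighted_median,
)
from conftest import make_instruments
from _oracle import wls_through_origin, wls_with_intercept


def inst(vid="rs1", bx=0.1, sx=0.01, by=0.05, sy=0.02):
    return HarmonizedInstrument(vid, "A", "G", bx, sx, by, sy, "kept", eaf=0.3)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        e = wald_ratio(inst(bx=0.1, by=0.2, sy=0.05))
        assert e.beta == pytest.approx(2.0)
        assert e.se == pytest.approx(0.5)
        assert e.method == "WaldRatio" and e.n_snp == 1

    def test_null_outcome(self):
        e = wald_ratio(inst(by=0.0))
        assert e.beta == 0.0 and e.or_ == 1.0

    def test_orientation_invariance(self):
        a = wald_ratio(inst(bx=0.1, by=0.2))
        b = wald_ratio(inst(bx=-0.1, by=-0.2))
        assert b.beta == a.beta and b.se == a.se

    def test_zero_exposure_raises(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(inst(bx=0.0))


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self):
        i = inst()
        e, het = ivw([i])
        w = wald_ratio(i)
        assert (e.beta, e.se, e.pval) == (w.beta, w.se, w.pval)
        assert het.q == 0.0 and het.pval == 1.0

    def test_shared_ratio_is_exact_with_zero_q(self):
        insts = [inst(f"rs{i}", bx=b, by=0.7 * b, sy=0.01 * (i + 1))
                 for i, b in enumerate([0.02, -0.05, 0.08, 0.03])]
        e, het = ivw(insts)
        assert e.beta == pytest.approx(0.7, rel=1e-12)
        assert het.q == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_oracle(self):
        insts = make_instruments(5, seed=42)
        bx = [i.beta_exp for i in insts]
        by = [i.beta_out for i in insts]
        sy = [i.se_out for i in insts]
        slope, se = wls_through_origin(bx, by, sy)
        e, _ = ivw(insts, random_effects=False)
        assert e.beta == pytest.approx(slope, rel=1e-10)
        assert e.se == pytest.approx(se, rel=1e-10)

    def test_random_effects_never_shrinks_se(self):
        insts = make_instruments(8, seed=5, noise=0.05)
        fixed, _ = ivw(insts, random_effects=False)
        random_, het = ivw(insts, random_effects=True)
        assert random_.se >= fixed.se
        assert random_.se == pytest.approx(
            fixed.se * math.sqrt(max(1.0, het.q / het.df)), rel=1e-12
        )

    def test_orientation_invariance(self):
        insts = make_instruments(6, seed=9)
        flipped = [
            dataclasses.replace(
                i, beta_exp=-i.beta_exp, beta_out=-i.beta_out, eaf=1 - i.eaf
            )
            if k % 2
            else i
            for k, i in enumerate(insts)
        ]
        a, ha = ivw(insts)
        b, hb = ivw(flipped)
        assert (a.beta, a.se, a.pval) == (b.beta, b.se, b.pval)
        assert ha.q == hb.q


class TestEgger:
    def test_exact_fit_through_origin(self):
        insts = [inst(f"rs{i}", bx=b, by=0.5 * b, sy=0.01) for i, b in enumerate([0.02, 0.05, 0.08, 0.03])]
        e, pleio, het = egger(insts)
        assert e.beta == pytest.approx(0.5, abs=1e-12)
        assert pleio.intercept == pytest.approx(0.0, abs=1e-12)
        assert het.q == pytest.approx(0.0, abs=1e-18)

    def test_exact_fit_with_offset(self):
        insts = [inst(f"rs{i}", bx=b, by=0.02 + 0.5 * b, sy=0.01) for i, b in enumerate([0.02, 0.05, 0.08, 0.03])]
        e, pleio, _ = egger(insts)
        assert e.beta == pytest.approx(0.5, abs=1e-12)
        assert pleio.intercept == pytest.approx(0.02, abs=1e-12)

    def test_matches_wls_oracle(self):
        insts = make_instruments(10, seed=3, intercept=0.02, noise=0.02)
        # the estimator orients bx >= 0 first; feed the oracle oriented data
        bx = np.array([i.beta_exp for i in insts])
        by = np.array([i.beta_out for i in insts])
        sy = np.array([i.se_out for i in insts])
        sign = np.where(bx < 0, -1.0, 1.0)
        (icpt, slope), (se_i, se_s) = wls_with_intercept(bx * sign, by * sign, sy)
        e, pleio, het = egger(insts, random_effects=False)
        assert e.beta == pytest.approx(slope, rel=1e-10)
        assert e.se == pytest.approx(se_s, rel=1e-10)
        assert pleio.intercept == pytest.approx(icpt, rel=1e-10)
        assert pleio.se == pytest.approx(se_i, rel=1e-10)
        assert het.df == len(insts) - 2

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger([inst("a"), inst("b")])

    def test_collinear_exposure(self):
        insts = [inst(f"rs{i}", bx=0.05) for i in range(4)]
        with pytest.raises(CollinearityError):
            egger(insts)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        # equal weights, ratios {1, 2, 9} -> middle ratio
        insts = [
            inst("a", bx=0.1, by=0.1, sy=0.1),
            inst("b", bx=0.1, by=0.2, sy=0.1),
            inst("c", bx=0.1, by=0.9, sy=0.1),
        ]
        e = weighted_median(insts, n_boot=100, seed=0)
        assert e.beta == pytest.approx(2.0, rel=1e-12)

    def test_dominant_instrument_drives_estimate(self):
        # brute-force the interpolation rule on the same 3-instrument fixture
        insts = [
            inst("a", bx=0.1, by=0.1, sy=0.01),  # ratio 1, weight (0.1/0.01)^2 = 100
            inst("b", bx=0.1, by=0.5, sy=0.1),  # ratio 5, weight 1
            inst("c", bx=0.1, by=0.9, sy=0.1),  # ratio 9, weight 1
        ]
        ratios = np.array([1.0, 5.0, 9.0])
        w = np.array([100.0, 1.0, 1.0]) / 102.0
        pos = np.cumsum(w) - 0.5 * w
        expected = float(np.interp(0.5, pos, ratios))
        e = weighted_median(insts, n_boot=100, seed=0)
        assert e.beta == pytest.approx(expected, rel=1e-12)
        # >50% of weight on the first instrument: estimate interpolates off its ratio
        assert abs(e.beta - 1.0) < 0.1

    def test_same_seed_bit_identical(self):
        insts = make_instruments(6, seed=2)
        a = weighted_median(insts, n_boot=200, seed=99)
        b = weighted_median(insts, n_boot=200, seed=99)
        assert (a.beta, a.se, a.pval) == (b.beta, b.se, b.pval)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median([inst("a"), inst("b")], seed=0)


class TestCochranQ:
    def test_identical_ratios(self):
        insts = [inst(f"rs{i}", bx=b, by=0.3 * b) for i, b in enumerate([0.02, 0.05, 0.08])]
        het = cochran_q(insts, 0.3)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.pval == pytest.approx(1.0)

    def test_two_instrument_hand_sum(self):
        a = inst("a", bx=0.1, by=0.05, sy=0.02)  # ratio 0.5, w = (0.1/0.02)^2 = 25
        b = inst("b", bx=0.2, by=0.02, sy=0.04)  # ratio 0.1, w = (0.2/0.04)^2 = 25
        beta_hat = 0.3
        expected = 25 * (0.5 - 0.3) ** 2 + 25 * (0.1 - 0.3) ** 2
        het = cochran_q([a, b], beta_hat)
        assert het.q == pytest.approx(expected, rel=1e-12)
        assert het.df == 1

    def test_scale_invariance(self):
        """Q is unchanged by rescaling bx, by and sy jointly by c."""
        insts = make_instruments(5, seed=8)
        c = 3.7
        scaled = [
            dataclasses.replace(
                i, beta_exp=c * i.beta_exp, beta_out=c * i.beta_out, se_out=c * i.se_out
            )
            for i in insts
        ]
        assert cochran_q(scaled, 0.4).q == pytest.approx(cochran_q(insts, 0.4).q, rel=1e-12)


class TestOddsScale:
    def test_vanishing_se_collapses_ci(self):
        or_, lo, hi = to_odds_scale(math.log(2.0), 1e-12)
        assert or_ == pytest.approx(2.0)
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_null_is_symmetric_in_log_space(self):
        or_, lo, hi = to_odds_scale(0.0, 0.3)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    def test_alcohol_pancreatitis_round_trip(self):
        """log-OR 0.5866 (SE 0.2517) -> OR 1.798 (1.097-2.944)."""
        or_, lo, hi = to_odds_scale(0.5866, 0.2517)
        assert or_ == pytest.approx(1.798, abs=5e-4)
        assert lo == pytest.approx(1.097, abs=5e-3)
        assert hi == pytest.approx(2.944, abs=5e-3)
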