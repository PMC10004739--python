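"""Univariable MR estimators and diagnostics.

Given harmonized instruments j = 1..k with exposure effects (bx_j, sx_j) and
outcome effects (by_j, sy_j), the causal effect of the exposure on the
outcome is estimated by:

* **Wald ratio** (single instrument): by / bx with SE sy / |bx|.
* **IVW**: weighted least squares of by on bx through the origin with
  weights w_j = 1 / sy_j^2, i.e. beta = sum(w bx by) / sum(w bx^2). The
  fixed-effects SE is (sum w bx^2)^{-1/2}; the multiplicative random-effects
  model inflates it by sqrt(max(1, Q / (k-1))) where Q is Cochran's Q, which
  is the primary analysis convention here.
* **MR-Egger**: the same weighted regression with a free intercept after
  orienting every bx >= 0. The slope estimates the causal effect under the
  InSIDE assumption; an intercept distinguishable from zero signals
  directional (unbalanced) horizontal pleiotropy. Small-sample inference
  uses t with k - 2 degrees of freedom.
* **Weighted median**: the ratio estimate at the 50th percentile of
  standardized weight, robust as long as at least half of the weight sits on
  valid instruments; its SE comes from a seeded parametric bootstrap.

Cochran's Q (weights (sy / bx)^{-2} on the ratio scale) quantifies
heterogeneity among per-instrument estimates. Results are reported as odds
ratios with 95% confidence intervals via ``to_odds_scale``.

Weights throughout are first-order: the exposure-side uncertainty is
ignored, which is the standard default of the field's tooling; pass
``second_order_weights=True`` to IVW to include it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateInstrumentError,
    DomainError,
    InsufficientInstrumentsError,
    CollinearityError,
)
from .gwas_io import HarmonizedInstrument

logger = logging.getLogger(__name__)

#: z for a two-sided 95% interval.
Z_95 = 1.959963984540054

#: Default bootstrap replicates for the weighted-median SE.
DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds and odds-ratio scales."""

    method: str
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    n_snp: int


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its degrees of freedom and upper-tail chi-square p."""

    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept test for directional pleiotropy."""

    intercept: float
    se: float
    pval: float


def _arrays(insts: Sequence[HarmonizedInstrument]):
    bx = np.array([i.beta_exp for i in insts], dtype=float)
    sx = np.array([i.se_exp for i in insts], dtype=float)
    by = np.array([i.beta_out for i in insts], dtype=float)
    sy = np.array([i.se_out for i in insts], dtype=float)
    return bx, sx, by, sy


def to_odds_scale(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect into (OR, 95% CI low, 95% CI high)."""
    if not se >= 0:
        raise DomainError(f"se must be non-negative, got {se}")
    return math.exp(beta), math.exp(beta - Z_95 * se), math.exp(beta + Z_95 * se)


def _make_estimate(method: str, beta: float, se: float, pval: float, n_snp: int) -> MREstimate:
    or_, lo, hi = to_odds_scale(beta, se)
    return MREstimate(method, beta, se, pval, or_, lo, hi, n_snp)


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-instrument ratio estimate by/bx with first-order SE sy/|bx|."""
    if inst.beta_exp == 0:
        raise DegenerateInstrumentError(f"{inst.variant_id}: exposure beta is zero")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return _make_estimate("WaldRatio", beta, se, pval, 1)


def ivw(
    insts: Sequence[HarmonizedInstrument],
    random_effects: bool = True,
    second_order_weights: bool = False,
) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with Cochran's Q.

    With a single instrument, delegates to :func:`wald_ratio` (Q undefined,
    reported as 0 on 0 df with p = 1).
    """
    if len(insts) == 0:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    if len(insts) == 1:
        logger.info("IVW with one instrument: falling back to the Wald ratio")
        est = wald_ratio(insts[0])
        est = MREstimate(
            "IVW", est.beta, est.se, est.pval, est.or_, est.ci_low, est.ci_high, 1
        )
        return est, HeterogeneityResult(0.0, 0, 1.0)
    bx, sx, by, sy = _arrays(insts)
    if (bx == 0).any():
        raise DegenerateInstrumentError("IVW requires all exposure betas nonzero")
    k = len(insts)
    if second_order_weights:
        # delta-method variance of the ratio propagated to the regression scale
        w = 1.0 / (sy**2 + (by / bx) ** 2 * sx**2)
    else:
        w = 1.0 / sy**2
    s_xx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / s_xx
    se_fixed = s_xx**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = k - 1
    q_p = float(stats.chi2.sf(q, df))
    se = se_fixed
    if random_effects:
        se = se_fixed * math.sqrt(max(1.0, q / df))
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return _make_estimate("IVW", beta, se, pval, k), HeterogeneityResult(q, df, q_p)


def egger(
    insts: Sequence[HarmonizedInstrument], random_effects: bool = True
) -> tuple[MREstimate, PleiotropyResult, HeterogeneityResult]:
    """MR-Egger weighted regression with a free intercept.

    Instruments are first oriented so every exposure beta is non-negative
    (the outcome beta is negated alongside), which is what gives the
    intercept its directional-pleiotropy interpretation. Slope and intercept
    p-values use t on k - 2 degrees of freedom.
    """
    if len(insts) < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires >= 3 instruments, got {len(insts)}"
        )
    bx, sx, by, sy = _arrays(insts)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise CollinearityError("zero spread in oriented exposure betas")
    k = len(insts)
    w = 1.0 / sy**2
    # weighted normal equations for [intercept, slope]
    sw = float(np.sum(w))
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx * swx
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    df = k - 2
    q_p = float(stats.chi2.sf(q, df))
    inflate = math.sqrt(max(1.0, q / df)) if random_effects else 1.0
    se_slope = math.sqrt(sw / det) * inflate
    se_int = math.sqrt(swxx / det) * inflate
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, df)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, df)
    return (
        _make_estimate("Egger", slope, se_slope, p_slope, k),
        PleiotropyResult(intercept, se_int, p_int),
        HeterogeneityResult(q, df, q_p),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median.

    Sort ratios ascending; the percentile position of item i is the
    cumulative weight up to i minus half its own weight, standardized to
    [0, 1]; the estimate linearly interpolates the ratio at position 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    pos = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, pos, r))


def weighted_median(
    insts: Sequence[HarmonizedInstrument],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Per-instrument ratios by/bx are weighted by (bx / sy)^2 (the inverse
    first-order variance of the ratio). The SE resamples each bx and by from
    normal(observed, se) ``n_boot`` times and takes the standard deviation of
    the recomputed medians; ``seed`` makes this reproducible.
    """
    if len(insts) < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 instruments, got {len(insts)}"
        )
    if n_boot < 100:
        logger.warning("n_boot=%d is small; the bootstrap SE will be noisy", n_boot)
    if seed is None:
        logger.warning("weighted_median called without a seed; SE is not reproducible")
    bx, sx, by, sy = _arrays(insts)
    if (bx == 0).any():
        raise DegenerateInstrumentError("weighted median requires all exposure betas nonzero")
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, len(insts)))
    by_star = rng.normal(by, sy, size=(n_boot, len(insts)))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx_star[b]
        ok = bxb != 0
        boots[b] = _weighted_median(by_star[b][ok] / bxb[ok], (bxb[ok] / sy[ok]) ** 2)
    se = float(np.std(boots, ddof=1))
    pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return _make_estimate("WeightedMedian", beta, se, pval, len(insts))


def cochran_q(insts: Sequence[HarmonizedInstrument], beta_hat: float) -> HeterogeneityResult:
    """Cochran's Q of per-instrument ratios around ``beta_hat``.

    Q = sum_j w_j (by_j/bx_j - beta_hat)^2 with first-order weights
    w_j = (sy_j / bx_j)^{-2}; p is the upper tail of chi-square on k - 1 df.
    """
    if len(insts) < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    bx, _, by, sy = _arrays(insts)
    if (bx == 0).any():
        raise DegenerateInstrumentError("Cochran's Q requires all exposure betas nonzero")
    w = (bx / sy) ** 2
    q = float(np.sum(w * (by / bx - beta_hat) ** 2))
    df = len(insts) - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))
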