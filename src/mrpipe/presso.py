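"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

Horizontal pleiotropy makes some instruments' outcome effects deviate from
the line implied by the causal effect. MR-PRESSO detects this by comparing
the observed residual sum of squares (RSS) of leave-one-out IVW fits with a
simulated null distribution:

* **Global test** — RSS_obs = sum_j w_j (by_j - b_{-j} bx_j)^2 where b_{-j}
  is the IVW slope fit without instrument j and w_j = 1/sy_j^2; the null is
  built by drawing by*_j ~ N(b_{-j} bx_j, sy_j) and bx*_j ~ N(bx_j, sx_j)
  and recomputing the RSS; the p-value is the tail fraction, reported as
  (count + 1)/(n_sim + 1) so it is never exactly zero.
* **Outlier test** — each instrument's observed residual term is ranked
  against its simulated counterparts; per-instrument p-values are
  Bonferroni-adjusted and indices below ``outlier_alpha`` are flagged.
* **Distortion test** — the change between the all-instrument estimate and
  the outlier-corrected estimate is compared against removals of random
  subsets of the same size.

The corrected estimate is exactly :func:`mrpipe.estimators.ivw` applied to
the retained instruments (random effects, as in the primary analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import MREstimate, ivw
from .exceptions import InsufficientInstrumentsError
from .gwas_io import HarmonizedInstrument

#: Default simulation count; the smallest reportable p is 1/(n_sim + 1), so
#: this must comfortably exceed n_snp / outlier_alpha for the Bonferroni
#: outlier test to be able to flag anything.
DEFAULT_N_SIM = 5000
DEFAULT_OUTLIER_ALPHA = 0.05
DISTORTION_SUBSETS = 1000


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_pvals: tuple[float, ...]
    outliers: tuple[int, ...]
    distortion_pval: float | None
    corrected: MREstimate
    n_sim: int
    seed: int | None


def _loo_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope with each instrument left out, vectorized.

    Works on 1-D arrays (one dataset) or 2-D arrays (n_sim stacked
    datasets, instruments along the last axis).
    """
    s_xy = (w * bx * by).sum(axis=-1, keepdims=True)
    s_xx = (w * bx * bx).sum(axis=-1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def _rss_terms(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    return w * (by - _loo_betas(bx, by, w) * bx) ** 2


def presso(
    insts: list[HarmonizedInstrument],
    n_sim: int = DEFAULT_N_SIM,
    outlier_alpha: float = DEFAULT_OUTLIER_ALPHA,
    seed: int | None = None,
) -> PressoResult:
    """Run the global, outlier and distortion tests.

    ``outlier_alpha`` is the familywise level: instrument j is flagged when
    its Bonferroni-adjusted simulation p-value falls below it. Results are
    deterministic given ``seed``.
    """
    k = len(insts)
    if k < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO requires >= 4 instruments, got {k}")
    if n_sim < 1000:
        raise ValueError(f"n_sim must be >= 1000, got {n_sim}")
    rng = np.random.default_rng(seed)
    bx = np.array([i.beta_exp for i in insts], dtype=float)
    sx = np.array([i.se_exp for i in insts], dtype=float)
    by = np.array([i.beta_out for i in insts], dtype=float)
    sy = np.array([i.se_out for i in insts], dtype=float)
    w = 1.0 / sy**2

    loo = _loo_betas(bx, by, w)
    terms_obs = w * (by - loo * bx) ** 2
    rss_obs = float(terms_obs.sum())

    bx_star = rng.normal(bx, sx, size=(n_sim, k))
    by_star = rng.normal(loo * bx, sy, size=(n_sim, k))
    terms_sim = _rss_terms(bx_star, by_star, w)
    rss_sim = terms_sim.sum(axis=1)

    global_pval = (float((rss_sim >= rss_obs).sum()) + 1.0) / (n_sim + 1.0)
    outlier_raw = ((terms_sim >= terms_obs).sum(axis=0) + 1.0) / (n_sim + 1.0)
    outlier_pvals = tuple(float(min(1.0, p * k)) for p in outlier_raw)
    outliers = tuple(int(j) for j in range(k) if outlier_pvals[j] < outlier_alpha)

    if not outliers:
        est, _ = ivw(insts, random_effects=True)
        corrected = MREstimate(
            "PRESSO-corrected",
            est.beta, est.se, est.pval, est.or_, est.ci_low, est.ci_high, est.n_snp,
        )
        return PressoResult(
            rss_obs, global_pval, outlier_pvals, outliers, None, corrected, n_sim, seed
        )

    retained = [inst for j, inst in enumerate(insts) if j not in outliers]
    if len(retained) < 2:
        raise InsufficientInstrumentsError(
            "fewer than 2 instruments remain after outlier removal"
        )
    est, _ = ivw(retained, random_effects=True)
    corrected = MREstimate(
        "PRESSO-corrected",
        est.beta, est.se, est.pval, est.or_, est.ci_low, est.ci_high, est.n_snp,
    )

    # distortion: observed estimate shift vs removal of random same-size subsets
    def _beta_ivw(mask: np.ndarray) -> float:
        return float((w[mask] * bx[mask] * by[mask]).sum() / (w[mask] * bx[mask] ** 2).sum())

    full_mask = np.ones(k, dtype=bool)
    beta_all = _beta_ivw(full_mask)
    d_obs = abs(est.beta - beta_all)
    n_out = len(outliers)
    count = 0
    for _ in range(DISTORTION_SUBSETS):
        drop = rng.choice(k, size=n_out, replace=False)
        mask = full_mask.copy()
        mask[drop] = False
        if abs(_beta_ivw(mask) - beta_all) >= d_obs:
            count += 1
    distortion_pval = (count + 1.0) / (DISTORTION_SUBSETS + 1.0)

    return PressoResult(
        rss_obs, global_pval, outlier_pvals, outliers, distortion_pval, corrected, n_sim, seed
    )
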