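"""Multivariable Mendelian randomization (MVMR).

When exposures share instruments or one exposure mediates another (alcohol,
BMI, cholelithiasis against a disease outcome, for instance), the
univariable estimate mixes direct and indirect pathways. MVMR regresses the
instruments' outcome effects jointly on their effects for *all* included
exposures:

    by_j = sum_e theta_e * bx_{j,e} + error,  weights w_j = 1 / sy_j^2,

with no intercept; theta_e is exposure e's direct effect conditional on the
others. The instrument set is conventionally the union of each exposure's
genome-wide-significant, clumped instruments, re-clumped jointly, with each
exposure's effects looked up for every union variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import MREstimate, to_odds_scale
from .exceptions import CollinearityError, InsufficientInstrumentsError

#: Relative condition threshold below which a singular value counts as zero.
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class MVMRDataset:
    """Instrument-by-exposure effect matrices with outcome effects.

    ``beta_exp_matrix`` and ``se_exp_matrix`` are (n_instruments,
    n_exposures); ``beta_out``/``se_out`` have one entry per instrument.
    """

    variant_ids: tuple[str, ...]
    beta_exp_matrix: np.ndarray
    se_exp_matrix: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    exposure_names: tuple[str, ...]

    def __post_init__(self):
        b = np.atleast_2d(np.asarray(self.beta_exp_matrix, dtype=float))
        s = np.atleast_2d(np.asarray(self.se_exp_matrix, dtype=float))
        by = np.asarray(self.beta_out, dtype=float)
        sy = np.asarray(self.se_out, dtype=float)
        n, k = b.shape
        if s.shape != (n, k) or by.shape != (n,) or sy.shape != (n,):
            raise ValueError("inconsistent MVMR array shapes")
        if len(self.exposure_names) != k:
            raise ValueError("exposure_names length must match the matrix width")
        if n < k + 1:
            raise InsufficientInstrumentsError(
                f"MVMR needs at least n_exposures + 1 = {k + 1} instruments, got {n}"
            )
        if not (sy > 0).all():
            raise ValueError("outcome SEs must be positive")
        object.__setattr__(self, "beta_exp_matrix", b)
        object.__setattr__(self, "se_exp_matrix", s)
        object.__setattr__(self, "beta_out", by)
        object.__setattr__(self, "se_out", sy)
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        object.__setattr__(self, "exposure_names", tuple(self.exposure_names))


def mvmr_ivw(data: MVMRDataset, random_effects: bool = True) -> list[MREstimate]:
    """Weighted least squares of outcome effects on all exposure columns.

    Returns one estimate per exposure, in ``exposure_names`` order. With a
    single exposure and ``random_effects=False`` this reduces exactly to
    fixed-effects univariable IVW. Random effects inflate every SE by
    sqrt(max(1, Q / (n - k))) as in the univariable model.
    """
    b = data.beta_exp_matrix
    by = data.beta_out
    w = 1.0 / data.se_out**2
    n, k = b.shape

    sw = np.sqrt(w)
    design = b * sw[:, None]
    rank = np.linalg.matrix_rank(design, tol=_RANK_RTOL * np.abs(design).max())
    if rank < k:
        norms = np.linalg.norm(design, axis=0)
        bad = [data.exposure_names[j] for j in range(k) if norms[j] <= _RANK_RTOL * max(1.0, norms.max())]
        detail = f" (degenerate columns: {bad})" if bad else ""
        raise CollinearityError(
            f"exposure design matrix is rank deficient (rank {rank} < {k}){detail}"
        )

    xtx = design.T @ design
    xty = design.T @ (by * sw)
    cov = np.linalg.inv(xtx)
    theta = cov @ xty
    resid = by - b @ theta
    q = float(np.sum(w * resid**2))
    df = n - k
    inflate = math.sqrt(max(1.0, q / df)) if random_effects else 1.0
    ses = np.sqrt(np.diag(cov)) * inflate

    out = []
    for j, name in enumerate(data.exposure_names):
        beta_j, se_j = float(theta[j]), float(ses[j])
        pval = 2.0 * stats.norm.sf(abs(beta_j) / se_j)
        or_, lo, hi = to_odds_scale(beta_j, se_j)
        out.append(MREstimate(f"MVMR-IVW[{name}]", beta_j, se_j, pval, or_, lo, hi, n))
    return out


def build_mvmr_dataset(
    per_exposure_instruments: Sequence[Sequence],
    exposure_tables: Sequence[dict],
    outcome_table: dict,
    exposure_names: Sequence[str],
) -> MVMRDataset:
    """Assemble an MVMR dataset from per-exposure instrument selections.

    ``per_exposure_instruments`` holds each exposure's selected (clumped)
    harmonized instruments; ``exposure_tables`` and ``outcome_table`` map
    variant id -> record so effects for non-selected union variants can be
    looked up in each GWAS. Variants missing from any table are dropped.
    """
    union: list[str] = []
    seen = set()
    for insts in per_exposure_instruments:
        for inst in insts:
            if inst.variant_id not in seen:
                seen.add(inst.variant_id)
                union.append(inst.variant_id)
    ids, bmat, smat, by, sy = [], [], [], [], []
    for vid in union:
        if vid not in outcome_table or any(vid not in t for t in exposure_tables):
            continue
        ids.append(vid)
        bmat.append([t[vid].beta for t in exposure_tables])
        smat.append([t[vid].se for t in exposure_tables])
        by.append(outcome_table[vid].beta)
        sy.append(outcome_table[vid].se)
    return MVMRDataset(
        tuple(ids),
        np.array(bmat),
        np.array(smat),
        np.array(by),
        np.array(sy),
        tuple(exposure_names),
    )
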