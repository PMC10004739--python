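"""Synthetic two-sample GWAS summary statistics with known ground truth.

Real two-sample MR studies draw exposure associations from one cohort (a
population-scale biobank) and outcome associations from another (a disease
case-control consortium). This module emulates that design at desk scale so
every pipeline stage — harmonization, clumping, estimation, pleiotropy
diagnostics — can be tested against a planted truth:

* per-variant minor-allele frequencies are uniform on ``maf_range``;
* true exposure effects are Gaussian, rescaled so the instruments jointly
  explain ``exposure_h2`` of the (unit-variance) exposure;
* the observed exposure effect is the truth plus sampling noise with
  SE = 1/sqrt(2 maf (1-maf) n_exp), the standard large-sample SE for a
  continuous trait in SD units;
* each variant's true outcome effect is theta * beta_true plus a direct
  (horizontally pleiotropic) effect alpha_j whose distribution is set by
  ``pleiotropy_mode``; the observed outcome effect adds case-control noise
  with SE = 1/sqrt(2 maf (1-maf) n_out * phi (1-phi)) for case fraction phi,
  the log-odds-scale analogue;
* the LD matrix is block-diagonal with configurable within-block r^2.

Summary statistics are simulated directly on the effect-size scale — no
individual-level genotypes — which is exactly what the estimators consume.
All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .gwas_io import VariantAssociation
from .instruments import LDMatrix

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")

#: Non-palindromic allele pairs the generator draws from; strand is then
#: unambiguous, so harmonization keeps every simulated variant.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"))

#: FinnGen-like acute-pancreatitis case fraction (4648 / 278,090).
DEFAULT_CASE_FRACTION = 0.017


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters: the planted truth of one simulated study.

    ``theta`` is the true causal effect (log-odds of outcome per SD of
    exposure). ``pleiotropy_frac`` of the variants get direct outcome
    effects ``alpha_j``: mean-zero Gaussian of SD ``pleiotropy_scale``
    (``balanced``), positive-mean Gaussian (``directional``), or
    proportional to instrument strength plus noise (``inside_violating``,
    which breaks the independence between pleiotropy and instrument
    strength that MR-Egger relies on).
    """

    theta: float = 0.0
    n_variants: int = 50
    n_exp: int = 300_000
    n_out: int = 280_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2: float = 0.05
    pleiotropy_mode: str = "none"
    pleiotropy_frac: float = 0.0
    pleiotropy_scale: float = 0.0
    ld_blocks: tuple[tuple[int, float], ...] | None = None
    case_fraction: float = DEFAULT_CASE_FRACTION
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.exposure_h2 < 1.0):
            raise ConfigurationError(f"exposure_h2 must lie in (0, 1), got {self.exposure_h2}")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ConfigurationError("pleiotropy_frac must lie in [0, 1]")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ConfigurationError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}, got {self.pleiotropy_mode!r}"
            )
        if not (0.0 < self.case_fraction < 1.0):
            raise ConfigurationError("case_fraction must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")


@dataclass(frozen=True)
class SimulationLedger:
    """Every true value behind one simulated dataset."""

    truth: SyntheticTruth
    variant_ids: tuple[str, ...]
    maf: np.ndarray
    beta_exp_true: np.ndarray
    alpha: np.ndarray = field(repr=False)
    beta_out_true: np.ndarray = field(repr=False)


def _pval(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    # chi-square survival keeps tiny p-values finite and nonzero
    return stats.chi2.sf((beta / se) ** 2, 1)


def simulate_pair(
    truth: SyntheticTruth,
) -> tuple[list[VariantAssociation], list[VariantAssociation], LDMatrix, SimulationLedger]:
    """Draw one exposure table, one outcome table, an LD matrix and the ledger."""
    rng = np.random.default_rng(truth.seed)
    m = truth.n_variants
    maf = rng.uniform(*truth.maf_range, size=m)
    het = 2.0 * maf * (1.0 - maf)

    # magnitudes bounded away from zero and per-variant explained variance
    # equalized (larger effects at lower MAF): the design emulates an
    # already-selected panel of strong instruments
    g = rng.uniform(0.5, 1.5, size=m) * rng.choice([-1.0, 1.0], size=m)
    raw_var = float(np.sum(g * g))
    if raw_var <= 0:
        raise ConfigurationError("degenerate draw: zero raw genetic variance")
    beta_true = g * np.sqrt(truth.exposure_h2 / (het * raw_var))

    se_exp = 1.0 / np.sqrt(het * truth.n_exp)
    beta_exp_hat = rng.normal(beta_true, se_exp)

    alpha = np.zeros(m)
    n_pleio = int(round(truth.pleiotropy_frac * m))
    if truth.pleiotropy_mode != "none" and n_pleio > 0 and truth.pleiotropy_scale > 0:
        idx = rng.choice(m, size=n_pleio, replace=False)
        scale = truth.pleiotropy_scale
        if truth.pleiotropy_mode == "balanced":
            alpha[idx] = rng.normal(0.0, scale, size=n_pleio)
        elif truth.pleiotropy_mode == "directional":
            # positive-mean direct effects on the exposure-increasing allele:
            # tying the sign to beta_true makes the bias directional after the
            # orientation every estimator applies
            alpha[idx] = np.sign(beta_true[idx]) * rng.normal(scale, scale / 2.0, size=n_pleio)
        else:  # inside_violating: direct effects track instrument strength
            rms = float(np.sqrt(np.mean(beta_true[idx] ** 2)))
            alpha[idx] = scale * beta_true[idx] / rms + rng.normal(
                0.0, scale / 2.0, size=n_pleio
            )

    beta_out_true = truth.theta * beta_true + alpha
    v_bar = truth.case_fraction * (1.0 - truth.case_fraction)
    se_out = 1.0 / np.sqrt(het * truth.n_out * v_bar)
    beta_out_hat = rng.normal(beta_out_true, se_out)

    ids = tuple(f"rs{j + 1}" for j in range(m))
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    p_exp = _pval(beta_exp_hat, se_exp)
    p_out = _pval(beta_out_hat, se_out)

    exposure, outcome = [], []
    for j in range(m):
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        exposure.append(
            VariantAssociation(ids[j], ea, oa, float(beta_exp_hat[j]), float(se_exp[j]),
                               float(p_exp[j]), truth.n_exp, eaf=float(maf[j]))
        )
        outcome.append(
            VariantAssociation(ids[j], ea, oa, float(beta_out_hat[j]), float(se_out[j]),
                               float(p_out[j]), truth.n_out, eaf=float(maf[j]))
        )

    ld = _block_ld(ids, truth.ld_blocks)
    ledger = SimulationLedger(truth, ids, maf, beta_true, alpha, beta_out_true)
    return exposure, outcome, ld, ledger


def _block_ld(ids: Sequence[str], blocks) -> LDMatrix:
    m = len(ids)
    r2 = np.eye(m)
    if blocks:
        start = 0
        for size, within in blocks:
            stop = min(start + size, m)
            if stop <= start:
                break
            r2[start:stop, start:stop] = within
            np.fill_diagonal(r2[start:stop, start:stop], 1.0)
            start = stop
    return LDMatrix(tuple(ids), r2)


@dataclass(frozen=True)
class MVMRSimulation:
    """Planted truth and observed effects for a multi-exposure design."""

    variant_ids: tuple[str, ...]
    beta_exp_true: np.ndarray
    beta_exp_hat: np.ndarray
    se_exp: np.ndarray
    beta_out_hat: np.ndarray
    se_out: np.ndarray
    theta: np.ndarray
    exposure_names: tuple[str, ...]


def simulate_mvmr(
    theta: Sequence[float],
    n_variants: int = 60,
    n_exp: int = 300_000,
    n_out: int = 280_000,
    exposure_h2: float = 0.05,
    shared_frac: float = 0.3,
    maf_range: tuple[float, float] = (0.05, 0.5),
    case_fraction: float = DEFAULT_CASE_FRACTION,
    seed: int = 0,
) -> MVMRSimulation:
    """Simulate summary statistics for several (possibly correlated) exposures.

    ``theta[e]`` is exposure e's true *direct* effect on the outcome.
    ``shared_frac`` of each exposure's genetic variance comes from a factor
    common to all exposures, inducing the cross-exposure effect correlation
    that makes multivariable adjustment non-trivial (a mediation-like
    structure: a shared pathway loads on every exposure).
    """
    k = len(theta)
    theta = np.asarray(theta, dtype=float)
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=n_variants)
    het = 2.0 * maf * (1.0 - maf)

    shared = rng.normal(size=n_variants)
    own = rng.normal(size=(n_variants, k))
    raw = np.sqrt(shared_frac) * shared[:, None] + np.sqrt(1.0 - shared_frac) * own
    beta_true = np.empty_like(raw)
    for e in range(k):
        raw_var = float(np.sum(het * raw[:, e] ** 2))
        beta_true[:, e] = raw[:, e] * np.sqrt(exposure_h2 / raw_var)

    se_exp = (1.0 / np.sqrt(het * n_exp))[:, None] * np.ones((1, k))
    beta_exp_hat = rng.normal(beta_true, se_exp)

    v_bar = case_fraction * (1.0 - case_fraction)
    se_out = 1.0 / np.sqrt(het * n_out * v_bar)
    beta_out_hat = rng.normal(beta_true @ theta, se_out)

    ids = tuple(f"rs{j + 1}" for j in range(n_variants))
    names = tuple(f"exposure_{e + 1}" for e in range(k))
    return MVMRSimulation(ids, beta_true, beta_exp_hat, se_exp, beta_out_hat, se_out, theta, names)


# --- hand-checkable toy fixture -------------------------------------------

# 14 variants: 12 usable (one of which the outcome study coded on the
# swapped allele), one palindromic A/T at eaf 0.50 (dropped), one allele
# mismatch (dropped). Outcome betas were written down as slope * beta_exp
# plus a fixed perturbation of alternating sign, so the IVW slope sits near
# FIXTURE_SLOPE by construction.
FIXTURE_SLOPE = 0.5

_FIXTURE_ROWS = [
    # id, ea, oa, eaf, beta_exp, se_exp, out_ea, out_oa, beta_out_raw, se_out, perturb
    ("rs001", "A", "G", 0.30, 0.040, 0.0030, "A", "G", None, 0.012, +0.004),
    ("rs002", "T", "C", 0.15, -0.035, 0.0032, "T", "C", None, 0.013, -0.004),
    ("rs003", "G", "A", 0.45, 0.050, 0.0029, "G", "A", None, 0.011, +0.003),
    ("rs004", "C", "A", 0.22, 0.033, 0.0031, "C", "A", None, 0.012, -0.003),
    ("rs005", "A", "C", 0.38, -0.042, 0.0030, "A", "C", None, 0.012, +0.005),
    ("rs006", "T", "G", 0.27, 0.038, 0.0033, "T", "G", None, 0.013, -0.005),
    ("rs007", "A", "G", 0.41, 0.046, 0.0030, "G", "A", None, 0.012, +0.002),  # swapped coding
    ("rs008", "G", "A", 0.19, -0.036, 0.0034, "G", "A", None, 0.014, -0.002),
    ("rs009", "C", "A", 0.33, 0.044, 0.0029, "C", "A", None, 0.011, +0.006),
    ("rs010", "A", "C", 0.29, 0.037, 0.0032, "A", "C", None, 0.012, -0.006),
    ("rs011", "T", "C", 0.36, -0.048, 0.0031, "T", "C", None, 0.013, +0.001),
    ("rs012", "T", "G", 0.24, 0.041, 0.0030, "T", "G", None, 0.012, -0.001),
    ("rs013", "A", "T", 0.50, 0.039, 0.0030, "A", "T", None, 0.012, 0.0),  # palindromic
    ("rs014", "A", "G", 0.31, 0.043, 0.0030, "A", "C", None, 0.012, 0.0),  # mismatch
]

_FIXTURE_N_EXP = 300_000
_FIXTURE_N_OUT = 280_000


def fixture_small() -> tuple[list[VariantAssociation], list[VariantAssociation], LDMatrix, dict]:
    """A deterministic 14-variant toy pair used across the test suite.

    Twelve variants survive harmonization (one needing an allele flip); one
    palindromic variant at eaf 0.50 and one allele-mismatched variant are
    dropped. The truth dict records the slope used to write the outcome
    betas.
    """
    exposure, outcome = [], []
    for vid, ea, oa, eaf, bx, sx, oea, ooa, _raw, sy, eps in _FIXTURE_ROWS:
        p_exp = float(stats.chi2.sf((bx / sx) ** 2, 1))
        exposure.append(VariantAssociation(vid, ea, oa, bx, sx, p_exp, _FIXTURE_N_EXP, eaf=eaf))
        by = FIXTURE_SLOPE * bx + eps
        # express the outcome effect on the outcome study's own coding
        if (oea, ooa) == (oa, ea):
            by_coded, eaf_out = -by, 1.0 - eaf
        else:
            by_coded, eaf_out = by, eaf
        p_out = float(stats.chi2.sf((by_coded / sy) ** 2, 1))
        outcome.append(
            VariantAssociation(vid, oea, ooa, by_coded, sy, p_out, _FIXTURE_N_OUT, eaf=eaf_out)
        )
    ld = LDMatrix.identity([r[0] for r in _FIXTURE_ROWS])
    truth = {"slope": FIXTURE_SLOPE, "n_usable": 12, "palindromic": "rs013", "mismatch": "rs014"}
    return exposure, outcome, ld, truth
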