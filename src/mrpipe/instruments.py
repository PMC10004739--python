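"""Instrument selection and strength quantification.

Instruments for Mendelian randomization must be (i) strongly associated with
the exposure (genome-wide significance, p < 5e-8 by default), (ii) mutually
independent (LD clumping at r^2 < 0.01 within a 10,000 kb window by default)
and (iii) collectively strong enough to avoid weak-instrument bias, which is
what the F statistic measures: F > 10 is the conventional bar.

Per-variant strength is F = beta^2 / se^2. The variance in the exposure
explained by a single variant is

    R^2 = 2 eaf (1-eaf) beta^2 / (2 eaf (1-eaf) beta^2 + 2 eaf (1-eaf) n se^2)

and the overall F statistic for a set of k variants explaining R^2 of the
variance in a sample of size n is

    F = ((n - k - 1) / k) * (R^2 / (1 - R^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, DomainError
from .gwas_io import HarmonizedInstrument

#: Genome-wide significance, the default instrument-selection threshold.
GENOME_WIDE_P = 5e-8
#: Default LD-clumping parameters.
DEFAULT_CLUMP_R2 = 0.01
DEFAULT_CLUMP_WINDOW_KB = 10_000
#: Conventional weak-instrument bar.
WEAK_INSTRUMENT_F = 10.0


@dataclass(frozen=True)
class LDMatrix:
    """Squared correlations (r^2) among candidate instruments.

    Abstracts a reference-panel LD estimate: symmetric, unit diagonal,
    entries in [0, 1]. ``positions`` optionally maps variant ids to
    (chromosome, basepair) so clumping can treat pairs farther apart than its
    window — or on different chromosomes — as unlinked; without positions
    every within-matrix pair counts as in-window.
    """

    variant_ids: tuple[str, ...]
    r2: np.ndarray
    positions: Mapping[str, tuple[str, int]] | None = None
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if r2.shape != (k, k):
            raise ConfigurationError(f"LD matrix shape {r2.shape} != ({k}, {k})")
        if not np.allclose(r2, r2.T):
            raise ConfigurationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise ConfigurationError("LD matrix diagonal must be 1")
        if (r2 < -1e-12).any() or (r2 > 1 + 1e-12).any():
            raise ConfigurationError("LD r^2 entries must lie in [0, 1]")
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        object.__setattr__(self, "_index", {v: i for i, v in enumerate(self.variant_ids)})

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(tuple(variant_ids), np.eye(len(variant_ids)))

    def pair_r2(self, a: str, b: str, window_kb: int | None = None) -> float:
        """r^2 between two variants, 0 when outside the clumping window."""
        ia, ib = self._index[a], self._index[b]
        if window_kb is not None and self.positions is not None:
            pa = self.positions.get(a)
            pb = self.positions.get(b)
            if pa is not None and pb is not None:
                if pa[0] != pb[0] or abs(pa[1] - pb[1]) > window_kb * 1000:
                    return 0.0
        return float(self.r2[ia, ib])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index


@dataclass(frozen=True)
class InstrumentSet:
    """A selected, clumped instrument set with its strength summaries.

    ``r2_total`` sums the per-variant R^2 over members (justified by their
    post-clumping independence); ``f_overall`` applies the overall-F formula
    with k = number of members and n = exposure sample size.
    """

    instruments: tuple[HarmonizedInstrument, ...]
    r2_total: float
    f_overall: float
    f_per_snp: tuple[float, ...]

    @property
    def weak(self) -> bool:
        """True when the set fails the conventional F > 10 bar."""
        return self.f_overall <= WEAK_INSTRUMENT_F

    @classmethod
    def from_instruments(
        cls, instruments: Sequence[HarmonizedInstrument], n: int | None = None
    ) -> "InstrumentSet":
        insts = tuple(instruments)
        if n is None:
            n = max((i.n_exp for i in insts), default=0)
        f_per = tuple(per_snp_f(i.beta_exp, i.se_exp) for i in insts)
        r2_total = sum(
            per_snp_r2(i.eaf, i.beta_exp, i.se_exp, i.n_exp or n)
            for i in insts
            if i.eaf is not None
        )
        k = len(insts)
        f_overall = overall_f(n, k, r2_total) if (k and n > k + 1) else 0.0
        return cls(insts, r2_total, f_overall, f_per)


def significance_filter(records: Sequence, p_threshold: float = GENOME_WIDE_P) -> list:
    """Records with exposure p-value below the threshold, order preserved.

    Accepts either raw :class:`~mrpipe.gwas_io.VariantAssociation` records
    (``pval``) or harmonized instruments (``pval_exp``).
    """
    if not (0.0 < p_threshold < 1.0):
        raise DomainError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    return [r for r in records if _pval(r) < p_threshold]


def _pval(record) -> float:
    return record.pval_exp if hasattr(record, "pval_exp") else record.pval


def _variant_id(record) -> str:
    return record.variant_id


def ld_clump(
    records: Sequence,
    ld: LDMatrix,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
) -> list:
    """Greedy LD clumping by ascending p-value.

    Repeatedly promote the remaining record with the smallest exposure
    p-value (ties broken by lexicographic variant id, so the result does not
    depend on input order) and discard every remaining record with
    r^2 >= ``r2_threshold`` against it within ``window_kb``. All pairwise
    r^2 among the kept set are below the threshold.
    """
    missing = [_variant_id(r) for r in records if _variant_id(r) not in ld]
    if missing:
        raise ConfigurationError(
            f"variants absent from the LD matrix: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    remaining = sorted(records, key=lambda r: (_pval(r), _variant_id(r)))
    kept = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        lead_id = _variant_id(lead)
        remaining = [
            r
            for r in remaining
            if ld.pair_r2(lead_id, _variant_id(r), window_kb) < r2_threshold
        ]
    return kept


def per_snp_f(beta: float, se: float) -> float:
    """Single-variant instrument strength, F = beta^2 / se^2."""
    if not se > 0:
        raise DomainError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def per_snp_r2(eaf: float, beta: float, se: float, n: int) -> float:
    """Exposure variance explained by one variant.

    The 2 eaf (1-eaf) factor cancels between numerator and denominator, so
    the value reduces to beta^2 / (beta^2 + n se^2); it is kept in this form
    because the inputs are the quantities GWAS tables report.
    """
    if not (0.0 < eaf < 1.0):
        raise DomainError(f"eaf must lie in (0, 1), got {eaf}")
    if not se > 0:
        raise DomainError(f"se must be positive, got {se}")
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    het = 2.0 * eaf * (1.0 - eaf)
    num = het * beta * beta
    return num / (num + het * n * se * se)


def overall_f(n: int, k: int, r2: float) -> float:
    """Overall F statistic for k instruments explaining r2 of the variance."""
    if not (0.0 <= r2 < 1.0):
        raise DomainError(f"r2 must lie in [0, 1), got {r2}")
    if k < 1 or n <= k + 1:
        raise DomainError(f"need n > k + 1 >= 2, got n={n}, k={k}")
    return ((n - k - 1) / k) * (r2 / (1.0 - r2))


def select_instruments(
    records: Sequence,
    ld: LDMatrix,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
) -> list:
    """Significance filter followed by LD clumping (the standard QC chain)."""
    return ld_clump(significance_filter(records, p_threshold), ld, r2_threshold, window_kb)
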