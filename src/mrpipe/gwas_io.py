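"""Reading, validation and harmonization of GWAS summary statistics.

A two-sample Mendelian randomization analysis combines per-variant effect
estimates from an exposure GWAS and an outcome GWAS. Before any estimator can
run, the two tables must be restricted to shared variants and expressed on a
common effect allele: this module owns that plumbing.

Canonical column names are ``SNP, effect_allele, other_allele, eaf, beta, se,
pval, n``; ``read_summary_stats`` accepts a ``column_map`` to translate other
headers. Harmonization resolves allele swaps (the outcome study coded the
opposite allele: negate its beta, complement its frequency), strand flips
(A/G reported as T/C: complement before comparing) and palindromic A/T or C/G
variants, whose strand cannot be inferred from alleles alone and which are
dropped when the effect-allele frequency is too close to 0.5 to disambiguate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import HarmonizationError, SchemaError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("SNP", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")

#: Default half-width of the ambiguity window around eaf = 0.5 inside which a
#: palindromic variant is dropped (window (0.42, 0.58)).
DEFAULT_PALINDROMIC_EAF_WINDOW = 0.08


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait in one GWAS.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log-odds for binary traits, SD units for continuous traits), ``se`` its
    standard error, ``eaf`` the effect-allele frequency (``None`` when the
    study did not report it), ``n`` the study sample size.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None

    def is_valid(self) -> bool:
        """Check the record invariants without raising."""
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            return False
        if self.effect_allele == self.other_allele:
            return False
        if not (self.se > 0):
            return False
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            return False
        if not (0.0 < self.pval <= 1.0):
            return False
        return self.n > 0

    def flipped(self) -> "VariantAssociation":
        """The same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A variant's paired exposure/outcome effects on a common effect allele.

    ``action_taken`` records what harmonization did: ``kept`` (alleles already
    aligned), ``allele_flipped`` (outcome beta negated and frequency
    complemented), ``dropped_palindromic`` or ``dropped_mismatch``. Exposure
    p-value and sample size are carried along because downstream instrument
    selection (clumping order, F and R-squared arithmetic) needs them.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    action_taken: str
    eaf: float | None = None
    pval_exp: float = 1.0
    n_exp: int = 0

    @property
    def retained(self) -> bool:
        return self.action_taken in ("kept", "allele_flipped")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G pairs, whose strand is ambiguous."""
    return _COMPLEMENT.get(effect_allele) == other_allele


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return _COMPLEMENT[ea], _COMPLEMENT[oa]


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[VariantAssociation]:
    """Read a GWAS summary-statistics table into validated records.

    Parameters
    ----------
    path:
        TSV or CSV file with one row per variant.
    column_map:
        Mapping from canonical names (``SNP``, ``beta``, ...) to the file's
        actual header names; omitted entries default to the canonical name.
    sep:
        Field separator; ``None`` autodetects tab vs comma.

    Rows violating the record invariants (non-positive SE, frequency outside
    (0,1), identical alleles...) are dropped with a logged count. Duplicate
    variant ids keep the row with the smallest p-value.
    """
    try:
        frame = pd.read_csv(path, sep=sep, engine="python")
    except OSError as exc:
        raise SchemaError(f"cannot read summary statistics from {path!r}: {exc}") from exc

    column_map = dict(column_map or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in frame.columns:
            raise SchemaError(
                f"column {source!r} (for {canonical!r}) absent from {path!r}; "
                f"available: {list(frame.columns)}"
            )
        rename[source] = canonical
    frame = frame.rename(columns=rename)[list(CANONICAL_COLUMNS)]

    records: list[VariantAssociation] = []
    n_invalid = 0
    for row in frame.itertuples(index=False):
        eaf = None if pd.isna(row.eaf) else float(row.eaf)
        rec = VariantAssociation(
            variant_id=str(row.SNP),
            effect_allele=str(row.effect_allele).upper(),
            other_allele=str(row.other_allele).upper(),
            eaf=eaf,
            beta=float(row.beta),
            se=float(row.se),
            pval=float(row.pval),
            n=int(row.n),
        )
        if rec.is_valid():
            records.append(rec)
        else:
            n_invalid += 1
    if n_invalid:
        logger.info("dropped %d invalid rows while reading %s", n_invalid, path)
    return deduplicate(records)


def deduplicate(records: Iterable[VariantAssociation]) -> list[VariantAssociation]:
    """Keep one row per variant id: the smallest p-value wins."""
    best: dict[str, VariantAssociation] = {}
    order: list[str] = []
    n_dups = 0
    for rec in records:
        prev = best.get(rec.variant_id)
        if prev is None:
            best[rec.variant_id] = rec
            order.append(rec.variant_id)
        else:
            n_dups += 1
            if rec.pval < prev.pval:
                best[rec.variant_id] = rec
    if n_dups:
        logger.info("discarded %d duplicate variant rows (kept smallest p)", n_dups)
    return [best[v] for v in order]


def to_frame(records: Sequence[VariantAssociation]) -> pd.DataFrame:
    """Records as a DataFrame with canonical column names."""
    return pd.DataFrame(
        {
            "SNP": [r.variant_id for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pval": [r.pval for r in records],
            "n": [r.n for r in records],
        }
    )


def write_summary_stats(records: Sequence[VariantAssociation], path, sep: str = "\t") -> None:
    to_frame(records).to_csv(path, sep=sep, index=False)


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW,
) -> list[HarmonizedInstrument]:
    """Align outcome effects onto the exposure's effect allele.

    Returns one :class:`HarmonizedInstrument` per variant present in both
    tables, tagged with the action taken; callers normally proceed with the
    ``retained`` subset (see :func:`retained`). The rules, applied per
    variant:

    * alleles identical -> ``kept``;
    * alleles swapped -> outcome beta negated, outcome eaf complemented,
      ``allele_flipped``;
    * alleles matching only after strand complementation are complemented
      first, then the two rules above apply (non-palindromic pairs only —
      for palindromic pairs complementation is indistinguishable from a
      swap);
    * palindromic (A/T or C/G) variants: dropped when the exposure
      effect-allele frequency lies within ``palindromic_eaf_window`` of 0.5
      or is missing (strand unverifiable); otherwise the outcome frequency
      decides — same side of 0.5 as the exposure keeps the coding, opposite
      side flips it, missing outcome frequency keeps it;
    * anything else -> ``dropped_mismatch``.
    """
    if not exposure or not outcome:
        raise HarmonizationError("harmonize requires non-empty exposure and outcome tables")
    out_by_id = {r.variant_id: r for r in outcome}
    shared = [r for r in exposure if r.variant_id in out_by_id]
    if not shared:
        exp_ids = [r.variant_id for r in exposure[:3]]
        out_ids = [r.variant_id for r in outcome[:3]]
        raise HarmonizationError(
            f"no shared variants between exposure (e.g. {exp_ids}) and outcome (e.g. {out_ids})"
        )

    result: list[HarmonizedInstrument] = []
    counts = {"kept": 0, "allele_flipped": 0, "dropped_palindromic": 0, "dropped_mismatch": 0}
    for exp in shared:
        out = out_by_id[exp.variant_id]
        action, out_aligned = _align_one(exp, out, palindromic_eaf_window)
        counts[action] += 1
        result.append(
            HarmonizedInstrument(
                variant_id=exp.variant_id,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=out_aligned.beta,
                se_out=out_aligned.se,
                eaf=exp.eaf,
                action_taken=action,
                pval_exp=exp.pval,
                n_exp=exp.n,
            )
        )
    logger.info(
        "harmonized %d shared variants: %s",
        len(shared),
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return result


def _align_one(
    exp: VariantAssociation, out: VariantAssociation, window: float
) -> tuple[str, VariantAssociation]:
    """Classify one exposure/outcome pair and return the aligned outcome."""
    ea, oa = exp.effect_allele, exp.other_allele
    if is_palindromic(ea, oa):
        if not is_palindromic(out.effect_allele, out.other_allele) or {
            out.effect_allele,
            out.other_allele,
        } != {ea, oa}:
            return "dropped_mismatch", out
        if exp.eaf is None or abs(exp.eaf - 0.5) < window:
            return "dropped_palindromic", out
        out_oriented = out if out.effect_allele == ea else out.flipped()
        if out_oriented.eaf is None:
            return "kept" if out.effect_allele == ea else "allele_flipped", out_oriented
        # frequencies on opposite sides of 0.5 imply the outcome study coded
        # the complementary strand: flip back
        if (exp.eaf - 0.5) * (out_oriented.eaf - 0.5) < 0:
            out_oriented = out_oriented.flipped()
            return ("allele_flipped" if out.effect_allele == ea else "kept"), out_oriented
        return ("kept" if out.effect_allele == ea else "allele_flipped"), out_oriented

    pairs = {
        (out.effect_allele, out.other_allele): "as_is",
        (out.other_allele, out.effect_allele): "swap",
    }
    cea, coa = _complement_pair(out.effect_allele, out.other_allele)
    pairs.setdefault((cea, coa), "as_is")
    pairs.setdefault((coa, cea), "swap")
    match = pairs.get((ea, oa))
    if match == "as_is":
        return "kept", out
    if match == "swap":
        return "allele_flipped", out.flipped()
    return "dropped_mismatch", out


def retained(instruments: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """The harmonized records usable as instruments (kept or allele-flipped)."""
    return [inst for inst in instruments if inst.retained]


def action_counts(instruments: Iterable[HarmonizedInstrument]) -> dict[str, int]:
    counts = {"kept": 0, "allele_flipped": 0, "dropped_palindromic": 0, "dropped_mismatch": 0}
    for inst in instruments:
        counts[inst.action_taken] += 1
    return counts
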