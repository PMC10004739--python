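"""Config-driven orchestration of the full MR analysis.

``run_univariable`` reproduces the standard analysis flow for every
exposure-outcome pair: significance filter, LD clumping, harmonization,
then IVW (primary), MR-Egger, weighted median and MR-PRESSO, with
heterogeneity (Cochran's Q) and pleiotropy (Egger intercept) diagnostics on
every row. ``run_multivariable`` estimates direct effects conditional on
co-included exposures. Output is a plot-ready TSV: one row per exposure x
outcome x method, byte-stable across reruns at a fixed seed.

A failed pair never aborts the run — its row is marked ``failed`` with the
reason, and the remaining pairs proceed (a study of many habits against
several outcomes must survive individual failures).

Significance is declared at two-sided alpha (default 0.05) with no
multiple-testing correction; the ``significant`` column flags it and the
run manifest records that convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from . import gwas_io, instruments
from . import mvmr as mvmr_mod
from .presso import DEFAULT_N_SIM, DEFAULT_OUTLIER_ALPHA, presso as _run_presso
from .exceptions import MRPipeError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "exposure", "outcome", "method", "status", "n_snp",
    "beta", "se", "or", "ci_low", "ci_high", "pval", "significant",
    "q", "q_df", "q_pval", "egger_intercept", "egger_intercept_pval",
    "presso_global_pval", "presso_n_outliers", "presso_distortion_pval",
    "f_overall", "r2_total", "weak_instruments", "reason",
]

DEFAULT_ESTIMATORS = ("IVW", "Egger", "WeightedMedian", "PRESSO")


@dataclass
class TableSpec:
    """One GWAS table: a name, a file path and an optional header mapping."""

    name: str
    path: str
    column_map: Mapping[str, str] | None = None


@dataclass
class StudyConfig:
    """Everything a run needs; loadable from a YAML file via :func:`load_config`."""

    exposures: list[TableSpec]
    outcomes: list[TableSpec]
    ld_path: str | None = None
    p_threshold: float = instruments.GENOME_WIDE_P
    clump_r2: float = instruments.DEFAULT_CLUMP_R2
    clump_window_kb: int = instruments.DEFAULT_CLUMP_WINDOW_KB
    palindromic_window: float = gwas_io.DEFAULT_PALINDROMIC_EAF_WINDOW
    estimators: tuple[str, ...] = DEFAULT_ESTIMATORS
    presso_n_sim: int = DEFAULT_N_SIM
    presso_outlier_alpha: float = DEFAULT_OUTLIER_ALPHA
    n_boot: int = est.DEFAULT_N_BOOT
    mvmr_sets: list[dict] = dc_field(default_factory=list)
    alpha: float = 0.05
    seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> StudyConfig:
    """Read a StudyConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    exposures = [TableSpec(**e) for e in raw.pop("exposures", [])]
    outcomes = [TableSpec(**o) for o in raw.pop("outcomes", [])]
    if "estimators" in raw:
        raw["estimators"] = tuple(raw["estimators"])
    return StudyConfig(exposures=exposures, outcomes=outcomes, **raw)


def load_ld_matrix(path) -> instruments.LDMatrix:
    """Read an LD r^2 matrix from TSV (variant ids as header and index)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return instruments.LDMatrix(tuple(frame.columns), frame.to_numpy(dtype=float))


def write_ld_matrix(ld: instruments.LDMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=list(ld.variant_ids), columns=list(ld.variant_ids)).to_csv(
        path, sep="\t"
    )


def _select_and_harmonize(config: StudyConfig, exposure: TableSpec, outcome: TableSpec):
    """The shared QC chain: read, filter, clump, harmonize; returns instruments."""
    exp_records = gwas_io.read_summary_stats(exposure.path, exposure.column_map)
    out_records = gwas_io.read_summary_stats(outcome.path, outcome.column_map)
    selected = instruments.significance_filter(exp_records, config.p_threshold)
    if config.ld_path:
        ld = load_ld_matrix(config.ld_path)
    else:
        ld = instruments.LDMatrix.identity([r.variant_id for r in selected])
    clumped = instruments.ld_clump(selected, ld, config.clump_r2, config.clump_window_kb)
    harmonized = gwas_io.harmonize(clumped, out_records, config.palindromic_window)
    return gwas_io.retained(harmonized), gwas_io.action_counts(harmonized)


def _blank_row(exposure: str, outcome: str, method: str) -> dict:
    row = {c: "" for c in RESULT_COLUMNS}
    row.update(exposure=exposure, outcome=outcome, method=method, status="ok", reason="")
    return row


def _fill_estimate(row: dict, e: est.MREstimate, alpha: float) -> None:
    row.update(
        n_snp=e.n_snp, beta=e.beta, se=e.se, pval=e.pval,
        significant=int(e.pval < alpha),
        **{"or": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high},
    )


def run_univariable(config: StudyConfig) -> pd.DataFrame:
    """One result row per exposure x outcome x requested method."""
    rows: list[dict] = []
    for exposure in config.exposures:
        for outcome in config.outcomes:
            rows.extend(_run_pair(config, exposure, outcome))
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame = frame.sort_values(["exposure", "outcome", "method"], kind="stable").reset_index(
        drop=True
    )
    return frame


def _run_pair(config: StudyConfig, exposure: TableSpec, outcome: TableSpec) -> list[dict]:
    methods = list(config.estimators)
    try:
        insts, counts = _select_and_harmonize(config, exposure, outcome)
        iset = instruments.InstrumentSet.from_instruments(insts)
        logger.info(
            "%s vs %s: %d instruments (%s), overall F=%.2f",
            exposure.name, outcome.name, len(insts), counts, iset.f_overall,
        )
    except MRPipeError as exc:
        return [
            {**_blank_row(exposure.name, outcome.name, m), "status": "failed", "reason": str(exc)}
            for m in methods
        ]

    shared = {
        "f_overall": iset.f_overall,
        "r2_total": iset.r2_total,
        "weak_instruments": int(iset.weak),
    }
    rows = []
    for method in methods:
        row = _blank_row(exposure.name, outcome.name, method)
        row.update(shared)
        try:
            if method == "IVW":
                e, het = est.ivw(insts, random_effects=True)
                _fill_estimate(row, e, config.alpha)
                row.update(q=het.q, q_df=het.df, q_pval=het.pval)
            elif method == "Egger":
                e, pleio, het = est.egger(insts)
                _fill_estimate(row, e, config.alpha)
                row.update(
                    q=het.q, q_df=het.df, q_pval=het.pval,
                    egger_intercept=pleio.intercept, egger_intercept_pval=pleio.pval,
                )
            elif method == "WeightedMedian":
                e = est.weighted_median(insts, n_boot=config.n_boot, seed=config.seed)
                _fill_estimate(row, e, config.alpha)
            elif method == "PRESSO":
                res = _run_presso(
                    insts, n_sim=config.presso_n_sim,
                    outlier_alpha=config.presso_outlier_alpha, seed=config.seed,
                )
                _fill_estimate(row, res.corrected, config.alpha)
                row.update(
                    presso_global_pval=res.global_pval,
                    presso_n_outliers=len(res.outliers),
                    presso_distortion_pval="" if res.distortion_pval is None else res.distortion_pval,
                )
            else:
                raise MRPipeError(f"unknown estimator {method!r}")
        except MRPipeError as exc:
            row.update(status="failed", reason=str(exc))
        rows.append(row)
    return rows


def run_multivariable(config: StudyConfig) -> pd.DataFrame:
    """Direct-effect estimates for each configured adjustment set.

    Each entry of ``config.mvmr_sets`` is ``{"focal": name, "adjust_for":
    [names]}``. The instrument set is the union of each included exposure's
    selected instruments, re-clumped jointly (lead variant = smallest
    p-value across exposures); all effects are aligned to the outcome
    study's allele coding so the design matrix is coherent across
    exposures. The focal exposure's univariable IVW row is emitted
    alongside for comparison.
    """
    rows: list[dict] = []
    registry: list[str] = []
    for spec in config.mvmr_sets:
        focal = spec["focal"]
        adjust_for = list(spec.get("adjust_for", []))
        for outcome in config.outcomes:
            registry.append(f"{focal}|{'+'.join(adjust_for)}|{outcome.name}")
            rows.extend(_run_mvmr_set(config, focal, adjust_for, outcome))
    frame = pd.DataFrame(rows, columns=MVMR_COLUMNS)
    frame.attrs["registry"] = registry
    return frame


MVMR_COLUMNS = [
    "focal", "adjusted_for", "outcome", "exposure", "role", "method", "status",
    "n_snp", "beta", "se", "or", "ci_low", "ci_high", "pval", "significant", "reason",
]


def _exposure_spec(config: StudyConfig, name: str) -> TableSpec:
    for spec in config.exposures:
        if spec.name == name:
            return spec
    raise MRPipeError(f"exposure {name!r} not present in config.exposures")


def _run_mvmr_set(
    config: StudyConfig, focal: str, adjust_for: list[str], outcome: TableSpec
) -> list[dict]:
    names = [focal] + adjust_for
    base = {
        "focal": focal, "adjusted_for": "+".join(adjust_for), "outcome": outcome.name,
        "method": "MVMR-IVW", "status": "ok", "reason": "",
    }
    try:
        out_records = gwas_io.read_summary_stats(outcome.path, outcome.column_map)
        out_by_id = {r.variant_id: r for r in out_records}

        selections: list[list] = []
        aligned_exp: list[dict] = []  # per exposure: variant -> beta/se on outcome coding
        pmin: dict[str, float] = {}
        for name in names:
            spec = _exposure_spec(config, name)
            exp_records = gwas_io.read_summary_stats(spec.path, spec.column_map)
            selected = instruments.significance_filter(exp_records, config.p_threshold)
            if config.ld_path:
                ld = load_ld_matrix(config.ld_path)
            else:
                ld = instruments.LDMatrix.identity([r.variant_id for r in selected])
            clumped = instruments.ld_clump(selected, ld, config.clump_r2, config.clump_window_kb)
            selections.append(clumped)
            # align the full exposure table to the outcome study's coding by
            # harmonizing with the roles reversed
            rev = gwas_io.harmonize(out_records, exp_records, config.palindromic_window)
            aligned = {
                h.variant_id: gwas_io.VariantAssociation(
                    h.variant_id, h.effect_allele, h.other_allele,
                    h.beta_out, h.se_out, 1.0, 1, eaf=h.eaf,
                )
                for h in gwas_io.retained(rev)
            }
            aligned_exp.append(aligned)
            for r in exp_records:
                pmin[r.variant_id] = min(pmin.get(r.variant_id, 1.0), r.pval)

        union: list[str] = []
        seen: set[str] = set()
        for sel in selections:
            for rec in sel:
                if rec.variant_id not in seen:
                    seen.add(rec.variant_id)
                    union.append(rec.variant_id)
        union = [v for v in union if v in out_by_id and all(v in a for a in aligned_exp)]
        # joint re-clump over the union, ordered by the best p across exposures
        if config.ld_path:
            ld = load_ld_matrix(config.ld_path)
            proxy = [
                gwas_io.VariantAssociation(v, "A", "G", 0.0, 1.0, pmin[v], 1) for v in union
            ]
            union = [
                r.variant_id
                for r in instruments.ld_clump(
                    proxy, ld, config.clump_r2, config.clump_window_kb
                )
            ]

        data = mvmr_mod.MVMRDataset(
            tuple(union),
            np.array([[a[v].beta for a in aligned_exp] for v in union]),
            np.array([[a[v].se for a in aligned_exp] for v in union]),
            np.array([out_by_id[v].beta for v in union]),
            np.array([out_by_id[v].se for v in union]),
            tuple(names),
        )
        estimates = mvmr_mod.mvmr_ivw(data)
    except MRPipeError as exc:
        return [{**{c: "" for c in MVMR_COLUMNS}, **base, "status": "failed", "reason": str(exc)}]

    rows = []
    for name, e in zip(names, estimates):
        row = {c: "" for c in MVMR_COLUMNS}
        row.update(base)
        row.update(exposure=name, role="focal" if name == focal else "covariate")
        _fill_estimate(row, e, config.alpha)
        rows.append(row)

    # univariable IVW on the focal exposure for side-by-side comparison
    row = {c: "" for c in MVMR_COLUMNS}
    row.update(base, exposure=focal, role="focal", method="IVW-univariable")
    try:
        insts, _ = _select_and_harmonize(config, _exposure_spec(config, focal), outcome)
        e, _het = est.ivw(insts, random_effects=True)
        _fill_estimate(row, e, config.alpha)
    except MRPipeError as exc:
        row.update(status="failed", reason=str(exc))
    rows.append(row)
    return rows


def format_table(frame: pd.DataFrame) -> str:
    """Render a results table as a byte-stable TSV string.

    Floats are rendered with ``repr`` (shortest round-trip), so identical
    results serialize identically across runs and platforms.
    """
    def fmt(v) -> str:
        if isinstance(v, float):
            return repr(v)
        return str(v)

    lines = ["\t".join(frame.columns)]
    for _, row in frame.iterrows():
        lines.append("\t".join(fmt(v) for v in row))
    return "\n".join(lines) + "\n"


def write_results(frame: pd.DataFrame, path) -> None:
    Path(path).write_text(format_table(frame), encoding="utf-8")


def write_manifest(config: StudyConfig, frame: pd.DataFrame, path) -> None:
    """Record config hash, seed and per-stage counts for reproducibility."""
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "alpha": config.alpha,
        "multiple_testing_correction": "none (two-sided alpha per test)",
        "n_rows": int(len(frame)),
        "n_failed": int((frame["status"] == "failed").sum()) if "status" in frame else 0,
        "registry": frame.attrs.get("registry", []),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
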