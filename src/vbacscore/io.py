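"""Cohort CSV dialect, report writers, and simulation-config parsing.

The cohort file is plain CSV: UTF-8, comma-separated, dot decimal,
empty string for missing, booleans as ``true``/``false``; outcomes as
``SUCCESS``/``FAILED`` (``1``/``0`` accepted on input).  Reading is
strict: rows are validated against the admission criteria and all
failures are collected and reported with their file line numbers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (CategoricalSpec, CovariateParams, LogisticOutcomeParams,
                     SimulationConfig, TruncNormalSpec)
from .scoring import (AdmissionRecord, Outcome, RecordValidationError,
                      ScoreBoundaries, parse_indication)

__all__ = [
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "write_report",
    "simulation_config_from_dict",
    "boundaries_from_dict",
    "COHORT_COLUMNS",
]

#: Canonical column order of the cohort CSV.
COHORT_COLUMNS = [
    "patient_id", "age", "gestational_age", "indication", "bishop", "bmi",
    "efw_g", "sfh_cm", "engaged", "outcome", "parity", "spontaneous_labour",
    "interdelivery_interval_months", "prior_vbac", "prior_nvd",
]

_REQUIRED = ["patient_id", "age", "gestational_age", "indication", "bishop", "bmi"]
_FLOAT_COLS = ["age", "gestational_age", "bmi", "efw_g", "sfh_cm",
               "interdelivery_interval_months", "efw_resolved_g", "success_prob"]
_INT_COLS = ["bishop", "parity"]
_BOOL_COLS = ["engaged", "spontaneous_labour", "prior_vbac", "prior_nvd"]
_SCORE_COLS = ["age_pts", "ga_pts", "indication_pts", "bishop_pts", "bmi_pts",
               "efw_pts", "total", "bin", "efw_resolved_g", "success_prob"]
_KNOWN = set(COHORT_COLUMNS) | set(_SCORE_COLS) | {"repeat_indication"}


class SchemaError(ValueError):
    """The CSV header does not match the cohort schema."""


class CohortValidationError(ValueError):
    """One or more rows failed validation; carries (line, field, message) triples."""

    def __init__(self, failures: list[tuple[int, str, str]]):
        self.failures = failures
        preview = "; ".join(f"line {ln} [{f}]: {m}" for ln, f, m in failures[:5])
        more = f" (+{len(failures) - 5} more)" if len(failures) > 5 else ""
        super().__init__(f"{len(failures)} invalid row(s): {preview}{more}")


def _parse_bool(text: str, field: str, line: int):
    t = text.strip().lower()
    if t == "":
        return None
    if t in ("true", "1"):
        return True
    if t in ("false", "0"):
        return False
    raise RecordValidationError(field, f"line {line}: {text!r} is not a boolean")


def _parse_num(text: str, field: str, line: int, caster):
    t = text.strip()
    if t == "":
        return None
    try:
        return caster(t)
    except ValueError:
        raise RecordValidationError(
            field, f"line {line}: malformed numeric value {text!r}") from None


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV into a typed table.

    Header matching is order-insensitive; unknown columns raise a
    warning, missing required columns an error.  Every row is validated
    (inclusion criteria, ranges, EFW resolvability); failures are
    collected and raised together with line numbers.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    if "efw_g" not in raw.columns and not {"sfh_cm", "engaged"} <= set(raw.columns):
        raise SchemaError(
            "cohort needs an efw_g column or both sfh_cm and engaged columns")
    unknown = [c for c in raw.columns if c not in _KNOWN]
    if unknown:
        warnings.warn(f"ignoring unknown column(s) {unknown} in {path}", stacklevel=2)

    rows: list[dict] = []
    failures: list[tuple[int, str, str]] = []
    for i, raw_row in enumerate(raw.to_dict("records")):
        line = i + 2  # header is line 1
        get = lambda c: str(raw_row.get(c, "")).strip()
        try:
            row = {
                "patient_id": get("patient_id") or None,
                "age": _parse_num(get("age"), "age", line, float),
                "gestational_age": _parse_num(get("gestational_age"),
                                              "gestational_age", line, float),
                "indication": get("indication"),
                "bishop": _parse_num(get("bishop"), "bishop", line, int),
                "bmi": _parse_num(get("bmi"), "bmi", line, float),
                "efw_g": _parse_num(get("efw_g"), "efw_g", line, float),
                "sfh_cm": _parse_num(get("sfh_cm"), "sfh_cm", line, float),
                "engaged": _parse_bool(get("engaged"), "engaged", line),
                "outcome": get("outcome") or None,
                "parity": _parse_num(get("parity"), "parity", line, int),
                "spontaneous_labour": _parse_bool(get("spontaneous_labour"),
                                                  "spontaneous_labour", line),
                "interdelivery_interval_months": _parse_num(
                    get("interdelivery_interval_months"),
                    "interdelivery_interval_months", line, float),
                "prior_vbac": _parse_bool(get("prior_vbac"), "prior_vbac", line),
                "prior_nvd": _parse_bool(get("prior_nvd"), "prior_nvd", line),
            }
            if "repeat_indication" in raw.columns:
                row["repeat_indication"] = get("repeat_indication") or None
            required = {k: row[k] for k in
                        ("age", "gestational_age", "bishop", "bmi")}
            for fieldname, value in required.items():
                if value is None:
                    raise RecordValidationError(
                        fieldname, f"line {line}: missing required value")
            rec = AdmissionRecord(
                age=row["age"], gestational_age=row["gestational_age"],
                indication=row["indication"], bishop=row["bishop"],
                bmi=row["bmi"], efw_g=row["efw_g"], sfh_cm=row["sfh_cm"],
                engaged=row["engaged"], outcome=row["outcome"],
                parity=row["parity"],
                spontaneous_labour=row["spontaneous_labour"],
                interdelivery_interval_months=row["interdelivery_interval_months"],
                prior_vbac=row["prior_vbac"], prior_nvd=row["prior_nvd"],
                patient_id=row["patient_id"])
            row["indication"] = rec.indication.value
            row["outcome"] = rec.outcome.value if rec.outcome is not None else None
            rows.append(row)
        except RecordValidationError as exc:
            failures.append((line, exc.field_name, str(exc)))
    if failures:
        raise CohortValidationError(failures)

    cols = COHORT_COLUMNS + (["repeat_indication"]
                             if "repeat_indication" in raw.columns else [])
    df = pd.DataFrame(rows, columns=cols)
    return _apply_types(df)


def _apply_types(df: pd.DataFrame) -> pd.DataFrame:
    for c in _FLOAT_COLS:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)
    for c in _INT_COLS:
        if c in df.columns:
            df[c] = pd.array(df[c], dtype="Int64")
    for c in _BOOL_COLS:
        if c in df.columns:
            df[c] = pd.array(df[c], dtype="boolean")
    return df


def write_cohort(df: pd.DataFrame, path) -> Path:
    """Write a cohort table in the canonical CSV dialect (stable across runs)."""
    path = Path(path)
    out = df.copy()
    for c in _BOOL_COLS:
        if c in out.columns:
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else str(bool(v)).lower())
    ordered = [c for c in COHORT_COLUMNS if c in out.columns] + \
        [c for c in out.columns if c not in COHORT_COLUMNS]
    out[ordered].to_csv(path, index=False, na_rep="")
    return path


def write_report(report, json_path, tsv_path) -> tuple[Path, Path]:
    """Write a validation report as full-precision JSON plus TSV tables."""
    from .validation import report_tables_tsv

    json_path, tsv_path = Path(json_path), Path(tsv_path)
    # open both before writing either, so a bad path never leaves partial output
    with open(json_path, "w", encoding="utf-8") as jf, \
            open(tsv_path, "w", encoding="utf-8") as tf:
        jf.write(report.to_json())
        jf.write("\n")
        tf.write(report_tables_tsv(report))
    return json_path, tsv_path


# --- configuration parsing ---------------------------------------------------

_TN_FIELDS = ("mean", "sd", "lower", "upper")


def _truncnormal(d: dict, default: TruncNormalSpec) -> TruncNormalSpec:
    merged = {f: d.get(f, getattr(default, f)) for f in _TN_FIELDS}
    return TruncNormalSpec(**merged)


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain (YAML/JSON) mapping."""
    d = dict(d or {})
    defaults = CovariateParams()
    cov_d = d.pop("covariates", {}) or {}
    cov_kwargs = {}
    for name in ("age", "gestational_age", "bmi", "efw", "interdelivery_interval"):
        if name in cov_d:
            cov_kwargs[name] = _truncnormal(cov_d[name], getattr(defaults, name))
    for name in ("indication", "bishop", "parity"):
        if name in cov_d:
            spec = cov_d[name]
            default = getattr(defaults, name)
            cov_kwargs[name] = CategoricalSpec(
                tuple(spec.get("levels", default.levels)),
                tuple(spec.get("probs", default.probs)))
    for name in ("p_spontaneous", "p_prior_vbac", "p_prior_nvd"):
        if name in cov_d:
            cov_kwargs[name] = float(cov_d[name])
    covariates = CovariateParams(**cov_kwargs)

    logistic_d = d.pop("logistic_params", {}) or {}
    logistic = LogisticOutcomeParams(
        odds_ratios={str(k): float(v) for k, v in
                     logistic_d.get("odds_ratios",
                                    LogisticOutcomeParams().odds_ratios).items()},
        intercept=logistic_d.get("intercept"))

    boundaries = boundaries_from_dict(d.pop("boundaries", None))
    allowed = {"n", "seed", "outcome_model", "bin_probs", "target_rate"}
    extra = set(d) - allowed
    if extra:
        raise ValueError(f"unknown simulation config key(s): {sorted(extra)}")
    return SimulationConfig(covariates=covariates, logistic_params=logistic,
                            boundaries=boundaries, **d)


def boundaries_from_dict(d: Optional[dict]) -> ScoreBoundaries:
    if not d:
        return ScoreBoundaries()
    return ScoreBoundaries(**d)


def write_sidecar(config: SimulationConfig, path) -> Path:
    """JSON sidecar recording config, seed and provenance next to a cohort CSV."""
    from dataclasses import asdict

    from . import __version__
    path = Path(path)
    payload = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=str)),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")
    return path
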