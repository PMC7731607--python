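"""Cohort-level evaluation of the admission score.

Given a scored cohort with outcomes, this module reproduces the whole
published evaluation battery on that cohort:

* bin calibration — observed success fraction per score bin next to the
  predicted fraction from a univariate logistic of outcome on the total
  score (the score-only model, kept deliberately separate from the
  multivariate table);
* multivariate logistic regression of outcome on the six model
  covariates (adjusted odds ratios), and on the five auxiliary
  covariates when present;
* ROC curve and AUC of the total score with a stratified
  percentile-bootstrap CI;
* per-covariate group comparisons between successful and failed TOLAC
  (pooled t on continuous covariates, Pearson chi-square on
  categoricals);
* tabulation of repeat-cesarean indications within the failed group,
  when that column is present.

Reports are plain dataclasses, serialisable to JSON (full precision,
with provenance) and TSV tables; regeneration from the same cohort and
seeds is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cohort import SimulationConfig, generate_cohort
from .scoring import Outcome, ScoreBin
from .stats import (ChiSquareResult, LogisticFit, RocResult, SeparationError,
                    TwoSampleResult, auc_bootstrap_ci, chi_square,
                    fit_logistic, roc_auc, two_sample_t)

__all__ = [
    "BinCalibrationRow",
    "ValidationReport",
    "bin_calibration",
    "validate",
    "tabulate_failed_indications",
    "replicate",
    "MODEL_COVARIATES",
    "AUXILIARY_COVARIATES",
]

#: Covariates of the six-variable model as entered in the adjusted
#: regression: continuous ones on their natural scale, the 3-level
#: indication as its ordinal 0/1/2 point code.
MODEL_COVARIATES = ["age", "gestational_age", "indication_pts", "bishop",
                    "bmi", "efw_resolved_g"]

AUXILIARY_COVARIATES = ["spontaneous_labour", "parity",
                        "interdelivery_interval_months", "prior_vbac",
                        "prior_nvd"]

_CONTINUOUS_COMPARISONS = ["age", "gestational_age", "bishop", "bmi",
                           "efw_resolved_g", "total"]


@dataclass
class BinCalibrationRow:
    """One score bin: occupancy, observed and model-predicted success."""

    bin: str
    n_in_bin: int
    frequency_pct: Optional[float]
    observed_success_pct: Optional[float]
    predicted_success_pct: Optional[float]

    def to_dict(self) -> dict:
        return {
            "bin": self.bin,
            "n_in_bin": self.n_in_bin,
            "frequency_pct": self.frequency_pct,
            "observed_success_pct": self.observed_success_pct,
            "predicted_success_pct": self.predicted_success_pct,
        }


def _outcome01(df: pd.DataFrame) -> np.ndarray:
    y = df["outcome"].map({Outcome.SUCCESS.value: 1.0, Outcome.FAILED.value: 0.0,
                           Outcome.SUCCESS: 1.0, Outcome.FAILED: 0.0})
    if y.isna().any():
        raise ValueError("cohort contains rows without a usable outcome")
    return y.to_numpy(dtype=float)


def bin_calibration(cohort: pd.DataFrame) -> list[BinCalibrationRow]:
    """Observed vs predicted success per score bin.

    Predicted values are mean fitted probabilities, within bin, from the
    univariate logistic regression of outcome on the total score.  All
    four bins are always emitted; empty bins carry explicit nulls rather
    than being dropped, so report shape is stable.
    """
    y = _outcome01(cohort)
    total = cohort["total"].to_numpy(dtype=float)
    fitted = None
    try:
        fit = fit_logistic(total[:, None], y, names=["total"])
    except (ValueError, SeparationError):
        # single-class or separated cohort: observed columns still stand,
        # the score-only logistic (hence "predicted") is undefined
        pass
    else:
        from scipy.special import expit
        fitted = expit(fit.coefficients[0] + fit.coefficients[1] * total)

    n = len(cohort)
    rows = []
    bins = cohort["bin"].astype(str).to_numpy()
    for b in ScoreBin:
        mask = bins == b.value
        k = int(mask.sum())
        if k == 0:
            rows.append(BinCalibrationRow(b.value, 0, 0.0 if n else None, None, None))
            continue
        rows.append(BinCalibrationRow(
            bin=b.value,
            n_in_bin=k,
            frequency_pct=100.0 * k / n,
            observed_success_pct=100.0 * float(y[mask].mean()),
            predicted_success_pct=(None if fitted is None
                                   else 100.0 * float(fitted[mask].mean())),
        ))
    return rows


def tabulate_failed_indications(cohort: pd.DataFrame) -> Optional[dict]:
    """Counts and whole-percentages of repeat-cesarean indications among failures.

    Requires a ``repeat_indication`` column (free-text label of why the
    emergency repeat cesarean was done); returns ``None`` when absent.
    """
    if "repeat_indication" not in cohort.columns:
        return None
    y = _outcome01(cohort)
    failed = cohort.loc[y == 0, "repeat_indication"].dropna()
    n_failed = int((y == 0).sum())
    counts = failed.value_counts().sort_index()
    return {
        "n_failed": n_failed,
        "indications": {
            str(label): {"count": int(c),
                         "pct": int(round(100.0 * c / n_failed)) if n_failed else None}
            for label, c in counts.items()
        },
    }


@dataclass
class ValidationReport:
    """Everything the evaluation computes on one cohort snapshot."""

    n: int
    overall_success_pct: float
    bin_table: list[BinCalibrationRow]
    univariate_fit: LogisticFit
    multivariate_fit: Optional[LogisticFit]
    auxiliary_fit: Optional[LogisticFit]
    roc: RocResult
    group_comparison: dict
    failed_indication_tabulation: Optional[dict]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def enc(v):
            if v is None:
                return None
            return v.to_dict()

        return {
            "n": self.n,
            "overall_success_pct": self.overall_success_pct,
            "bin_table": [r.to_dict() for r in self.bin_table],
            "univariate_fit": self.univariate_fit.to_dict(),
            "multivariate_fit": enc(self.multivariate_fit),
            "auxiliary_fit": enc(self.auxiliary_fit),
            "roc": self.roc.to_dict(),
            "group_comparison": {k: v.to_dict() for k, v in self.group_comparison.items()},
            "failed_indication_tabulation": self.failed_indication_tabulation,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _group_comparisons(cohort: pd.DataFrame, y: np.ndarray) -> dict:
    out: dict = {}
    succ = y == 1
    for col in _CONTINUOUS_COMPARISONS:
        if col not in cohort.columns:
            continue
        a = cohort.loc[succ, col].to_numpy(dtype=float)
        b = cohort.loc[~succ, col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2 or a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
            continue
        out[col] = two_sample_t(a.mean(), a.std(ddof=1), len(a),
                                b.mean(), b.std(ddof=1), len(b))
    table = pd.crosstab(cohort["indication"], pd.Series(y, index=cohort.index))
    if table.shape[0] >= 2 and table.shape[1] == 2 and (table.sum(0) > 0).all():
        out["indication"] = chi_square(table.to_numpy())
    return out


def validate(cohort: pd.DataFrame, seed: Optional[int] = None,
             n_boot: int = 2000, alpha: float = 0.05,
             provenance: Optional[dict] = None) -> ValidationReport:
    """Run the full evaluation battery on a scored cohort with outcomes.

    ``seed`` drives the bootstrap (the only random sub-procedure), so a
    report is a deterministic function of (cohort, seed, n_boot, alpha).
    Sections whose columns are absent are reported as absent, never
    fabricated.
    """
    if "total" not in cohort.columns or "outcome" not in cohort.columns:
        raise ValueError("cohort must be scored (total/bin) and carry outcomes")
    y = _outcome01(cohort)
    if min(y.sum(), (1 - y).sum()) < 2:
        raise ValueError("need at least two patients in each outcome class")
    n = len(cohort)

    total = cohort["total"].to_numpy(dtype=float)
    uni = fit_logistic(total[:, None], y, names=["total"], alpha=alpha)

    multi = None
    if all(c in cohort.columns for c in MODEL_COVARIATES):
        X = cohort[MODEL_COVARIATES].to_numpy(dtype=float)
        multi = fit_logistic(X, y, names=MODEL_COVARIATES, alpha=alpha)

    aux = None
    aux_cols = [c for c in AUXILIARY_COVARIATES if c in cohort.columns]
    if len(aux_cols) == len(AUXILIARY_COVARIATES) and \
            not cohort[aux_cols].isna().any().any():
        Xa = cohort[aux_cols].astype(float).to_numpy()
        aux = fit_logistic(Xa, y, names=aux_cols, alpha=alpha)

    roc = roc_auc(total, y)
    roc.ci_low, roc.ci_high = auc_bootstrap_ci(total, y, n_boot=n_boot,
                                               alpha=alpha, seed=seed)

    report = ValidationReport(
        n=n,
        overall_success_pct=100.0 * float(y.mean()),
        bin_table=bin_calibration(cohort),
        univariate_fit=uni,
        multivariate_fit=multi,
        auxiliary_fit=aux,
        roc=roc,
        group_comparison=_group_comparisons(cohort, y),
        failed_indication_tabulation=tabulate_failed_indications(cohort),
        provenance={
            "package_version": _pkg_version,
            "bootstrap_seed": seed,
            "n_boot": n_boot,
            "alpha": alpha,
            **(provenance or {}),
        },
    )
    return report


def report_tables_tsv(report: ValidationReport) -> str:
    """Render the report's tables as a single TSV document."""
    lines: list[str] = []
    lines.append("# Bin calibration")
    lines.append("bin\tn\tfrequency_pct\tobserved_success_pct\tpredicted_success_pct")
    for r in report.bin_table:
        fmt = lambda v, nd: "NA" if v is None else f"{v:.{nd}f}"
        lines.append(f"{ScoreBin(r.bin).label}\t{r.n_in_bin}\t"
                     f"{fmt(r.frequency_pct, 2)}\t{fmt(r.observed_success_pct, 0)}\t"
                     f"{fmt(r.predicted_success_pct, 0)}")
    lines.append("")
    for title, fit in (("Univariate regression (total score)", report.univariate_fit),
                       ("Multivariate regression (model covariates)", report.multivariate_fit),
                       ("Multivariate regression (auxiliary covariates)", report.auxiliary_fit)):
        lines.append(f"# {title}")
        if fit is None:
            lines.append("absent")
            lines.append("")
            continue
        lines.append("term\todds_ratio\tci_low\tci_high\tp_value")
        ci = fit.or_conf_int
        for i, name in enumerate(fit.names):
            lines.append(f"{name}\t{fit.odds_ratios[i]:.3f}\t{ci[i, 0]:.3f}\t"
                         f"{ci[i, 1]:.3f}\t{fit.wald_p_values[i]:.4g}")
        lines.append("")
    lines.append("# Discrimination")
    lines.append("auc\tci_low\tci_high")
    lines.append(f"{report.roc.auc:.3f}\t{report.roc.ci_low:.3f}\t{report.roc.ci_high:.3f}")
    lines.append("")
    lines.append("# Group comparison (successful vs failed)")
    lines.append("covariate\tstatistic\tp_value\tdetail")
    for name, res in report.group_comparison.items():
        if isinstance(res, TwoSampleResult):
            lines.append(f"{name}\t{res.t_stat:.3f}\t{res.p_value:.4g}\t"
                         f"diff {res.mean_diff:.3f} [{res.ci_low:.3f}, {res.ci_high:.3f}]")
        elif isinstance(res, ChiSquareResult):
            lines.append(f"{name}\t{res.statistic:.3f}\t{res.p_value:.4g}\tdf {res.df}")
    if report.failed_indication_tabulation is not None:
        lines.append("")
        lines.append("# Repeat-cesarean indications in failed group")
        lines.append("indication\tcount\tpct")
        tab = report.failed_indication_tabulation
        for label, row in tab["indications"].items():
            lines.append(f"{label}\t{row['count']}\t{row['pct']}")
    lines.append("")
    return "\n".join(lines)


def replicate(config: SimulationConfig, seed: int, outdir,
              n_boot: int = 2000, alpha: float = 0.05) -> dict:
    """simulate -> score -> validate, writing the full report bundle.

    ``config.seed`` drives cohort generation and ``seed`` the bootstrap,
    so the bundle (cohort CSV, report JSON, report TSV, run metadata) is
    byte-identical across repeat runs with the same arguments.
    """
    from .io import write_cohort, write_report  # local import to avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    cohort_path = outdir / "cohort.csv"
    write_cohort(cohort, cohort_path)
    report = validate(cohort, seed=seed, n_boot=n_boot, alpha=alpha,
                      provenance={"generator_seed": config.seed,
                                  "config_hash": config.config_hash()})
    json_path, tsv_path = write_report(report, outdir / "report.json",
                                       outdir / "report.tsv")
    return {"cohort": cohort_path, "report_json": json_path, "report_tsv": tsv_path}
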