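"""Admission VBAC score: six 0/1/2-point variables totalling 0-12.

The score is computed at the time of admission for a trial of labour after
cesarean (TOLAC) from six covariates: maternal age, gestational age,
indication for the primary cesarean, Bishop score, BMI, and clinically
estimated fetal weight (EFW, measured directly in grams or derived from
symphysis-fundal height via Johnson's formula).  Higher totals indicate a
more favourable profile for successful vaginal birth.  Totals are grouped
into four reporting bins (0-3, 4-6, 7-9, >=10).

The printed category tables leave a few boundaries ambiguous (age exactly
25 or 30, BMI in [29, 30), gestational age "39-40" in completed weeks).
This module resolves them with documented half-open conventions, all
exposed through :class:`ScoreBoundaries` so alternative readings can be
evaluated without touching scoring logic.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "Indication",
    "Outcome",
    "ScoreBin",
    "ScoreBoundaries",
    "JohnsonParams",
    "AdmissionRecord",
    "ScoreBreakdown",
    "RecordValidationError",
    "parse_indication",
    "score_age",
    "score_gestational_age",
    "score_indication",
    "score_bishop",
    "score_bmi",
    "score_efw",
    "johnson_efw",
    "resolve_efw",
    "vbac_score",
    "score_bin",
    "score_cohort",
    "troyer_parisi_score",
    "DEFAULT_BOUNDARIES",
    "DEFAULT_JOHNSON",
]


class RecordValidationError(ValueError):
    """A covariate failed admission-record validation.

    Carries the offending field name so batch readers can report
    per-row, per-field failures.
    """

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class Indication(str, enum.Enum):
    """Indication category for the primary cesarean section.

    Grouped by reported association with TOLAC success: non-progress of
    labour (NPOL) and unclassified indications carry 0 points; growth
    restriction, oligohydramnios and antepartum haemorrhage 1 point;
    breech presentation and fetal distress (non-recurrent, favourable)
    2 points.
    """

    NPOL_OR_OTHER = "NPOL_OR_OTHER"
    IUGR_OLIGO_APH = "IUGR_OLIGO_APH"
    BREECH_OR_FETAL_DISTRESS = "BREECH_OR_FETAL_DISTRESS"


class Outcome(str, enum.Enum):
    SUCCESS = "SUCCESS"  # vaginal delivery
    FAILED = "FAILED"    # emergency repeat cesarean


class ScoreBin(str, enum.Enum):
    B0_3 = "B0_3"
    B4_6 = "B4_6"
    B7_9 = "B7_9"
    B10_PLUS = "B10_PLUS"

    @property
    def label(self) -> str:
        return {"B0_3": "0-3", "B4_6": "4-6", "B7_9": "7-9", "B10_PLUS": ">=10"}[self.value]


#: Explicit alias table mapping free-text primary-cesarean indications onto
#: the three scored categories.  Anything not listed here is rejected rather
#: than silently bucketed into the zero-point group.
INDICATION_ALIASES: dict[str, Indication] = {
    "npol": Indication.NPOL_OR_OTHER,
    "non-progress of labour": Indication.NPOL_OR_OTHER,
    "non-progress of labor": Indication.NPOL_OR_OTHER,
    "nonprogress of labour": Indication.NPOL_OR_OTHER,
    "failure to progress": Indication.NPOL_OR_OTHER,
    "dysfunctional labour": Indication.NPOL_OR_OTHER,
    "dysfunctional labor": Indication.NPOL_OR_OTHER,
    "failed induction": Indication.NPOL_OR_OTHER,
    "cephalopelvic disproportion": Indication.NPOL_OR_OTHER,
    "other": Indication.NPOL_OR_OTHER,
    "iugr": Indication.IUGR_OLIGO_APH,
    "intrauterine growth restriction": Indication.IUGR_OLIGO_APH,
    "oligohydramnios": Indication.IUGR_OLIGO_APH,
    "aph": Indication.IUGR_OLIGO_APH,
    "antepartum haemorrhage": Indication.IUGR_OLIGO_APH,
    "antepartum hemorrhage": Indication.IUGR_OLIGO_APH,
    "breech": Indication.BREECH_OR_FETAL_DISTRESS,
    "breech presentation": Indication.BREECH_OR_FETAL_DISTRESS,
    "fetal distress": Indication.BREECH_OR_FETAL_DISTRESS,
    "foetal distress": Indication.BREECH_OR_FETAL_DISTRESS,
    "non-reassuring fetal heart rate": Indication.BREECH_OR_FETAL_DISTRESS,
}


def parse_indication(value: Union[str, Indication]) -> Indication:
    """Map an indication label onto one of the three scored categories.

    Accepts enum members, enum value strings, or any free-text alias in
    :data:`INDICATION_ALIASES` (case-insensitive).  Unknown text raises,
    listing the three categories — there is no silent fallback to the
    zero-point group.
    """
    if isinstance(value, Indication):
        return value
    text = str(value).strip()
    try:
        return Indication(text.upper())
    except ValueError:
        pass
    alias = INDICATION_ALIASES.get(text.lower())
    if alias is not None:
        return alias
    raise RecordValidationError(
        "indication",
        f"unrecognised indication {value!r}; expected one of "
        f"{[m.value for m in Indication]} or a known alias",
    )


@dataclass(frozen=True)
class ScoreBoundaries:
    """Category boundaries for the six scored variables.

    The conventions close the gaps/overlaps the printed category lists
    leave open: age uses [18, 25) -> 2, [25, 30] -> 1, (30, 35] -> 0;
    gestational age <39 -> 0, [39, 41) -> 1 (completed weeks 39-40),
    >=41 -> 2; BMI <25 -> 2, [25, 30) -> 1, >=30 -> 0.
    """

    age_young: float = 25.0   # 2 points strictly below; 1 point from here to age_mid inclusive
    age_mid: float = 30.0     # 0 points strictly above
    ga_term: float = 39.0     # 0 points strictly below
    ga_post: float = 41.0     # 2 points at or above (completed week >40)
    bishop_mid: int = 4       # 1 point from here (0-3 scores 0)
    bishop_high: int = 6      # 2 points from here
    bmi_lean: float = 25.0    # 2 points strictly below
    bmi_obese: float = 30.0   # 0 points at or above
    efw_small: float = 2500.0  # 2 points strictly below
    efw_large: float = 3500.0  # 0 points strictly above; [2500, 3500] scores 1


DEFAULT_BOUNDARIES = ScoreBoundaries()

#: Inclusion-criteria limits enforced at validation time.
AGE_MIN, AGE_MAX = 18.0, 35.0
GA_MIN = 37.0
SFH_MIN, SFH_MAX = 20.0, 50.0


@dataclass(frozen=True)
class JohnsonParams:
    """Constants of Johnson's formula for clinical fetal-weight estimation.

    EFW in grams = (symphysis-fundal height in cm − station offset) × 155,
    with offset 11 when the head is engaged and 12 when unengaged.  The
    constants come from standard obstetric references and are configurable.
    """

    station_offset_engaged: int = 11
    station_offset_unengaged: int = 12
    gram_factor: float = 155.0

    def __post_init__(self):
        if not (self.station_offset_engaged > 0 and self.station_offset_unengaged > 0
                and self.gram_factor > 0):
            raise ValueError("JohnsonParams constants must all be positive")


DEFAULT_JOHNSON = JohnsonParams()


@dataclass
class AdmissionRecord:
    """One patient's admission covariates and (optionally) TOLAC outcome.

    Validation enforces the study's inclusion criteria: singleton term
    pregnancy with maternal age 18-35 years and gestational age >=37
    completed weeks; Bishop score an integer 0-10.  EFW must be resolvable
    either directly (``efw_g``) or through Johnson's formula
    (``sfh_cm`` + ``engaged``).
    """

    age: float
    gestational_age: float
    indication: Union[Indication, str]
    bishop: int
    bmi: float
    efw_g: Optional[float] = None
    sfh_cm: Optional[float] = None
    engaged: Optional[bool] = None
    outcome: Optional[Union[Outcome, str]] = None
    parity: Optional[int] = None
    spontaneous_labour: Optional[bool] = None
    interdelivery_interval_months: Optional[float] = None
    prior_vbac: Optional[bool] = None
    prior_nvd: Optional[bool] = None
    patient_id: Optional[str] = None

    def __post_init__(self):
        self.indication = parse_indication(self.indication)
        if self.outcome is not None and not isinstance(self.outcome, Outcome):
            self.outcome = _parse_outcome(self.outcome)
        self.validate()

    def validate(self) -> None:
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise RecordValidationError(
                "age",
                f"{self.age} outside inclusion criterion maternal age "
                f"{AGE_MIN:g}-{AGE_MAX:g} years",
            )
        if self.gestational_age < GA_MIN:
            raise RecordValidationError(
                "gestational_age",
                f"{self.gestational_age} below inclusion criterion "
                f">={GA_MIN:g} completed weeks",
            )
        if not float(self.bishop).is_integer() or not (0 <= self.bishop <= 10):
            raise RecordValidationError(
                "bishop", f"{self.bishop} must be an integer in [0, 10]")
        self.bishop = int(self.bishop)
        if not self.bmi > 0:
            raise RecordValidationError("bmi", f"{self.bmi} must be positive")
        if self.efw_g is None and (self.sfh_cm is None or self.engaged is None):
            raise RecordValidationError(
                "efw_g",
                "estimated fetal weight unresolvable: provide efw_g or both "
                "sfh_cm and engaged",
            )
        if self.efw_g is not None and not self.efw_g > 0:
            raise RecordValidationError("efw_g", f"{self.efw_g} must be positive")
        if self.sfh_cm is not None and not (SFH_MIN <= self.sfh_cm <= SFH_MAX):
            raise RecordValidationError(
                "sfh_cm", f"{self.sfh_cm} outside plausible range "
                f"[{SFH_MIN:g}, {SFH_MAX:g}] cm")
        if self.parity is not None and self.parity < 1:
            raise RecordValidationError("parity", "parity must be >= 1")


def _parse_outcome(value) -> Outcome:
    if isinstance(value, Outcome):
        return value
    text = str(value).strip().upper()
    if text in ("SUCCESS", "1", "1.0", "TRUE"):
        return Outcome.SUCCESS
    if text in ("FAILED", "FAILURE", "0", "0.0", "FALSE"):
        return Outcome.FAILED
    raise RecordValidationError("outcome", f"unrecognised outcome {value!r}")


@dataclass(frozen=True)
class ScoreBreakdown:
    """The six component points, their 0-12 total, and the reporting bin."""

    age_pts: int
    ga_pts: int
    indication_pts: int
    bishop_pts: int
    bmi_pts: int
    efw_pts: int
    total: int = field(init=False)
    bin: ScoreBin = field(init=False)

    def __post_init__(self):
        components = (self.age_pts, self.ga_pts, self.indication_pts,
                      self.bishop_pts, self.bmi_pts, self.efw_pts)
        if any(c not in (0, 1, 2) for c in components):
            raise ValueError(f"component points must each be 0, 1 or 2; got {components}")
        object.__setattr__(self, "total", sum(components))
        object.__setattr__(self, "bin", score_bin(self.total))


# --- component scorers -------------------------------------------------------

def score_age(age: float, boundaries: ScoreBoundaries = DEFAULT_BOUNDARIES) -> int:
    """Points for maternal age: young favours success (18-25 -> 2, >30 -> 0)."""
    if not (AGE_MIN <= age <= AGE_MAX):
        raise RecordValidationError(
            "age", f"{age} outside inclusion criterion maternal age "
            f"{AGE_MIN:g}-{AGE_MAX:g} years")
    if age < boundaries.age_young:
        return 2
    if age <= boundaries.age_mid:
        return 1
    return 0


def score_gestational_age(ga: float, boundaries: ScoreBoundaries = DEFAULT_BOUNDARIES) -> int:
    """Points for gestational age in completed weeks (<39 -> 0, 39-40 -> 1, >40 -> 2)."""
    if ga < GA_MIN:
        raise RecordValidationError(
            "gestational_age", f"{ga} below inclusion criterion >={GA_MIN:g} weeks")
    if ga < boundaries.ga_term:
        return 0
    if ga < boundaries.ga_post:
        return 1
    return 2


def score_indication(ind: Union[Indication, str]) -> int:
    """Points for the primary-cesarean indication category."""
    ind = parse_indication(ind)
    return {
        Indication.NPOL_OR_OTHER: 0,
        Indication.IUGR_OLIGO_APH: 1,
        Indication.BREECH_OR_FETAL_DISTRESS: 2,
    }[ind]


def score_bishop(bishop: int, boundaries: ScoreBoundaries = DEFAULT_BOUNDARIES) -> int:
    """Points for the admission Bishop score (0-3 -> 0, 4-5 -> 1, 6-10 -> 2)."""
    if not float(bishop).is_integer() or not (0 <= bishop <= 10):
        raise RecordValidationError("bishop", f"{bishop} must be an integer in [0, 10]")
    bishop = int(bishop)
    if bishop < boundaries.bishop_mid:
        return 0
    if bishop < boundaries.bishop_high:
        return 1
    return 2


def score_bmi(bmi: float, boundaries: ScoreBoundaries = DEFAULT_BOUNDARIES) -> int:
    """Points for admission BMI in kg/m2 (<25 -> 2, 25-29 -> 1, >=30 -> 0)."""
    if not bmi > 0:
        raise RecordValidationError("bmi", f"{bmi} must be positive")
    if bmi < boundaries.bmi_lean:
        return 2
    if bmi < boundaries.bmi_obese:
        return 1
    return 0


def score_efw(efw: float, boundaries: ScoreBoundaries = DEFAULT_BOUNDARIES) -> int:
    """Points for estimated fetal weight in grams (<2500 -> 2, 2500-3500 -> 1, >3500 -> 0)."""
    if not efw > 0:
        raise RecordValidationError("efw_g", f"{efw} must be positive")
    if efw < boundaries.efw_small:
        return 2
    if efw <= boundaries.efw_large:
        return 1
    return 0


def johnson_efw(sfh_cm: float, engaged: bool,
                params: JohnsonParams = DEFAULT_JOHNSON) -> float:
    """Clinical fetal-weight estimate from symphysis-fundal height.

    Johnson's formula: EFW = (SFH − n) × 155 g with n = 11 when the fetal
    head is engaged and n = 12 when it is not.
    """
    if not (SFH_MIN <= sfh_cm <= SFH_MAX):
        raise RecordValidationError(
            "sfh_cm", f"{sfh_cm} outside plausible range [{SFH_MIN:g}, {SFH_MAX:g}] cm")
    offset = params.station_offset_engaged if engaged else params.station_offset_unengaged
    efw = (sfh_cm - offset) * params.gram_factor
    if efw <= 0:
        raise RecordValidationError(
            "sfh_cm", f"Johnson estimate nonpositive ({efw:g} g) for SFH {sfh_cm} cm")
    return efw


def resolve_efw(record: AdmissionRecord,
                params: JohnsonParams = DEFAULT_JOHNSON) -> float:
    """Resolve a record's EFW: direct grams take precedence over Johnson's formula.

    When both are supplied and disagree by more than 10% a warning is
    emitted and the direct measurement is used.
    """
    if record.efw_g is not None:
        if record.sfh_cm is not None and record.engaged is not None:
            derived = johnson_efw(record.sfh_cm, record.engaged, params)
            if abs(derived - record.efw_g) > 0.10 * record.efw_g:
                warnings.warn(
                    f"efw_g={record.efw_g:g} g and Johnson estimate "
                    f"{derived:g} g disagree by >10%; using efw_g",
                    stacklevel=2)
        return record.efw_g
    return johnson_efw(record.sfh_cm, record.engaged, params)


def score_bin(total: int) -> ScoreBin:
    """Reporting bin of a 0-12 total: 0-3, 4-6, 7-9, >=10."""
    if not float(total).is_integer() or not (0 <= total <= 12):
        raise ValueError(f"total {total} outside [0, 12]")
    total = int(total)
    if total <= 3:
        return ScoreBin.B0_3
    if total <= 6:
        return ScoreBin.B4_6
    if total <= 9:
        return ScoreBin.B7_9
    return ScoreBin.B10_PLUS


def vbac_score(record: AdmissionRecord,
               boundaries: ScoreBoundaries = DEFAULT_BOUNDARIES,
               johnson: JohnsonParams = DEFAULT_JOHNSON) -> ScoreBreakdown:
    """Score one admission record: six components, total 0-12, and bin."""
    record.validate()
    return ScoreBreakdown(
        age_pts=score_age(record.age, boundaries),
        ga_pts=score_gestational_age(record.gestational_age, boundaries),
        indication_pts=score_indication(record.indication),
        bishop_pts=score_bishop(record.bishop, boundaries),
        bmi_pts=score_bmi(record.bmi, boundaries),
        efw_pts=score_efw(resolve_efw(record, johnson), boundaries),
    )


def troyer_parisi_score(dysfunctional_labour: bool, nonreassuring_fhr: bool,
                        no_prior_vaginal: bool, induced: bool) -> int:
    """Four-variable comparator score (one point per risk factor, 0-4).

    Unlike the admission score, higher values here indicate a *less*
    favourable profile: patients scoring 0 had the highest reported
    success rates.
    """
    return int(bool(dysfunctional_labour)) + int(bool(nonreassuring_fhr)) + \
        int(bool(no_prior_vaginal)) + int(bool(induced))


# --- vectorised cohort scoring ----------------------------------------------

_POINT_COLUMNS = ["age_pts", "ga_pts", "indication_pts", "bishop_pts",
                  "bmi_pts", "efw_pts"]

_INDICATION_POINTS = {
    Indication.NPOL_OR_OTHER.value: 0,
    Indication.IUGR_OLIGO_APH.value: 1,
    Indication.BREECH_OR_FETAL_DISTRESS.value: 2,
}

_BIN_LABELS = np.array([ScoreBin.B0_3.value, ScoreBin.B4_6.value,
                        ScoreBin.B7_9.value, ScoreBin.B10_PLUS.value])


def score_cohort(df: pd.DataFrame,
                 boundaries: ScoreBoundaries = DEFAULT_BOUNDARIES,
                 johnson: JohnsonParams = DEFAULT_JOHNSON) -> pd.DataFrame:
    """Score every row of a cohort table, appending point columns, total and bin.

    Vectorised equivalent of :func:`vbac_score` applied row-wise (the two
    paths are cross-checked in the test suite).  Expects validated input;
    range violations raise naming the field and offending row labels.
    """
    df = df.copy()
    b = boundaries

    age = df["age"].to_numpy(dtype=float)
    _check_range(df.index, "age", (age >= AGE_MIN) & (age <= AGE_MAX))
    ga = df["gestational_age"].to_numpy(dtype=float)
    _check_range(df.index, "gestational_age", ga >= GA_MIN)
    bishop = df["bishop"].to_numpy(dtype=float)
    _check_range(df.index, "bishop", (bishop >= 0) & (bishop <= 10) & (bishop == np.floor(bishop)))
    bmi = df["bmi"].to_numpy(dtype=float)
    _check_range(df.index, "bmi", bmi > 0)

    efw = df["efw_g"].to_numpy(dtype=float) if "efw_g" in df else np.full(len(df), np.nan)
    need = np.isnan(efw)
    if need.any():
        if "sfh_cm" not in df or "engaged" not in df:
            _check_range(df.index, "efw_g", ~need)
        sfh = df["sfh_cm"].to_numpy(dtype=float)
        engaged = df["engaged"].fillna(False).to_numpy(dtype=bool)
        resolvable = need & ~np.isnan(sfh)
        _check_range(df.index, "efw_g", ~need | resolvable)
        _check_range(df.index, "sfh_cm", ~resolvable | ((sfh >= SFH_MIN) & (sfh <= SFH_MAX)))
        offset = np.where(engaged, johnson.station_offset_engaged,
                          johnson.station_offset_unengaged)
        efw = np.where(resolvable, (sfh - offset) * johnson.gram_factor, efw)
    _check_range(df.index, "efw_g", efw > 0)
    df["efw_resolved_g"] = efw

    df["age_pts"] = np.where(age < b.age_young, 2, np.where(age <= b.age_mid, 1, 0))
    df["ga_pts"] = np.where(ga < b.ga_term, 0, np.where(ga < b.ga_post, 1, 2))
    df["indication_pts"] = df["indication"].map(
        lambda v: _INDICATION_POINTS[parse_indication(v).value]).astype(int)
    df["bishop_pts"] = np.where(bishop < b.bishop_mid, 0,
                                np.where(bishop < b.bishop_high, 1, 2))
    df["bmi_pts"] = np.where(bmi < b.bmi_lean, 2, np.where(bmi < b.bmi_obese, 1, 0))
    df["efw_pts"] = np.where(efw < b.efw_small, 2, np.where(efw <= b.efw_large, 1, 0))
    df["total"] = df[_POINT_COLUMNS].sum(axis=1)
    df["bin"] = _BIN_LABELS[np.digitize(df["total"].to_numpy(), [4, 7, 10])]
    return df


def _check_range(index, field_name: str, ok: np.ndarray) -> None:
    if not np.all(ok):
        bad = list(index[~ok][:10])
        raise RecordValidationError(
            field_name, f"invalid values at rows {bad}"
            + ("..." if (~ok).sum() > 10 else ""))
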