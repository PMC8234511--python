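"""Predictor and outcome derivation from raw longitudinal data.

Covers KDIGO-based AKI detection and staging from serial serum creatinine
(two published algorithm variants), CKD-EPI (2009) eGFR estimation, and
ascertainment of the two study outcomes: 90-day death-or-readmission and
1-year progression to CKD G4-G5.

Conventions (configurable where noted):

- Creatinine is in mg/dL, eGFR in mL/min/1.73 m2.
- Outcome windows are half-open at the start and closed at the end,
  ``(t0, t0 + horizon]``; "3 months" is operationalized as >= 90 days.
- Staging multipliers follow the KDIGO convention: stage 1 when a criterion
  fires, stage 2 at >= 2.0x the criterion's reference creatinine, stage 3 at
  >= 3.0x the reference or an absolute creatinine >= 4.0 mg/dL.
  Urine-output and dialysis-based staging are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INPATIENT",
    "OUTPATIENT",
    "CreatinineSeries",
    "AkiResult",
    "StagingRules",
    "detect_aki_grampian",
    "detect_aki_alberta",
    "ckd_epi_egfr",
    "ascertain_ckd_g45",
    "ascertain_death_or_readmission",
    "series_from_frame",
]

INPATIENT = "inpatient"
OUTPATIENT = "outpatient"

#: AKI criterion identifiers, in the order they are evaluated.
CRITERIA = ("delta48h", "ratio7d", "ratio8_90d", "ratio91_365d", "alberta_baseline", "none")


@dataclass
class CreatinineSeries:
    """Serial creatinine for one subject around a hospital admission.

    ``observations`` is an ordered list of ``(timestamp, scr, setting)``
    with setting either ``inpatient`` or ``outpatient``.
    """

    subject_id: str
    observations: list[tuple[pd.Timestamp, float, str]]
    admission_date: pd.Timestamp
    discharge_date: pd.Timestamp

    def __post_init__(self) -> None:
        self.admission_date = pd.Timestamp(self.admission_date)
        self.discharge_date = pd.Timestamp(self.discharge_date)
        if self.discharge_date < self.admission_date:
            raise ValueError(f"subject {self.subject_id}: discharge before admission")
        obs = [(pd.Timestamp(t), float(v), s) for t, v, s in self.observations]
        times = [t for t, _, _ in obs]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"subject {self.subject_id}: observations not time-sorted")
        if any(v <= 0 for _, v, _ in obs):
            raise ValueError(f"subject {self.subject_id}: nonpositive creatinine")
        if any(s not in (INPATIENT, OUTPATIENT) for _, _, s in obs):
            raise ValueError(f"subject {self.subject_id}: unknown setting flag")
        self.observations = obs

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.observations], dtype="datetime64[ns]")

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v, _ in self.observations], dtype=float)

    @property
    def settings(self) -> np.ndarray:
        return np.array([s for _, _, s in self.observations])


def series_from_frame(
    samples: pd.DataFrame, admissions: pd.DataFrame
) -> list[CreatinineSeries]:
    """Build :class:`CreatinineSeries` from delimited tables.

    ``samples`` has columns ``subject_id, timestamp, scr_mg_dl, setting``;
    ``admissions`` has columns ``subject_id, admission_date, discharge_date``.
    """
    adm = admissions.set_index("subject_id")
    out = []
    for sid, grp in samples.groupby("subject_id", sort=True):
        grp = grp.sort_values("timestamp")
        obs = [
            (pd.Timestamp(t), float(v), str(s))
            for t, v, s in zip(grp["timestamp"], grp["scr_mg_dl"], grp["setting"])
        ]
        row = adm.loc[sid]
        out.append(
            CreatinineSeries(
                subject_id=str(sid),
                observations=obs,
                admission_date=pd.Timestamp(row["admission_date"]),
                discharge_date=pd.Timestamp(row["discharge_date"]),
            )
        )
    return out


@dataclass(frozen=True)
class StagingRules:
    """KDIGO-style severity multipliers applied to a criterion's reference."""

    stage2_multiplier: float = 2.0
    stage3_multiplier: float = 3.0
    stage3_absolute: float = 4.0
    ratio_threshold: float = 1.5   # "50% rise"
    delta_threshold: float = 0.3   # mg/dL within 48 h, strict >

    def stage(self, index_value: float, reference: float) -> int:
        if index_value >= self.stage3_multiplier * reference or index_value >= self.stage3_absolute:
            return 3
        if index_value >= self.stage2_multiplier * reference:
            return 2
        return 1


KDIGO_STAGING = StagingRules()


@dataclass(frozen=True)
class AkiResult:
    """Outcome of AKI detection on one admission."""

    flag: bool
    stage: int
    triggering_criterion: str
    reference: float | None = None
    index_value: float | None = None
    index_time: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.flag != (self.stage >= 1):
            raise ValueError("stage >= 1 iff flag is true")
        if self.flag == (self.triggering_criterion == "none"):
            raise ValueError("triggering_criterion is 'none' iff flag is false")


_NO_AKI = AkiResult(flag=False, stage=0, triggering_criterion="none")


def _candidate_criteria(
    series: CreatinineSeries, idx: int, rules: StagingRules
) -> list[tuple[str, float]]:
    """(criterion, reference) pairs that fire for observation ``idx`` as index."""
    t = series.times[idx]
    c = series.values[idx]
    times, values = series.times, series.values
    before = times < t
    fired: list[tuple[str, float]] = []

    win48 = before & (times >= t - np.timedelta64(48, "h"))
    if win48.any():
        ref = values[win48].min()
        if c - ref > rules.delta_threshold:
            fired.append(("delta48h", float(ref)))

    win7 = before & (times >= t - np.timedelta64(7, "D"))
    if win7.any():
        ref = values[win7].min()
        if c >= rules.ratio_threshold * ref:
            fired.append(("ratio7d", float(ref)))

    # Median of 8-90 days back is preferred whenever ANY sample exists there;
    # otherwise fall back to the 91-365 day median.
    win8_90 = (times <= t - np.timedelta64(8, "D")) & (times >= t - np.timedelta64(90, "D"))
    win91_365 = (times <= t - np.timedelta64(91, "D")) & (times >= t - np.timedelta64(365, "D"))
    if win8_90.any():
        ref = float(np.median(values[win8_90]))
        if c >= rules.ratio_threshold * ref:
            fired.append(("ratio8_90d", ref))
    elif win91_365.any():
        ref = float(np.median(values[win91_365]))
        if c >= rules.ratio_threshold * ref:
            fired.append(("ratio91_365d", ref))
    return fired


_CRITERION_ORDER = {name: i for i, name in enumerate(CRITERIA)}


def detect_aki_grampian(
    series: CreatinineSeries, rules: StagingRules = KDIGO_STAGING
) -> AkiResult:
    """Detect and stage AKI by the Grampian KDIGO-based algorithm.

    Every in-admission creatinine is tested as a candidate index value
    against three criteria: (1) a rise of more than 0.3 mg/dL above the
    lowest creatinine of the preceding 48 hours; (2) a 50% rise above the
    lowest creatinine of the past 7 days; (3) a 50% rise above the median
    creatinine of days 8-90 back, or days 91-365 back if no closer samples
    exist.  The reference value of the firing criterion anchors staging.
    When several criteria fire, the one giving the highest stage is
    reported, ties broken in the order listed above.
    """
    if not series.observations:
        raise ValueError(f"subject {series.subject_id}: empty creatinine series")
    in_adm = (series.times >= np.datetime64(series.admission_date)) & (
        series.times <= np.datetime64(series.discharge_date)
    )
    best: AkiResult = _NO_AKI
    for idx in np.flatnonzero(in_adm):
        c = float(series.values[idx])
        for criterion, ref in _candidate_criteria(series, int(idx), rules):
            stage = rules.stage(c, ref)
            result = AkiResult(
                flag=True,
                stage=stage,
                triggering_criterion=criterion,
                reference=ref,
                index_value=c,
                index_time=pd.Timestamp(series.times[idx]),
            )
            if (stage, -_CRITERION_ORDER[criterion]) > (
                best.stage,
                -_CRITERION_ORDER.get(best.triggering_criterion, 99),
            ):
                best = result
    return best


def detect_aki_alberta(
    series: CreatinineSeries, rules: StagingRules = KDIGO_STAGING
) -> AkiResult | None:
    """Detect and stage AKI by the Alberta algorithm.

    AKI is present when the peak in-hospital creatinine rises by more than
    0.3 mg/dL, or by 50% or more, above the most recent outpatient baseline
    drawn 7-365 days before admission.  Returns ``None`` (indeterminate,
    distinct from "no AKI") when no qualifying baseline or no in-hospital
    creatinine exists.
    """
    if not series.observations:
        raise ValueError(f"subject {series.subject_id}: empty creatinine series")
    adm = np.datetime64(series.admission_date)
    times, values, settings = series.times, series.values, series.settings
    base_win = (
        (settings == OUTPATIENT)
        & (times <= adm - np.timedelta64(7, "D"))
        & (times >= adm - np.timedelta64(365, "D"))
    )
    if not base_win.any():
        return None
    baseline = float(values[np.flatnonzero(base_win)[-1]])  # most recent qualifying
    in_adm = (times >= adm) & (times <= np.datetime64(series.discharge_date))
    if not in_adm.any():
        return None
    peak_idx = np.flatnonzero(in_adm)[np.argmax(values[in_adm])]
    peak = float(values[peak_idx])
    if peak - baseline > rules.delta_threshold or peak >= rules.ratio_threshold * baseline:
        return AkiResult(
            flag=True,
            stage=rules.stage(peak, baseline),
            triggering_criterion="alberta_baseline",
            reference=baseline,
            index_value=peak,
            index_time=pd.Timestamp(times[peak_idx]),
        )
    return _NO_AKI


# -- eGFR -----------------------------------------------------------------

def ckd_epi_egfr(scr, age, sex, black: bool = False):
    """CKD-EPI (2009) estimated GFR in mL/min/1.73 m2.

    ``sex`` is ``"female"`` or ``"male"`` (scalar or array).  The race
    coefficient is configurable and OFF by default, matching UK laboratory
    practice of the study era which applied the non-Black coefficient
    universally.  Accepts scalars or arrays; strictly decreasing in
    creatinine at fixed age and sex.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    sex_arr = np.asarray(sex)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    if np.any(age < 18):
        raise ValueError("CKD-EPI 2009 is an adult (age >= 18) equation")
    female = sex_arr == "female"
    if not np.all(female | (sex_arr == "male")):
        raise ValueError("sex must be 'female' or 'male'")
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * np.where(female, 1.018, 1.0)
    )
    if black:
        egfr = egfr * 1.159
    return float(egfr) if egfr.ndim == 0 else egfr


# -- outcomes -------------------------------------------------------------

def ascertain_ckd_g45(
    assessments: Iterable[tuple[pd.Timestamp, float, str]] | pd.DataFrame,
    index_date: pd.Timestamp,
    horizon_days: int = 365,
    egfr_threshold: float = 30.0,
    min_separation_days: int = 90,
) -> bool:
    """CKD G4-G5 progression within the horizon after cohort entry.

    Requires a minimum of two OUTPATIENT eGFR assessments below the
    threshold, separated by at least ``min_separation_days`` (the "3 month"
    rule), inside ``(index_date, index_date + horizon]``.  Absent data means
    no observed outcome (``False``), never an error; adding qualifying
    assessments can only turn the result from False to True.
    """
    if isinstance(assessments, pd.DataFrame):
        rows = list(zip(assessments["timestamp"], assessments["egfr"], assessments["setting"]))
    else:
        rows = list(assessments)
    index_date = pd.Timestamp(index_date)
    end = index_date + pd.Timedelta(days=horizon_days)
    qual = sorted(
        pd.Timestamp(t)
        for t, egfr, setting in rows
        if setting == OUTPATIENT
        and float(egfr) < egfr_threshold
        and index_date < pd.Timestamp(t) <= end
    )
    if len(qual) < 2:
        return False
    return (qual[-1] - qual[0]) >= pd.Timedelta(days=min_separation_days)


def ascertain_death_or_readmission(
    events: pd.DataFrame,
    discharge_date: pd.Timestamp,
    window_days: int = 90,
) -> bool:
    """Death or unplanned readmission within ``(discharge, discharge + window]``.

    ``events`` is an event-log slice for one case with columns
    ``activity`` and ``timestamp``.  Events timestamped before discharge
    signal a malformed log and raise ``ValueError``.
    """
    discharge_date = pd.Timestamp(discharge_date)
    if len(events) == 0:
        return False
    ts = pd.to_datetime(events["timestamp"])
    if (ts < discharge_date).any():
        raise ValueError("malformed event log: events precede the discharge date")
    end = discharge_date + pd.Timedelta(days=window_days)
    poor = events["activity"].isin(["death", "readmission"])
    return bool((poor & (ts > discharge_date) & (ts <= end)).any())
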