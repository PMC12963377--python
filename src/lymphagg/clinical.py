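"""Clinical endpoint summaries for a neoadjuvant trial cohort.

Implements the endpoint arithmetic on a per-patient table: single-lesion
best response by percent change of the longest diameter (partial response at
or below -30% from baseline; progression at +20% from nadir plus 5 mm
absolute, per RECIST 1.1), CA19-9 biomarker response with the >37 U/mL
abnormal cutoff and the bilirubin <3 mg/dL evaluability rule, cohort
proportions (resection, CAP score, margins, nodal stage, response and
biomarker rates), grade-4 adverse-event tabulation, and Kaplan-Meier median
survival with log-log confidence intervals.

Percentages are rounded to the nearest integer, half away from zero.
Denominators follow the trial's conventions: enrolled patients for the
resection rate; resected patients for CAP/margin/nodal proportions; patients
completing treatment for response and CA19-9 rates.  Best response is also
tabulated over all enrolled patients with "NE" (no imaging) as a category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClinicalRecord:
    """One trial patient."""

    patient_id: str
    enrolled: bool = True
    completed_treatment: bool = False
    resected: bool = False
    cap_score: int | None = None        # 0 complete ... 3 poor/no response
    margins: str | None = None          # R0 / R1 / R2
    pn_stage: int | None = None         # 0 / 1 / 2
    ca199_series: list[dict] = field(default_factory=list)
    lesion_series: list[dict] = field(default_factory=list)
    aes: list[dict] = field(default_factory=list)
    dfs_time: float = math.nan
    dfs_event: bool = False
    pfs_time: float = math.nan
    pfs_event: bool = False
    os_time: float = math.nan
    os_event: bool = False

    def __post_init__(self) -> None:
        if self.resected:
            if self.cap_score is None or self.margins is None or self.pn_stage is None:
                raise ValidationError(
                    f"{self.patient_id}: resected patients need CAP, margins, pN")
        for series in (self.ca199_series, self.lesion_series):
            days = [pt["day"] for pt in series]
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValidationError(
                    f"{self.patient_id}: series days must be strictly increasing")
        for ae in self.aes:
            if not 1 <= ae["grade"] <= 4:
                raise ValidationError(
                    f"{self.patient_id}: AE grade {ae['grade']} outside 1..4")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, half away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent(num: int, den: int) -> int:
    if den <= 0:
        raise ValidationError("percentage with non-positive denominator")
    if num > den:
        raise ValidationError("numerator exceeds denominator")
    return round_half_away(100.0 * num / den)


# ---------------------------------------------------------------------------
# per-patient endpoints

def recist_best_response(lesion_series: list[dict],
                         pr_threshold: float = -30.0,
                         pd_threshold: float = 20.0) -> str:
    """Best response category for a single target lesion: PR, SD, PD or NE.

    Baseline is the first measurement.  PR when the best percent change from
    baseline is at or below ``pr_threshold``; PD when any measurement rises
    at least ``pd_threshold`` percent AND 5 mm absolute above the nadir of
    the preceding measurements; NE with fewer than two measurements.
    """
    diameters = [pt["longest_diameter"] for pt in lesion_series]
    if any(d <= 0 for d in diameters):
        raise ValidationError("lesion diameters must be positive")
    if len(diameters) < 2:
        return "NE"
    baseline = diameters[0]
    changes = [(d - baseline) / baseline * 100.0 for d in diameters[1:]]
    if min(changes) <= pr_threshold:
        return "PR"
    nadir = baseline
    for d in diameters[1:]:
        from_nadir = (d - nadir) / nadir * 100.0
        if from_nadir >= pd_threshold and (d - nadir) >= 5.0:
            return "PD"
        nadir = min(nadir, d)
    return "SD"


def ca199_response(series: list[dict],
                   upper_normal: float = 37.0,
                   bilirubin_max: float = 3.0) -> dict:
    """CA19-9 response flags for one patient.

    Draws with total bilirubin at or above ``bilirubin_max`` mg/dL are
    dropped; the patient is evaluable with at least two remaining draws.
    ``decreased``: last < first.  ``converted``: first abnormal (strictly
    above ``upper_normal`` U/mL) and last normal (at or below it).
    """
    if not series:
        raise ValidationError("empty CA19-9 series")
    usable = [pt for pt in series if pt.get("bilirubin", 0.0) < bilirubin_max]
    if len(usable) < 2:
        return {"evaluable": False, "decreased": False, "converted": False}
    first, last = usable[0]["value"], usable[-1]["value"]
    return {
        "evaluable": True,
        "decreased": last < first,
        "converted": first > upper_normal and last <= upper_normal,
    }


# ---------------------------------------------------------------------------
# Kaplan-Meier plumbing

def km_median(times: np.ndarray, events: np.ndarray) -> dict:
    """Product-limit median survival with a 95% log-log CI.

    The median is the smallest time at which the survival curve falls to
    0.5 or below; when the curve never crosses 0.5 the median and the
    affected CI bounds are "not reached" (returned as ``inf``).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise ValidationError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return {"median": median, "ci_low": lo, "ci_high": hi}


# ---------------------------------------------------------------------------
# cohort summary

@dataclass
class CohortSummary:
    """Printed-style cohort proportions (integer percent) and counts."""

    n_enrolled: int
    n_resected: int
    n_completed: int
    resection_rate: int
    cap_distribution: dict[int, int]        # score -> percent of resected
    cap_counts: dict[int, int]
    r0_rate: int
    pn0_rate: int
    orr: int                                # PR / completed
    sd_rate: int
    best_response_counts: dict[str, int]    # over all enrolled, incl. NE
    ca199_decrease_rate: int
    ca199_conversion_rate: int
    tumor_shrinkage_rate: int
    grade4_ae_count: int
    km: dict[str, dict]

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_cohort(records: list[ClinicalRecord],
                     upper_normal: float = 37.0,
                     bilirubin_max: float = 3.0) -> CohortSummary:
    """Compute the cohort's endpoint summaries.

    Proportions use the trial's denominators (see module docstring) and are
    rounded to the nearest integer percent, half away from zero.
    """
    if not records:
        raise ValidationError("empty cohort")
    enrolled = [r for r in records if r.enrolled]
    resected = [r for r in enrolled if r.resected]
    completed = [r for r in enrolled if r.completed_treatment]
    n, n_res, n_comp = len(enrolled), len(resected), len(completed)
    if n_res == 0 or n_comp == 0:
        raise ValidationError("cohort has no resected or no completed patients")

    cap_counts: dict[int, int] = {}
    for r in resected:
        cap_counts[r.cap_score] = cap_counts.get(r.cap_score, 0) + 1
    cap_distribution = {k: percent(v, n_res) for k, v in sorted(cap_counts.items())}

    responses_all = {r.patient_id: recist_best_response(r.lesion_series)
                     for r in enrolled}
    best_counts: dict[str, int] = {}
    for resp in responses_all.values():
        best_counts[resp] = best_counts.get(resp, 0) + 1
    comp_resp = [responses_all[r.patient_id] for r in completed]
    n_pr = sum(resp == "PR" for resp in comp_resp)
    n_sd = sum(resp == "SD" for resp in comp_resp)

    shrank = 0
    for r in completed:
        d = [pt["longest_diameter"] for pt in r.lesion_series]
        if len(d) >= 2 and min(d[1:]) < d[0]:
            shrank += 1

    ca_flags = [ca199_response(r.ca199_series, upper_normal, bilirubin_max)
                for r in completed]
    n_decreased = sum(f["decreased"] for f in ca_flags)
    n_converted = sum(f["converted"] for f in ca_flags)

    grade4 = sum(1 for r in enrolled for ae in r.aes if ae["grade"] == 4)

    km: dict[str, dict] = {}
    for name, pool in (("dfs", resected), ("pfs", completed), ("os", completed)):
        times = np.array([getattr(r, f"{name}_time") for r in pool])
        events = np.array([getattr(r, f"{name}_event") for r in pool])
        ok = np.isfinite(times)
        if ok.sum() >= 2:
            km[name] = km_median(times[ok], events[ok])

    return CohortSummary(
        n_enrolled=n, n_resected=n_res, n_completed=n_comp,
        resection_rate=percent(n_res, n),
        cap_distribution=cap_distribution,
        cap_counts=dict(sorted(cap_counts.items())),
        r0_rate=percent(sum(r.margins == "R0" for r in resected), n_res),
        pn0_rate=percent(sum(r.pn_stage == 0 for r in resected), n_res),
        orr=percent(n_pr, n_comp),
        sd_rate=percent(n_sd, n_comp),
        best_response_counts=dict(sorted(best_counts.items())),
        ca199_decrease_rate=percent(n_decreased, n_comp),
        ca199_conversion_rate=percent(n_converted, n_comp),
        tumor_shrinkage_rate=percent(shrank, n_comp),
        grade4_ae_count=grade4,
        km=km)


# ---------------------------------------------------------------------------
# cohort serialization (one wide CSV + long-format companions)

def write_cohort(records: list[ClinicalRecord], out_dir) -> None:
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wide = pd.DataFrame([{
        "patient_id": r.patient_id, "enrolled": r.enrolled,
        "completed_treatment": r.completed_treatment, "resected": r.resected,
        "cap_score": r.cap_score, "margins": r.margins, "pn_stage": r.pn_stage,
        "dfs_time": r.dfs_time, "dfs_event": r.dfs_event,
        "pfs_time": r.pfs_time, "pfs_event": r.pfs_event,
        "os_time": r.os_time, "os_event": r.os_event,
    } for r in records])
    wide.to_csv(out / "patients.csv", index=False, float_format="%.17g")
    ca = [{"patient_id": r.patient_id, **pt}
          for r in records for pt in r.ca199_series]
    pd.DataFrame(ca).to_csv(out / "ca199.csv", index=False, float_format="%.17g")
    les = [{"patient_id": r.patient_id, **pt}
           for r in records for pt in r.lesion_series]
    pd.DataFrame(les).to_csv(out / "lesions.csv", index=False, float_format="%.17g")
    aes = [{"patient_id": r.patient_id, **ae}
           for r in records for ae in r.aes]
    pd.DataFrame(aes, columns=["patient_id", "term", "grade"]).to_csv(
        out / "aes.csv", index=False)


def read_cohort(in_dir) -> list[ClinicalRecord]:
    from pathlib import Path
    src = Path(in_dir)
    wide = pd.read_csv(src / "patients.csv", float_precision="round_trip")
    ca = pd.read_csv(src / "ca199.csv", float_precision="round_trip")
    les = pd.read_csv(src / "lesions.csv", float_precision="round_trip")
    aes = pd.read_csv(src / "aes.csv")
    records = []
    for _, row in wide.iterrows():
        pid = row["patient_id"]
        records.append(ClinicalRecord(
            patient_id=pid,
            enrolled=bool(row["enrolled"]),
            completed_treatment=bool(row["completed_treatment"]),
            resected=bool(row["resected"]),
            cap_score=None if pd.isna(row["cap_score"]) else int(row["cap_score"]),
            margins=None if pd.isna(row["margins"]) else str(row["margins"]),
            pn_stage=None if pd.isna(row["pn_stage"]) else int(row["pn_stage"]),
            ca199_series=ca[ca["patient_id"] == pid]
                .drop(columns="patient_id").to_dict("records"),
            lesion_series=les[les["patient_id"] == pid]
                .drop(columns="patient_id").to_dict("records"),
            aes=aes[aes["patient_id"] == pid]
                .drop(columns="patient_id").to_dict("records"),
            dfs_time=float(row["dfs_time"]), dfs_event=bool(row["dfs_event"]),
            pfs_time=float(row["pfs_time"]), pfs_event=bool(row["pfs_event"]),
            os_time=float(row["os_time"]), os_event=bool(row["os_event"])))
    return records
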