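"""Progression-specific survival endpoints and Kaplan-Meier / log-rank.

Timelines are modeled as integer days from the primary surgery (t = 0).
Four endpoints are derived per patient:

RFS
    relapse-free survival — first surgical reoperation or death is the
    event; otherwise censored at end of follow-up.
P4FS
    progression-free survival to grade 4 — progression to grade 4
    (histology at a reoperation) or death is the event.
TTP4
    time to progression to grade 4 — only progression is an event; death
    censors the patient at the death date.
OS
    overall survival — death is the event.

Treatment grouping uses only therapy episodes started strictly before the
endpoint-defining event (or censoring time): none -> surgery_only,
radiation only -> radiation, chemotherapy only -> chemo, both ->
combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ENDPOINTS = ("RFS", "P4FS", "TTP4", "OS")
MODALITIES = ("radiation", "chemo")


@dataclass
class TherapyEpisode:
    modality: str  # "radiation" | "chemo"
    start: float
    end: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.start < 0:
            raise ValueError("therapy start before primary surgery")


@dataclass
class Reoperation:
    time: float
    grade: int  # histological grade at reoperation (2-4)


@dataclass
class PatientTimeline:
    patient: str
    therapies: list[TherapyEpisode] = field(default_factory=list)
    reoperations: list[Reoperation] = field(default_factory=list)
    death: float | None = None
    follow_up_end: float | None = None

    def __post_init__(self) -> None:
        self.reoperations = sorted(self.reoperations, key=lambda r: r.time)
        for reop in self.reoperations:
            if reop.time < 0:
                raise ValueError("reoperation before primary surgery")

    @property
    def progression_to_grade4(self) -> float | None:
        """Date of the first reoperation with grade 4 histology, if any."""
        for reop in self.reoperations:
            if reop.grade >= 4:
                return reop.time
        return None


@dataclass(frozen=True)
class EndpointRecord:
    patient: str
    endpoint: str
    time: float
    event: int  # 1 = event, 0 = censored
    treatment_group: str


def _first(*times: float | None) -> float | None:
    usable = [t for t in times if t is not None]
    return min(usable) if usable else None


def treatment_group(timeline: PatientTimeline, before: float) -> str:
    """Group by therapy modalities started strictly before ``before``."""
    started = {ep.modality for ep in timeline.therapies if ep.start < before}
    if started == {"radiation", "chemo"}:
        return "combination"
    if started == {"radiation"}:
        return "radiation"
    if started == {"chemo"}:
        return "chemo"
    return "surgery_only"


def derive_endpoint(timeline: PatientTimeline, endpoint: str) -> EndpointRecord:
    """Derive a (time, event, treatment group) record for one endpoint."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; use one of {ENDPOINTS}")
    reop = timeline.reoperations[0].time if timeline.reoperations else None
    prog4 = timeline.progression_to_grade4
    death = timeline.death
    fup = timeline.follow_up_end

    if endpoint == "RFS":
        t = _first(reop, death)
    elif endpoint == "P4FS":
        t = _first(prog4, death)
    elif endpoint == "TTP4":
        t = prog4
    else:  # OS
        t = death
    if t is not None:
        # TTP4 censors at death when death precedes any grade-4 progression.
        if endpoint == "TTP4" and death is not None and death < t:
            time, event = death, 0
        else:
            time, event = t, 1
    else:
        censor = death if endpoint == "TTP4" and death is not None else fup
        if censor is None:
            raise ValueError(
                f"patient {timeline.patient}: no event and no follow-up end"
            )
        time, event = censor, 0
    return EndpointRecord(
        patient=timeline.patient,
        endpoint=endpoint,
        time=float(time),
        event=event,
        treatment_group=treatment_group(timeline, time),
    )


def endpoint_table(
    timelines: list[PatientTimeline], endpoint: str
) -> pd.DataFrame:
    records = [derive_endpoint(tl, endpoint) for tl in timelines]
    return pd.DataFrame(
        {
            "patient": [r.patient for r in records],
            "endpoint": endpoint,
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "treatment_group": [r.treatment_group for r in records],
        }
    )


def km_logrank(records: pd.DataFrame, by: str = "treatment_group"):
    """Kaplan-Meier curves per group plus the multi-group log-rank test.

    Returns ``(curves, statistic, p_value)`` where ``curves`` maps group
    name to a DataFrame of step coordinates (time, survival). Groups with
    no records are dropped with a warning.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = {}
    for name, sub in records.groupby(by):
        if len(sub) == 0:
            warnings.warn(f"group {name!r} has no records; dropped", stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(name))
        sf = kmf.survival_function_
        groups[str(name)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    if len(groups) < 2:
        raise ValueError("log-rank requires at least two nonempty groups")
    kept = records[records[by].astype(str).isin(groups)]
    if kept["event"].sum() == 0:
        return groups, 0.0, 1.0  # no events anywhere: nothing to compare
    res = multivariate_logrank_test(kept["time"], kept[by], kept["event"])
    return groups, float(res.test_statistic), float(res.p_value)


def timelines_to_frame(timelines: list[PatientTimeline]) -> pd.DataFrame:
    """Long-format episode table (one row per surgery/therapy/event)."""
    rows = []
    for tl in timelines:
        rows.append((tl.patient, "primary_surgery", 0.0, ""))
        for ep in tl.therapies:
            rows.append((tl.patient, f"therapy_{ep.modality}", ep.start, ""))
        for reop in tl.reoperations:
            rows.append((tl.patient, "reoperation", reop.time, str(reop.grade)))
        if tl.death is not None:
            rows.append((tl.patient, "death", tl.death, ""))
        if tl.follow_up_end is not None:
            rows.append((tl.patient, "follow_up_end", tl.follow_up_end, ""))
    return pd.DataFrame(rows, columns=["patient", "episode", "time", "detail"])


def timelines_from_frame(frame: pd.DataFrame) -> list[PatientTimeline]:
    timelines = []
    for patient, sub in frame.groupby("patient", sort=True):
        tl = PatientTimeline(patient=str(patient))
        for _, row in sub.iterrows():
            kind, time = row["episode"], float(row["time"])
            if kind.startswith("therapy_"):
                tl.therapies.append(
                    TherapyEpisode(modality=kind.removeprefix("therapy_"), start=time)
                )
            elif kind == "reoperation":
                tl.reoperations.append(Reoperation(time=time, grade=int(row["detail"])))
            elif kind == "death":
                tl.death = time
            elif kind == "follow_up_end":
                tl.follow_up_end = time
        tl.reoperations.sort(key=lambda r: r.time)
        timelines.append(tl)
    return timelines
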