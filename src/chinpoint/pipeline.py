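"""Per-record measurement pipeline: landmarks -> frame -> chin -> lip metrics."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chin import ChinConstruction, construct_chin
from .geometry import (
    ProfilePoint,
    SagittalFrame,
    facial_convexity_angle,
    fit_midsagittal_frame,
    project,
)
from .landmarks import Cohort, SubjectRecord
from .lips import LIP_VARIABLES, LipMeasurements, measure_subject

__all__ = ["RecordMeasurement", "measure_record", "measure_cohort", "long_measurements"]


@dataclass(frozen=True)
class RecordMeasurement:
    """Everything the pipeline derives from one subject/timepoint record."""

    record: SubjectRecord
    frame: SagittalFrame
    profile: dict[str, ProfilePoint]
    construction: ChinConstruction
    convexity_deg: float
    acp_based: LipMeasurements
    mcp_based: LipMeasurements


def measure_record(
    record: SubjectRecord,
    target_angle: float = 170.0,
    mode: str = "perpendicular",
) -> RecordMeasurement:
    """Fit the frame, build the chin construction and measure the lips."""
    frame = fit_midsagittal_frame(record.landmark_set)
    profile = project(record.landmark_set, frame)
    g, sn, acp = profile["G'"], profile["Sn'"], profile["ACP"]
    construction = construct_chin(g, sn, acp, target_angle=target_angle)
    acp_based, mcp_based = measure_subject(profile, construction, mode=mode)
    return RecordMeasurement(
        record=record,
        frame=frame,
        profile=profile,
        construction=construction,
        convexity_deg=facial_convexity_angle(g, sn, acp),
        acp_based=acp_based,
        mcp_based=mcp_based,
    )


def measure_cohort(
    cohort: Cohort,
    target_angle: float = 170.0,
    mode: str = "perpendicular",
) -> pd.DataFrame:
    """Wide per-(subject, timepoint) measurement table.

    Columns: subject_id, sex, timepoint, convexity_deg, acp_a, acp_s,
    mcp_a, mcp_s, x_signed_mm, x_abs_mm, and the four lip distances per
    pogonion source ({var}_acp / {var}_mcp).  Rows are sorted by
    (subject_id, timepoint) so the output is order-independent.
    """
    rows = []
    for rec in sorted(cohort.records, key=lambda r: (r.subject_id, r.timepoint)):
        m = measure_record(rec, target_angle=target_angle, mode=mode)
        c = m.construction
        row = {
            "subject_id": rec.subject_id,
            "sex": rec.sex,
            "timepoint": rec.timepoint,
            "convexity_deg": m.convexity_deg,
            "acp_a": c.acp.a,
            "acp_s": c.acp.s,
            "mcp_a": c.mcp.a,
            "mcp_s": c.mcp.s,
            "x_signed_mm": c.x,
            "x_abs_mm": abs(c.x),
        }
        for var in LIP_VARIABLES:
            row[f"{var}_acp"] = m.acp_based.as_dict()[var]
            row[f"{var}_mcp"] = m.mcp_based.as_dict()[var]
        rows.append(row)
    return pd.DataFrame(rows)


def long_measurements(wide: pd.DataFrame, aesthetic_window: float = 2.0) -> pd.DataFrame:
    """Long per-source measurement table with aesthetic flags (for export)."""
    rows = []
    for r in wide.itertuples(index=False):
        for source in ("acp", "mcp"):
            row = {
                "subject_id": r.subject_id,
                "sex": r.sex,
                "timepoint": r.timepoint,
                "source": source.upper(),
            }
            for var in LIP_VARIABLES:
                d = getattr(r, f"{var}_{source}")
                row[var] = d
                row[f"{var}_flag"] = (
                    "within" if abs(d) <= aesthetic_window else "outside"
                )
            rows.append(row)
    return pd.DataFrame(rows)
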