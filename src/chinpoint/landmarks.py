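"""Subject landmark records: domain types, validation, QC and file I/O.

A subject is described at each timepoint (T0 pre-surgery, T1
post-surgery) by seven named midline soft-tissue landmarks in
millimetres:

========  =======================================================
name      landmark
========  =======================================================
``G'``    soft-tissue glabella (most anterior point of the lower forehead)
``Sn'``   subnasale (nasal base / upper-lip junction)
``Pn'``   pronasale (nose tip)
``Col``   columella point
``UL``    most anterior point of the upper lip
``LL``    most anterior point of the lower lip
``ACP``   actual chin point = soft-tissue pogonion in the midsagittal plane
========  =======================================================

On disk a cohort is a long CSV (one row per landmark) with columns
``subject_id, sex, timepoint, landmark, anterior_mm, superior_mm,
lateral_mm``, or an equivalent JSON mirror.  The column names label the
nominal scanner axes; the measurement frame is always refit from the
landmarks themselves, so any rigidly transformed copy of a cohort
yields identical measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import SagittalFrame, fit_midsagittal_frame, lateral_coordinate

__all__ = [
    "Point3",
    "LandmarkSet",
    "SubjectRecord",
    "Cohort",
    "QCResult",
    "REQUIRED_LANDMARKS",
    "DEFAULT_SEX_ALIASES",
    "read_cohort",
    "write_cohort",
    "chin_deviation_qc",
]

REQUIRED_LANDMARKS: tuple[str, ...] = ("G'", "Sn'", "Pn'", "Col", "UL", "LL", "ACP")

DEFAULT_SEX_ALIASES: Mapping[str, str] = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
}

_COLUMNS = [
    "subject_id",
    "sex",
    "timepoint",
    "landmark",
    "anterior_mm",
    "superior_mm",
    "lateral_mm",
]


def _canonical_landmark_name(name: str) -> str:
    # accept the unicode prime variants (G′ etc.) used in print
    return str(name).strip().replace("′", "'")


def normalize_sex(value: str, aliases: Mapping[str, str] | None = None) -> str:
    aliases = dict(DEFAULT_SEX_ALIASES if aliases is None else aliases)
    key = str(value).strip().lower()
    if key not in aliases:
        raise ValidationError(f"unknown sex label {value!r}")
    return aliases[key]


@dataclass(frozen=True)
class Point3:
    """A 3D landmark position in mm (anterior, superior, lateral axes)."""

    anterior: float
    superior: float
    lateral: float

    def __post_init__(self) -> None:
        for v in (self.anterior, self.superior, self.lateral):
            if not np.isfinite(v):
                raise ValidationError(f"non-finite coordinate in {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.anterior, self.superior, self.lateral], dtype=float)


class LandmarkSet:
    """The seven required midline landmarks of one subject/timepoint."""

    def __init__(self, landmarks: Mapping[str, Point3]):
        canon = {_canonical_landmark_name(k): v for k, v in landmarks.items()}
        missing = [n for n in REQUIRED_LANDMARKS if n not in canon]
        if missing:
            raise ValidationError(f"missing required landmark(s): {', '.join(missing)}")
        unknown = [n for n in canon if n not in REQUIRED_LANDMARKS]
        if unknown:
            raise ValidationError(f"unknown landmark name(s): {', '.join(unknown)}")
        if np.linalg.norm(canon["G'"].as_array() - canon["Sn'"].as_array()) <= 1e-6:
            raise ValidationError("G' and Sn' coincide")
        if np.linalg.norm(canon["ACP"].as_array() - canon["Sn'"].as_array()) <= 1e-6:
            raise ValidationError("ACP and Sn' coincide")
        self._landmarks = {n: canon[n] for n in REQUIRED_LANDMARKS}

    def __getitem__(self, name: str) -> Point3:
        return self._landmarks[_canonical_landmark_name(name)]

    def __iter__(self) -> Iterator[str]:
        return iter(self._landmarks)

    def items(self):
        return self._landmarks.items()

    def as_matrix(self) -> np.ndarray:
        """7x3 matrix in the canonical landmark order."""
        return np.stack([self._landmarks[n].as_array() for n in REQUIRED_LANDMARKS])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        """Rigidly transformed copy (p -> R p + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return LandmarkSet(
            {
                n: Point3(*(R @ p.as_array() + t))
                for n, p in self._landmarks.items()
            }
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        return bool(np.array_equal(self.as_matrix(), other.as_matrix()))


@dataclass(frozen=True)
class SubjectRecord:
    """One subject at one timepoint."""

    subject_id: str
    sex: str  # "male" | "female"
    timepoint: str  # "T0" | "T1"
    landmark_set: LandmarkSet

    def __post_init__(self) -> None:
        if not str(self.subject_id):
            raise ValidationError("subject_id must be nonempty")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.timepoint not in ("T0", "T1"):
            raise ValidationError(
                f"timepoint must be 'T0' or 'T1', got {self.timepoint!r}"
            )


@dataclass
class Cohort:
    """A collection of subject records, unique per (subject, timepoint)."""

    records: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            key = (r.subject_id, r.timepoint)
            if key in seen:
                raise ValidationError(f"duplicate record for subject/timepoint {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def subject_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.subject_id not in out:
                out.append(r.subject_id)
        return out

    def record(self, subject_id: str, timepoint: str) -> SubjectRecord:
        for r in self.records:
            if r.subject_id == subject_id and r.timepoint == timepoint:
                return r
        raise KeyError((subject_id, timepoint))

    def unpaired_subject_ids(self) -> list[str]:
        """Subjects missing either the T0 or the T1 record."""
        by_subject: dict[str, set[str]] = {}
        for r in self.records:
            by_subject.setdefault(r.subject_id, set()).add(r.timepoint)
        return [s for s, tps in by_subject.items() if tps != {"T0", "T1"}]

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        keep = set(subject_ids)
        return Cohort([r for r in self.records if r.subject_id in keep])


@dataclass(frozen=True)
class QCResult:
    passed: bool
    deviation_mm: float


def chin_deviation_qc(
    record: SubjectRecord,
    frame: SagittalFrame | None = None,
    threshold: float = 3.0,
) -> QCResult:
    """Soft-tissue chin-deviation check used as an asymmetry exclusion rule.

    The deviation is the absolute lateral (out-of-plane) coordinate of the
    ACP in the fitted midsagittal frame; a record *fails* when it strictly
    exceeds ``threshold`` (default 3 mm).
    """
    if frame is None:
        frame = fit_midsagittal_frame(record.landmark_set)
    dev = abs(lateral_coordinate(record.landmark_set["ACP"], frame))
    return QCResult(passed=dev <= threshold, deviation_mm=float(dev))


def _cohort_from_long_frame(
    df: pd.DataFrame, sex_aliases: Mapping[str, str] | None
) -> Cohort:
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing column(s): {', '.join(missing_cols)}")
    records = []
    df = df.copy()
    df["landmark"] = df["landmark"].map(_canonical_landmark_name)
    for (sid, tp), grp in df.groupby(["subject_id", "timepoint"], sort=True):
        sid = str(sid)
        dup = grp["landmark"][grp["landmark"].duplicated()].tolist()
        if dup:
            raise ValidationError(
                f"subject {sid!r} {tp}: duplicated landmark(s) {sorted(set(dup))}"
            )
        pts: dict[str, Point3] = {}
        for row in grp.itertuples(index=False):
            try:
                pts[row.landmark] = Point3(
                    float(row.anterior_mm),
                    float(row.superior_mm),
                    float(row.lateral_mm),
                )
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"subject {sid!r} {tp}: bad coordinates for {row.landmark}: {exc}"
                ) from exc
        sexes = set(grp["sex"].astype(str))
        if len(sexes) != 1:
            raise ValidationError(f"subject {sid!r} {tp}: inconsistent sex labels")
        try:
            lset = LandmarkSet(pts)
        except ValidationError as exc:
            raise ValidationError(f"subject {sid!r} {tp}: {exc}") from exc
        records.append(
            SubjectRecord(
                subject_id=sid,
                sex=normalize_sex(sexes.pop(), sex_aliases),
                timepoint=str(tp),
                landmark_set=lset,
            )
        )
    return Cohort(records)


def read_cohort(
    path: str | Path,
    format: str | None = None,
    sex_aliases: Mapping[str, str] | None = None,
) -> Cohort:
    """Read and validate a landmark cohort from CSV or JSON.

    ``format`` is inferred from the file suffix when omitted.  All
    coordinates are in millimetres; sex labels are normalized through the
    alias map (default accepts m/f/male/female, case-insensitive).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"landmark file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"subject_id": str})
    elif fmt == "json":
        payload = json.loads(path.read_text())
        rows = []
        for rec in payload:
            for lname, coords in rec.get("landmarks", {}).items():
                rows.append(
                    {
                        "subject_id": rec.get("subject_id"),
                        "sex": rec.get("sex"),
                        "timepoint": rec.get("timepoint"),
                        "landmark": lname,
                        "anterior_mm": coords.get("anterior_mm"),
                        "superior_mm": coords.get("superior_mm"),
                        "lateral_mm": coords.get("lateral_mm"),
                    }
                )
        df = pd.DataFrame(rows, columns=_COLUMNS)
    else:
        raise ValidationError(f"unsupported landmark format {fmt!r}")
    return _cohort_from_long_frame(df, sex_aliases)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format DataFrame view of a cohort (deterministic row order)."""
    rows = []
    for r in sorted(cohort.records, key=lambda r: (r.subject_id, r.timepoint)):
        for name in REQUIRED_LANDMARKS:
            p = r.landmark_set[name]
            rows.append(
                (r.subject_id, r.sex, r.timepoint, name, p.anterior, p.superior, p.lateral)
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_cohort(cohort: Cohort, path: str | Path, format: str | None = None) -> Path:
    """Write a cohort to CSV or JSON at full float precision.

    ``read_cohort(write_cohort(c))`` reproduces every coordinate exactly
    (shortest round-trip float formatting).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    df = cohort_to_frame(cohort)
    if fmt == "csv":
        df.to_csv(path, index=False, lineterminator="\n")
    elif fmt == "json":
        payload = []
        for (sid, sex, tp), grp in df.groupby(
            ["subject_id", "sex", "timepoint"], sort=True
        ):
            payload.append(
                {
                    "subject_id": sid,
                    "sex": sex,
                    "timepoint": tp,
                    "landmarks": {
                        row.landmark: {
                            "anterior_mm": row.anterior_mm,
                            "superior_mm": row.superior_mm,
                            "lateral_mm": row.lateral_mm,
                        }
                        for row in grp.itertuples(index=False)
                    },
                }
            )
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ValidationError(f"unsupported landmark format {fmt!r}")
    return path
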