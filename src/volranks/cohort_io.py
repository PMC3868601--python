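"""Subject volume tables: reading, writing, normalization and age banding.

The unit of input is one subject: demographics plus grey-matter (GM),
white-matter (WM) and cerebrospinal-fluid (CSF) volumes from tissue
segmentation, in any consistent per-subject unit (voxel counts or mm³ —
units cancel in normalization). Brain tissue volume is GM+WM; dividing
by total intracranial volume (TIV = tissue + CSF) gives the unitless
normalized brain volume in (0, 1) that all downstream models use.

Age is re-expressed as one of five coded bands — 1: <70, 2: 70–74,
3: 75–79, 4: 80–84, 5: 85–89 years — because subject counts at
single-year ages are too small to estimate percentile ranks. Fractional
ages use half-open intervals ([70, 75), …, [85, 90)) so every real age
maps to exactly one code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "NormalizedRecord",
    "GroupedCohort",
    "LoadResult",
    "AGE_BAND_LABELS",
    "assign_age_group",
    "normalize_record",
    "group_cohort",
    "load_cohort",
    "write_cohort",
    "cohort_frame",
]

#: Printed label of each age-group code.
AGE_BAND_LABELS: Mapping[int, str] = {
    1: "<70",
    2: "70-74",
    3: "75-79",
    4: "80-84",
    5: "85-89",
}

AGE_MIN = 55.0
AGE_MAX = 90.0  # exclusive

REQUIRED_COLUMNS = (
    "subject_id",
    "age_years",
    "sex",
    "diagnosis",
    "gm_volume",
    "wm_volume",
    "csf_volume",
)

VALID_SEX = frozenset({"M", "F", "unknown"})
VALID_DIAGNOSIS = frozenset({"normal", "AD"})


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's raw segmentation volumes plus demographics."""

    subject_id: str
    age_years: float
    sex: str
    diagnosis: str
    gm_volume: float
    wm_volume: float
    csf_volume: float


@dataclass(frozen=True)
class NormalizedRecord:
    """A subject reduced to its age-group code and normalized volume."""

    subject_id: str
    age_group_code: int
    normalized_volume: float


@dataclass
class GroupedCohort:
    """Normalized volumes partitioned into the five coded age bands."""

    label: str
    groups: Dict[int, np.ndarray]

    @property
    def n(self) -> int:
        return int(sum(len(v) for v in self.groups.values()))

    @property
    def codes(self) -> List[int]:
        return sorted(self.groups)

    def values(self) -> np.ndarray:
        """All normalized volumes, concatenated in code order."""
        return np.concatenate([self.groups[c] for c in self.codes])

    def design(self) -> Tuple[np.ndarray, np.ndarray]:
        """Subject-level (code, volume) arrays for regression."""
        x = np.concatenate(
            [np.full(len(self.groups[c]), c, dtype=float) for c in self.codes]
        )
        return x, self.values()


@dataclass
class LoadResult:
    """Outcome of reading a cohort table: accepted records + rejections."""

    records: List[SubjectRecord]
    rejected: List[Tuple[int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def assign_age_group(age_years: float) -> int:
    """Map an age in years to its band code 1–5.

    Bands are half-open on the right: <70 → 1, [70,75) → 2, [75,80) → 3,
    [80,85) → 4, [85,90) → 5. Ages outside [55, 90) are rejected.
    """
    if not np.isfinite(age_years) or not (AGE_MIN <= age_years < AGE_MAX):
        raise ValueError(
            f"age {age_years!r} outside accepted cohort range [{AGE_MIN}, {AGE_MAX})"
        )
    if age_years < 70:
        return 1
    return 2 + int((age_years - 70) // 5)


def normalize_record(record: SubjectRecord) -> NormalizedRecord:
    """Normalize a subject's tissue volume by total intracranial volume.

    normalized_volume = (GM + WM) / (GM + WM + CSF). Strictly inside
    (0, 1) whenever both tissue and CSF are positive; 1.0 at the CSF=0
    boundary. Zero TIV is an error naming the subject.
    """
    tissue = record.gm_volume + record.wm_volume
    tiv = tissue + record.csf_volume
    if tiv <= 0:
        raise ValueError(
            f"subject {record.subject_id!r}: total intracranial volume is not positive"
        )
    return NormalizedRecord(
        subject_id=record.subject_id,
        age_group_code=assign_age_group(record.age_years),
        normalized_volume=tissue / tiv,
    )


def group_cohort(records: Iterable[SubjectRecord], label: str = "custom") -> GroupedCohort:
    """Partition subjects into the five coded age bands.

    Every record lands in exactly one band; band membership is decided
    solely by :func:`assign_age_group`.
    """
    buckets: Dict[int, List[float]] = {}
    for rec in records:
        norm = normalize_record(rec)
        buckets.setdefault(norm.age_group_code, []).append(norm.normalized_volume)
    return GroupedCohort(
        label=label, groups={c: np.asarray(v, dtype=float) for c, v in buckets.items()}
    )


def _parse_row(row: Mapping[str, str]) -> SubjectRecord:
    try:
        age = float(row["age_years"])
    except ValueError as exc:
        raise ValueError(f"unparseable age {row['age_years']!r}") from exc
    volumes = {}
    for col in ("gm_volume", "wm_volume", "csf_volume"):
        try:
            volumes[col] = float(row[col])
        except ValueError as exc:
            raise ValueError(f"unparseable {col} {row[col]!r}") from exc
        if not np.isfinite(volumes[col]) or volumes[col] < 0:
            raise ValueError(f"negative or non-finite {col} {row[col]!r}")
    sex = row["sex"].strip() or "unknown"
    if sex not in VALID_SEX:
        raise ValueError(f"unknown sex {sex!r}")
    diagnosis = row["diagnosis"].strip()
    if diagnosis not in VALID_DIAGNOSIS:
        raise ValueError(f"diagnosis {diagnosis!r} not one of {sorted(VALID_DIAGNOSIS)}")
    assign_age_group(age)  # range check; raises outside [55, 90)
    return SubjectRecord(
        subject_id=row["subject_id"],
        age_years=age,
        sex=sex,
        diagnosis=diagnosis,
        **volumes,
    )


def load_cohort(path: str | Path, delimiter: str = ",") -> LoadResult:
    """Read a delimited subject table.

    The header must name all required columns (missing columns are a hard
    error). Malformed rows — unparseable numbers, out-of-range ages,
    unrecognized diagnosis labels — are rejected individually and
    reported with their 1-based file row number; well-formed rows are
    kept.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: List[SubjectRecord] = []
    rejected: List[Tuple[int, str]] = []
    for idx, row in enumerate(frame.to_dict(orient="records")):
        file_row = idx + 2  # 1-based, after the header line
        try:
            records.append(_parse_row(row))
        except ValueError as exc:
            rejected.append((file_row, str(exc)))
    return LoadResult(records=records, rejected=rejected)


def cohort_frame(records: Sequence[SubjectRecord], normalized: bool = True) -> pd.DataFrame:
    """Tabulate records; optionally append derived columns."""
    frame = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "age_years": r.age_years,
                "sex": r.sex,
                "diagnosis": r.diagnosis,
                "gm_volume": r.gm_volume,
                "wm_volume": r.wm_volume,
                "csf_volume": r.csf_volume,
            }
            for r in records
        ]
    )
    if normalized and len(frame):
        norm = [normalize_record(r) for r in records]
        frame["normalized_volume"] = [n.normalized_volume for n in norm]
        frame["age_group_code"] = [n.age_group_code for n in norm]
    return frame


def write_cohort(
    records: Sequence[SubjectRecord],
    path: str | Path,
    delimiter: str = ",",
    normalized: bool = True,
) -> Path:
    """Write records as a delimited table (full float precision)."""
    path = Path(path)
    frame = cohort_frame(records, normalized=normalized)
    frame.to_csv(path, sep=delimiter, index=False, quoting=csv.QUOTE_MINIMAL,
                 float_format="%.17g")
    return path
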