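"""Cohort demographics: loading, validation, quality scoring, and design matrices.

A cohort table lists one row per subject with demographics (age in months,
sex, scanner field strength) and three image-quality indicators as produced
by standard segmentation pipelines: mean voxel resolution (mm), a
contrast-to-noise indicator (CNR) and an inhomogeneity-to-noise indicator
(INR).  The three indicators are combined into a single quality score by
summing their z-transformed values, oriented so that larger means better
data (resolution is negated: smaller voxels are better).

The canonical row order of the table defines the subject order of every
probability stack used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "CohortTable",
    "DESIGN_COLUMNS",
    "load_cohort_table",
    "quality_indicator",
    "age_bracket_filter",
    "build_design_matrix",
]

REQUIRED_COLUMNS = ("subject_id", "age_months", "sex", "field_strength",
                    "resolution", "cnr", "inr")

#: fixed design-matrix column order: age (months), sex (male=1/female=0),
#: field strength (3T=1/1.5T=0), combined quality score (z-units)
DESIGN_COLUMNS = ("age_months", "sex", "field_strength", "quality")

_SEX_CODES = {"M": 1.0, "F": 0.0, "m": 1.0, "f": 0.0,
              "male": 1.0, "female": 0.0}
_FIELD_CODES = {1.5: 0.0, 3.0: 1.0}


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age_months: float
    sex: str                 # "M" or "F"
    field_strength: float    # 1.5 or 3.0 tesla
    resolution: float        # mean voxel edge, mm
    cnr: float
    inr: float

    def __post_init__(self) -> None:
        if not (self.age_months > 0):
            raise ValueError(
                f"subject {self.subject_id!r}: age_months must be positive, "
                f"got {self.age_months}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"subject {self.subject_id!r}: sex must be M or F")
        if self.field_strength not in _FIELD_CODES:
            raise ValueError(
                f"subject {self.subject_id!r}: field_strength must be 1.5 or 3")
        for name in ("resolution", "cnr", "inr"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"subject {self.subject_id!r}: {name} not finite")
        if not self.resolution > 0:
            raise ValueError(f"subject {self.subject_id!r}: resolution must be > 0")


@dataclass
class CohortTable:
    """Ordered subject records; row order is canonical for all image stacks."""

    records: list[SubjectRecord]
    quality: np.ndarray | None = None   # combined indicator, z-units

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        seen: set[str] = set()
        for sid in ids:
            if sid in seen:
                raise ValueError(f"duplicate subject_id {sid!r}")
            seen.add(sid)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    @property
    def ages(self) -> np.ndarray:
        return np.array([r.age_months for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([{
            "subject_id": r.subject_id,
            "age_months": r.age_months,
            "sex": r.sex,
            "field_strength": r.field_strength,
            "resolution": r.resolution,
            "cnr": r.cnr,
            "inr": r.inr,
        } for r in self.records])
        if self.quality is not None:
            df["quality"] = self.quality
        return df

    def subset(self, index: np.ndarray) -> "CohortTable":
        recs = [self.records[i] for i in np.asarray(index)]
        q = None if self.quality is None else np.asarray(self.quality)[index]
        return CohortTable(recs, q)


def load_cohort_table(path) -> CohortTable:
    """Read a cohort CSV/TSV with the required columns into a validated table.

    Columns: ``subject_id,age_months,sex,field_strength,resolution,cnr,inr``;
    sex in {M,F}, field_strength in {1.5,3}.  Missing columns, unparsable
    ages, and duplicate ids raise with the offending column/row named.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} missing column(s): "
                         + ", ".join(repr(c) for c in missing))
    records = []
    for i, row in df.iterrows():
        try:
            age = float(row["age_months"])
        except (TypeError, ValueError):
            raise ValueError(
                f"row {i} (subject {row['subject_id']!r}): "
                f"unparsable age_months {row['age_months']!r}") from None
        sex = str(row["sex"]).strip()
        sex = "M" if sex in _SEX_CODES and _SEX_CODES[sex] == 1.0 else \
              ("F" if sex in _SEX_CODES else sex)
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            age_months=age,
            sex=sex,
            field_strength=float(row["field_strength"]),
            resolution=float(row["resolution"]),
            cnr=float(row["cnr"]),
            inr=float(row["inr"]),
        ))
    return CohortTable(records)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    # constant columns (up to float rounding of the mean) contribute zero
    if sd <= 1e-12 * max(float(np.abs(v).max()), 1e-300):
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def quality_indicator(table: CohortTable,
                      orientation: dict[str, int] | None = None) -> np.ndarray:
    """Combined data-quality score: sum of oriented z-scores of the indicators.

    Orientation is fixed so that larger = better data: resolution is negated
    (smaller voxel edges are better); CNR and INR count as higher-is-better.
    Pass ``orientation`` (e.g. ``{"inr": -1}``) to override per indicator.
    Constant columns contribute 0.  The result is also stored on the table.
    """
    if len(table) < 2:
        raise ValueError("quality indicator needs at least 2 subjects")
    orient = {"resolution": -1, "cnr": +1, "inr": +1}
    if orientation:
        orient.update(orientation)
    df = table.to_frame()
    q = np.zeros(len(table))
    for name, sign in orient.items():
        q += sign * _zscore(df[name].to_numpy(dtype=float))
    table.quality = q
    return q


def age_bracket_filter(table: CohortTable, bracket_months: int = 24,
                       min_n: int = 20) -> tuple[CohortTable, dict]:
    """Drop subjects in under-covered age brackets.

    Ages are binned into half-open brackets ``[k*b, (k+1)*b)`` months anchored
    at zero; every bracket holding fewer than ``min_n`` subjects is removed
    wholesale.  Returns the filtered table and a report dict listing removed
    brackets and subject ids.  Idempotent: brackets that survive keep all
    their members, so a second pass removes nothing.
    """
    if bracket_months <= 0:
        raise ValueError("bracket_months must be positive")
    ages = table.ages
    bracket = (ages // bracket_months).astype(int)
    counts: dict[int, int] = {}
    for b in bracket:
        counts[b] = counts.get(b, 0) + 1
    bad = {b for b, n in counts.items() if n < min_n}
    keep = np.array([b not in bad for b in bracket])
    if not keep.any():
        raise ValueError("no bracket adequately covered")
    removed_ids = [r.subject_id for r, k in zip(table.records, keep) if not k]
    report = {
        "bracket_months": bracket_months,
        "min_n": min_n,
        "removed_brackets": [
            {"bracket": [int(b) * bracket_months, (int(b) + 1) * bracket_months],
             "count": counts[b]} for b in sorted(bad)],
        "removed_subjects": removed_ids,
        "n_before": len(table),
        "n_after": int(keep.sum()),
    }
    return table.subset(np.flatnonzero(keep)), report


def build_design_matrix(table: CohortTable) -> np.ndarray:
    """Encode the cohort as the fixed 4-column design matrix.

    Column order (see ``DESIGN_COLUMNS``): age in months (continuous), sex
    (male=1, female=0), field strength (3T=1, 1.5T=0), combined quality score.
    Quality is computed on the fly if not already present.
    """
    if table.quality is None:
        quality_indicator(table)
    X = np.empty((len(table), 4))
    for i, r in enumerate(table.records):
        X[i, 0] = r.age_months
        X[i, 1] = 1.0 if r.sex == "M" else 0.0
        X[i, 2] = _FIELD_CODES[r.field_strength]
    X[:, 3] = table.quality
    return X
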