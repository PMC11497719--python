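"""Cohort data model, schema-validated I/O, and per-question subsetting.

A cohort is one row per subject: demographics, clinical diagnostic group,
adjudicated amyloid status, and the plasma marker panel (P-tau181, GFAP,
NfL, Abeta42/40). The six built-in clinical questions turn a cohort into a
labelled case/control table for model development.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MARKERS",
    "MARKER_DIRECTIONS",
    "GROUPS",
    "MarkerPanel",
    "Subject",
    "CohortTable",
    "ClinicalQuestionSpec",
    "QUESTIONS",
    "CohortValidationError",
    "QuestionSubsetError",
    "load_cohort",
    "write_cohort",
    "subset_for_question",
]

#: Plasma markers carried by the panel, in canonical order.
MARKERS = ("abeta_ratio", "ptau181", "gfap", "nfl", "nfl_age_corrected")

#: Direction in which each marker is abnormal: a low Abeta42/40 ratio
#: indicates amyloid pathology, the other markers rise with pathology.
MARKER_DIRECTIONS = {
    "abeta_ratio": "lower_abnormal",
    "ptau181": "higher_abnormal",
    "gfap": "higher_abnormal",
    "nfl": "higher_abnormal",
    "nfl_age_corrected": "higher_abnormal",
}

GROUPS = ("SCD", "MCI", "AD_dementia", "FTD", "DLB", "control_other")
SEXES = ("female", "male", "unknown")
AMYLOID_STATES = ("positive", "negative", "unknown")

REQUIRED_COLUMNS = ("subject_id", "age", "sex", "group", "amyloid")
MARKER_COLUMNS = MARKERS


class CohortValidationError(ValueError):
    """A cohort file or table violates the schema or a clinical invariant."""


class QuestionSubsetError(ValueError):
    """A question subset is empty or contains a single outcome class."""


@dataclass
class MarkerPanel:
    """One subject's plasma marker concentrations (pg/mL; ratio unitless)."""

    ptau181: float | None = None
    gfap: float | None = None
    nfl: float | None = None
    nfl_age_corrected: float | None = None
    abeta_ratio: float | None = None

    def __post_init__(self) -> None:
        for name in ("ptau181", "gfap", "nfl", "nfl_age_corrected"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise CohortValidationError(f"{name} must be > 0, got {v!r}")
        if self.abeta_ratio is not None and not (0 < self.abeta_ratio < 1):
            raise CohortValidationError(
                f"abeta_ratio must lie in (0, 1), got {self.abeta_ratio!r}"
            )

    def as_dict(self) -> dict[str, float | None]:
        return {m: getattr(self, m) for m in MARKERS}


@dataclass
class Subject:
    subject_id: str
    age: float
    sex: str
    group: str
    amyloid: str
    markers: MarkerPanel = field(default_factory=MarkerPanel)

    def __post_init__(self) -> None:
        if not (0 < self.age < 120):
            raise CohortValidationError(
                f"subject {self.subject_id}: age {self.age} out of range"
            )
        if self.sex not in SEXES:
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown sex {self.sex!r}"
            )
        if self.group not in GROUPS:
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown group {self.group!r}"
            )
        if self.amyloid not in AMYLOID_STATES:
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown amyloid state {self.amyloid!r}"
            )
        if self.group == "AD_dementia" and self.amyloid != "positive":
            raise CohortValidationError(
                f"subject {self.subject_id}: AD_dementia requires amyloid-positive "
                f"status (biological diagnosis), got {self.amyloid!r}"
            )


class CohortTable:
    """An ordered collection of subjects backed by a pandas DataFrame.

    Columns: subject_id, age, sex, group, amyloid, and the five marker
    columns (NaN where a marker was not measured).
    """

    def __init__(self, name: str, df: pd.DataFrame, provenance: dict | None = None):
        self.name = name
        self.df = df.reset_index(drop=True)
        self.provenance = dict(provenance or {})
        self.load_report: dict = {}
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_subjects(
        cls, name: str, subjects: list[Subject], provenance: dict | None = None
    ) -> "CohortTable":
        rows = []
        for s in subjects:
            row = {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "group": s.group,
                "amyloid": s.amyloid,
            }
            row.update({m: np.nan if v is None else v for m, v in s.markers.as_dict().items()})
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(MARKER_COLUMNS))
        return cls(name, df, provenance)

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            raise CohortValidationError(f"cohort {self.name!r} is empty")
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortValidationError(f"missing required columns: {missing_cols}")
        for m in MARKER_COLUMNS:
            if m not in df.columns:
                self.df[m] = np.nan
        dup = df["subject_id"][df["subject_id"].duplicated()]
        if len(dup):
            raise CohortValidationError(f"duplicate subject_id(s): {sorted(set(dup))}")
        bad_group = df.loc[~df["group"].isin(GROUPS), "subject_id"]
        if len(bad_group):
            raise CohortValidationError(
                f"unknown group label for subject(s): {list(bad_group)}"
            )
        bad_amy = df.loc[~df["amyloid"].isin(AMYLOID_STATES), "subject_id"]
        if len(bad_amy):
            raise CohortValidationError(
                f"unknown amyloid state for subject(s): {list(bad_amy)}"
            )
        ad_neg = df.loc[
            (df["group"] == "AD_dementia") & (df["amyloid"] != "positive"), "subject_id"
        ]
        if len(ad_neg):
            raise CohortValidationError(
                "AD_dementia subjects must be amyloid-positive; violated by "
                f"subject(s): {list(ad_neg)}"
            )
        for m in MARKER_COLUMNS:
            vals = pd.to_numeric(df[m], errors="coerce")
            bad = df.loc[vals.notna() & (vals <= 0), "subject_id"]
            if len(bad):
                raise CohortValidationError(
                    f"non-positive {m} for subject(s): {list(bad)}"
                )

    # -- queries ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def group_counts(self) -> dict[str, int]:
        return self.df["group"].value_counts().to_dict()

    def subjects(self) -> list[Subject]:
        out = []
        for _, r in self.df.iterrows():
            panel = MarkerPanel(
                **{m: (None if pd.isna(r[m]) else float(r[m])) for m in MARKERS}
            )
            out.append(
                Subject(
                    subject_id=str(r["subject_id"]),
                    age=float(r["age"]),
                    sex=r["sex"],
                    group=r["group"],
                    amyloid=r["amyloid"],
                    markers=panel,
                )
            )
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _resolve_schema(schema_config) -> dict[str, str]:
    """Canonical-name -> file-column mapping. Accepts dict, YAML/JSON path, None."""
    if schema_config is None:
        return {}
    if isinstance(schema_config, Mapping):
        return dict(schema_config)
    path = Path(schema_config)
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, Mapping):
        raise CohortValidationError(f"schema config {path} is not a mapping")
    return dict(loaded)


def load_cohort(
    path,
    schema_config=None,
    name: str | None = None,
    sep: str = ",",
) -> CohortTable:
    """Read a delimited cohort file into a validated :class:`CohortTable`.

    ``schema_config`` maps canonical column names (subject_id, age, sex,
    group, amyloid, ptau181, gfap, nfl, nfl_age_corrected, abeta_ratio) to
    the file's own headers; unmapped canonical names default to themselves.
    Rows with missing marker cells are retained (markers set to NaN) and the
    per-column missing counts are recorded in ``cohort.load_report``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    mapping = _resolve_schema(schema_config)
    rename = {}
    for canonical in list(REQUIRED_COLUMNS) + list(MARKER_COLUMNS):
        source = mapping.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in REQUIRED_COLUMNS:
            raise CohortValidationError(
                f"required column {canonical!r} (file column {source!r}) "
                f"not found in {path.name}"
            )
    df = raw.rename(columns=rename)
    df["subject_id"] = df["subject_id"].astype(str)
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    for cat_col, default in (("sex", "unknown"), ("amyloid", "unknown")):
        df[cat_col] = df[cat_col].fillna(default).astype(str)
    for m in MARKER_COLUMNS:
        if m in df.columns:
            df[m] = pd.to_numeric(df[m], errors="coerce")
        else:
            df[m] = np.nan

    missing = {m: int(df[m].isna().sum()) for m in MARKER_COLUMNS}
    cohort = CohortTable(name or path.stem, df[list(REQUIRED_COLUMNS) + list(MARKER_COLUMNS)])
    cohort.load_report = {
        "path": str(path),
        "n_subjects": int(len(df)),
        "missing": missing,
    }
    cohort.provenance["source"] = str(path)
    return cohort


def write_cohort(cohort: CohortTable, path, sep: str = ",") -> None:
    """Write a cohort back to delimited text (lossless round trip)."""
    cohort.df.to_csv(path, sep=sep, index=False)


def write_load_report(cohort: CohortTable, path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort.load_report, fh, indent=2)


# ---------------------------------------------------------------------------
# Clinical questions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalQuestionSpec:
    """One of the six case/control contrasts the tool is developed for."""

    question_id: str
    label: str
    inclusion_filter: Callable[[pd.DataFrame], pd.Series]
    positive_class: Callable[[pd.DataFrame], pd.Series]
    requires_amyloid: bool  # unknown-amyloid subjects excluded at subsetting
    positive_label: str


def _dementia_groups(df):
    return df["group"].isin(["SCD", "MCI", "AD_dementia", "FTD", "DLB"])


def _controls(df):  # amyloid-negative SCD, the control arm of Q4 and Q6
    return (df["group"] == "SCD") & (df["amyloid"] == "negative")


QUESTIONS: dict[str, ClinicalQuestionSpec] = {
    "Q1_abeta_all": ClinicalQuestionSpec(
        "Q1_abeta_all",
        "Amyloid-positive vs amyloid-negative, total cohort",
        inclusion_filter=_dementia_groups,
        positive_class=lambda df: df["amyloid"] == "positive",
        requires_amyloid=True,
        positive_label="abeta_positive",
    ),
    "Q2_abeta_predementia": ClinicalQuestionSpec(
        "Q2_abeta_predementia",
        "Amyloid-positive vs amyloid-negative, SCD + MCI (pre-dementia)",
        inclusion_filter=lambda df: df["group"].isin(["SCD", "MCI"]),
        positive_class=lambda df: df["amyloid"] == "positive",
        requires_amyloid=True,
        positive_label="abeta_positive",
    ),
    "Q3_ad_vs_ftd": ClinicalQuestionSpec(
        "Q3_ad_vs_ftd",
        "AD dementia vs FTD",
        inclusion_filter=lambda df: df["group"].isin(["AD_dementia", "FTD"]),
        positive_class=lambda df: df["group"] == "AD_dementia",
        requires_amyloid=False,
        positive_label="AD_dementia",
    ),
    "Q4_ctrl_vs_ftd": ClinicalQuestionSpec(
        "Q4_ctrl_vs_ftd",
        "Controls (amyloid-negative SCD) vs FTD",
        inclusion_filter=lambda df: _controls(df) | (df["group"] == "FTD"),
        positive_class=lambda df: df["group"] == "FTD",
        requires_amyloid=True,
        positive_label="FTD",
    ),
    "Q5_ad_vs_dlb": ClinicalQuestionSpec(
        "Q5_ad_vs_dlb",
        "AD dementia vs DLB",
        inclusion_filter=lambda df: df["group"].isin(["AD_dementia", "DLB"]),
        positive_class=lambda df: df["group"] == "AD_dementia",
        requires_amyloid=False,
        positive_label="AD_dementia",
    ),
    "Q6_ctrl_vs_dlb": ClinicalQuestionSpec(
        "Q6_ctrl_vs_dlb",
        "Controls (amyloid-negative SCD) vs DLB",
        inclusion_filter=lambda df: _controls(df) | (df["group"] == "DLB"),
        positive_class=lambda df: df["group"] == "DLB",
        requires_amyloid=True,
        positive_label="DLB",
    ),
}


def subset_for_question(
    cohort: CohortTable,
    question: ClinicalQuestionSpec | str,
    allow_single_class: bool = False,
) -> pd.DataFrame:
    """Filter a cohort to one clinical question and attach the 0/1 outcome.

    Subjects with unknown amyloid status are excluded from the questions
    whose case or control definition depends on amyloid status (Q1, Q2,
    Q4, Q6); they are never dropped from the cohort itself.
    """
    if isinstance(question, str):
        question = QUESTIONS[question]
    df = cohort.df
    mask = question.inclusion_filter(df)
    if question.requires_amyloid:
        mask &= df["amyloid"] != "unknown"
    sub = df.loc[mask].copy()
    if len(sub) == 0:
        raise QuestionSubsetError(
            f"{question.question_id}: no subjects pass the inclusion filter"
        )
    sub["outcome"] = question.positive_class(sub).astype(int)
    classes = set(sub["outcome"].unique())
    if classes != {0, 1} and not allow_single_class:
        present = question.positive_label if classes == {1} else "controls"
        absent = "controls" if classes == {1} else question.positive_label
        raise QuestionSubsetError(
            f"{question.question_id}: subset contains only {present}; "
            f"no {absent} subjects"
        )
    sub.attrs["question_id"] = question.question_id
    sub.attrs["positive_label"] = question.positive_label
    return sub.reset_index(drop=True)
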