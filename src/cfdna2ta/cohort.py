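"""Cohort data model for dd-cfDNA rejection surveillance.

A *sample* is one blood draw with a paired endomyocardial biopsy. It carries
the biomarker triplet — dd-cfDNA% (donor fraction, percent), DQS
(donor-quantity score, genomic copies/mL plasma) and total cfDNA (copies/mL)
— together with the biopsy grades from the two grading systems: acute
cellular rejection (ACR: 0, 1R, 2R, 3R) and pathologic antibody-mediated
rejection (pAMR: 0, 1H+, 1I+, 2, 3).

The three biomarkers are linked by the identity

    dd-cfDNA% = 100 * DQS / total cfDNA

which is validated (within a relative tolerance absorbing reporting
rounding) whenever all three are present; violations are flagged, never
silently repaired.

A *cohort* is a patient-clustered collection of samples. Patients typically
contribute several draws, which is why every resampling procedure downstream
operates one-sample-per-patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ACR_GRADES = ("0", "1R", "2R", "3R")
PAMR_GRADES = ("0", "1H+", "1I+", "2", "3")

#: grades that constitute acute rejection in each arm
AR_ACR_GRADES = frozenset({"2R", "3R"})
AR_PAMR_GRADES = frozenset({"1H+", "1I+", "2", "3"})

#: draws earlier than this many days post-transplant are ineligible
MIN_DAYS_POST_TX = 28

#: default relative tolerance for the fraction/quantity identity
IDENTITY_RTOL = 0.10

REQUIRED_COLUMNS = (
    "patient_id",
    "sample_id",
    "days_post_tx",
    "dd_cfdna_pct",
    "dqs_cpml",
    "total_cfdna_cpml",
    "acr_grade",
    "pamr_grade",
)
OPTIONAL_COLUMNS = ("indication", "dsa", "lvef_pct", "cav", "on_treatment")
CANONICAL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS

_STRING_COLUMNS = ("patient_id", "sample_id", "acr_grade", "pamr_grade", "indication")
_NUMERIC_COLUMNS = ("days_post_tx", "dd_cfdna_pct", "dqs_cpml", "total_cfdna_cpml", "lvef_pct")
_BOOL_COLUMNS = ("dsa", "cav", "on_treatment")


class CohortError(ValueError):
    """Raised for malformed cohort tables or unlabelable samples."""


@dataclass(frozen=True)
class RejectionLabel:
    """Binary acute-rejection label with the arm(s) that triggered it."""

    is_ar: bool
    category: str  # non_AR | ACR_only | AMR_only | mixed

    def __post_init__(self) -> None:
        if self.category not in ("non_AR", "ACR_only", "AMR_only", "mixed"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.is_ar != (self.category != "non_AR"):
            raise ValueError("is_ar must be true iff category != non_AR")


@dataclass
class Sample:
    """One biopsy-matched blood draw."""

    patient_id: str
    sample_id: str
    days_post_tx: int
    dd_cfdna_pct: float
    dqs_cpml: float
    total_cfdna_cpml: float
    acr_grade: str | None = None
    pamr_grade: str | None = None
    indication: str = "surveillance"
    dsa: bool | None = None
    lvef_pct: float | None = None
    cav: bool | None = None

    def validate(self, identity_rtol: float = IDENTITY_RTOL) -> list[str]:
        """Return a list of problems (empty if the sample is well formed)."""
        problems: list[str] = []
        for name in ("dd_cfdna_pct", "dqs_cpml", "total_cfdna_cpml"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                problems.append(f"{name} not finite and nonnegative: {v!r}")
        if np.isfinite(self.total_cfdna_cpml) and self.total_cfdna_cpml <= 0:
            problems.append("total_cfdna_cpml must be > 0")
        if self.days_post_tx < 0:
            problems.append("days_post_tx must be nonnegative")
        if self.acr_grade is not None and self.acr_grade not in ACR_GRADES:
            problems.append(f"unknown ACR grade {self.acr_grade!r}")
        if self.pamr_grade is not None and self.pamr_grade not in PAMR_GRADES:
            problems.append(f"unknown pAMR grade {self.pamr_grade!r}")
        if not problems and self.total_cfdna_cpml > 0:
            implied = 100.0 * self.dqs_cpml / self.total_cfdna_cpml
            scale = max(abs(self.dd_cfdna_pct), abs(implied))
            if scale > 0 and abs(self.dd_cfdna_pct - implied) > identity_rtol * scale:
                problems.append(
                    "dd_cfdna_pct inconsistent with 100*dqs/total "
                    f"({self.dd_cfdna_pct:.4g} vs {implied:.4g})"
                )
        return problems


def label_rejection(
    sample: Sample | None = None,
    *,
    acr_grade: str | None = None,
    pamr_grade: str | None = None,
    strict: bool = False,
) -> RejectionLabel:
    """Label a sample as acute rejection (AR) or not from its biopsy grades.

    AR comprises ACR grades 2R/3R and pAMR grades 1H+/1I+/2/3; non-AR is
    pAMR0 with ACR 0 or 1R. When exactly one grading system is reported the
    missing one is assumed at its non-rejection level — clinical reports
    routinely omit a grade that was unremarkable — unless ``strict`` is set,
    in which case a missing grade is an error.
    """
    if sample is not None:
        acr_grade, pamr_grade = sample.acr_grade, sample.pamr_grade
    acr_missing = acr_grade is None or (isinstance(acr_grade, float) and np.isnan(acr_grade))
    pamr_missing = pamr_grade is None or (isinstance(pamr_grade, float) and np.isnan(pamr_grade))
    if acr_missing and pamr_missing:
        sid = sample.sample_id if sample is not None else "<unknown>"
        raise CohortError(f"sample {sid}: both biopsy grades missing, cannot label")
    if strict and (acr_missing or pamr_missing):
        sid = sample.sample_id if sample is not None else "<unknown>"
        raise CohortError(f"sample {sid}: missing grade not allowed in strict mode")
    if not acr_missing and acr_grade not in ACR_GRADES:
        raise CohortError(f"unknown ACR grade {acr_grade!r}")
    if not pamr_missing and pamr_grade not in PAMR_GRADES:
        raise CohortError(f"unknown pAMR grade {pamr_grade!r}")
    acr_hit = (not acr_missing) and acr_grade in AR_ACR_GRADES
    pamr_hit = (not pamr_missing) and pamr_grade in AR_PAMR_GRADES
    if acr_hit and pamr_hit:
        return RejectionLabel(True, "mixed")
    if acr_hit:
        return RejectionLabel(True, "ACR_only")
    if pamr_hit:
        return RejectionLabel(True, "AMR_only")
    return RejectionLabel(False, "non_AR")


@dataclass
class Cohort:
    """Patient-clustered cohort of biopsy-matched dd-cfDNA samples.

    ``frame`` holds one row per sample in canonical columns; ``exclusion_log``
    records (sample_id, reason) pairs removed by eligibility filtering;
    ``identity_flags`` lists sample_ids whose dd-cfDNA% disagrees with
    100*DQS/total beyond tolerance (kept in the data, flagged here).
    """

    frame: pd.DataFrame
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)
    identity_flags: list[str] = field(default_factory=list)

    # -- construction -----------------------------------------------------
    def __post_init__(self) -> None:
        self.frame = _canonicalize_frame(self.frame)
        self.validate()

    @classmethod
    def from_samples(cls, samples: Iterable[Sample]) -> "Cohort":
        rows = [vars(s).copy() for s in samples]
        frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS[:-1]))
        return cls(frame)

    # -- validation -------------------------------------------------------
    def validate(self, identity_rtol: float = IDENTITY_RTOL) -> None:
        df = self.frame
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise CohortError(f"duplicate sample_id values: {dups}")
        if len(df):
            bio = df[["dd_cfdna_pct", "dqs_cpml", "total_cfdna_cpml"]].to_numpy(float)
            if not np.isfinite(bio).all() or (bio < 0).any():
                raise CohortError("biomarkers must be finite and nonnegative")
            if (df["total_cfdna_cpml"].to_numpy(float) <= 0).any():
                raise CohortError("total_cfdna_cpml must be strictly positive")
            implied = 100.0 * df["dqs_cpml"].to_numpy(float) / df["total_cfdna_cpml"].to_numpy(float)
            stated = df["dd_cfdna_pct"].to_numpy(float)
            scale = np.maximum(np.abs(stated), np.abs(implied))
            bad = (scale > 0) & (np.abs(stated - implied) > identity_rtol * scale)
            flags = df.loc[bad, "sample_id"].tolist()
            if flags and flags != self.identity_flags:
                self.identity_flags = flags
                warnings.warn(
                    f"{len(flags)} sample(s) violate dd-cfDNA% = 100*DQS/total "
                    f"beyond {identity_rtol:.0%} relative tolerance: {flags[:5]}...",
                    stacklevel=2,
                )

    # -- basic accessors --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    @property
    def samples(self) -> list[Sample]:
        out = []
        for _, row in self.frame.iterrows():
            kw = {k: row[k] for k in CANONICAL_COLUMNS[:-1] if k in row}
            for k in ("acr_grade", "pamr_grade"):
                if pd.isna(kw.get(k)):
                    kw[k] = None
            for k in ("dsa", "cav", "lvef_pct"):
                if k in kw and pd.isna(kw[k]):
                    kw[k] = None
            kw["days_post_tx"] = int(kw["days_post_tx"])
            out.append(Sample(**kw))
        return out

    def labels(self, strict: bool = False) -> np.ndarray:
        """Boolean AR label per sample (vectorized over the frame)."""
        return np.array([lab.is_ar for lab in self.rejection_labels(strict=strict)])

    def rejection_labels(self, strict: bool = False) -> list[RejectionLabel]:
        out = []
        for sid, acr, pamr in zip(
            self.frame["sample_id"], self.frame["acr_grade"], self.frame["pamr_grade"]
        ):
            acr = None if pd.isna(acr) else acr
            pamr = None if pd.isna(pamr) else pamr
            if acr is None and pamr is None:
                raise CohortError(f"sample {sid}: both biopsy grades missing, cannot label")
            out.append(label_rejection(acr_grade=acr, pamr_grade=pamr, strict=strict))
        return out

    def biomarkers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(dd_cfdna_pct, dqs_cpml, total_cfdna_cpml) as float arrays."""
        df = self.frame
        return (
            df["dd_cfdna_pct"].to_numpy(float),
            df["dqs_cpml"].to_numpy(float),
            df["total_cfdna_cpml"].to_numpy(float),
        )

    def patient_groups(self) -> list[np.ndarray]:
        """Positional sample indices grouped by patient, in first-seen order."""
        codes, _ = pd.factorize(self.frame["patient_id"])
        return [np.flatnonzero(codes == k) for k in range(codes.max() + 1)]

    def subset(self, mask: np.ndarray) -> "Cohort":
        sub = Cohort.__new__(Cohort)
        sub.frame = self.frame.loc[np.asarray(mask)].reset_index(drop=True)
        sub.exclusion_log = list(self.exclusion_log)
        sub.identity_flags = []
        sub.__post_init__()
        return sub


def _canonicalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"missing required column(s): {missing}")
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    for c in _STRING_COLUMNS:
        df[c] = df[c].map(lambda v: v if pd.isna(v) else str(v))
    for c in _NUMERIC_COLUMNS:
        try:
            df[c] = pd.to_numeric(df[c])
        except (TypeError, ValueError) as exc:
            raise CohortError(f"column {c!r} not numeric: {exc}") from None
    for c in _BOOL_COLUMNS:
        df[c] = df[c].map(_parse_bool)
    return df[list(CANONICAL_COLUMNS)].reset_index(drop=True)


def _parse_bool(v):
    if pd.isna(v):
        return np.nan
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "y", "1.0"):
        return True
    if s in ("false", "0", "no", "n", "0.0"):
        return False
    raise CohortError(f"cannot parse boolean value {v!r}")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def apply_eligibility_filters(cohort: Cohort) -> Cohort:
    """Drop ineligible draws, logging each exclusion.

    A draw is ineligible when taken earlier than 28 days post-transplant or —
    when an explicit ``on_treatment`` flag column is present — while the
    patient was being treated for rejection. Idempotent: re-filtering a
    filtered cohort removes nothing.
    """
    df = cohort.frame
    early = df["days_post_tx"].to_numpy(float) < MIN_DAYS_POST_TX
    treated = df["on_treatment"].map(lambda v: v is True).to_numpy(bool)
    keep = ~(early | treated)
    log = list(cohort.exclusion_log)
    for sid, e, t in zip(df["sample_id"], early, treated):
        if e:
            log.append((sid, f"drawn <{MIN_DAYS_POST_TX} days post-transplant"))
        elif t:
            log.append((sid, "drawn during treatment for rejection"))
    out = cohort.subset(keep)
    out.exclusion_log = log
    return out


def read_cohort(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
    *,
    apply_filters: bool = True,
    identity_rtol: float = IDENTITY_RTOL,
) -> Cohort:
    """Read a delimited cohort table (CSV, or TSV by extension).

    ``schema_config`` maps file column names to canonical ones
    (``{"file_col": "canonical_col"}``). Rows failing eligibility filters are
    excluded and recorded in the returned cohort's ``exclusion_log``.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        dtype={c: str for c in _STRING_COLUMNS},
        keep_default_na=True,
    )
    if schema_config:
        df = df.rename(columns=dict(schema_config))
    cohort = Cohort(df)
    cohort.validate(identity_rtol=identity_rtol)
    if apply_filters:
        cohort = apply_eligibility_filters(cohort)
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort table; round-trips through :func:`read_cohort` exactly.

    Missing optional values are written as empty fields; floats use the
    shortest round-trip representation.
    """
    path = Path(path)
    df = cohort.frame.copy()
    if "on_treatment" in df.columns and df["on_treatment"].isna().all():
        df = df.drop(columns=["on_treatment"])
    df.to_csv(path, sep=_sep_for(path), index=False, na_rep="")
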