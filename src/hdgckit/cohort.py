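"""Patient records, HDGC eligibility, and cohort composition tables.

Hereditary diffuse gastric cancer (HDGC) eligibility is a clinical
definition over the proband's histology, age at diagnosis, and first- or
second-degree family history. A patient is eligible when at least one of
four conditions holds:

1. two or more gastric cancer (GC) cases among 1st/2nd-degree relatives
   together with one confirmed diffuse GC diagnosed before age 50
   (``condition1_mode="combined"``, the default), or — under the
   alternative disjunctive reading (``"either"``) — two or more GC cases
   of any kind OR one confirmed diffuse GC relative before 50;
2. three or more confirmed diffuse GC cases among 1st/2nd-degree
   relatives, independent of age at onset;
3. the proband's own diffuse GC diagnosed before age 40 with no family
   history of diffuse GC;
4. personal or family history of diffuse GC together with lobular breast
   cancer, one of which was diagnosed before age 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .stats import percent

__all__ = [
    "FamilyHistoryEntry",
    "PatientRecord",
    "EligibilityResult",
    "classify_hdgc",
    "cohort_composition",
    "read_clinical_tsv",
]

HISTOLOGIES = ("diffuse", "other")
DIAGNOSES = ("GC", "diffuse_GC", "lobular_breast")


@dataclass(frozen=True)
class FamilyHistoryEntry:
    """One affected relative.

    ``degree`` is 1 or 2 (first- or second-degree relative). ``confirmed``
    marks a pathologically confirmed diagnosis; unconfirmed GC still counts
    toward condition 1's case count but never toward diffuse-specific
    clauses.
    """

    degree: int
    diagnosis: str
    age_at_dx: float
    confirmed: bool = False

    def __post_init__(self) -> None:
        if self.degree not in (1, 2):
            raise ValueError(f"relative degree must be 1 or 2, got {self.degree}")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")

    @property
    def is_gc(self) -> bool:
        return self.diagnosis in ("GC", "diffuse_GC")

    @property
    def is_confirmed_diffuse(self) -> bool:
        return self.diagnosis == "diffuse_GC" and self.confirmed


@dataclass
class PatientRecord:
    patient_id: str
    age_at_dx: float
    sex: str
    histology: str
    family_history: list[FamilyHistoryEntry] = field(default_factory=list)
    personal_lobular_breast: bool = False
    stage_t: str = "unknown"
    stage_n: str = "unknown"
    stage_m: str = "unknown"
    ajcc_stage: str = "unknown"
    ebv_status: str = "unknown"
    survival_time: float = 0.0
    survival_event: bool = False

    def __post_init__(self) -> None:
        if self.age_at_dx <= 0:
            raise ValueError(f"{self.patient_id}: age_at_dx must be positive")
        if self.survival_time < 0:
            raise ValueError(f"{self.patient_id}: negative survival time")
        if self.ebv_status not in ("positive", "negative", "unknown"):
            raise ValueError(f"{self.patient_id}: bad ebv_status {self.ebv_status!r}")


@dataclass
class EligibilityResult:
    conditions_met: frozenset[int]
    @property
    def eligible(self) -> bool:
        return bool(self.conditions_met)


def classify_hdgc(patient: PatientRecord, condition1_mode: str = "combined") -> EligibilityResult:
    """Evaluate the four HDGC eligibility conditions for one patient."""
    if patient.histology not in HISTOLOGIES:
        raise ValueError(f"unknown histology {patient.histology!r}")
    if condition1_mode not in ("combined", "either"):
        raise ValueError("condition1_mode must be 'combined' or 'either'")
    fh = patient.family_history
    met: set[int] = set()

    gc_cases = sum(1 for r in fh if r.is_gc)
    diffuse_confirmed_before_50 = any(r.is_confirmed_diffuse and r.age_at_dx < 50 for r in fh)
    if condition1_mode == "combined":
        if gc_cases >= 2 and diffuse_confirmed_before_50:
            met.add(1)
    else:
        if gc_cases >= 2 or diffuse_confirmed_before_50:
            met.add(1)

    if sum(1 for r in fh if r.is_confirmed_diffuse) >= 3:
        met.add(2)

    family_diffuse = any(r.diagnosis == "diffuse_GC" for r in fh)
    if patient.histology == "diffuse" and patient.age_at_dx < 40 and not family_diffuse:
        met.add(3)

    personal_diffuse = patient.histology == "diffuse"
    lobular_entries = [r for r in fh if r.diagnosis == "lobular_breast"]
    has_lobular = patient.personal_lobular_breast or bool(lobular_entries)
    has_diffuse = personal_diffuse or family_diffuse
    if has_diffuse and has_lobular:
        before_50 = (
            (personal_diffuse and patient.age_at_dx < 50)
            or any(r.diagnosis == "diffuse_GC" and r.age_at_dx < 50 for r in fh)
            or any(r.age_at_dx < 50 for r in lobular_entries)
        )
        if before_50:
            met.add(4)

    return EligibilityResult(frozenset(met))


def cohort_composition(
    patients: list[PatientRecord], condition1_mode: str = "combined"
) -> pd.DataFrame:
    """Cohort composition by condition, age band, sex, and AJCC stage.

    Mirrors the layout of the clinical characteristics table: one row per
    category with count and one-decimal percentage of the cohort.
    """
    if not patients:
        raise ValueError("cohort_composition requires at least one patient")
    n = len(patients)
    rows: list[tuple[str, str, int]] = []
    elig = {p.patient_id: classify_hdgc(p, condition1_mode) for p in patients}
    rows.append(("age", "<40", sum(1 for p in patients if p.age_at_dx < 40)))
    rows.append(("age", ">=40", sum(1 for p in patients if p.age_at_dx >= 40)))
    for sex in ("male", "female"):
        rows.append(("sex", sex, sum(1 for p in patients if p.sex == sex)))
    fam_diffuse = sum(
        1 for p in patients if any(r.diagnosis == "diffuse_GC" for r in p.family_history)
    )
    rows.append(("family_history_diffuse_gc", "yes", fam_diffuse))
    rows.append(("family_history_diffuse_gc", "no", n - fam_diffuse))
    for c in (1, 2, 3, 4):
        rows.append(
            ("condition", str(c), sum(1 for p in patients if c in elig[p.patient_id].conditions_met))
        )
    for stage in ("I_II", "III_IV", "unknown"):
        rows.append(("ajcc_stage", stage, sum(1 for p in patients if p.ajcc_stage == stage)))
    for status in ("positive", "negative", "unknown"):
        rows.append(("ebv_status", status, sum(1 for p in patients if p.ebv_status == status)))
    df = pd.DataFrame(rows, columns=["characteristic", "category", "count"])
    df["percent"] = [percent(c, n) for c in df["count"]]
    return df


def read_clinical_tsv(manifest_path: str, family_path: str | None = None) -> list[PatientRecord]:
    """Load patients from a clinical manifest TSV plus a family-history TSV.

    Manifest columns: patient_id, age_at_dx, sex, histology,
    personal_lobular_breast, stage_t, stage_n, stage_m, ajcc_stage,
    ebv_status, survival_time, survival_event. Family-history columns (one
    relative per row): patient_id, degree, diagnosis, age_at_dx, confirmed.
    """
    manifest = pd.read_csv(manifest_path, sep="\t", dtype={"patient_id": str})
    fam: dict[str, list[FamilyHistoryEntry]] = {}
    if family_path is not None:
        fam_df = pd.read_csv(family_path, sep="\t", dtype={"patient_id": str})
        for r in fam_df.itertuples():
            fam.setdefault(r.patient_id, []).append(
                FamilyHistoryEntry(int(r.degree), r.diagnosis, float(r.age_at_dx), bool(r.confirmed))
            )
    patients = []
    for r in manifest.itertuples():
        patients.append(
            PatientRecord(
                patient_id=r.patient_id,
                age_at_dx=float(r.age_at_dx),
                sex=r.sex,
                histology=r.histology,
                family_history=fam.get(r.patient_id, []),
                personal_lobular_breast=bool(r.personal_lobular_breast),
                stage_t=str(r.stage_t),
                stage_n=str(r.stage_n),
                stage_m=str(r.stage_m),
                ajcc_stage=str(r.ajcc_stage),
                ebv_status=r.ebv_status,
                survival_time=float(r.survival_time),
                survival_event=bool(r.survival_event),
            )
        )
    return patients
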