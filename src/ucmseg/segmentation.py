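"""Needs-based segmentation rule cascade.

Three nested classifiers cover a whole resident population and its emergency
admissions:

* **Lifelong segments (LS1–LS7)** — every resident gets exactly one label by a
  fixed precedence: severe frailty (Clinical Frailty Scale above a cut-off)
  wins outright ("Leaving Well", LS7); otherwise chronic-disease stage
  (none / early / advanced) picks the tier and a psychosocial overlay (mental
  health diagnoses, social issues) picks the variant within the tier.
* **Needs-based sub-segments (A1–A5 / B1–B5)** — residents living with chronic
  disease (LS3–LS6) are further stratified: letter = disease stage (A early,
  B advanced), digit = complexity (1 single condition, 2 multiple conditions,
  3 mental-health issues, 4 social issues, 5 both).
* **Episodic segments (ES1–ES6)** — each emergency admission is classified
  from the resident's lifelong segment plus triage acuity (PACS, 1 = most
  acute): Leaving Well admissions are ES6; otherwise the PACS class sets
  resource tier (low-resource / low-acuity / high-acuity) and the lifelong
  psychosocial variant splits ES2/ES3 and ES4/ES5.

All three label sets are mutually exclusive and collectively exhaustive by
construction; the segment assigned is a deterministic, total function of the
resident's derived clinical profile and the configuration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .catalog import (
    CciWeightTable,
    ConditionCatalog,
    compute_cci,
    is_mental_health_code,
    match_conditions,
    normalise_icd10,
)

__all__ = [
    "Stage",
    "LS_LABELS",
    "SUBSEGMENT_LABELS",
    "ES_LABELS",
    "ResidentRecord",
    "DiagnosisEvent",
    "EncounterEvent",
    "AdmissionEpisode",
    "ClinicalProfile",
    "LifelongAssignment",
    "EpisodicAssignment",
    "SegmentationConfig",
    "SegmentationResult",
    "SegmentationError",
    "derive_clinical_profile",
    "assign_lifelong_segment",
    "assign_subsegment",
    "assign_episodic_segment",
    "segment_population",
    "PSYCHOSOCIAL_LS",
]

LS_LABELS = ("LS1", "LS2", "LS3", "LS4", "LS5", "LS6", "LS7")
SUBSEGMENT_LABELS = ("A1", "A2", "A3", "A4", "A5", "B1", "B2", "B3", "B4", "B5")
ES_LABELS = ("ES1", "ES2", "ES3", "ES4", "ES5", "ES6")

#: lifelong segments whose residents carry a psychosocial overlay
PSYCHOSOCIAL_LS = frozenset({"LS2", "LS4", "LS6"})


class Stage(str, enum.Enum):
    NONE = "NONE"
    EARLY = "EARLY"
    ADVANCED = "ADVANCED"


class SegmentationError(ValueError):
    """Input-integrity or rule-consistency failure during segmentation."""


class SegmentationConfig(BaseModel):
    """Tunable boundaries of the rule cascade (defaults mirror the deployed model)."""

    model_config = ConfigDict(frozen=True)

    cfs_leaving_well_threshold: int = Field(default=7, ge=1, le=9)
    mental_range: tuple[str, str] = ("F00", "F99")
    social_sources: frozenset[Literal["MSW_VISIT", "RENTAL_HOUSING"]] = frozenset(
        {"MSW_VISIT", "RENTAL_HOUSING"}
    )
    multiple_threshold: int = Field(default=2, ge=1)
    pacs_class_map: Mapping[int, Literal["LOW_RESOURCE", "LOW_ACUITY", "HIGH_ACUITY"]] = {
        1: "HIGH_ACUITY", 2: "LOW_ACUITY", 3: "LOW_RESOURCE", 4: "LOW_RESOURCE",
    }
    mental_codes_count_as_chronic: bool = False
    psychosocial_requires_multiple: bool = False
    route_mental_only_to_ls4: bool = False

    @field_validator("pacs_class_map")
    @classmethod
    def _total_over_pacs(cls, v: Mapping[int, str]) -> Mapping[int, str]:
        if set(v) != {1, 2, 3, 4}:
            raise ValueError("pacs_class_map must cover exactly PACS values 1-4")
        return dict(v)


# ---------------------------------------------------------------------------
# Record types (rows of the four input tables)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidentRecord:
    resident_id: str
    age: float
    sex: str = "F"
    ethnicity: str = "Chinese"
    rental_housing: bool = False
    cfs: int | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise SegmentationError(f"{self.resident_id}: age must be >= 0")
        if self.cfs is not None and not 1 <= self.cfs <= 9:
            raise SegmentationError(f"{self.resident_id}: CFS must be within 1-9")


@dataclass(frozen=True)
class DiagnosisEvent:
    resident_id: str
    icd10_code: str
    date: date | None = None
    priority: str = "primary"
    complication_flag: bool = False


@dataclass(frozen=True)
class EncounterEvent:
    resident_id: str
    date: date
    channel: Literal["ED", "SOC", "INPATIENT", "MSW"]
    cost: float = 0.0
    bed_days: float = 0.0

    def __post_init__(self) -> None:
        if self.channel != "INPATIENT" and self.bed_days > 0:
            raise SegmentationError("bed_days > 0 only allowed on INPATIENT encounters")
        if self.cost < 0 or self.bed_days < 0:
            raise SegmentationError("cost and bed_days must be non-negative")


@dataclass(frozen=True)
class AdmissionEpisode:
    admission_id: str
    resident_id: str
    admit_date: date
    pacs: int
    length_of_stay: float
    cost: float = 0.0
    readmit_30d: bool = False

    def __post_init__(self) -> None:
        if self.pacs not in (1, 2, 3, 4):
            raise SegmentationError(f"{self.admission_id}: PACS must be in 1-4")
        if self.length_of_stay <= 0:
            raise SegmentationError(f"{self.admission_id}: length_of_stay must be > 0")


@dataclass(frozen=True)
class ClinicalProfile:
    """Per-resident derived state feeding the rule cascade."""

    resident_id: str
    conditions: frozenset[str]
    stage: Stage
    has_mental: bool
    has_social: bool
    cfs: int | None
    cci: int
    unmatched_codes: tuple[str, ...] = ()

    @property
    def n_chronic(self) -> int:
        return len(self.conditions)


@dataclass(frozen=True)
class LifelongAssignment:
    resident_id: str
    ls: str
    subsegment: str | None
    fired_rules: tuple[str, ...] = ()


@dataclass(frozen=True)
class EpisodicAssignment:
    admission_id: str
    es: str


# ---------------------------------------------------------------------------
# Profile derivation
# ---------------------------------------------------------------------------

def derive_clinical_profile(
    resident: ResidentRecord,
    diagnoses: Sequence[DiagnosisEvent],
    encounters: Sequence[EncounterEvent],
    catalog: ConditionCatalog,
    config: SegmentationConfig,
    cci_table: CciWeightTable | None = None,
) -> ClinicalProfile:
    """Reduce a resident's history to the bio-psycho-social state the rules read.

    Chronic conditions come from prefix-matching diagnosis codes against the
    catalog; the stage is ADVANCED when any matched condition shows an
    advanced-stage marker code or any matching diagnosis carries the
    complication flag.  Mental-health codes (ICD-10 F chapter by default) set
    the mental flag and are kept out of the somatic condition set unless
    ``mental_codes_count_as_chronic`` is on.  Social issues are proxied by a
    documented medical-social-worker visit and/or public rental housing,
    according to ``config.social_sources``.
    """
    for ev in diagnoses:
        if ev.resident_id != resident.resident_id:
            raise SegmentationError(
                f"diagnosis for {ev.resident_id} passed with resident {resident.resident_id}"
            )
    for ev in encounters:
        if ev.resident_id != resident.resident_id:
            raise SegmentationError(
                f"encounter for {ev.resident_id} passed with resident {resident.resident_id}"
            )

    codes = [normalise_icd10(ev.icd10_code) for ev in diagnoses]
    mental = [c for c in codes if is_mental_health_code(c, config.mental_range)]
    somatic_events = [
        (c, ev) for c, ev in zip(codes, diagnoses)
        if not is_mental_health_code(c, config.mental_range)
    ]

    matches = match_conditions([c for c, _ in somatic_events], catalog)
    conditions = set(matches.present)
    advanced = any(matches.present.values())
    # a complication flag on a diagnosis that maps to a catalog condition also
    # promotes the resident to the advanced stage
    for code, ev in somatic_events:
        if ev.complication_flag and catalog.lookup(code) is not None:
            advanced = True
    if config.mental_codes_count_as_chronic and mental:
        conditions.add("mental_health")

    if conditions:
        stage = Stage.ADVANCED if advanced else Stage.EARLY
    else:
        stage = Stage.NONE

    has_msw = any(ev.channel == "MSW" for ev in encounters)
    has_social = (
        ("MSW_VISIT" in config.social_sources and has_msw)
        or ("RENTAL_HOUSING" in config.social_sources and resident.rental_housing)
    )

    cci = compute_cci(codes, cci_table) if cci_table is not None else 0
    return ClinicalProfile(
        resident_id=resident.resident_id,
        conditions=frozenset(conditions),
        stage=stage,
        has_mental=bool(mental),
        has_social=has_social,
        cfs=resident.cfs,
        cci=cci,
        unmatched_codes=matches.unmatched,
    )


# ---------------------------------------------------------------------------
# Rule cascade
# ---------------------------------------------------------------------------

def assign_lifelong_segment(
    profile: ClinicalProfile, config: SegmentationConfig
) -> tuple[str, tuple[str, ...]]:
    """Assign the lifelong segment; returns ``(label, fired_rules)``.

    Precedence: frailty beats disease stage beats psychosocial overlay.  An
    absent CFS never fires the frailty rule.
    """
    psychosocial = profile.has_mental or profile.has_social
    if profile.cfs is not None and profile.cfs > config.cfs_leaving_well_threshold:
        return "LS7", (f"cfs>{config.cfs_leaving_well_threshold}",)
    if profile.stage is Stage.ADVANCED:
        if psychosocial:
            return "LS6", ("stage_advanced", "psychosocial")
        return "LS5", ("stage_advanced",)
    if profile.stage is Stage.EARLY:
        if psychosocial:
            return "LS4", ("stage_early", "psychosocial")
        return "LS3", ("stage_early",)
    if config.route_mental_only_to_ls4 and profile.has_mental:
        return "LS4", ("stage_none", "mental_only_routed")
    if profile.has_social:
        return "LS2", ("stage_none", "social")
    return "LS1", ("stage_none",)


def assign_subsegment(
    profile: ClinicalProfile, ls: str, config: SegmentationConfig
) -> str | None:
    """Needs-based sub-segment for chronic-disease residents (LS3–LS6).

    Letter A/B tracks early/advanced stage; the digit ranks complexity:
    5 both mental and social, 4 social only, 3 mental only, 2 multiple
    conditions without psychosocial issues, 1 a single condition.  With
    ``psychosocial_requires_multiple`` on, single-condition residents fall to
    digit 1 even when psychosocial flags are set.
    """
    if ls not in ("LS3", "LS4", "LS5", "LS6"):
        return None
    if not profile.conditions and not (
        config.route_mental_only_to_ls4 and ls == "LS4" and profile.has_mental
    ):
        raise SegmentationError(
            f"{profile.resident_id}: {ls} assigned but no chronic conditions on profile"
        )
    letter = "B" if profile.stage is Stage.ADVANCED else "A"
    mental, social = profile.has_mental, profile.has_social
    if config.psychosocial_requires_multiple and profile.n_chronic < config.multiple_threshold:
        mental = social = False
    if mental and social:
        digit = 5
    elif social:
        digit = 4
    elif mental:
        digit = 3
    elif profile.n_chronic >= config.multiple_threshold:
        digit = 2
    else:
        digit = 1
    return f"{letter}{digit}"


def assign_episodic_segment(
    admission: AdmissionEpisode,
    ls_assignment: LifelongAssignment,
    config: SegmentationConfig,
) -> str:
    """Episodic segment for one emergency admission.

    Leaving Well residents are ES6 regardless of acuity; otherwise the PACS
    class picks the tier and the lifelong psychosocial variant (LS2/LS4/LS6)
    splits each acuity tier.
    """
    if admission.pacs not in config.pacs_class_map:
        raise SegmentationError(f"{admission.admission_id}: unknown PACS {admission.pacs}")
    if ls_assignment.ls == "LS7":
        return "ES6"
    pacs_class = config.pacs_class_map[admission.pacs]
    psychosocial = ls_assignment.ls in PSYCHOSOCIAL_LS
    if pacs_class == "LOW_RESOURCE":
        return "ES1"
    if pacs_class == "LOW_ACUITY":
        return "ES3" if psychosocial else "ES2"
    return "ES5" if psychosocial else "ES4"


# ---------------------------------------------------------------------------
# Population-level driver
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """Assignments plus derived profiles and run diagnostics."""

    lifelong: pd.DataFrame  # resident_id, ls, subsegment, fired_rules
    episodic: pd.DataFrame  # admission_id, es
    profiles: pd.DataFrame  # resident_id, n_chronic, stage, has_mental, ...
    diagnostics: dict = field(default_factory=dict)


def _rows_by_resident(df: pd.DataFrame) -> dict:
    if df.empty:
        return {}
    return {rid: grp for rid, grp in df.groupby("resident_id", sort=False)}


def segment_population(
    residents: pd.DataFrame,
    diagnoses: pd.DataFrame,
    encounters: pd.DataFrame,
    admissions: pd.DataFrame,
    catalog: ConditionCatalog,
    config: SegmentationConfig | None = None,
    cci_table: CciWeightTable | None = None,
) -> SegmentationResult:
    """Classify every resident and every admission; nothing is dropped silently.

    Input tables follow the documented CSV schemas.  Admissions referencing a
    resident absent from the registry are excluded with a recorded reason
    (mirroring the exclusion of records with incomplete essential data);
    duplicate resident ids are an error.  Results are independent of row order
    and of duplicated diagnosis rows.
    """
    config = config or SegmentationConfig()
    if residents["resident_id"].duplicated().any():
        dupes = residents.loc[residents["resident_id"].duplicated(), "resident_id"]
        raise SegmentationError(f"duplicate resident_id(s): {sorted(set(dupes))[:5]}")

    diag_by_res = _rows_by_resident(diagnoses)
    enc_by_res = _rows_by_resident(encounters)
    known = set(residents["resident_id"])

    ls_rows: list[dict] = []
    prof_rows: list[dict] = []
    unmatched_tally: dict[str, int] = {}
    excluded: list[dict] = []
    assignments: dict[str, LifelongAssignment] = {}

    for rec in residents.sort_values("resident_id").itertuples(index=False):
        cfs = getattr(rec, "cfs", None)
        if cfs is not None and pd.isna(cfs):
            cfs = None
        resident = ResidentRecord(
            resident_id=rec.resident_id,
            age=float(rec.age),
            sex=str(getattr(rec, "sex", "F")),
            ethnicity=str(getattr(rec, "ethnicity", "")),
            rental_housing=bool(getattr(rec, "rental_housing", False)),
            cfs=None if cfs is None else int(cfs),
        )
        diag_df = diag_by_res.get(resident.resident_id)
        diag_events = [] if diag_df is None else [
            DiagnosisEvent(
                resident_id=resident.resident_id,
                icd10_code=str(r.icd10_code),
                complication_flag=bool(getattr(r, "complication_flag", False)),
            )
            for r in diag_df.itertuples(index=False)
        ]
        enc_df = enc_by_res.get(resident.resident_id)
        enc_events = [] if enc_df is None else [
            EncounterEvent(
                resident_id=resident.resident_id,
                date=pd.Timestamp(r.date).date(),
                channel=str(r.channel),
                cost=float(r.cost),
                bed_days=float(getattr(r, "bed_days", 0.0)),
            )
            for r in enc_df.itertuples(index=False)
        ]
        profile = derive_clinical_profile(
            resident, diag_events, enc_events, catalog, config, cci_table
        )
        for code in profile.unmatched_codes:
            unmatched_tally[code] = unmatched_tally.get(code, 0) + 1
        ls, fired = assign_lifelong_segment(profile, config)
        sub = assign_subsegment(profile, ls, config)
        assignment = LifelongAssignment(resident.resident_id, ls, sub, fired)
        assignments[resident.resident_id] = assignment
        ls_rows.append({
            "resident_id": resident.resident_id, "ls": ls, "subsegment": sub,
            "fired_rules": ";".join(fired),
        })
        prof_rows.append({
            "resident_id": resident.resident_id,
            "n_chronic": profile.n_chronic,
            "stage": profile.stage.value,
            "has_mental": profile.has_mental,
            "has_social": profile.has_social,
            "cfs": profile.cfs,
            "cci": profile.cci,
            "age": resident.age,
            "sex": resident.sex,
            "ethnicity": resident.ethnicity,
        })

    es_rows: list[dict] = []
    if len(admissions):
        for adm in admissions.sort_values("admission_id").itertuples(index=False):
            if adm.resident_id not in known:
                excluded.append({
                    "table": "admissions", "id": str(adm.admission_id),
                    "reason": f"resident {adm.resident_id} absent from registry",
                })
                continue
            episode = AdmissionEpisode(
                admission_id=str(adm.admission_id),
                resident_id=str(adm.resident_id),
                admit_date=pd.Timestamp(adm.admit_date).date(),
                pacs=int(adm.pacs),
                length_of_stay=float(adm.length_of_stay),
                cost=float(getattr(adm, "cost", 0.0)),
                readmit_30d=bool(getattr(adm, "readmit_30d", False)),
            )
            es = assign_episodic_segment(episode, assignments[episode.resident_id], config)
            es_rows.append({"admission_id": episode.admission_id, "es": es})

    lifelong = pd.DataFrame(ls_rows, columns=["resident_id", "ls", "subsegment", "fired_rules"])
    episodic = pd.DataFrame(es_rows, columns=["admission_id", "es"])
    profiles = pd.DataFrame(prof_rows, columns=[
        "resident_id", "n_chronic", "stage", "has_mental", "has_social", "cfs", "cci",
        "age", "sex", "ethnicity",
    ])
    diagnostics = {
        "n_residents": len(lifelong),
        "n_admissions_classified": len(episodic),
        "n_excluded": len(excluded),
        "excluded_records": excluded,
        "unmatched_icd10": dict(sorted(unmatched_tally.items())),
        "ls_counts": lifelong["ls"].value_counts().to_dict() if len(lifelong) else {},
    }
    return SegmentationResult(lifelong, episodic, profiles, diagnostics)
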