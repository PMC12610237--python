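"""CSV readers/writers, schema validation with quarantine, and the pipeline driver.

Input tables are plain UTF-8 CSVs with a header row and ISO-8601 dates:
``residents.csv``, ``diagnoses.csv``, ``encounters.csv``, ``admissions.csv``
(schemas below).  Rows that fail validation are quarantined with a recorded
reason rather than aborting the run, mirroring the exclusion of records with
incomplete essential segmentation data; a missing required *column* is a hard
schema error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .catalog import (
    ConditionCatalog,
    InvalidCodeError,
    default_catalog,
    default_cci_table,
    load_catalog,
    normalise_icd10,
)
from .evaluation import (
    build_report,
    chi_square_independence,
    one_way_anova,
    summarise_by_segment,
    summarise_episodic,
    write_report,
)
from .segmentation import SegmentationConfig, SegmentationResult, segment_population

__all__ = ["RunConfig", "TableSet", "SchemaError", "read_tables", "run_pipeline"]

log = logging.getLogger("ucmseg")

_SCHEMAS: dict[str, dict[str, list[str]]] = {
    "residents": {
        "required": ["resident_id", "age"],
        "optional": ["sex", "ethnicity", "rental_housing", "cfs"],
    },
    "diagnoses": {
        "required": ["resident_id", "icd10_code"],
        "optional": ["date", "priority", "complication_flag"],
    },
    "encounters": {
        "required": ["resident_id", "date", "channel"],
        "optional": ["cost", "bed_days"],
    },
    "admissions": {
        "required": ["admission_id", "resident_id", "admit_date", "pacs",
                     "length_of_stay"],
        "optional": ["cost", "readmit_30d"],
    },
}

_CHANNELS = {"ED", "SOC", "INPATIENT", "MSW"}


class SchemaError(ValueError):
    """A structurally unusable input file (e.g. missing required column)."""


class RunConfig(BaseModel):
    """End-to-end pipeline configuration (paths + rule overrides)."""

    residents: Path
    diagnoses: Path
    encounters: Path
    admissions: Path
    catalog: Path | None = None
    out_dir: Path = Path("ucmseg_out")
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: run config must be a mapping")
        if "segmentation" in raw and raw["segmentation"] is not None:
            raw["segmentation"] = SegmentationConfig(**raw["segmentation"])
        return cls(**raw)


@dataclass
class TableSet:
    residents: pd.DataFrame
    diagnoses: pd.DataFrame
    encounters: pd.DataFrame
    admissions: pd.DataFrame
    quarantined: list[dict] = field(default_factory=list)


def _check_columns(name: str, df: pd.DataFrame, path: Path) -> None:
    missing = set(_SCHEMAS[name]["required"]) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: table '{name}' missing required column(s) "
                          f"{sorted(missing)}")


def _quarantine(rows: list[dict], table: str, idx, reason: str) -> None:
    rows.append({"table": table, "row": int(idx), "reason": reason})


def read_tables(
    residents_path: str | Path,
    diagnoses_path: str | Path,
    encounters_path: str | Path,
    admissions_path: str | Path,
) -> TableSet:
    """Read and validate the four input tables.

    Row-level problems (out-of-range PACS or CFS, unknown channel, negative
    cost, un-normalisable ICD-10 code, non-positive length of stay) quarantine
    the row with a reason.  Diagnosis codes are normalised (uppercased,
    undotted) in place.
    """
    paths = {"residents": Path(residents_path), "diagnoses": Path(diagnoses_path),
             "encounters": Path(encounters_path), "admissions": Path(admissions_path)}
    frames: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        if not path.exists():
            raise SchemaError(f"input file not found: {path}")
        try:
            frames[name] = pd.read_csv(path)
        except Exception as exc:  # malformed CSV surfaces the file name
            raise SchemaError(f"failed to parse {path}: {exc}") from exc
        _check_columns(name, frames[name], path)

    quarantined: list[dict] = []

    res = frames["residents"].copy()
    if "rental_housing" not in res:
        res["rental_housing"] = False
    res["rental_housing"] = res["rental_housing"].astype(bool)
    if "cfs" not in res:
        res["cfs"] = pd.NA
    res["cfs"] = pd.to_numeric(res["cfs"], errors="coerce").astype("Int64")
    bad_age = pd.to_numeric(res["age"], errors="coerce").isna() | (res["age"].astype(float) < 0)
    bad_cfs = res["cfs"].notna() & ~res["cfs"].between(1, 9)
    for idx in res.index[bad_age]:
        _quarantine(quarantined, "residents", idx, "age missing or negative")
    for idx in res.index[bad_cfs]:
        _quarantine(quarantined, "residents", idx, "cfs out of range 1-9")
    res = res[~(bad_age | bad_cfs)].reset_index(drop=True)

    diag = frames["diagnoses"].copy()
    if "complication_flag" not in diag:
        diag["complication_flag"] = False
    diag["complication_flag"] = diag["complication_flag"].astype(bool)
    normed, keep = [], []
    for idx, code in zip(diag.index, diag["icd10_code"].astype(str)):
        try:
            normed.append(normalise_icd10(code))
            keep.append(idx)
        except InvalidCodeError:
            _quarantine(quarantined, "diagnoses", idx, f"invalid ICD-10 code {code!r}")
    diag = diag.loc[keep].reset_index(drop=True)
    diag["icd10_code"] = normed

    enc = frames["encounters"].copy()
    if "cost" not in enc:
        enc["cost"] = 0.0
    if "bed_days" not in enc:
        enc["bed_days"] = 0.0
    enc["bed_days"] = enc["bed_days"].fillna(0.0)
    bad_channel = ~enc["channel"].isin(_CHANNELS)
    bad_cost = pd.to_numeric(enc["cost"], errors="coerce").fillna(-1) < 0
    bad_bed = (enc["bed_days"].astype(float) > 0) & (enc["channel"] != "INPATIENT")
    for idx in enc.index[bad_channel]:
        _quarantine(quarantined, "encounters", idx, "unknown channel")
    for idx in enc.index[bad_cost & ~bad_channel]:
        _quarantine(quarantined, "encounters", idx, "negative or missing cost")
    for idx in enc.index[bad_bed & ~bad_channel & ~bad_cost]:
        _quarantine(quarantined, "encounters", idx, "bed_days on non-inpatient row")
    enc = enc[~(bad_channel | bad_cost | bad_bed)].reset_index(drop=True)

    adm = frames["admissions"].copy()
    if "cost" not in adm:
        adm["cost"] = 0.0
    if "readmit_30d" not in adm:
        adm["readmit_30d"] = False
    adm["readmit_30d"] = adm["readmit_30d"].astype(bool)
    pacs = pd.to_numeric(adm["pacs"], errors="coerce")
    bad_pacs = ~pacs.isin([1, 2, 3, 4])
    los = pd.to_numeric(adm["length_of_stay"], errors="coerce")
    bad_los = los.isna() | (los <= 0)
    for idx in adm.index[bad_pacs]:
        _quarantine(quarantined, "admissions", idx, "pacs out of range")
    for idx in adm.index[bad_los & ~bad_pacs]:
        _quarantine(quarantined, "admissions", idx, "length_of_stay must be > 0")
    adm = adm[~(bad_pacs | bad_los)].reset_index(drop=True)
    adm["pacs"] = adm["pacs"].astype(int)

    if quarantined:
        log.warning("quarantined %d row(s) during read", len(quarantined))
    return TableSet(res, diag, enc, adm, quarantined)


def run_pipeline(config: RunConfig) -> tuple[SegmentationResult, dict[str, Path]]:
    """Read → segment → evaluate → report; writes all artifacts under out_dir.

    Returns the segmentation result plus a map of written artifact paths.
    Stage failures are re-raised with the stage name prefixed.
    """
    logging.basicConfig(level=config.log_level)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    tables = _stage("read", read_tables, config.residents, config.diagnoses,
                    config.encounters, config.admissions)
    log.info("read: %d residents, %d diagnoses, %d encounters, %d admissions "
             "(%d quarantined)", len(tables.residents), len(tables.diagnoses),
             len(tables.encounters), len(tables.admissions), len(tables.quarantined))

    catalog: ConditionCatalog = (
        load_catalog(config.catalog) if config.catalog else default_catalog()
    )
    result = _stage("segment", segment_population, tables.residents, tables.diagnoses,
                    tables.encounters, tables.admissions, catalog,
                    config.segmentation, default_cci_table())
    log.info("segment: %s", result.diagnostics["ls_counts"])

    ls_table, sub_table = _stage("evaluate", summarise_by_segment, result.lifelong,
                                 tables.residents, result.profiles, tables.encounters)
    es_table = _stage("evaluate", summarise_episodic, result.episodic, tables.admissions)

    tests = []
    merged = result.lifelong.merge(result.profiles, on="resident_id")
    chronic = merged[merged["subsegment"].notna() & (merged["subsegment"] != "")]
    if len(chronic):
        from .evaluation import annual_utilisation

        util = annual_utilisation(tables.residents, tables.encounters)
        chronic = chronic.merge(util, on="resident_id")
        groups = [g["annual_cost"].to_numpy()
                  for _, g in chronic.groupby("subsegment") if len(g) >= 2]
        if len(groups) >= 2:
            tests.append(one_way_anova(groups))
        sex_tab = pd.crosstab(chronic["subsegment"], chronic["sex"])
        if sex_tab.shape[0] >= 2 and sex_tab.shape[1] >= 2 and \
                (sex_tab.to_numpy().sum(axis=0) > 0).all():
            tests.append(chi_square_independence(sex_tab.to_numpy()))

    report = _stage("report", build_report, ls_table, sub_table, es_table, tests, {
        "seed": config.seed,
        "n_residents": len(tables.residents),
        "n_admissions": len(tables.admissions),
        "quarantined": len(tables.quarantined),
    })
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_report(report, out)
    lifelong_path = out / "assignments_lifelong.csv"
    episodic_path = out / "assignments_episodic.csv"
    diag_path = out / "diagnostics.json"
    result.lifelong.to_csv(lifelong_path, index=False)
    result.episodic.to_csv(episodic_path, index=False)
    diag = dict(result.diagnostics)
    diag["quarantined_rows"] = tables.quarantined
    diag_path.write_text(json.dumps(diag, indent=2, default=str))
    paths.update({"lifelong": lifelong_path, "episodic": episodic_path,
                  "diagnostics": diag_path})
    return result, paths
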