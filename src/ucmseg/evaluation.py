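"""Segment-distinctness evaluation: profile/utilisation tables and tests.

Mirrors the published evaluation surface: per-lifelong-segment and
per-sub-segment profile and utilisation tables (counts, shares, means and
standard deviations of age, Charlson index, ED / specialist-outpatient /
inpatient visits, hospital bed-days, annual cost), a per-episodic-segment
outcome table (length of stay, admission cost, 30-day readmission
proportion), and the between-segment tests: one-way ANOVA for continuous
outcomes, Pearson chi-square for categorical associations, and an ordinary
least-squares trend of outcome on segment rank adjusting for configurable
covariates (age and sex by default).

Annual utilisation is aggregated over the calendar year of each resident's
latest visit; residents with no recorded visits contribute zeros.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import ES_LABELS, LS_LABELS, SUBSEGMENT_LABELS

__all__ = [
    "TestResult",
    "EvaluationReport",
    "EvaluationError",
    "annual_utilisation",
    "summarise_by_segment",
    "summarise_episodic",
    "one_way_anova",
    "chi_square_independence",
    "linear_trend",
    "build_report",
    "render_markdown_table",
]


class EvaluationError(ValueError):
    """Degenerate or inconsistent evaluation input."""


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: tuple[int, ...]
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise EvaluationError(f"{self.test}: p-value outside [0,1]")

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic,
                "df": list(self.df), "p_value": self.p_value}


@dataclass
class EvaluationReport:
    lifelong_profile: pd.DataFrame
    subsegment_utilisation: pd.DataFrame
    episodic_outcomes: pd.DataFrame
    tests: list[TestResult]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "lifelong_profile": self.lifelong_profile.to_dict(orient="records"),
            "subsegment_utilisation": self.subsegment_utilisation.to_dict(orient="records"),
            "episodic_outcomes": self.episodic_outcomes.to_dict(orient="records"),
            "tests": [t.to_dict() for t in self.tests],
        }

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def annual_utilisation(residents: pd.DataFrame, encounters: pd.DataFrame) -> pd.DataFrame:
    """Per-resident utilisation in the calendar year of their latest visit.

    Returns one row per resident (zeros for residents with no encounters):
    ed_visits, soc_visits, inpatient_admissions, bed_days, annual_cost.
    """
    out = pd.DataFrame({"resident_id": residents["resident_id"]})
    zero_cols = ["ed_visits", "soc_visits", "inpatient_admissions", "bed_days", "annual_cost"]
    if encounters.empty:
        for c in zero_cols:
            out[c] = 0.0
        return out
    enc = encounters.copy()
    enc["year"] = pd.to_datetime(enc["date"]).dt.year
    latest = enc.groupby("resident_id")["year"].max().rename("latest_year")
    enc = enc.join(latest, on="resident_id")
    enc = enc[enc["year"] == enc["latest_year"]]
    agg = enc.groupby("resident_id").agg(
        ed_visits=("channel", lambda s: int((s == "ED").sum())),
        soc_visits=("channel", lambda s: int((s == "SOC").sum())),
        inpatient_admissions=("channel", lambda s: int((s == "INPATIENT").sum())),
        bed_days=("bed_days", "sum"),
        annual_cost=("cost", "sum"),
    ).reset_index()
    out = out.merge(agg, on="resident_id", how="left").fillna(0.0)
    return out


def _mean_sd_table(df: pd.DataFrame, by: str, labels: Sequence[str],
                   metrics: Sequence[str]) -> pd.DataFrame:
    present = df[df[by].notna() & (df[by] != "")]
    rows = []
    total = len(present)
    for label in labels:
        grp = present[present[by] == label]
        row: dict = {"segment": label, "n": len(grp),
                     "share": len(grp) / total if total else 0.0}
        for m in metrics:
            vals = grp[m].astype(float)
            row[f"mean_{m}"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"sd_{m}"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def summarise_by_segment(
    assignments: pd.DataFrame,
    residents: pd.DataFrame,
    profiles: pd.DataFrame,
    encounters: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lifelong-segment and per-sub-segment summary tables.

    Raises on residents missing from the assignment or profile tables: every
    resident must be covered (the segmentation is collectively exhaustive).
    """
    if set(residents["resident_id"]) - set(assignments["resident_id"]):
        raise EvaluationError("assignments do not cover all residents")
    if set(residents["resident_id"]) - set(profiles["resident_id"]):
        raise EvaluationError("profiles do not cover all residents")
    util = annual_utilisation(residents, encounters)
    merged = (
        assignments.merge(profiles[["resident_id", "age", "cci"]], on="resident_id")
        .merge(util, on="resident_id")
    )
    metrics = ["age", "cci", "ed_visits", "soc_visits", "inpatient_admissions",
               "bed_days", "annual_cost"]
    ls_table = _mean_sd_table(merged, "ls", LS_LABELS, metrics)
    sub_table = _mean_sd_table(merged, "subsegment", SUBSEGMENT_LABELS, metrics)
    return ls_table, sub_table


def summarise_episodic(
    episodic_assignments: pd.DataFrame, admissions: pd.DataFrame
) -> pd.DataFrame:
    """Per-episodic-segment n, share, mean/sd LOS and cost, readmission rate."""
    merged = episodic_assignments.merge(admissions, on="admission_id", how="left")
    if merged["length_of_stay"].isna().any():
        raise EvaluationError("episodic assignments reference unknown admissions")
    rows = []
    total = len(merged)
    for label in ES_LABELS:
        grp = merged[merged["es"] == label]
        los = grp["length_of_stay"].astype(float)
        cost = grp["cost"].astype(float)
        rows.append({
            "segment": label, "n": len(grp),
            "share": len(grp) / total if total else 0.0,
            "mean_los": float(los.mean()) if len(grp) else float("nan"),
            "sd_los": float(los.std(ddof=1)) if len(grp) > 1 else float("nan"),
            "mean_cost": float(cost.mean()) if len(grp) else float("nan"),
            "sd_cost": float(cost.std(ddof=1)) if len(grp) > 1 else float("nan"),
            "readmit_rate": float(grp["readmit_30d"].astype(bool).mean()) if len(grp)
                            else float("nan"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# between-segment tests
# ---------------------------------------------------------------------------

def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA across ≥2 groups of continuous values."""
    if len(groups) < 2:
        raise EvaluationError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise EvaluationError("each ANOVA group needs at least two values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise EvaluationError("all values identical: ANOVA undefined")
    k, n = len(arrays), len(pooled)
    stat, p = stats.f_oneway(*arrays)
    return TestResult("one_way_anova", float(stat), (k - 1, n - k), float(p))


def chi_square_independence(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise EvaluationError("contingency table must be at least 2x2")
    if (counts < 0).any():
        raise EvaluationError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise EvaluationError("zero row or column margin: chi-square undefined")
    res = stats.chi2_contingency(counts, correction=False)
    r, c = counts.shape
    return TestResult("chi_square", float(res.statistic), ((r - 1) * (c - 1),),
                      float(res.pvalue))


def linear_trend(
    outcome: Sequence[float],
    segment_rank: Sequence[float],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OLS of outcome on segment rank (plus optional covariates).

    Returns a coefficient table with columns term, coef, se, t, p.  Raises on
    a collinear design (e.g. a constant covariate duplicating the intercept).
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = pd.DataFrame({"segment_rank": np.asarray(segment_rank, dtype=float)})
    if covariates is not None:
        x = pd.concat([x, covariates.reset_index(drop=True)], axis=1)
    if len(y) <= x.shape[1] + 1:
        raise EvaluationError("n must exceed number of predictors + 1")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise EvaluationError("collinear design matrix")
    fit = sm.OLS(y, design).fit()
    return pd.DataFrame({
        "term": fit.params.index,
        "coef": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def render_markdown_table(df: pd.DataFrame, floatfmt: str = "{:.2f}") -> str:
    def fmt(v):
        if isinstance(v, float):
            return "" if np.isnan(v) else floatfmt.format(v)
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def build_report(
    ls_table: pd.DataFrame,
    sub_table: pd.DataFrame,
    es_table: pd.DataFrame,
    tests: Sequence[TestResult],
    metadata: dict | None = None,
) -> EvaluationReport:
    """Assemble the machine-readable report; validates segment label sets."""
    for df, labels, name in ((ls_table, LS_LABELS, "lifelong"),
                             (sub_table, SUBSEGMENT_LABELS, "subsegment"),
                             (es_table, ES_LABELS, "episodic")):
        if list(df["segment"]) != list(labels):
            raise EvaluationError(f"{name} table segment set mismatch")
    return EvaluationReport(ls_table, sub_table, es_table, list(tests),
                            dict(metadata or {}))


def write_report(report: EvaluationReport, directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    json_path = directory / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2, default=str))
    md = [
        "# Segmentation evaluation report", "",
        "## Lifelong segments (profile and utilisation)", "",
        render_markdown_table(report.lifelong_profile), "",
        "## Needs-based sub-segments (utilisation and cost)", "",
        render_markdown_table(report.subsegment_utilisation), "",
        "## Episodic segments (admission outcomes)", "",
        render_markdown_table(report.episodic_outcomes), "",
        "## Between-segment tests", "",
    ]
    for t in report.tests:
        df = ",".join(str(d) for d in t.df)
        md.append(f"- {t.test}: statistic={t.statistic:.4f}, df=({df}), p={t.p_value:.3g}")
    md_path = directory / "report.md"
    md_path.write_text("\n".join(md) + "\n")
    return {"json": json_path, "markdown": md_path}
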