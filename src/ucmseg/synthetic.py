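"""Synthetic administrative cohort with planted segment labels.

Emulates a one-year regional cohort as seen through hospital administrative
tables: a resident registry, historical ICD-10 diagnoses, encounter-level
utilisation (emergency department, specialist outpatient, inpatient,
medical-social-worker visits) and emergency admission episodes.  Every
resident is first assigned a ground-truth lifelong segment and (for chronic
segments) a needs-based sub-segment, and the records are then *constructed*
to satisfy exactly that label's criteria under the default rule
configuration — so the segmentation cascade can be tested for perfect label
recovery with no access to real data.

Outcome magnitudes are calibrated to the published per-segment means:
per-sub-segment annual ED/outpatient/inpatient visit counts, hospital
bed-days and overall cost, and per-episodic-segment length of stay, admission
cost and 30-day readmission probability.  Counts use a negative-binomial
family (mild over-dispersion by default), positive outcomes a gamma family
parameterised by mean and coefficient of variation.  Annual cost and bed-day
totals attach to encounter rows; they are drawn conditional on at least one
eligible encounter with the mean rescaled by the inclusion probability, so
the *unconditional* per-resident mean equals the configured value exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .catalog import ConditionCatalog, default_catalog
from .segmentation import ES_LABELS, LS_LABELS, SUBSEGMENT_LABELS

__all__ = [
    "DemographicParams",
    "UtilisationParams",
    "EpisodicParams",
    "SimulationConfig",
    "SyntheticBundle",
    "default_sim_config",
    "generate_population",
    "write_bundle",
]


class DemographicParams(BaseModel):
    model_config = ConfigDict(frozen=True)
    mean_age: float = Field(ge=0)
    sd_age: float = Field(default=15.0, ge=0)
    female: float = Field(ge=0, le=1)
    ethnicity: dict[str, float]


class UtilisationParams(BaseModel):
    """Per-segment annual utilisation means (counts, days, SGD)."""

    model_config = ConfigDict(frozen=True)
    ed_visits: float = Field(ge=0)
    soc_visits: float = Field(ge=0)
    inpatient_admissions: float = Field(ge=0)
    bed_days: float = Field(ge=0)
    annual_cost: float = Field(ge=0)


class EpisodicParams(BaseModel):
    """Per-episodic-segment admission outcome parameters."""

    model_config = ConfigDict(frozen=True)
    mean_los: float = Field(gt=0)
    mean_cost: float = Field(ge=0)
    readmit_prob: float = Field(ge=0, le=1)


# Published per-segment profile means (mean age, share female, ethnicity mix)
_DEMOGRAPHICS: dict[str, DemographicParams] = {
    "LS1": DemographicParams(mean_age=38.9, female=0.493,
                             ethnicity={"Chinese": 0.599, "Malay": 0.115, "Indian": 0.119, "Others": 0.167}),
    "LS2": DemographicParams(mean_age=37.2, female=0.499,
                             ethnicity={"Chinese": 0.303, "Malay": 0.390, "Indian": 0.145, "Others": 0.162}),
    "LS3": DemographicParams(mean_age=56.7, female=0.503,
                             ethnicity={"Chinese": 0.688, "Malay": 0.119, "Indian": 0.105, "Others": 0.088}),
    "LS4": DemographicParams(mean_age=61.4, female=0.569,
                             ethnicity={"Chinese": 0.659, "Malay": 0.163, "Indian": 0.107, "Others": 0.071}),
    "LS5": DemographicParams(mean_age=63.7, female=0.446,
                             ethnicity={"Chinese": 0.622, "Malay": 0.165, "Indian": 0.133, "Others": 0.080}),
    "LS6": DemographicParams(mean_age=67.6, female=0.496,
                             ethnicity={"Chinese": 0.606, "Malay": 0.188, "Indian": 0.127, "Others": 0.079}),
    "LS7": DemographicParams(mean_age=76.9, female=0.467,
                             ethnicity={"Chinese": 0.696, "Malay": 0.131, "Indian": 0.070, "Others": 0.103}),
}

# Published per-sub-segment utilisation/cost means; LS1/LS2/LS7 values are
# fill-ins for segments the published table does not cover (documented in the
# methods note) so that every resident has a generating distribution.
_UTILISATION: dict[str, UtilisationParams] = {
    "A1": UtilisationParams(ed_visits=0.6, soc_visits=2.0, inpatient_admissions=0.3, bed_days=0.7, annual_cost=1941),
    "A2": UtilisationParams(ed_visits=0.4, soc_visits=2.7, inpatient_admissions=0.4, bed_days=0.8, annual_cost=2538),
    "A3": UtilisationParams(ed_visits=0.9, soc_visits=3.0, inpatient_admissions=0.5, bed_days=2.3, annual_cost=3981),
    "A4": UtilisationParams(ed_visits=0.9, soc_visits=3.5, inpatient_admissions=0.7, bed_days=4.8, annual_cost=6955),
    "A5": UtilisationParams(ed_visits=1.6, soc_visits=3.7, inpatient_admissions=1.0, bed_days=9.5, annual_cost=10682),
    "B1": UtilisationParams(ed_visits=0.7, soc_visits=2.6, inpatient_admissions=0.6, bed_days=2.8, annual_cost=5432),
    "B2": UtilisationParams(ed_visits=0.7, soc_visits=3.4, inpatient_admissions=0.7, bed_days=2.7, annual_cost=6018),
    "B3": UtilisationParams(ed_visits=1.3, soc_visits=3.5, inpatient_admissions=1.1, bed_days=8.1, annual_cost=10399),
    "B4": UtilisationParams(ed_visits=1.1, soc_visits=4.9, inpatient_admissions=1.3, bed_days=9.9, annual_cost=14524),
    "B5": UtilisationParams(ed_visits=2.1, soc_visits=4.8, inpatient_admissions=2.0, bed_days=22.6, annual_cost=23356),
    "LS1": UtilisationParams(ed_visits=0.1, soc_visits=0.3, inpatient_admissions=0.05, bed_days=0.2, annual_cost=500),
    "LS2": UtilisationParams(ed_visits=0.2, soc_visits=0.5, inpatient_admissions=0.1, bed_days=0.4, annual_cost=900),
    "LS7": UtilisationParams(ed_visits=1.5, soc_visits=3.0, inpatient_admissions=1.8, bed_days=25.0, annual_cost=24000),
}

# Published per-episodic-segment admission outcomes
_EPISODIC: dict[str, EpisodicParams] = {
    "ES1": EpisodicParams(mean_los=2.2, mean_cost=3283, readmit_prob=0.014),
    "ES2": EpisodicParams(mean_los=4.3, mean_cost=5571, readmit_prob=0.053),
    "ES3": EpisodicParams(mean_los=8.2, mean_cost=8384, readmit_prob=0.163),
    "ES4": EpisodicParams(mean_los=6.7, mean_cost=14314, readmit_prob=0.068),
    "ES5": EpisodicParams(mean_los=11.8, mean_cost=17298, readmit_prob=0.161),
    "ES6": EpisodicParams(mean_los=10.7, mean_cost=10655, readmit_prob=0.299),
}

# Published shares: Living Well 43.1%, Early Disease 33.0%; the chronic block
# (LS3-LS6) totals 55.2% of the cohort.  The remaining segment shares are
# fill-ins chosen once to respect those anchors and sum to one.
_LS_PREVALENCE = {
    "LS1": 0.431, "LS2": 0.010, "LS3": 0.330, "LS4": 0.090,
    "LS5": 0.080, "LS6": 0.052, "LS7": 0.007,
}
_EARLY_SUBSEGMENTS = {"A1": 0.42, "A2": 0.35, "A3": 0.09, "A4": 0.09, "A5": 0.05}
_ADVANCED_SUBSEGMENTS = {"B1": 0.30, "B2": 0.30, "B3": 0.16, "B4": 0.14, "B5": 0.10}

_MENTAL_CODES = ("F329", "F419", "F200", "F319", "F039")
_UNLISTED_CODES = ("Z000", "Z018", "R51", "J069")  # routine / acute, not chronic


class SimulationConfig(BaseModel):
    """Cohort size, planted prevalences, and outcome-generating parameters."""

    model_config = ConfigDict(frozen=True)

    n_residents: int = Field(default=20_000, ge=0)
    seed: int = 0
    observation_year: int = 2022
    ls_prevalence: dict[str, float] = dict(_LS_PREVALENCE)
    early_subsegment_prevalence: dict[str, float] = dict(_EARLY_SUBSEGMENTS)
    advanced_subsegment_prevalence: dict[str, float] = dict(_ADVANCED_SUBSEGMENTS)
    demographics: dict[str, DemographicParams] = dict(_DEMOGRAPHICS)
    utilisation: dict[str, UtilisationParams] = dict(_UTILISATION)
    episodic: dict[str, EpisodicParams] = dict(_EPISODIC)
    admission_rate: float = Field(default=1.0, ge=0)
    pacs_probs: dict[int, float] = {1: 0.15, 2: 0.55, 3: 0.20, 4: 0.10}
    count_dispersion: float = Field(default=0.3, ge=0)  # NB2 alpha: var = mu + alpha*mu^2
    cost_cv: float = Field(default=1.0, gt=0)
    p_unlisted_code: float = Field(default=0.2, ge=0, le=1)
    p_cfs_recorded: float = Field(default=0.3, ge=0, le=1)  # for non-frail residents

    @model_validator(mode="after")
    def _check_distributions(self) -> "SimulationConfig":
        for name, dist, labels in (
            ("ls_prevalence", self.ls_prevalence, set(LS_LABELS)),
            ("early_subsegment_prevalence", self.early_subsegment_prevalence,
             {s for s in SUBSEGMENT_LABELS if s.startswith("A")}),
            ("advanced_subsegment_prevalence", self.advanced_subsegment_prevalence,
             {s for s in SUBSEGMENT_LABELS if s.startswith("B")}),
        ):
            if set(dist) != labels:
                raise ValueError(f"{name} must cover exactly {sorted(labels)}")
            if any(p < 0 or p > 1 for p in dist.values()):
                raise ValueError(f"{name} probabilities must lie in [0,1]")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if abs(sum(self.pacs_probs.values()) - 1.0) > 1e-9 or set(self.pacs_probs) != {1, 2, 3, 4}:
            raise ValueError("pacs_probs must cover PACS 1-4 and sum to 1")
        if set(self.episodic) != set(ES_LABELS):
            raise ValueError(f"episodic params must cover {ES_LABELS}")
        return self


def default_sim_config(n_residents: int = 20_000, seed: int = 0, **overrides) -> SimulationConfig:
    """The default study conditions: published table cells plus documented fill-ins."""
    return SimulationConfig(n_residents=n_residents, seed=seed, **overrides)


@dataclass
class SyntheticBundle:
    """Generated tables plus the planted ground-truth labels."""

    residents: pd.DataFrame
    diagnoses: pd.DataFrame
    encounters: pd.DataFrame
    admissions: pd.DataFrame
    truth_lifelong: pd.DataFrame  # resident_id, ls, subsegment
    truth_episodic: pd.DataFrame  # admission_id, es


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _planted_es(ls: str, pacs: int) -> str:
    # generation-side label table, kept independent of the rule engine
    if ls == "LS7":
        return "ES6"
    overlay = ls in ("LS2", "LS4", "LS6")
    if pacs in (3, 4):
        return "ES1"
    if pacs == 2:
        return "ES3" if overlay else "ES2"
    return "ES5" if overlay else "ES4"


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if mean <= 0:
        return 0
    if alpha <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / alpha
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _nb_p0(mean: float, alpha: float) -> float:
    if mean <= 0:
        return 1.0
    if alpha <= 0:
        return math.exp(-mean)
    r = 1.0 / alpha
    return (r / (r + mean)) ** r


def _gamma_draw(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean <= 0:
        return 0.0
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def _condition_codes(catalog: ConditionCatalog) -> tuple[list[str], dict[str, str], dict[str, str]]:
    """Per-condition example codes: an early-stage code for every condition and
    an advanced-marker code where the catalog defines one."""
    early: dict[str, str] = {}
    advanced: dict[str, str] = {}
    for entry in catalog.entries:
        for prefix in entry.icd10_prefixes:
            for cand in (prefix + "9", prefix + "0", prefix):
                hit = catalog.lookup(cand)
                if hit == (entry.condition_id, False):
                    early[entry.condition_id] = cand
                    break
            if entry.condition_id in early:
                break
        for marker in entry.advanced_marker_prefixes:
            cand = marker if len(marker) >= 3 else marker + "0"
            hit = catalog.lookup(cand)
            if hit == (entry.condition_id, True):
                advanced[entry.condition_id] = cand
                break
    usable = sorted(early)  # conditions that can appear at the early stage
    return usable, early, advanced


def _restrict(dist: dict[str, float], keys: tuple[str, ...]) -> tuple[list[str], np.ndarray]:
    labels = [k for k in keys if dist.get(k, 0) > 0]
    w = np.array([dist[k] for k in labels], dtype=float)
    return labels, w / w.sum()


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def generate_population(
    config: SimulationConfig, catalog: ConditionCatalog | None = None
) -> SyntheticBundle:
    """Generate a fully labelled cohort; byte-reproducible under (seed, config).

    Residents are drawn segment-first (lifelong prevalences, then the
    sub-segment conditional restricted to the digits compatible with the
    drawn lifelong segment), and records are constructed to satisfy exactly
    the planted label: e.g. an LS4/A5 resident receives at least one
    early-stage somatic code with no advanced marker or complication flag,
    one mental-health (F-chapter) code, a social-issue proxy, and a CFS of at
    most 7 when recorded.
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)
    usable_conditions, early_code, advanced_code = _condition_codes(catalog)
    year = config.observation_year
    year_start = date(year, 1, 1)

    ls_labels, ls_p = _restrict(config.ls_prevalence, LS_LABELS)
    sub_by_ls = {
        "LS3": _restrict(config.early_subsegment_prevalence, ("A1", "A2")),
        "LS4": _restrict(config.early_subsegment_prevalence, ("A3", "A4", "A5")),
        "LS5": _restrict(config.advanced_subsegment_prevalence, ("B1", "B2")),
        "LS6": _restrict(config.advanced_subsegment_prevalence, ("B3", "B4", "B5")),
    }
    pacs_values = np.array(sorted(config.pacs_probs))
    pacs_p = np.array([config.pacs_probs[v] for v in pacs_values], dtype=float)

    res_rows, diag_rows, enc_rows, adm_rows = [], [], [], []
    truth_ls_rows, truth_es_rows = [], []

    n_ls = rng.multinomial(config.n_residents, ls_p) if config.n_residents else np.zeros(
        len(ls_labels), dtype=int)
    planted_ls = np.repeat(ls_labels, n_ls)
    rng.shuffle(planted_ls)

    alpha = config.count_dispersion
    cv = config.cost_cv

    for i, ls in enumerate(planted_ls):
        rid = f"R{i:06d}"
        sub = None
        if ls in sub_by_ls:
            labels, p = sub_by_ls[ls]
            sub = str(labels[int(rng.choice(len(labels), p=p))])
        digit = int(sub[1]) if sub else 0
        advanced_stage = ls in ("LS5", "LS6")
        has_mental = digit in (3, 5)
        has_social = digit in (4, 5) or ls == "LS2"

        # demographics
        demo = config.demographics[ls]
        age = float(np.clip(rng.normal(demo.mean_age, demo.sd_age), 0.0, 105.0))
        sex = "F" if rng.random() < demo.female else "M"
        eth_labels = sorted(demo.ethnicity)
        eth_w = np.array([demo.ethnicity[k] for k in eth_labels], dtype=float)
        ethnicity = eth_labels[int(rng.choice(len(eth_labels), p=eth_w / eth_w.sum()))]

        # frailty: planted LS7 residents sit above the cut-off; everyone else
        # is either unrecorded or at most 7
        if ls == "LS7":
            cfs: int | None = int(rng.integers(8, 10))
        elif rng.random() < config.p_cfs_recorded:
            cfs = int(rng.integers(1, 8))
        else:
            cfs = None

        rental = False
        add_msw = False
        if has_social:
            if rng.random() < 0.5:
                rental = True
            else:
                add_msw = True

        # chronic conditions; LS7 residents get advanced disease history so the
        # frailty rule is what distinguishes them
        condition_stage_advanced = advanced_stage or ls == "LS7"
        if ls in ("LS1", "LS2"):
            n_cond = 0
        elif digit == 1:
            n_cond = 1
        elif digit == 2:
            n_cond = int(rng.integers(2, 5))
        elif digit in (3, 4, 5):
            n_cond = int(rng.integers(1, 5))
        else:  # LS7
            n_cond = int(rng.integers(1, 4))
        chosen = (
            [usable_conditions[j] for j in rng.choice(len(usable_conditions), size=n_cond,
                                                      replace=False)]
            if n_cond else []
        )
        for k, cond in enumerate(chosen):
            dx_date = year_start - timedelta(days=int(rng.integers(0, 7 * 365)))
            make_advanced = condition_stage_advanced and k == 0
            if make_advanced and cond in advanced_code:
                diag_rows.append((rid, advanced_code[cond], dx_date.isoformat(),
                                  "primary", False))
            elif make_advanced:
                diag_rows.append((rid, early_code[cond], dx_date.isoformat(),
                                  "primary", True))  # staged via complication flag
            else:
                diag_rows.append((rid, early_code[cond], dx_date.isoformat(),
                                  "secondary", False))
        if has_mental:
            code = _MENTAL_CODES[int(rng.integers(len(_MENTAL_CODES)))]
            dx_date = year_start - timedelta(days=int(rng.integers(0, 7 * 365)))
            diag_rows.append((rid, code, dx_date.isoformat(), "secondary", False))
        if rng.random() < config.p_unlisted_code:
            code = _UNLISTED_CODES[int(rng.integers(len(_UNLISTED_CODES)))]
            dx_date = year_start - timedelta(days=int(rng.integers(0, 3 * 365)))
            diag_rows.append((rid, code, dx_date.isoformat(), "secondary", False))

        res_rows.append((rid, round(age, 1), sex, ethnicity, rental,
                         "" if cfs is None else cfs))
        truth_ls_rows.append((rid, ls, sub or ""))

        # annual utilisation in the observation year
        util = config.utilisation[sub or ls]
        n_ed = _nb_draw(rng, util.ed_visits, alpha)
        n_soc = _nb_draw(rng, util.soc_visits, alpha)
        n_ip = _nb_draw(rng, util.inpatient_admissions, alpha)
        visits: list[tuple[str, float]] = (
            [("ED", 0.0)] * n_ed + [("SOC", 0.0)] * n_soc + [("INPATIENT", 0.0)] * n_ip
        )
        if add_msw:
            visits.append(("MSW", 0.0))

        p_ip_any = 1.0 - _nb_p0(util.inpatient_admissions, alpha)
        total_bed_days = (
            _gamma_draw(rng, util.bed_days / p_ip_any, cv) if n_ip > 0 and p_ip_any > 0 else 0.0
        )
        if add_msw:
            p_any = 1.0
        else:
            p_any = 1.0 - (_nb_p0(util.ed_visits, alpha) * _nb_p0(util.soc_visits, alpha)
                           * _nb_p0(util.inpatient_admissions, alpha))
        total_cost = (
            _gamma_draw(rng, util.annual_cost / p_any, cv) if visits and p_any > 0 else 0.0
        )
        if visits:
            cost_each = total_cost / len(visits)
            bed_each = total_bed_days / n_ip if n_ip else 0.0
            for channel, _ in visits:
                day = year_start + timedelta(days=int(rng.integers(0, 365)))
                enc_rows.append((rid, day.isoformat(), channel,
                                 round(cost_each, 2),
                                 round(bed_each, 3) if channel == "INPATIENT" else 0.0))

        # emergency admission episodes
        n_adm = int(rng.poisson(config.admission_rate))
        for k in range(n_adm):
            pacs = int(pacs_values[int(rng.choice(len(pacs_values), p=pacs_p))])
            es = _planted_es(ls, pacs)
            ep = config.episodic[es]
            los = max(_gamma_draw(rng, ep.mean_los, cv), 1e-3)
            adm_cost = _gamma_draw(rng, ep.mean_cost, cv)
            readmit = bool(rng.random() < ep.readmit_prob)
            day = year_start + timedelta(days=int(rng.integers(0, 365)))
            aid = f"A{i:06d}_{k}"
            adm_rows.append((aid, rid, day.isoformat(), pacs,
                             round(los, 4), round(adm_cost, 2), readmit))
            truth_es_rows.append((aid, es))

    residents = pd.DataFrame(res_rows, columns=[
        "resident_id", "age", "sex", "ethnicity", "rental_housing", "cfs"])
    residents["cfs"] = pd.to_numeric(residents["cfs"], errors="coerce").astype("Int64")
    diagnoses = pd.DataFrame(diag_rows, columns=[
        "resident_id", "icd10_code", "date", "priority", "complication_flag"])
    encounters = pd.DataFrame(enc_rows, columns=[
        "resident_id", "date", "channel", "cost", "bed_days"])
    admissions = pd.DataFrame(adm_rows, columns=[
        "admission_id", "resident_id", "admit_date", "pacs", "length_of_stay",
        "cost", "readmit_30d"])
    truth_lifelong = pd.DataFrame(truth_ls_rows, columns=["resident_id", "ls", "subsegment"])
    truth_episodic = pd.DataFrame(truth_es_rows, columns=["admission_id", "es"])
    return SyntheticBundle(residents, diagnoses, encounters, admissions,
                           truth_lifelong, truth_episodic)


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Write the four input CSVs plus the planted truth tables; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "residents": bundle.residents,
        "diagnoses": bundle.diagnoses,
        "encounters": bundle.encounters,
        "admissions": bundle.admissions,
        "truth_labels": bundle.truth_lifelong,
        "truth_episodes": bundle.truth_episodic,
    }
    paths: dict[str, Path] = {}
    for name, df in files.items():
        path = directory / f"{name}.csv"
        try:
            df.to_csv(path, index=False)
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        paths[name] = path
    return paths
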