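"""Rule cascade: profile derivation, LS/NBSS/ES assignment, population driver."""

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ucmseg as u
from ucmseg.segmentation import PSYCHOSOCIAL_LS, SegmentationError, Stage

RES = u.ResidentRecord(resident_id="r1", age=50.0)
D = date(2022, 6, 1)


def _profile(stage=Stage.NONE, mental=False, social=False, cfs=None, n_chronic=0):
    conditions = frozenset(f"cond{i}" for i in range(n_chronic))
    return u.ClinicalProfile(
        resident_id="r1", conditions=conditions, stage=stage,
        has_mental=mental, has_social=social, cfs=cfs, cci=0,
    )


# ---------------------------------------------------------------------------
# profile derivation
# ---------------------------------------------------------------------------

def test_mental_only_profile(catalog, seg_config):
    diag = [u.DiagnosisEvent("r1", "F320")]
    prof = u.derive_clinical_profile(RES, diag, [], catalog, seg_config)
    assert prof.conditions == frozenset()
    assert prof.stage is Stage.NONE
    assert prof.has_mental and not prof.has_social


def test_early_disease_with_msw_visit(catalog, seg_config):
    diag = [u.DiagnosisEvent("r1", "E119")]
    enc = [u.EncounterEvent("r1", D, "MSW")]
    prof = u.derive_clinical_profile(RES, diag, enc, catalog, seg_config)
    assert prof.n_chronic == 1
    assert prof.stage is Stage.EARLY
    assert prof.has_social


def test_complication_flag_promotes_to_advanced(catalog, seg_config):
    diag = [u.DiagnosisEvent("r1", "E1121", complication_flag=True)]
    prof = u.derive_clinical_profile(RES, diag, [], catalog, seg_config)
    assert prof.stage is Stage.ADVANCED


def test_complication_flag_on_unlisted_code_is_ignored(catalog, seg_config):
    diag = [u.DiagnosisEvent("r1", "Z000", complication_flag=True)]
    prof = u.derive_clinical_profile(RES, diag, [], catalog, seg_config)
    assert prof.stage is Stage.NONE
    assert prof.unmatched_codes == ("Z000",)


def test_rental_housing_sets_social_flag(catalog, seg_config):
    rental = u.ResidentRecord("r1", 40.0, rental_housing=True)
    prof = u.derive_clinical_profile(rental, [], [], catalog, seg_config)
    assert prof.has_social


def test_social_sources_configurable(catalog):
    cfg = u.SegmentationConfig(social_sources=frozenset({"MSW_VISIT"}))
    rental = u.ResidentRecord("r1", 40.0, rental_housing=True)
    prof = u.derive_clinical_profile(rental, [], [], catalog, cfg)
    assert not prof.has_social


def test_foreign_event_rejected(catalog, seg_config):
    with pytest.raises(SegmentationError):
        u.derive_clinical_profile(RES, [u.DiagnosisEvent("other", "E119")], [],
                                  catalog, seg_config)


def test_cci_attached_to_profile(catalog, seg_config, cci_table):
    diag = [u.DiagnosisEvent("r1", "I21"), u.DiagnosisEvent("r1", "I509")]
    prof = u.derive_clinical_profile(RES, diag, [], catalog, seg_config, cci_table)
    assert prof.cci == 2  # infarction + heart failure


# ---------------------------------------------------------------------------
# lifelong segment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("profile,expected", [
    (_profile(), "LS1"),
    (_profile(social=True), "LS2"),
    (_profile(stage=Stage.EARLY, n_chronic=1), "LS3"),
    (_profile(stage=Stage.EARLY, n_chronic=1, social=True), "LS4"),
    (_profile(stage=Stage.EARLY, n_chronic=2, mental=True), "LS4"),
    (_profile(stage=Stage.ADVANCED, n_chronic=1), "LS5"),
    (_profile(stage=Stage.ADVANCED, n_chronic=1, mental=True, social=True), "LS6"),
    (_profile(stage=Stage.ADVANCED, n_chronic=2, cfs=8), "LS7"),
    (_profile(cfs=9), "LS7"),
    (_profile(cfs=7), "LS1"),  # at the boundary the frailty rule does not fire
    (_profile(mental=True), "LS1"),  # mental-only: LS2 is social-only by default
])
def test_lifelong_assignment(profile, expected, seg_config):
    ls, fired = u.assign_lifelong_segment(profile, seg_config)
    assert ls == expected
    assert fired


def test_mental_only_routing_switch():
    cfg = u.SegmentationConfig(route_mental_only_to_ls4=True)
    ls, _ = u.assign_lifelong_segment(_profile(mental=True), cfg)
    assert ls == "LS4"
    assert u.assign_subsegment(_profile(mental=True), "LS4", cfg) == "A3"


def test_frailty_threshold_configurable():
    cfg = u.SegmentationConfig(cfs_leaving_well_threshold=5)
    assert u.assign_lifelong_segment(_profile(cfs=6), cfg)[0] == "LS7"


# ---------------------------------------------------------------------------
# sub-segment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("profile,ls,expected", [
    (_profile(stage=Stage.EARLY, n_chronic=1), "LS3", "A1"),
    (_profile(stage=Stage.EARLY, n_chronic=3), "LS3", "A2"),
    (_profile(stage=Stage.EARLY, n_chronic=2, mental=True), "LS4", "A3"),
    (_profile(stage=Stage.EARLY, n_chronic=1, social=True), "LS4", "A4"),
    (_profile(stage=Stage.ADVANCED, n_chronic=1), "LS5", "B1"),
    (_profile(stage=Stage.ADVANCED, n_chronic=3, mental=True, social=True), "LS6", "B5"),
    (_profile(), "LS1", None),
    (_profile(social=True), "LS2", None),
    (_profile(stage=Stage.ADVANCED, n_chronic=2, cfs=9), "LS7", None),
])
def test_subsegment_assignment(profile, ls, expected, seg_config):
    assert u.assign_subsegment(profile, ls, seg_config) == expected


def test_subsegment_inconsistency_error(seg_config):
    with pytest.raises(SegmentationError):
        u.assign_subsegment(_profile(), "LS3", seg_config)


def test_psychosocial_requires_multiple_switch():
    cfg = u.SegmentationConfig(psychosocial_requires_multiple=True)
    single_mental = _profile(stage=Stage.EARLY, n_chronic=1, mental=True)
    assert u.assign_subsegment(single_mental, "LS4", cfg) == "A1"
    multi_mental = _profile(stage=Stage.EARLY, n_chronic=2, mental=True)
    assert u.assign_subsegment(multi_mental, "LS4", cfg) == "A3"


# ---------------------------------------------------------------------------
# episodic segment
# ---------------------------------------------------------------------------

def _admission(pacs):
    return u.AdmissionEpisode("a1", "r1", D, pacs=pacs, length_of_stay=3.0)


@pytest.mark.parametrize("ls,pacs,expected", [
    ("LS7", 1, "ES6"),
    ("LS7", 4, "ES6"),
    ("LS4", 2, "ES3"),
    ("LS3", 2, "ES2"),
    ("LS3", 1, "ES4"),
    ("LS6", 1, "ES5"),
    ("LS1", 4, "ES1"),
    ("LS2", 3, "ES1"),
])
def test_episodic_assignment(ls, pacs, expected, seg_config):
    assignment = u.LifelongAssignment("r1", ls, None)
    assert u.assign_episodic_segment(_admission(pacs), assignment, seg_config) == expected


def test_invalid_pacs_rejected():
    with pytest.raises(SegmentationError):
        _admission(9)


# ---------------------------------------------------------------------------
# oracle equivalence and MECE over the whole rule space
# ---------------------------------------------------------------------------

def _oracle_ls(stage, mental, social, cfs):
    """Independent lookup-table formulation of the lifelong rules."""
    if cfs is not None and cfs >= 8:
        return "LS7"
    tier = {("ADVANCED", True): "LS6", ("ADVANCED", False): "LS5",
            ("EARLY", True): "LS4", ("EARLY", False): "LS3"}
    if stage in ("ADVANCED", "EARLY"):
        return tier[(stage, mental or social)]
    return "LS2" if social else "LS1"


def _oracle_sub(ls, stage, mental, social, n_chronic):
    if ls not in ("LS3", "LS4", "LS5", "LS6"):
        return None
    digit = {(True, True): "5", (False, True): "4", (True, False): "3"}.get(
        (mental, social), "2" if n_chronic >= 2 else "1")
    return ("B" if stage == "ADVANCED" else "A") + digit


_ORACLE_ES = {  # exhaustive (ls, pacs) -> es literal table
    **{("LS7", p): "ES6" for p in (1, 2, 3, 4)},
    **{(ls, 4): "ES1" for ls in ("LS1", "LS2", "LS3", "LS4", "LS5", "LS6")},
    **{(ls, 3): "ES1" for ls in ("LS1", "LS2", "LS3", "LS4", "LS5", "LS6")},
    ("LS1", 2): "ES2", ("LS3", 2): "ES2", ("LS5", 2): "ES2",
    ("LS2", 2): "ES3", ("LS4", 2): "ES3", ("LS6", 2): "ES3",
    ("LS1", 1): "ES4", ("LS3", 1): "ES4", ("LS5", 1): "ES4",
    ("LS2", 1): "ES5", ("LS4", 1): "ES5", ("LS6", 1): "ES5",
}


def _consistent_profiles():
    """The full consistent cross-product of rule inputs."""
    for stage in Stage:
        for mental in (False, True):
            for social in (False, True):
                for cfs in (None, 1, 4, 7, 8, 9):
                    for n_chronic in (0, 1, 2, 3):
                        if (stage is Stage.NONE) != (n_chronic == 0):
                            continue
                        yield _profile(stage=stage, mental=mental, social=social,
                                       cfs=cfs, n_chronic=n_chronic)


def test_rule_engine_matches_brute_force_oracle(seg_config):
    ls_seen, sub_seen, es_seen = set(), set(), set()
    for prof in _consistent_profiles():
        ls, _ = u.assign_lifelong_segment(prof, seg_config)
        assert ls == _oracle_ls(prof.stage.value, prof.has_mental, prof.has_social,
                                prof.cfs)
        sub = u.assign_subsegment(prof, ls, seg_config)
        assert sub == _oracle_sub(ls, prof.stage.value, prof.has_mental,
                                  prof.has_social, prof.n_chronic)
        ls_seen.add(ls)
        if sub:
            sub_seen.add(sub)
        for pacs in (1, 2, 3, 4):
            assignment = u.LifelongAssignment(prof.resident_id, ls, sub)
            es = u.assign_episodic_segment(_admission(pacs), assignment, seg_config)
            assert es == _ORACLE_ES[(ls, pacs)]
            es_seen.add(es)
    assert ls_seen == set(u.LS_LABELS)
    assert sub_seen == set(u.SUBSEGMENT_LABELS)
    assert es_seen == set(u.ES_LABELS)


@given(
    stage=st.sampled_from(list(Stage)),
    mental=st.booleans(),
    social=st.booleans(),
    cfs=st.one_of(st.none(), st.integers(1, 9)),
    n_extra=st.integers(0, 5),
    pacs=st.integers(1, 4),
)
@settings(max_examples=1000, deadline=None, derandomize=True)
def test_mece_every_input_gets_exactly_one_label(stage, mental, social, cfs,
                                                 n_extra, pacs):
    """Any consistent profile receives exactly one LS label; a sub-label exists
    iff LS3-LS6; every admission receives exactly one ES label."""
    n_chronic = 0 if stage is Stage.NONE else 1 + n_extra
    prof = _profile(stage=stage, mental=mental, social=social, cfs=cfs,
                    n_chronic=n_chronic)
    cfg = u.SegmentationConfig()
    ls, _ = u.assign_lifelong_segment(prof, cfg)
    assert ls in u.LS_LABELS
    sub = u.assign_subsegment(prof, ls, cfg)
    assert (sub is not None) == (ls in ("LS3", "LS4", "LS5", "LS6"))
    if sub is not None:
        assert sub in u.SUBSEGMENT_LABELS
        assert sub[0] == ("B" if stage is Stage.ADVANCED else "A")
    es = u.assign_episodic_segment(_admission(pacs),
                                   u.LifelongAssignment("r1", ls, sub), cfg)
    assert es in u.ES_LABELS
    assert (es == "ES6") == (ls == "LS7")
    if ls in PSYCHOSOCIAL_LS:
        assert es in ("ES1", "ES3", "ES5", "ES6")


# ---------------------------------------------------------------------------
# population driver
# ---------------------------------------------------------------------------

def _tiny_tables():
    residents = pd.DataFrame({
        "resident_id": ["healthy", "early_rental", "frail"],
        "age": [30, 55, 85],
        "sex": ["F", "M", "F"],
        "ethnicity": ["Chinese"] * 3,
        "rental_housing": [False, True, False],
        "cfs": [None, None, 9],
    })
    diagnoses = pd.DataFrame({
        "resident_id": ["early_rental", "frail"],
        "icd10_code": ["E119", "I21"],
        "complication_flag": [False, False],
    })
    encounters = pd.DataFrame(columns=["resident_id", "date", "channel", "cost", "bed_days"])
    admissions = pd.DataFrame({
        "admission_id": ["a1", "a2"],
        "resident_id": ["early_rental", "frail"],
        "admit_date": ["2022-03-01", "2022-04-01"],
        "pacs": [2, 1],
        "length_of_stay": [3.0, 10.0],
        "cost": [1000.0, 9000.0],
        "readmit_30d": [False, True],
    })
    return residents, diagnoses, encounters, admissions


def test_segment_population_hand_example(catalog, seg_config):
    residents, diagnoses, encounters, admissions = _tiny_tables()
    result = u.segment_population(residents, diagnoses, encounters, admissions,
                                  catalog, seg_config)
    labels = dict(zip(result.lifelong["resident_id"], result.lifelong["ls"]))
    assert labels == {"healthy": "LS1", "early_rental": "LS4", "frail": "LS7"}
    es = dict(zip(result.episodic["admission_id"], result.episodic["es"]))
    assert es == {"a1": "ES3", "a2": "ES6"}
    subs = dict(zip(result.lifelong["resident_id"], result.lifelong["subsegment"]))
    assert subs["early_rental"] == "A4" and subs["healthy"] is None


def test_segment_population_empty_inputs(catalog, seg_config):
    residents = pd.DataFrame(columns=["resident_id", "age"])
    empty = pd.DataFrame(columns=["resident_id"])
    admissions = pd.DataFrame(columns=["admission_id", "resident_id", "admit_date",
                                       "pacs", "length_of_stay"])
    result = u.segment_population(residents, empty, empty, admissions, catalog, seg_config)
    assert result.lifelong.empty and result.episodic.empty
    assert result.diagnostics["n_excluded"] == 0


def test_segment_population_orphan_admission_excluded(catalog, seg_config):
    residents, diagnoses, encounters, admissions = _tiny_tables()
    admissions.loc[len(admissions)] = ["a3", "ghost", "2022-05-01", 2, 1.0, 0.0, False]
    result = u.segment_population(residents, diagnoses, encounters, admissions,
                                  catalog, seg_config)
    assert len(result.episodic) == 2
    assert result.diagnostics["n_excluded"] == 1
    assert "ghost" in result.diagnostics["excluded_records"][0]["reason"]


def test_segment_population_duplicate_resident_rejected(catalog, seg_config):
    residents, diagnoses, encounters, admissions = _tiny_tables()
    residents = pd.concat([residents, residents.iloc[[0]]], ignore_index=True)
    with pytest.raises(SegmentationError, match="duplicate"):
        u.segment_population(residents, diagnoses, encounters, admissions,
                             catalog, seg_config)


def test_segment_population_row_order_invariant(catalog, seg_config):
    residents, diagnoses, encounters, admissions = _tiny_tables()
    base = u.segment_population(residents, diagnoses, encounters, admissions,
                                catalog, seg_config)
    shuffled = u.segment_population(
        residents.sample(frac=1, random_state=3),
        pd.concat([diagnoses, diagnoses]),  # duplicated diagnosis rows
        encounters,
        admissions.sample(frac=1, random_state=4),
        catalog, seg_config)
    pd.testing.assert_frame_equal(base.lifelong, shuffled.lifelong)
    pd.testing.assert_frame_equal(base.episodic, shuffled.episodic)


def test_mece_on_generated_cohort(small_bundle, catalog, seg_config):
    b = small_bundle
    result = u.segment_population(b.residents, b.diagnoses, b.encounters,
                                  b.admissions, catalog, seg_config)
    assert len(result.lifelong) == len(b.residents)
    assert result.lifelong["ls"].isin(u.LS_LABELS).all()
    counts = result.lifelong["ls"].value_counts().sum()
    assert counts == len(b.residents)
    chronic = result.lifelong["ls"].isin(["LS3", "LS4", "LS5", "LS6"])
    assert result.lifelong.loc[chronic, "subsegment"].notna().all()
    assert result.lifelong.loc[~chronic, "subsegment"].isna().all()
    assert len(result.episodic) == len(b.admissions)
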