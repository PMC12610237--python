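import pytest

import ucmseg as u


@pytest.fixture(scope="session")
def catalog():
    return u.default_catalog()


@pytest.fixture(scope="session")
def cci_table():
    return u.default_cci_table()


@pytest.fixture(scope="session")
def seg_config():
    return u.SegmentationConfig()


@pytest.fixture(scope="session")
def small_bundle():
    """A small labelled cohort for fast structural tests."""
    return u.generate_population(u.default_sim_config(n_residents=400, seed=11))


@pytest.fixture(scope="session")
def cohort20k(catalog, cci_table, seg_config):
    """One 20,000-resident cohort, segmented and summarised; shared across the
    calibration-recovery tests to keep the suite fast."""
    cfg = u.default_sim_config(n_residents=20_000, seed=1)
    bundle = u.generate_population(cfg)
    result = u.segment_population(
        bundle.residents, bundle.diagnoses, bundle.encounters, bundle.admissions,
        catalog, seg_config, cci_table,
    )
    ls_table, sub_table = u.summarise_by_segment(
        result.lifelong, bundle.residents, result.profiles, bundle.encounters)
    es_table = u.summarise_episodic(result.episodic, bundle.admissions)
    return {"config": cfg, "bundle": bundle, "result": result,
            "ls_table": ls_table, "sub_table": sub_table, "es_table": es_table}
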