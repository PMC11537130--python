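import numpy as np
import pandas as pd
import pytest

from metamodtrend import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_sim_config():
    return SimConfig(
        seed=11,
        n_patients=12,
        visits_per_patient=3,
        n_metabolites=60,
        module_sizes=(15, 12),
        affected_modules={0: -0.12},
        target_module=0,
        missing_rate=0.08,
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    """A reduced synthetic cohort for fast unit tests."""
    return generate_cohort(small_sim_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort (31 patients x 4 visits, 300 metabolites)."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture()
def toy_tables(tmp_path):
    """Tiny on-disk dataset: 4 samples / 2 patients / 3 metabolites."""
    abundance = pd.DataFrame(
        {
            "sample_id": ["p1_v1", "p1_v2", "p2_v1", "p2_v2"],
            "met_a": [1.0, 2.0, 3.0, 4.0],
            "met_b": [2.0, np.nan, 6.0, 8.0],
            "met_c": [5.0, 5.0, 5.0, 5.0],
        }
    )
    visits = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2", "p2"],
            "sample_id": ["p1_v1", "p1_v2", "p2_v1", "p2_v2"],
            "time_years": [0.0, 1.1, 0.0, 0.9],
        }
    )
    cohort = pd.DataFrame(
        {
            "patient_id": ["p1", "p2"],
            "age_baseline": [40.0, 50.0],
            "sex": [1, 0],
            "dmt_history": [1, 1],
        }
    )
    pathways = pd.DataFrame(
        {
            "metabolite_id": ["met_a", "met_b", "met_c"],
            "sub_pathway": ["pw1", "pw1", "pw2"],
            "super_pathway": ["sp", "sp", "sp"],
        }
    )
    clinical = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2", "p2"],
            "time_years": [0.0, 1.1, 0.0, 0.9],
            "edss": [2.0, 1.0, 3.5, 3.5],
            "t25fw_s": [6.0, 5.0, 7.0, 8.5],
            "hpt_dom_s": [25.0, 24.0, 30.0, 30.0],
            "hpt_nondom_s": [26.0, 25.0, 31.0, 31.0],
            "pst": [50.0, 52.0, 45.0, 44.0],
            "nqol_anxiety": [52.0, 45.0, 50.0, 51.0],
        }
    )
    paths = {}
    for name, df in [
        ("abundance", abundance),
        ("visits", visits),
        ("cohort", cohort),
        ("pathways", pathways),
        ("clinical", clinical),
    ]:
        path = tmp_path / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
        paths[name] = path
    return paths
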