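import numpy as np
import pytest

from treatmark import simulate
from treatmark.cohorts import PatientRecord


def make_patient(case_id="p0", project="SYN-A", sex="female",
                 vital_status="alive", time_years=2.0, drugs=(), age=60.0):
    return PatientRecord(case_id=case_id, project=project, sex=sex,
                         vital_status=vital_status, time_years=time_years,
                         drugs=frozenset(drugs), age=age)


def two_project_cohort(n_a=6, n_b=8, rng=None):
    """Project A female-only, project B both sexes (the two-project layout
    with one single-sex project)."""
    rng = rng or np.random.default_rng(0)
    patients = []
    for i in range(n_a):
        patients.append(make_patient(f"A{i}", "PROJ-A", "female",
                                     "dead" if i % 3 == 0 else "alive",
                                     float(rng.uniform(0.5, 10))))
    for i in range(n_b):
        patients.append(make_patient(f"B{i}", "PROJ-B",
                                     "female" if i % 2 == 0 else "male",
                                     "dead" if i % 3 == 0 else "alive",
                                     float(rng.uniform(0.5, 10))))
    return patients


@pytest.fixture(scope="session")
def default_cohort():
    """One full default synthetic cohort, shared across tests."""
    return simulate.generate_cohort(simulate.default_config(seed=2024))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast pipeline-level tests."""
    cfg = simulate.default_config(
        seed=7,
        projects={"SYN-A": {"female": 60}, "SYN-B": {"female": 50, "male": 60}},
        n_genes=60, n_cpgs=300,
        markers=simulate.default_markers(3, 3, 1, 1))
    return cfg, simulate.generate_cohort(cfg)
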