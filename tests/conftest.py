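import numpy as np
import pandas as pd
import pytest

from lupus_ssc import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests."""
    cfg = sim.SimulationConfig(
        n_patients=24,
        visits_min=4,
        visits_max=6,
        n_healthy=14,
        n_genes=240,
        n_activity_genes=30,
        seed=7,
    )
    return sim.generate_cohort(cfg)


@pytest.fixture()
def toy_clinical():
    """Two SLE patients (3 visits each) plus two healthy controls."""
    rows = []
    for pid, sledais in (("P1", [2, 4, 6]), ("P2", [8, 5, 3])):
        for v, s in enumerate(sledais):
            rows.append(
                dict(
                    patient_id=pid,
                    sample_id=f"{pid}V{v}",
                    visit_index=v,
                    time_days=30.0 * v,
                    sledai=s,
                    state="SLE",
                    age_group="pediatric",
                    sex="female",
                    race="white",
                    drug_cs=False,
                    drug_hc=False,
                    drug_is=False,
                    drug_ifnk=False,
                    cohort="toy",
                )
            )
    for h in ("H1", "H2"):
        rows.append(
            dict(
                patient_id=h,
                sample_id=f"{h}V0",
                visit_index=0,
                time_days=0.0,
                sledai=0,
                state="healthy",
                age_group="adult",
                sex="male",
                race="black",
                drug_cs=False,
                drug_hc=False,
                drug_is=False,
                drug_ifnk=False,
                cohort="toy",
            )
        )
    return pd.DataFrame(rows)


def truth_sample_labels(clinical: pd.DataFrame, truth) -> pd.Series:
    """Ground-truth subtype per SLE sample."""
    sle = clinical[clinical["state"] == "SLE"]
    return pd.Series(
        {r.sample_id: truth.subtype_of_patient[r.patient_id] for r in sle.itertuples()}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
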