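import numpy as np
import pandas as pd
import pytest

from immunodiffnet import (
    ClinicalTable,
    ImmuneProfileMatrix,
    PlantedBlock,
    SyntheticCohortConfig,
    generate_cohort,
)

INFLAMMATORY_BLOCK = ("IL6", "IL4", "TNFa", "IL1b", "IL17")


@pytest.fixture
def tiny_matrix():
    """2 markers x 3 patients, raw state."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]],
        index=["sBTLA", "IL6"], columns=["P01", "P02", "P03"])
    return ImmuneProfileMatrix(
        values=values,
        marker_kinds={"sBTLA": "checkpoint", "IL6": "cytokine"})


@pytest.fixture
def tiny_clinical():
    table = pd.DataFrame(
        {"response": ["R", "NR", "R"],
         "performance_status": ["PS0", "PSgt0", "PS0"],
         "os_months": [10.0, 2.0, 24.0]},
        index=pd.Index(["P01", "P02", "P03"], name="patient_id"))
    return ClinicalTable(table=table)


@pytest.fixture
def planted_cohort():
    """Default-margin 27-patient cohort with one rho=0.9 block in NR."""
    cfg = SyntheticCohortConfig(planted_blocks=(
        PlantedBlock(markers=INFLAMMATORY_BLOCK, contrast="response",
                     condition="NR", rho=0.9),))
    return generate_cohort(cfg, seed=7)


def make_estimate(r, n, p):
    """Correlation-estimate stub for classification tests."""
    from immunodiffnet import CorrelationEstimate
    z = float(np.arctanh(np.clip(r, -0.999999, 0.999999)))
    return CorrelationEstimate(r=r, n=n, p=p, z=z, se_z=1.0 / np.sqrt(n - 3))
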