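import numpy as np
import pandas as pd
import pytest

from mirfingerprint.containers import CtMatrix, CountMatrix, SampleSheet
from mirfingerprint.synthetic import SimulationSpec, simulate_qpcr_cohort


@pytest.fixture
def noise_free_spec():
    """Deterministic two-assay design: assayA has FC=2, assayB null."""
    return SimulationSpec(
        cohorts=("1",),
        n_case=3,
        n_control=3,
        assay_effects={"assayA": {"1": 2.0}, "assayB": {"1": 1.0}},
        n_reference_genes=3,
        reference_noise_sd=0.0,
        target_noise_sd=0.0,
        load_shift_sd=0.0,
        hemolysis_fraction=0.0,
        spikein_sd=0.0,
        seed=0,
        fixed_base_ct={},
    )


@pytest.fixture
def small_cohort():
    """One simulated cohort with mild noise, used across module tests."""
    spec = SimulationSpec(seed=11)
    ct, sheet, truth = simulate_qpcr_cohort(spec, "1")
    return ct, sheet, truth


@pytest.fixture
def tiny_ct():
    """Hand-built 4-assay x 4-sample Ct matrix with roles."""
    ct = pd.DataFrame(
        {
            "s1": [24.0, 15.0, 20.0, 21.0],
            "s2": [24.0, 22.0, 20.5, 21.5],
            "s3": [23.0, 22.5, 19.5, 20.5],
            "s4": [25.0, 23.0, 21.0, 22.0],
        },
        index=["miR-23a-3p", "miR-451a", "UniSp3", "ref-x"],
    )
    roles = pd.Series(
        ["target", "target", "spike-in", "reference-candidate"], index=ct.index
    )
    return CtMatrix(ct, roles)


@pytest.fixture
def count_matrix():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.poisson(50, size=(30, 6)),
        index=[f"g{i:02d}" for i in range(30)],
        columns=[f"s{j}" for j in range(6)],
    )
    return CountMatrix(df)


@pytest.fixture
def sheet_10v10():
    records = [(f"1-case-{k:02d}", "case", "1") for k in range(10)] + [
        (f"1-ctrl-{k:02d}", "control", "1") for k in range(10)
    ]
    return SampleSheet.from_records(records)
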