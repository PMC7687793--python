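import numpy as np
import pandas as pd
import pytest

from ewasmeta.references import IOTFCutoffs, LMSReference, load_synthetic_iotf, load_synthetic_lms


@pytest.fixture(scope="session")
def lms_synth():
    return load_synthetic_lms()


@pytest.fixture(scope="session")
def iotf_synth():
    return load_synthetic_iotf()


def make_flat_lms(L, M, S, ages=(0.0, 50.0)):
    """Reference with constant parameters at all ages, both sexes."""
    rows = [
        {"sex": sex, "age_years": a, "L": L, "M": M, "S": S}
        for sex in ("F", "M")
        for a in ages
    ]
    return LMSReference(pd.DataFrame(rows))


def make_flat_iotf(uw=14.0, ow=18.0, ob=21.0, ages=(0.0, 50.0)):
    rows = [
        {
            "sex": sex,
            "age_years": a,
            "bmi_underweight": uw,
            "bmi_overweight": ow,
            "bmi_obesity": ob,
        }
        for sex in ("F", "M")
        for a in ages
    ]
    return IOTFCutoffs(pd.DataFrame(rows))


@pytest.fixture
def flat_iotf():
    return make_flat_iotf()


def make_samples(bmis, sex="F", age=8.0):
    n = len(bmis)
    return pd.DataFrame(
        {
            "bmi_kg_m2": np.asarray(bmis, dtype=float),
            "sex": [sex] * n,
            "age_years": [age] * n,
        },
        index=[f"s{i}" for i in range(n)],
    )
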