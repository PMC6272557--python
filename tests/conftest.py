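import numpy as np
import pytest

from astraqc import SampleRecord, default_config, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20150213)


def make_sample(sample_id="RA01", region="Sx", **contents_mg_g):
    """A valid perennial Shanxi sample with given contents (mg/g)."""
    base = {
        "glucose": 0.0034,
        "fructose": 0.0013,
        "inositol": 0.0755,
        "sorbitol": 0.0015,
        "dulcitol": 0.0051,
        "sucrose": 17.5,
        "betaine": 1.4,
    }
    base.update(contents_mg_g)
    return SampleRecord(
        sample_id=sample_id,
        species="MG",
        region=region,
        growth_years=5,
        cultivation="PA",
        contents=base,
    )


@pytest.fixture
def sample():
    return make_sample()


@pytest.fixture(scope="session")
def study_cohort():
    """One study-shaped synthetic cohort (48 samples, fixed seed)."""
    return generate_cohort(default_config(seed=7))
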