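import pandas as pd
import pytest

from fh_spectrum import load_fixture
from fh_spectrum.synthetic_cohort import PlantedVariant, SimConfig


@pytest.fixture(scope="session")
def catalogue() -> pd.DataFrame:
    """The packaged 40-variant pathogenic catalogue."""
    return load_fixture("pv_catalogue")


@pytest.fixture()
def single_variant_config() -> SimConfig:
    """One LDLR variant planted at the study's confirmed-carrier frequency."""
    return SimConfig(
        n_subjects=5130,
        seed=7,
        variant_catalogue=[
            PlantedVariant(
                gene="LDLR",
                hgvs_c="c.301G>A",
                evidence="PS3,PM1,PM2,PP2,PP3,PP4,PP5",
                carrier_freq=12 / 5130,
            )
        ],
    )


def make_subject(**overrides):
    from fh_spectrum import SubjectRecord

    base = dict(subject_id="S1", age=50.0, tc=7.0, tg=1.8, hdl=1.3)
    base.update(overrides)
    return SubjectRecord(**base)
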