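import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mfsoil.cli import default_class_assignment
from mfsoil.synthetic import StudyDesign, generate_design

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def composites(design) -> list[str]:
    meta = generate_design(design, 0)
    return list(dict.fromkeys(meta["composite_id"]))


@pytest.fixture(scope="session")
def class_assignment(composites) -> dict[str, str]:
    """The 1/2/3/9 class layout used for planted-structure recovery."""
    return default_class_assignment(composites)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_counts() -> pd.DataFrame:
    """Small OTU table with mixed abundances and zeros."""
    return pd.DataFrame(
        {
            "otuA": [10, 0, 3, 7],
            "otuB": [5, 5, 5, 5],
            "otuC": [0, 0, 1, 0],
            "otuD": [100, 50, 20, 30],
        },
        index=["s1", "s2", "s3", "s4"],
    )
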