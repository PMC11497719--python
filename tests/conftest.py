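import numpy as np
import pandas as pd
import pytest

from plasmapanel import default_config, generate_cohort
from plasmapanel.cohort import CohortTable

PANEL = ("ptau181", "gfap", "nfl_age_corrected")


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Default 1199-subject synthetic development cohort, fixed seed."""
    return generate_cohort(default_config(seed=11))


@pytest.fixture(scope="session")
def synthetic_cohort_alt():
    """An independent draw standing in for an external validation cohort."""
    cfg = default_config(seed=47)
    cfg.name = "synthetic_validation"
    return generate_cohort(cfg)


def tiny_cohort_df():
    """Three hand-built subjects: SCD amyloid-negative, MCI amyloid-positive,
    and FTD with unknown amyloid."""
    return pd.DataFrame(
        {
            "subject_id": ["s1", "s2", "s3"],
            "age": [60.0, 70.0, 62.0],
            "sex": ["female", "male", "female"],
            "group": ["SCD", "MCI", "FTD"],
            "amyloid": ["negative", "positive", "unknown"],
            "abeta_ratio": [0.062, 0.051, 0.06],
            "ptau181": [1.2, 2.6, 1.8],
            "gfap": [60.0, 120.0, 110.0],
            "nfl": [10.0, 18.0, 40.0],
            "nfl_age_corrected": [10.0, 18.0, 40.0],
        }
    )


@pytest.fixture
def tiny_cohort():
    return CohortTable("tiny", tiny_cohort_df())
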