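import pandas as pd
import pytest

from psindex import default_design, run_study


@pytest.fixture(scope="session")
def study() -> tuple[pd.DataFrame, pd.DataFrame]:
    """One full robustness-study run (168 groups), shared across tests."""
    return run_study(default_design(seed=777))


@pytest.fixture(scope="session")
def study_mothers(study) -> pd.DataFrame:
    return study[0]


@pytest.fixture(scope="session")
def study_groups(study) -> pd.DataFrame:
    return study[1]
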