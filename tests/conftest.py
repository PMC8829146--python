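from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from etmnet import table1_fixture_path
from etmnet.pipeline_cli import validate_fixture_table

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_path():
    return table1_fixture_path()


@pytest.fixture(scope="session")
def table1_report(table1_path):
    """Row-by-row evaluation of the published eTM pair table."""
    return validate_fixture_table(table1_path)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_817)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
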