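from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from myh7rules.cli import worked_examples_path
from myh7rules.engine import load_default_config
from myh7rules.io import read_evidence

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    return load_default_config()


@pytest.fixture(scope="session")
def worked_examples():
    result = read_evidence(worked_examples_path())
    assert not result.errors
    return result.bundles
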