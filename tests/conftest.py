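import pytest

from aoxdesign.fixtures import study_case_bundle
from aoxdesign.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def study_bundle():
    """Deterministic study-case input bundle (built once per session)."""
    return study_case_bundle()


@pytest.fixture(scope="session")
def study_report(study_bundle):
    """Full pipeline report for the study-case bundle."""
    return run_pipeline(RunConfig(), study_bundle)
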