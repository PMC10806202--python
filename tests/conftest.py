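import numpy as np
import pytest

import prtrace as pt

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "repro",
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("repro")
except ImportError:  # hypothesis only needed for the property tests
    pass


@pytest.fixture(scope="session")
def ref_params() -> pt.ParamSet:
    """Perseverance parameters in the fitted-mouse regime."""
    return pt.REFERENCE_PERSEVERANCE_PARAMS


@pytest.fixture(scope="session")
def short_run(ref_params) -> pt.FreeRunResult:
    """A small free-run session (300 choices) shared by fast tests."""
    return pt.free_run(
        ref_params, pt.ModelKind.PERSEVERANCE,
        stop=pt.StopRule(max_choices=300), seed=7,
    )


@pytest.fixture(scope="session")
def full_run(ref_params) -> pt.FreeRunResult:
    """One full session under the default termination rules."""
    return pt.free_run(ref_params, pt.ModelKind.PERSEVERANCE, seed=0)
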