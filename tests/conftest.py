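"""Shared fixtures: the calibrated synthetic reference inputs and strategy menus."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings as hyp_settings

from darescreen import (
    CohortModel,
    ModelSettings,
    ParameterSet,
    reference_schedules,
    standard_strategies,
)

hyp_settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_case() -> tuple[ParameterSet, ModelSettings]:
    return ParameterSet(), ModelSettings()


@pytest.fixture(scope="session")
def reference(base_case):
    """Calibrated synthetic schedules (3 % lifetime risk, ~24.2 disc. LY)."""
    params, settings = base_case
    return reference_schedules(seed=1, settings=settings, params=params)


@pytest.fixture(scope="session")
def reference_model(base_case, reference) -> CohortModel:
    params, settings = base_case
    return CohortModel(params, settings, reference)


@pytest.fixture(scope="session")
def menu(base_case):
    """The full eleven-strategy menu."""
    _, settings = base_case
    return standard_strategies(settings)


@pytest.fixture(scope="session")
def menu_50plus(menu):
    """No screening plus the five age >= 50 strategies, least intensive first."""
    keep = [s for s in menu if (not s.screening) or s.screen_start_age == 50]
    return sorted(keep, key=lambda s: -s.interval_years if s.screening else -99)


@pytest.fixture(scope="session")
def reference_summaries(reference_model, menu):
    """OutcomeSummary per strategy on the reference fixture (computed once)."""
    return {s.label: reference_model.run(s)[1] for s in menu}
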