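"""PSA sampling distributions, CEAC behaviour and one-way analysis."""

from __future__ import annotations

import numpy as np
import pytest

from darescreen.parameters import ModelSettings, ParameterSet
from darescreen.sensitivity import (
    PsaSettings,
    ceac,
    owsa,
    run_psa,
    sample_parameters,
    shift_survival,
)


@pytest.fixture(scope="module")
def small_draws(base_case, reference, menu):
    params, settings = base_case
    strats = [menu[0]] + [
        s for s in menu
        if s.screening and s.screen_start_age == 50 and s.interval_years in (4, 2)
    ]
    psa = PsaSettings(n_iterations=40, seed=9)
    return run_psa(strats, params, settings, reference, psa), strats


class TestSampleParameters:
    def test_tiny_sd_converges_to_base(self):
        base = ParameterSet()
        psa = PsaSettings(n_iterations=1, seed=0, sd_fraction=1e-7)
        drawn = sample_parameters(base, psa, 0)
        assert drawn.cost_false_positive == pytest.approx(218.0, rel=1e-5)
        assert drawn.utility_no_cancer == pytest.approx(0.76, abs=1e-5)
        assert drawn.dare_sensitivity == pytest.approx(0.9, abs=1e-5)

    def test_fixed_seed_reproducible(self):
        base = ParameterSet()
        psa = PsaSettings(n_iterations=10, seed=42)
        a = [sample_parameters(base, psa, i) for i in range(10)]
        b = [sample_parameters(base, psa, i) for i in range(10)]
        assert a == b
        # different iterations give different draws
        assert a[0] != a[1]

    def test_sampled_values_respect_domains(self):
        base = ParameterSet()
        psa = PsaSettings(n_iterations=1, seed=7)
        for i in range(300):
            d = sample_parameters(base, psa, i)
            assert 0.0 <= d.dare_sensitivity <= 1.0
            assert 0.0 <= d.utility_distal <= 1.0
            assert d.cost_workup >= 0.0

    def test_gamma_moments_match(self):
        """Method-of-moments gamma: sample mean ~ base, SD ~ 0.3 x base."""
        base = ParameterSet()
        psa = PsaSettings(n_iterations=1, seed=5)
        xs = np.array(
            [sample_parameters(base, psa, i).cost_false_positive for i in range(4000)]
        )
        se = 0.3 * 218 / np.sqrt(len(xs))
        assert abs(xs.mean() - 218.0) < 3 * se
        assert abs(xs.std(ddof=1) - 65.4) / 65.4 < 0.05

    def test_sd_override_used(self):
        base = ParameterSet()
        psa = PsaSettings(n_iterations=1, seed=5, sd_overrides={"cost_screen": 1e-9})
        xs = [sample_parameters(base, psa, i).cost_screen for i in range(50)]
        assert np.allclose(xs, 16.0, atol=1e-6)

    def test_infeasible_beta_sd_warns_and_clips(self):
        base = ParameterSet()
        psa = PsaSettings(n_iterations=1, seed=1, sd_overrides={"utility_no_cancer": 0.6})
        with pytest.warns(RuntimeWarning, match="utility_no_cancer"):
            d = sample_parameters(base, psa, 0)
        assert 0.0 <= d.utility_no_cancer <= 1.0


class TestRunPsaAndCeac:
    def test_single_iteration_is_one_deterministic_run(self, base_case, reference, menu):
        params, settings = base_case
        psa = PsaSettings(n_iterations=1, seed=4)
        a = run_psa(menu[:2], params, settings, reference, psa)
        b = run_psa(menu[:2], params, settings, reference, psa)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        assert a.costs.shape == (1, 2)

    def test_screening_gains_qalys_at_base_and_in_most_draws(self, small_draws):
        draws, _ = small_draws
        dq = draws.qalys[:, 1:] - draws.qalys[:, [0]]
        assert (dq > 0).mean() > 0.9

    def test_ceac_zero_wtp_is_probability_of_being_cheaper(self, small_draws):
        draws, _ = small_draws
        c = ceac(draws, "No screening", [0.0])
        for j, s in enumerate(draws.strategies[1:], start=1):
            cheaper = (draws.costs[:, j] < draws.costs[:, 0]).mean()
            assert c[s].iloc[0] == pytest.approx(cheaper)

    def test_ceac_probabilities_in_unit_interval(self, small_draws):
        draws, _ = small_draws
        c = ceac(draws, "No screening", [0, 1e4, 5e4, 1e5])
        assert ((c.values >= 0) & (c.values <= 1)).all()

    def test_pairwise_ceac_monotone_when_qaly_gain_positive(self, small_draws):
        """For iterations with positive incremental QALYs the pairwise net
        monetary benefit rises with willingness to pay, so the curve cannot
        decrease."""
        draws, _ = small_draws
        grid = np.linspace(0, 2e5, 21)
        for j, s in enumerate(draws.strategies[1:], start=1):
            dq = draws.qalys[:, j] - draws.qalys[:, 0]
            dc = draws.costs[:, j] - draws.costs[:, 0]
            keep = dq > 0
            probs = [(l * dq[keep] - dc[keep] > 0).mean() for l in grid]
            assert all(a <= b + 1e-12 for a, b in zip(probs, probs[1:]))

    def test_multiway_ceac_sums_to_at_most_one(self, small_draws):
        draws, _ = small_draws
        c = ceac(draws, "No screening", [0, 2e4, 5e4], method="multiway")
        assert np.allclose(c.sum(axis=1), 1.0)

    def test_empty_wtp_grid_rejected(self, small_draws):
        draws, _ = small_draws
        with pytest.raises(ValueError):
            ceac(draws, "No screening", [])

    def test_unknown_comparator_rejected(self, small_draws):
        draws, _ = small_draws
        with pytest.raises(ValueError):
            ceac(draws, "not a strategy", [0.0])


class TestOwsa:
    def test_degenerate_range_returns_base_icers(self, base_case, reference,
                                                 menu_50plus):
        params, settings = base_case
        one = owsa("cost_false_positive", (218.0, 218.0), 1,
                   menu_50plus, params, settings, reference)
        two = owsa("cost_false_positive", (218.0, 218.0), 2,
                   menu_50plus, params, settings, reference)
        cols = [c for c in one.columns if c.startswith("icer")]
        assert np.allclose(one[cols].iloc[0], two[cols].iloc[0])
        assert np.allclose(one[cols].iloc[0], two[cols].iloc[1])

    def test_unknown_parameter_rejected(self, base_case, reference, menu_50plus):
        params, settings = base_case
        with pytest.raises(KeyError):
            owsa("no_such_knob", (0, 1), 2, menu_50plus, params, settings, reference)

    def test_survival_shift_scenario_changes_hazard(self, reference):
        worse = shift_survival(reference, 1.5)
        better = shift_survival(reference, 0.5)
        base_p = reference.survival["local"].annual_death_prob(0)
        assert worse.survival["local"].annual_death_prob(0) == pytest.approx(1.5 * base_p)
        assert better.survival["local"].annual_death_prob(0) == pytest.approx(0.5 * base_p)
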