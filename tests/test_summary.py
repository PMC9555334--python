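"""Value waterfall assembly, ROI, and sensitivity analyses."""

from dataclasses import replace

import numpy as np
import pytest

from dpcvalue.cohort import CohortSpec, ControlSegment, RoundingPolicy, ValidationError
from dpcvalue.compensation import UptakeParams
from dpcvalue.config import replication_config
from dpcvalue.summary import (
    UndefinedValueError,
    ValueWaterfall,
    one_way_sensitivity,
    probabilistic_sensitivity,
    roi,
    run_scenario,
    value_per_appointment,
)

C, M, U = (
    ControlSegment.controlled,
    ControlSegment.moderately_controlled,
    ControlSegment.uncontrolled,
)


class TestValuePerAppointment:
    def test_recomputed_from_published_components(self):
        # 1,313,177 + 1,796,506 - 209,988 = 2,899,695; / 2217 = 1307.94
        v = value_per_appointment(1_313_177, 1_796_506, 209_988, 2217)
        assert v == pytest.approx(1307.94, abs=0.005)

    @pytest.mark.parametrize(
        "prof, inpat, comp, attended", [(100, 0, 100, 5), (0, 0, 0, 7)]
    )
    def test_zero_margin_is_zero_value(self, prof, inpat, comp, attended):
        assert value_per_appointment(prof, inpat, comp, attended) == 0.0

    def test_zero_attended_raises_not_inf(self):
        with pytest.raises(UndefinedValueError):
            value_per_appointment(100.0, 100.0, 0.0, 0)


class TestRunScenario:
    def test_replication_intermediates(self, config):
        result = run_scenario(config)
        assert result.funnel.total_unengaged == 22_171
        assert result.compensation.engaged_count == 2217
        assert round(result.compensation.annual_compensation) == 209_988
        # hospitalized from the computed engaged cohort (2217), floored
        assert result.hospitalized == 751
        assert result.waterfall.attended_appointments == 2217

    def test_published_engaged_override_gives_757_admissions(self, config):
        result = run_scenario(
            replace(config, uptake=UptakeParams(0.10, engaged_override=2235))
        )
        assert result.hospitalized == 757

    def test_zero_uptake_degenerate_scenario(self, config):
        result = run_scenario(replace(config, uptake=UptakeParams(0.0)))
        assert result.compensation.annual_compensation == 0.0
        assert result.waterfall.inpatient_revenue_annual == 0.0
        assert result.waterfall.value_per_appointment is None
        with pytest.raises(UndefinedValueError):
            value_per_appointment(0, 0, 0, result.waterfall.attended_appointments)

    def test_runs_are_deterministic(self, config):
        assert run_scenario(config).waterfall == run_scenario(config).waterfall

    def test_waterfall_identity_exact_in_cents(self, config):
        w = run_scenario(config).waterfall
        assert w.total_margin_cents == (
            w.professional_revenue_cents
            + w.inpatient_revenue_cents
            - w.provider_compensation_cents
        )


class TestRoi:
    def test_direct_arithmetic(self):
        w = ValueWaterfall(289_969_500, 0, 0, 2217)  # margin $2,899,695
        assert roi(w, 1_000_000) == pytest.approx(1.899695)

    def test_cost_equal_to_margin_is_zero(self):
        w = ValueWaterfall(100_00, 0, 0, 1)
        assert roi(w, 100.0) == 0.0

    def test_zero_margin_is_minus_one(self):
        w = ValueWaterfall(0, 0, 0, 1)
        assert roi(w, 500.0) == -1.0

    def test_nonpositive_cost_rejected(self):
        with pytest.raises(ValidationError):
            roi(ValueWaterfall(0, 0, 0, 1), 0.0)


class TestOneWay:
    def test_value_per_appointment_insensitive_to_uptake(self, config):
        # every numerator term is gated by uptake, so per-appointment value
        # is structurally flat in it (exactly so without count rounding)
        cfg = replace(
            config,
            rounding=RoundingPolicy.none,
            inpatient=replace(config.inpatient, count_rounding=RoundingPolicy.none),
        )
        res = one_way_sensitivity(cfg, "uptake_fraction", 0.05, 0.20)
        # flat up to the half-cent quantisation of the waterfall components
        assert res.low_value_per_appointment == pytest.approx(
            res.high_value_per_appointment, abs=1e-4
        )

    def test_uptake_near_invariance_under_integer_rounding(self, config):
        res = one_way_sensitivity(config, "uptake_fraction", 0.05, 0.20)
        assert res.low_value_per_appointment == pytest.approx(
            res.high_value_per_appointment, rel=0.02
        )

    def test_hospitalization_rate_is_monotone(self, config):
        res = one_way_sensitivity(config, "hospitalization_rate", 0.0, 0.339)
        assert res.low_value_per_appointment < res.high_value_per_appointment

    def test_equal_bounds_equal_outputs(self, config):
        res = one_way_sensitivity(config, "conversion_factor", 41.94, 41.94)
        assert res.low_value_per_appointment == res.high_value_per_appointment

    def test_unknown_parameter_lists_registered_names(self, config):
        with pytest.raises(ValidationError, match="uptake_fraction"):
            one_way_sensitivity(config, "nope", 0, 1)

    def test_payer_share_renormalizes(self, config):
        res = one_way_sensitivity(config, "payer_mix.commercial", 0.4, 0.9)
        # richer commercial mix pays more per admission and per service
        assert res.low_value_per_appointment < res.high_value_per_appointment


class TestPsa:
    def test_point_masses_reproduce_deterministic_run(self, config):
        det = run_scenario(config).waterfall.value_per_appointment
        res = probabilistic_sensitivity(
            config,
            {
                "uptake_fraction": {"dist": "point", "value": 0.10},
                "hospitalization_rate": {"dist": "point", "value": 0.339},
            },
            n_draws=20,
            seed=1,
        )
        assert all(s == det for s in res.samples)

    def test_fixed_seed_identical_quantiles(self, config):
        dists = {"uptake_fraction": {"dist": "uniform", "low": 0.05, "high": 0.2}}
        a = probabilistic_sensitivity(config, dists, 50, seed=42)
        b = probabilistic_sensitivity(config, dists, 50, seed=42)
        assert a.quantiles == b.quantiles
        assert a.samples == b.samples

    def test_hosp_rate_uniform_below_upper_bound_drags_median_down(self, config):
        det = run_scenario(config).waterfall.value_per_appointment
        res = probabilistic_sensitivity(
            config,
            {"hospitalization_rate": {"dist": "uniform", "low": 0.0, "high": 0.339}},
            n_draws=100,
            seed=7,
        )
        assert res.quantiles[0.5] < det

    def test_invalid_distribution_rejected(self, config):
        with pytest.raises(ValidationError):
            probabilistic_sensitivity(
                config, {"uptake_fraction": {"dist": "beta", "a": -1, "b": 2}}, 5, 0
            )
        with pytest.raises(ValidationError):
            probabilistic_sensitivity(
                config, {"uptake_fraction": {"dist": "cauchy"}}, 5, 0
            )


def test_waterfall_identity_over_random_configs(config):
    """Margin identity holds to the cent for arbitrary perturbed scenarios."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        total = int(rng.integers(0, 300_000))
        cuts = np.sort(rng.random(2))
        fracs = {C: cuts[0], M: cuts[1] - cuts[0], U: 1.0 - cuts[1]}
        spec = CohortSpec(
            total,
            fracs,
            {s: float(rng.random()) for s in (C, M, U)},
            {s: float(rng.random()) for s in (C, M, U)},
        )
        cfg = replace(
            config,
            cohort=spec,
            uptake=UptakeParams(float(rng.random())),
            conversion_factor=float(rng.random() * 100),
            fee_scale=float(rng.random() * 3),
        )
        w = run_scenario(cfg).waterfall
        assert w.total_margin_cents == (
            w.professional_revenue_cents
            + w.inpatient_revenue_cents
            - w.provider_compensation_cents
        )
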