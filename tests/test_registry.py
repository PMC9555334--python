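"""Record-level eligibility rules and the synthetic registry generator."""

import datetime as dt
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dpcvalue.cohort import DEFAULT_POLICIES, ControlSegment, PayerMix, RoundingPolicy
from dpcvalue.registry import (
    PatientRecord,
    RegistryParams,
    add_months,
    aggregate_registry,
    classify_control,
    generate_registry,
    is_overdue,
    is_unengaged,
    read_registry_csv,
    write_registry_csv,
)
from dpcvalue.cohort import CohortSpec, ValidationError, engagement_funnel

C, M, U = (
    ControlSegment.controlled,
    ControlSegment.moderately_controlled,
    ControlSegment.uncontrolled,
)

AS_OF = dt.date(2022, 7, 1)


def make_params(n, seed=0, **kw):
    defaults = dict(
        n_patients=n,
        segment_fractions={C: 0.50, M: 0.355, U: 0.145},
        overdue_rate={C: 0.131, M: 0.298, U: 0.611},
        no_future_visit_rate={C: 0.962, M: 0.867, U: 0.756},
        payer_mix=PayerMix({"commercial": 0.663, "medicare": 0.205, "medicaid": 0.132}),
        evaluation_date=AS_OF,
        random_seed=seed,
    )
    defaults.update(kw)
    return RegistryParams(**defaults)


def record(hba1c=9.5, last=None, nxt=None, payer="commercial"):
    return PatientRecord("P1", hba1c, last, nxt, payer)


class TestClassifyControl:
    @pytest.mark.parametrize(
        "hba1c, segment",
        [
            (6.9, C),
            (5.0, C),
            (7.0, M),  # boundary maps upward: half-open bands
            (8.99, M),
            (9.0, U),
            (12.5, U),
            (None, M),  # absent value treated as moderately controlled
        ],
    )
    def test_banding(self, hba1c, segment):
        assert classify_control(hba1c) is segment

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            classify_control(0.0)

    @given(st.one_of(st.none(), st.floats(0.01, 20.0)))
    def test_partition_is_total(self, hba1c):
        assert classify_control(hba1c) in ControlSegment


class TestMonthArithmetic:
    def test_month_end_clamps(self):
        assert add_months(dt.date(2022, 7, 31), -5) == dt.date(2022, 2, 28)
        assert add_months(dt.date(2024, 7, 31), -5) == dt.date(2024, 2, 29)

    def test_roundtrip_mid_month(self):
        assert add_months(dt.date(2022, 7, 15), -11) == dt.date(2021, 8, 15)
        assert add_months(dt.date(2022, 7, 15), 3) == dt.date(2022, 10, 15)


class TestEligibility:
    def test_controlled_visit_a_year_ago_is_overdue(self):
        rec = record(hba1c=6.0, last=add_months(AS_OF, -12))
        assert is_overdue(rec, DEFAULT_POLICIES[C], AS_OF)

    def test_boundary_is_strict(self):
        # a visit exactly `lookback` months ago is not yet overdue
        rec = record(hba1c=9.5, last=add_months(AS_OF, -2))
        assert not is_overdue(rec, DEFAULT_POLICIES[U], AS_OF)
        one_day_earlier = record(
            hba1c=9.5, last=add_months(AS_OF, -2) - dt.timedelta(days=1)
        )
        assert is_overdue(one_day_earlier, DEFAULT_POLICIES[U], AS_OF)

    def test_never_seen_patient_is_overdue(self):
        assert is_overdue(record(last=None), DEFAULT_POLICIES[U], AS_OF)

    def test_unengaged_requires_overdue_and_no_near_visit(self):
        policy = DEFAULT_POLICIES[U]
        overdue_no_visit = record(last=add_months(AS_OF, -6), nxt=None)
        assert is_unengaged(overdue_no_visit, policy, AS_OF)
        overdue_soon_visit = record(
            last=add_months(AS_OF, -6), nxt=add_months(AS_OF, 2)
        )
        assert not is_unengaged(overdue_soon_visit, policy, AS_OF)
        overdue_far_visit = record(
            last=add_months(AS_OF, -6), nxt=add_months(AS_OF, 4)
        )
        assert is_unengaged(overdue_far_visit, policy, AS_OF)
        current_patient = record(last=add_months(AS_OF, -1), nxt=None)
        assert not is_unengaged(current_patient, policy, AS_OF)


class TestGenerator:
    def test_empty(self):
        assert generate_registry(make_params(0)) == []

    def test_same_seed_identical_streams(self):
        a = generate_registry(make_params(500, seed=7))
        b = generate_registry(make_params(500, seed=7))
        assert a == b
        c = generate_registry(make_params(500, seed=8))
        assert a != c

    def test_unengaged_rate_matches_composite(self):
        # composite unengaged rate: sum_s f_s * overdue_s * no_future_s = 0.22171
        n = 10_000
        records = generate_registry(make_params(n, seed=3))
        funnel = aggregate_registry(records, as_of=AS_OF)
        p = 0.22171
        se = math.sqrt(p * (1 - p) / n)
        assert abs(funnel.total_unengaged / n - p) < 3 * se

    def test_statuses_reconstructable_from_dates(self):
        # the census must recover exactly the drawn statuses via the windows
        records = generate_registry(make_params(2_000, seed=1))
        for rec in records:
            seg = classify_control(rec.hba1c)
            policy = DEFAULT_POLICIES[seg]
            assert rec.next_scheduled_visit_date is None or (
                rec.next_scheduled_visit_date > AS_OF
            )
            if not is_overdue(rec, policy, AS_OF):
                assert not is_unengaged(rec, policy, AS_OF)

    def test_missing_hba1c_stays_in_moderate_segment(self):
        records = generate_registry(make_params(4_000, seed=5, missing_hba1c_fraction=0.3))
        missing = [r for r in records if r.hba1c is None]
        assert missing, "expected some records without an HbA1c value"
        assert all(classify_control(r.hba1c) is M for r in missing)


class TestAggregate:
    def test_single_unengaged_controlled_record(self):
        rec = record(hba1c=6.0, last=None, nxt=None)
        funnel = aggregate_registry([rec], as_of=AS_OF)
        row = funnel.row(C)
        assert (row.population, row.overdue, row.unengaged) == (1, 1, 1)

    def test_everyone_scheduled_tomorrow_is_engaged(self):
        records = [
            PatientRecord(f"P{i}", 9.5, None, AS_OF + dt.timedelta(days=1), "medicare")
            for i in range(20)
        ]
        funnel = aggregate_registry(records, as_of=AS_OF)
        assert funnel.total_unengaged == 0
        assert funnel.total_overdue == 20  # never seen, so all overdue

    def test_oracle_equivalence_with_aggregate_model(self):
        # record-level census converges to the count-level model (no rounding)
        n = 20_000
        params = make_params(n, seed=11)
        funnel = aggregate_registry(generate_registry(params), as_of=AS_OF)
        spec = CohortSpec(
            n, params.segment_fractions, params.overdue_rate, params.no_future_visit_rate
        )
        exact = engagement_funnel(spec, RoundingPolicy.none)
        for seg in (C, M, U):
            for attr in ("population", "overdue", "unengaged"):
                p = getattr(exact.row(seg), attr) / n
                got = getattr(funnel.row(seg), attr) / n
                se = math.sqrt(max(p * (1 - p), 1e-12) / n)
                assert abs(got - p) < 3 * se + 1e-12


def test_registry_csv_roundtrip(tmp_path):
    records = generate_registry(make_params(200, seed=2, missing_hba1c_fraction=0.2))
    path = tmp_path / "registry.csv"
    write_registry_csv(records, path)
    assert read_registry_csv(path) == records
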