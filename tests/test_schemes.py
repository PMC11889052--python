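"""Payment engines: horizon rule, assessments, settlements, stream composition."""

import numpy as np
import pytest

from ltra import (
    Assessment,
    EnrolleeHistory,
    InflationModel,
    Intervention,
    SchemeConfig,
    baseline_trajectory,
    generate_profile,
    horizon_for_age,
    long_term_assessment,
    one_year_payments,
    reassessed_expectations,
    scheme_payment_stream,
    switch_settlement,
)
from ltra.errors import ContractError

EVERYONE_H5 = SchemeConfig(kind="long_term", horizon_rule=((200, 5),), terminal_horizon=5)
EVERYONE_H1 = SchemeConfig(kind="long_term", horizon_rule=((200, 1),), terminal_horizon=1)


class TestHorizonRule:
    @pytest.mark.parametrize(
        "age,expected", [(0, 10), (40, 10), (70, 10), (71, 5), (80, 5), (81, 1), (95, 1)]
    )
    def test_default_rule_thresholds_are_exclusive(self, age, expected):
        assert horizon_for_age(SchemeConfig(), age) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ContractError):
            horizon_for_age(SchemeConfig(), -1)

    def test_horizons_must_shrink_with_age(self):
        with pytest.raises(ContractError):
            SchemeConfig(horizon_rule=((70, 5), (80, 10)))


class TestOneYearPayments:
    def test_tracks_baseline_without_intervention(self, flat_profile, no_inflation):
        base = baseline_trajectory(flat_profile, 40, 10, no_inflation)
        stream = one_year_payments(reassessed_expectations(base, None), 10)
        assert stream.as_array() == pytest.approx(base.as_array())
        assert stream.total() - base.total() == pytest.approx(0.0)

    def test_zero_savings_leaves_payments_unchanged(self, flat_profile, no_inflation):
        base = baseline_trajectory(flat_profile, 40, 10, no_inflation)
        iv = Intervention(cost_multiplier=2.0, savings_fraction=0.0)
        stream = one_year_payments(reassessed_expectations(base, iv), 10)
        assert stream.as_array() == pytest.approx(base.as_array())

    def test_payment_lag_convention(self, no_inflation):
        profile = generate_profile("log_linear", {"c0": 1000.0, "a0": 40, "beta": 0.0})
        base = baseline_trajectory(profile, 40, 4, no_inflation)
        iv = Intervention(year=1, savings_fraction=0.3, cost_onset_lag=1, payment_onset_lag=2)
        stream = one_year_payments(reassessed_expectations(base, iv), 4)
        assert stream.as_array() == pytest.approx([1000.0, 1000.0, 700.0, 700.0])

    def test_window_beyond_trajectory_rejected(self, flat_profile, no_inflation):
        base = baseline_trajectory(flat_profile, 40, 5, no_inflation)
        with pytest.raises(ContractError):
            one_year_payments(reassessed_expectations(base, None), 6)


class TestLongTermAssessment:
    def test_schedule_equals_baseline_slice(self, flat_profile, no_inflation):
        base = baseline_trajectory(flat_profile, 40, 10, no_inflation)
        assessment = long_term_assessment(base, 0, EVERYONE_H5)
        assert assessment.scheduled_payments == (100.0,) * 5
        assert assessment.horizon == 5

    def test_degenerate_single_year_horizon(self, paper):
        base = paper.baseline()
        assessment = long_term_assessment(base, 0, EVERYONE_H1)
        assert assessment.scheduled_payments == (base.values[0],)

    def test_schedule_is_immutable(self, flat_profile, no_inflation):
        base = baseline_trajectory(flat_profile, 40, 10, no_inflation)
        assessment = long_term_assessment(base, 0, EVERYONE_H5)
        with pytest.raises((AttributeError, TypeError)):
            assessment.scheduled_payments = (0.0,) * 5  # type: ignore[misc]

    def test_horizon_exceeding_trajectory_rejected(self, flat_profile, no_inflation):
        base = baseline_trajectory(flat_profile, 40, 3, no_inflation)
        with pytest.raises(ContractError):
            long_term_assessment(base, 0, EVERYONE_H5)


class TestSwitchSettlement:
    def _assessment(self, payments):
        return Assessment(assessment_year=0, horizon=len(payments),
                          scheduled_payments=tuple(payments))

    def test_seven_years_remain_after_three_of_ten(self):
        old = self._assessment([1000.0] * 10)
        rec = switch_settlement(old, [1000.0] * 7, switch_year=3)
        assert rec.remaining_years == 7
        assert rec.transfer == pytest.approx(0.0)

    def test_departing_insurer_pays_on_risk_increase(self):
        old = self._assessment([1000.0] * 10)
        rec = switch_settlement(old, [1100.0] * 7, switch_year=3)
        assert rec.transfer == pytest.approx(700.0)

    def test_departing_insurer_receives_on_risk_decrease(self):
        old = self._assessment([1000.0] * 10)
        rec = switch_settlement(old, [900.0] * 7, switch_year=3)
        assert rec.transfer == pytest.approx(-700.0)

    def test_switch_after_final_year_settles_zero(self):
        old = self._assessment([1000.0] * 10)
        rec = switch_settlement(old, [], switch_year=10)
        assert rec.remaining_years == 0
        assert rec.transfer == 0.0

    def test_length_mismatch_rejected(self):
        old = self._assessment([1000.0] * 10)
        with pytest.raises(ContractError):
            switch_settlement(old, [1000.0] * 6, switch_year=3)

    def test_switch_outside_horizon_rejected(self):
        old = self._assessment([1000.0] * 10)
        with pytest.raises(ContractError):
            switch_settlement(old, [1000.0] * 10, switch_year=0)


def _history(profile, window=10, start_age=40, **kwargs):
    return EnrolleeHistory(profile=profile, inflation=InflationModel(0.0),
                           start_age=start_age, window=window, **kwargs)


class TestSchemePaymentStream:
    def test_one_year_without_events_pays_baseline(self, flat_profile, no_inflation):
        stream = scheme_payment_stream(SchemeConfig(kind="one_year"), _history(flat_profile))
        base = baseline_trajectory(flat_profile, 40, 10, no_inflation)
        assert stream.as_array() == pytest.approx(base.as_array())

    def test_long_term_freezes_schedule_against_later_shocks(self, flat_profile):
        mult = np.ones(10)
        mult[3:] = 2.5  # morbidity doubles after assessment
        shocked = _history(flat_profile, risk_multipliers=mult)
        clean = _history(flat_profile)
        cfg = SchemeConfig(kind="long_term")
        assert scheme_payment_stream(cfg, shocked).payments == scheme_payment_stream(cfg, clean).payments

    def test_one_year_reprices_the_same_shock(self, flat_profile):
        mult = np.ones(10)
        mult[3:] = 2.5
        stream = scheme_payment_stream(SchemeConfig(kind="one_year"),
                                       _history(flat_profile, risk_multipliers=mult))
        assert stream.payments[3] == pytest.approx(250.0)

    def test_switch_with_unchanged_risk_is_seamless(self, flat_profile, no_inflation):
        hist = _history(flat_profile, switch_years=frozenset({4}))
        stream = scheme_payment_stream(SchemeConfig(kind="long_term"), hist)
        base = baseline_trajectory(flat_profile, 40, 10, no_inflation)
        assert stream.as_array() == pytest.approx(base.as_array())
        assert len(stream.settlements) == 1
        assert stream.settlements[0].transfer == pytest.approx(0.0)
        assert len(set(stream.provenance)) == 2  # old and new assessment

    def test_switch_after_shock_settles_the_difference(self, flat_profile):
        mult = np.ones(10)
        mult[2:] = 1.5
        hist = _history(flat_profile, risk_multipliers=mult, switch_years=frozenset({4}))
        stream = scheme_payment_stream(SchemeConfig(kind="long_term"), hist)
        # pre-switch payments from old (multiplier-1) schedule, post-switch repriced
        assert stream.payments[:4] == (100.0,) * 4
        assert stream.payments[4:] == (150.0,) * 6
        # departing insurer pays 6 remaining years x 50 extra
        assert stream.settlements[0].transfer == pytest.approx(300.0)

    def test_single_year_horizon_matches_one_year_scheme(self, flat_profile):
        mult = 1.0 + 0.5 * np.random.default_rng(7).random(10)
        hist = _history(flat_profile, risk_multipliers=mult)
        lt = scheme_payment_stream(EVERYONE_H1, hist)
        oy = scheme_payment_stream(SchemeConfig(kind="one_year"), hist)
        assert lt.payments == oy.payments

    def test_old_age_horizon_rule_degenerates_to_one_year(self, flat_profile):
        mult = 1.0 + 0.5 * np.random.default_rng(11).random(5)
        hist = _history(flat_profile, window=5, start_age=81, risk_multipliers=mult)
        lt = scheme_payment_stream(SchemeConfig(kind="long_term"), hist)
        oy = scheme_payment_stream(SchemeConfig(kind="one_year"), hist)
        assert lt.payments == oy.payments

    def test_mid_horizon_threshold_crossing_honors_running_schedule(self, flat_profile):
        # enrollee turns 71 during a 10-year schedule issued at 68: schedule runs on
        hist = _history(flat_profile, window=10, start_age=68)
        stream = scheme_payment_stream(SchemeConfig(kind="long_term"), hist)
        assert len(set(stream.provenance)) == 1

    def test_exit_cancels_remaining_payments_without_transfer(self, flat_profile):
        hist = _history(flat_profile, exit_year=4)
        stream = scheme_payment_stream(SchemeConfig(kind="long_term"), hist)
        assert stream.payments[:4] == (100.0,) * 4
        assert stream.payments[4:] == (0.0,) * 6
        assert stream.provenance[4:] == ("exited",) * 6
        assert stream.settlement_total() == 0.0

    def test_every_year_has_traceable_provenance(self, flat_profile):
        hist = _history(flat_profile, window=10, switch_years=frozenset({3, 7}))
        stream = scheme_payment_stream(SchemeConfig(kind="long_term"), hist)
        assert len(stream.provenance) == 10
        assert all(p.startswith("A") for p in stream.provenance)
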