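import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from traymass import (
    AdjustmentFactors,
    HarvestRecord,
    LedgerError,
    LedgerEvent,
    PlantLedger,
    adjust_manual,
    compute_adjustment_factors,
    evaluate_regression,
    harvest_error,
    init_substrate_mass,
    ledger_count,
    mass_per_plant,
    per_plant_resolution,
    sensor_accuracy,
)

START = pd.Timestamp("2025-01-01T00:00:00Z")


def _ledger(schedule, n0=20, m_sub=None, m_basket=0.0):
    events = [
        LedgerEvent(START + pd.Timedelta(days=day), removed, "harvest")
        for day, removed in schedule
    ]
    return PlantLedger(n0=n0, m_sub=m_sub, m_basket=m_basket, events=events)


# test-trial schedule: 2 plants every 2-3 days from day 13; validation: 10 on day 18
TEST_SCHEDULE = [(13, 2), (15, 2), (18, 2), (20, 2), (23, 2), (26, 2), (29, 2)]
VALIDATION_SCHEDULE = [(18, 10)]


class TestLedger:
    def test_test_schedule_leaves_six(self):
        ledger = _ledger(TEST_SCHEDULE)
        assert ledger_count(ledger, START + pd.Timedelta(days=31)) == 6

    def test_validation_schedule_leaves_ten(self):
        ledger = _ledger(VALIDATION_SCHEDULE)
        assert ledger_count(ledger, START + pd.Timedelta(days=18)) == 10
        assert ledger_count(ledger, START + pd.Timedelta(days=17.9)) == 20

    def test_no_events_constant_count(self):
        ledger = _ledger([])
        assert ledger_count(ledger, START + pd.Timedelta(days=100)) == 20

    def test_conservation_removals_plus_remaining(self):
        for schedule, remaining in [(TEST_SCHEDULE, 6), (VALIDATION_SCHEDULE, 10)]:
            removed = sum(k for _, k in schedule)
            assert removed + remaining == 20

    def test_overdraw_rejected(self):
        with pytest.raises(LedgerError):
            _ledger([(5, 25)])


class TestSubstrate:
    def test_init_divides_by_count(self):
        assert init_substrate_mass(1000.0, 20) == 50.0
        assert init_substrate_mass(0.0, 20) == 0.0

    def test_zero_count_rejected(self):
        with pytest.raises(LedgerError):
            init_substrate_mass(1000.0, 0)


class TestMassPerPlant:
    def test_substrate_subtracted(self):
        ledger = _ledger([], n0=10, m_sub=50.0)
        assert mass_per_plant(1000.0, ledger, START) == pytest.approx(50.0)

    def test_substrate_only_tray_is_zero(self):
        ledger = _ledger([], n0=10, m_sub=50.0)
        assert mass_per_plant(500.0, ledger, START) == 0.0

    def test_after_thinning_uses_updated_count(self):
        ledger = _ledger([(10, 4)], n0=10, m_sub=50.0)
        t = START + pd.Timedelta(days=11)
        assert mass_per_plant(700.0, ledger, t) == pytest.approx(400.0 / 6)

    def test_empty_tray_rejected(self):
        ledger = _ledger([(10, 10)], n0=10, m_sub=50.0)
        with pytest.raises(LedgerError):
            mass_per_plant(100.0, ledger, START + pd.Timedelta(days=11))

    @pytest.mark.parametrize("k", [1, 4, 9])
    def test_average_harvest_leaves_per_plant_mass_unchanged(self, k):
        """Removing k average plants together with their substrate plugs
        does not move the per-plant mass of the remaining plants."""
        m_sub, n, m_plant = 50.0, 10, 30.0
        ledger = _ledger([(5, k)], n0=n, m_sub=m_sub)
        before = mass_per_plant(n * (m_sub + m_plant), ledger, START)
        after = mass_per_plant(
            (n - k) * (m_sub + m_plant), ledger, START + pd.Timedelta(days=6)
        )
        assert before == pytest.approx(m_plant)
        assert after == pytest.approx(m_plant)


class TestAdjustment:
    def test_leaf_fraction(self):
        records = [HarvestRecord("p1", 18, 150.0, 77.0, 23.0)]
        ledger = _ledger([], m_sub=50.0, m_basket=0.0)
        factors = compute_adjustment_factors(records, 150.0, ledger)
        assert factors.c_man == pytest.approx(0.77)

    def test_rootless_limit(self):
        records = [HarvestRecord("p1", 18, 130.0, 80.0, 0.0)]
        ledger = _ledger([], m_sub=50.0)
        assert compute_adjustment_factors(records, 130.0, ledger).c_man == 1.0

    def test_unbiased_sample_gives_unit_c_sample(self):
        records = [HarvestRecord("p1", 18, 160.0, 77.0, 23.0)]
        ledger = _ledger([], m_sub=50.0, m_basket=10.0)
        factors = compute_adjustment_factors(records, 160.0, ledger)
        assert factors.c_sample == pytest.approx(1.0)

    def test_adjust_manual_published_factors(self):
        # c_man = 0.77, c_sample = 0.67: 150 g pot -> 103.43 g leaf estimate
        ledger = _ledger([], m_sub=50.0, m_basket=10.0)
        factors = AdjustmentFactors(c_man=0.77, c_sample=0.67)
        assert adjust_manual(150.0, factors, ledger) == pytest.approx(103.43, abs=0.005)

    def test_identity_and_plantless_limits(self):
        ledger = _ledger([], m_sub=0.0, m_basket=0.0)
        identity = AdjustmentFactors(c_man=0.8, c_sample=0.8)
        assert adjust_manual(42.0, identity, ledger) == pytest.approx(42.0)
        ledger2 = _ledger([], m_sub=50.0, m_basket=10.0)
        assert adjust_manual(60.0, identity, ledger2) == 0.0

    @settings(deadline=None, max_examples=100)
    @given(
        m_man=st.floats(60.0, 500.0),
        c_man=st.floats(0.1, 1.0),
        c_sample=st.floats(0.1, 1.0),
        scale=st.floats(0.2, 1.0),
    )
    def test_linear_in_net_mass_and_scale_invariant(self, m_man, c_man, c_sample, scale):
        """m_man-linearity, and joint rescaling of both factors cancels."""
        ledger = _ledger([], m_sub=50.0, m_basket=10.0)
        base = adjust_manual(m_man, AdjustmentFactors(c_man, c_sample), ledger)
        doubled = adjust_manual(
            2 * m_man - 60.0, AdjustmentFactors(c_man, c_sample), ledger
        )
        assert math.isclose(doubled, 2 * base, rel_tol=1e-9, abs_tol=1e-9)
        scaled = adjust_manual(
            m_man, AdjustmentFactors(c_man * scale, c_sample * scale), ledger
        )
        assert math.isclose(scaled, base, rel_tol=1e-9, abs_tol=1e-9)


class TestAccuracyArithmetic:
    def test_five_kg_cells(self):
        per_cell, tray = sensor_accuracy(5000.0, 0.02, 4)
        assert per_cell == 1.0
        assert tray == 4.0

    def test_zero_accuracy(self):
        assert sensor_accuracy(5000.0, 0.0, 3) == (0.0, 0.0)

    def test_resolution_per_plant(self):
        assert per_plant_resolution(4.0, 10) == pytest.approx(0.4)
        res6 = per_plant_resolution(4.0, 6)
        assert res6 == pytest.approx(2.0 / 3.0)
        assert math.floor(res6 * 100) / 100 == 0.66  # printed two-decimal form
        assert per_plant_resolution(0.0, 5) == 0.0

    def test_zero_plants_rejected(self):
        with pytest.raises(LedgerError):
            per_plant_resolution(4.0, 0)


class TestHarvestError:
    @pytest.mark.parametrize(
        "m_lc,m_leaf,abs_exp,rel_exp",
        [(14.94, 15.19, 0.25, 1.65), (83.15, 83.8, 0.65, 0.78)],
    )
    def test_validation_trial_errors(self, m_lc, m_leaf, abs_exp, rel_exp):
        abs_err, rel_err = harvest_error(m_lc, m_leaf)
        assert abs_err == pytest.approx(abs_exp, abs=1e-9)
        assert round(rel_err, 2) == rel_exp

    def test_equal_inputs(self):
        assert harvest_error(10.0, 10.0) == (0.0, 0.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(LedgerError):
            harvest_error(1.0, 0.0)


class TestRegression:
    def test_identical_vectors(self):
        fit = evaluate_regression([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (fit.slope, fit.intercept, fit.r_squared) == (1.0, 0.0, 1.0)
        assert fit.mae == 0.0 and fit.rmse == 0.0

    def test_exact_proportionality(self):
        fit = evaluate_regression([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noise_reduces_r_squared_consistently(self):
        """R^2 falls below 1 by about noise_var / total_var (OLS oracle)."""
        rng = np.random.default_rng(1234)
        x = np.linspace(10, 100, 200)
        noise = rng.normal(0, 3.0, 200)
        y = 1.5 * x + noise
        fit = evaluate_regression(x, y)
        expected_r2 = 1.0 - noise.var() / y.var()
        assert fit.r_squared == pytest.approx(expected_r2, abs=0.01)

    def test_degenerate_sensor_rejected(self):
        with pytest.raises(LedgerError):
            evaluate_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(LedgerError):
            evaluate_regression([1.0, 2.0], [1.0, 2.0])
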