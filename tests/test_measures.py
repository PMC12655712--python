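"""Feed-diary measurement pipeline: volumes, Eq-style production formula,
intakes, growth z-scores, derived ratios and risk flags."""

import math

import numpy as np
import pandas as pd
import pytest

from milksupply import measures
from milksupply.errors import (
    DataQualityWarning,
    DiaryInvalidError,
    InsufficientEventsError,
    InvalidInputError,
    UndefinedGainError,
    AgeOutOfRangeError,
)
from milksupply.growth import waz, weight_for_waz
from milksupply.measures import (
    FeedDiary,
    FeedEvent,
    FeedKind,
    avg_daily_weight_gain,
    breast_volume,
    bv_change,
    compute_intakes,
    compute_mp_24h,
    delta_waz,
    derive_risk_flags,
    event_volume,
    formula_to_growth_ratio,
    grams_to_ml,
    infer_naked_weight,
)

from conftest import breastfeed, diary_from_feeds


class TestGramsToMl:
    @pytest.mark.parametrize("mass,expected", [(103, 100.0), (0, 0.0), (82.4, 80.0)])
    def test_density_conversion(self, mass, expected):
        assert grams_to_ml(mass) == pytest.approx(expected)

    def test_negative_clamps_with_warning(self):
        with pytest.warns(DataQualityWarning):
            assert grams_to_ml(-3.0) == 0.0

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), None])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            grams_to_ml(bad)


class TestEventVolume:
    def test_weight_difference(self):
        e = FeedEvent(0, 15, FeedKind.BREASTFEED, 5000.0, 5082.4)
        assert event_volume(e) == pytest.approx(80.0)

    def test_zero_difference(self):
        e = FeedEvent(0, 15, FeedKind.BREASTFEED, 5000.0, 5000.0)
        assert event_volume(e) == 0.0

    def test_small_negative_within_scale_tolerance(self):
        e = FeedEvent(0, 15, FeedKind.BREASTFEED, 5000.0, 4999.0)
        with pytest.warns(DataQualityWarning):
            assert event_volume(e) == 0.0

    def test_large_negative_clamped_never_propagated(self):
        e = FeedEvent(0, 15, FeedKind.BREASTFEED, 5000.0, 4950.0)
        with pytest.warns(DataQualityWarning):
            assert event_volume(e) == 0.0

    def test_missing_weight_raises(self):
        e = FeedEvent(0, 15, FeedKind.BREASTFEED, None, 5000.0)
        with pytest.raises(InvalidInputError):
            event_volume(e)


class TestMilkProduction:
    def test_worked_example(self, simple_diary):
        # volumes 80+70+90+60+85 over T = 24.5 h, first feed excluded
        assert compute_mp_24h(simple_diary) == pytest.approx(385 * 24 / 24.5)

    def test_t_equal_24_is_identity(self):
        d = diary_from_feeds([(0, 60), (24, 385)])
        assert compute_mp_24h(d) == pytest.approx(385.0)

    def test_single_feed_errors(self):
        d = diary_from_feeds([(0, 60)])
        with pytest.raises(InsufficientEventsError):
            compute_mp_24h(d)

    def test_span_outside_window_errors(self):
        d = diary_from_feeds([(0, 60), (10, 300)])
        with pytest.raises(DiaryInvalidError):
            compute_mp_24h(d)

    def test_formula_feeds_never_enter_production(self):
        events = [breastfeed(0, 60), breastfeed(24, 385)]
        events.append(FeedEvent(600, 620, FeedKind.FORMULA_BOTTLE, 5000, 5103))
        d = FeedDiary("X", events)
        assert compute_mp_24h(d) == pytest.approx(385.0)

    def test_brute_force_oracle_random_diaries(self):
        """MP equals a direct re-evaluation (sum non-first milk-removal
        volumes x 24/T) on randomly generated diaries."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(3, 15)
            ends = np.sort(rng.uniform(0.5, 22.5, n - 1))
            span = rng.uniform(23.0, 26.0)
            spec = [(0.0, rng.uniform(20, 120))] + [
                (float(h), float(rng.uniform(20, 120))) for h in ends
            ] + [(span, float(rng.uniform(20, 120)))]
            d = diary_from_feeds(spec)
            expected = sum(v for _, v in spec[1:]) * 24.0 / span
            assert compute_mp_24h(d) == pytest.approx(expected, rel=1e-9)

    def test_time_stretch_scales_inversely(self):
        spec = [(0, 60), (5, 80), (12, 90), (24, 70)]
        base = compute_mp_24h(diary_from_feeds(spec))
        stretched = diary_from_feeds([(h * 1.1, v) for h, v in spec])
        assert compute_mp_24h(stretched) == pytest.approx(base / 1.1, rel=1e-12)


class TestIntakes:
    def test_breastmilk_and_formula_split(self):
        events = [breastfeed(0, 50)] + [breastfeed(h, 150) for h in (6, 12, 18, 24)]
        events.append(FeedEvent(500, 515, FeedKind.FORMULA_BOTTLE, 5000, 5103))
        bm, fm, tot = compute_intakes(FeedDiary("X", events))
        assert bm == pytest.approx(600.0)
        assert fm == pytest.approx(100.0)
        assert tot == pytest.approx(700.0)

    def test_no_formula_events_gives_zero(self, simple_diary):
        assert compute_intakes(simple_diary).formula == 0.0

    def test_pump_counts_to_production_not_intake(self):
        events = [breastfeed(0, 50), breastfeed(24, 200)]
        events.append(
            FeedEvent(700, 720, FeedKind.PUMP_EXPRESSION, 1200, 1200 + 103)
        )
        d = FeedDiary("X", events)
        assert compute_mp_24h(d) == pytest.approx(300.0)
        assert compute_intakes(d).breastmilk == pytest.approx(200.0)

    def test_expressed_bottle_counts_to_intake_not_production(self):
        events = [breastfeed(0, 50), breastfeed(24, 200)]
        events.append(
            FeedEvent(700, 715, FeedKind.EXPRESSED_BOTTLE, 5000, 5000 + 103)
        )
        d = FeedDiary("X", events)
        assert compute_mp_24h(d) == pytest.approx(200.0)
        assert compute_intakes(d).breastmilk == pytest.approx(300.0)

    def test_conservation_total_is_sum(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            events = [breastfeed(0, 50)]
            for h in np.sort(rng.uniform(1, 23, 6)):
                events.append(breastfeed(float(h), float(rng.uniform(20, 120))))
            events.append(breastfeed(24.4, 90))
            for h in rng.uniform(1, 23, 2):
                vol = rng.uniform(30, 150) * 1.03
                events.append(
                    FeedEvent(h * 60, h * 60 + 12, FeedKind.FORMULA_BOTTLE,
                              5000, 5000 + vol)
                )
            bm, fm, tot = compute_intakes(FeedDiary("X", events))
            assert tot == pytest.approx(bm + fm, rel=1e-12)


class TestNakedWeight:
    def test_measured_weight_passes_through(self):
        assert infer_naked_weight(5400.0, 5600.0) == 5400.0

    def test_prefeed_weight_minus_clothing_allowance(self):
        assert infer_naked_weight(None, 5600.0) == 5400.0

    def test_both_absent_is_missing(self):
        assert infer_naked_weight(None, None) is None


class TestGrowthZScores:
    def test_weight_at_median_gives_zero(self, ref):
        row = ref.table.iloc[10]
        assert waz(row["M"], row["age_days"], row["sex"], ref) == pytest.approx(0.0)

    def test_closed_form_l_equal_one(self, flat_ref):
        # L=1, M=5000, S=0.1: z = (W/M - 1)/S
        assert waz(5500, 100, "male", flat_ref) == pytest.approx(1.0)

    def test_algebraic_inversion_gives_unit_z(self, ref):
        L, M, S = ref.lms_at("female", 70)
        w = M * (1 + L * S) ** (1 / L)
        assert waz(w, 70, "female", ref) == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_across_grid(self, ref):
        rng = np.random.default_rng(5)
        for _ in range(100):
            z = rng.uniform(-3, 3)
            age = rng.uniform(0, 196)
            sex = rng.choice(["male", "female"])
            w = weight_for_waz(z, age, sex, ref)
            assert waz(w, age, sex, ref) == pytest.approx(z, rel=1e-6, abs=1e-9)

    def test_age_outside_grid_errors(self, ref):
        with pytest.raises(AgeOutOfRangeError):
            waz(5000, 4000, "male", ref)

    def test_delta_waz(self):
        assert delta_waz(0.2, -0.5) == pytest.approx(0.7)
        assert delta_waz(-0.5, 0.2) == pytest.approx(-0.7)
        assert delta_waz(0.3, 0.3) == 0.0
        assert delta_waz(None, 0.1) is None


class TestDailyGain:
    def test_regain_adjusted_divisor(self):
        assert avg_daily_weight_gain(5400, 3400, 58) == pytest.approx(40.0)

    def test_no_gain(self):
        assert avg_daily_weight_gain(3400, 3400, 60) == 0.0

    def test_divisor_one_at_day_nine(self):
        assert avg_daily_weight_gain(3430, 3400, 9) == pytest.approx(30.0)

    def test_within_regain_period_undefined(self):
        with pytest.raises(UndefinedGainError):
            avg_daily_weight_gain(3500, 3400, 8)


class TestFormulaToGrowth:
    @pytest.mark.parametrize(
        "formula,gain,expected",
        [(200, 40, 5.0), (0, 40, 0.0), (0, -5, 0.0), (122, 30.5, 4.0)],
    )
    def test_ratio(self, formula, gain, expected):
        assert formula_to_growth_ratio(formula, gain) == pytest.approx(expected)

    def test_supplementation_without_gain_is_maximal_risk(self):
        assert formula_to_growth_ratio(100, 0) == math.inf
        assert formula_to_growth_ratio(100, -3) == math.inf


class TestBreastVolume:
    @pytest.fixture
    def lookup(self):
        return pd.DataFrame(
            {"band": [12, 12], "cup": ["B", "D"], "volume_cm3": [450, 600]}
        )

    def test_lookup_and_change(self, lookup):
        pre = breast_volume(12, "B", lookup)
        post = breast_volume(12, "D", lookup)
        assert (pre, post) == (450.0, 600.0)
        assert bv_change(pre, post) == 150.0  # >= 100: not minimal growth

    def test_identical_sizes_flag_minimal_growth(self, lookup):
        v = breast_volume(12, "B", lookup)
        assert bv_change(v, v) == 0.0
        assert bv_change(v, v) < measures.MIN_BREAST_GROWTH_CM3

    def test_negative_change_flags_minimal_growth(self):
        # the cohort's most extreme published shrinkage
        assert bv_change(500, 270) == -230.0
        assert bv_change(500, 270) < measures.MIN_BREAST_GROWTH_CM3

    def test_unmapped_size_is_missing(self, lookup):
        assert breast_volume(14, "B", lookup) is None
        assert breast_volume(None, "B", lookup) is None


class TestRiskFlags:
    def test_flags_match_direct_threshold_comparison(self):
        rng = np.random.default_rng(11)
        n = 1000
        df = pd.DataFrame(
            {
                "bmi": np.where(rng.random(n) < 0.1, np.nan, rng.uniform(16, 45, n)),
                "maternal_age": np.where(rng.random(n) < 0.1, np.nan,
                                         rng.uniform(20, 48, n)),
                "bv_change": np.where(rng.random(n) < 0.2, np.nan,
                                      rng.uniform(-250, 700, n)),
            }
        )
        out = derive_risk_flags(df)
        for col, src, thresh, op in [
            ("ow", "bmi", 25.0, "ge"),
            ("advanced_age", "maternal_age", 35.0, "ge"),
            ("minimal_breast_growth", "bv_change", 100.0, "lt"),
        ]:
            missing = df[src].isna()
            assert out.loc[missing, col].isna().all()
            vals = df.loc[~missing, src]
            expect = vals >= thresh if op == "ge" else vals < thresh
            assert (out.loc[~missing, col].astype(bool) == expect).all()
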