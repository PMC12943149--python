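import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import occasions_frame
from tdp.trajectory import (
    apply_exclusions,
    build_hourly_profile,
    chrono_indicators,
    hourly_profiles,
    parse_hhmm,
)


def participant_row(pid="P1", age=70, sex="male", **kw):
    row = {"person_id": pid, "age": age, "sex": sex, "grip1": 30.0, "grip2": 31.0,
           "grip3": 29.0, "weight_loss_kg": 0.0, "stress_level": 3,
           "eq5d_mobility": 1, "eq5d_usual": 1}
    row.update(kw)
    return row


class TestExclusions:
    def make(self, rows, occ_rows):
        return pd.DataFrame(rows), occasions_frame(occ_rows)

    def test_implausible_energy_male_cap(self):
        parts, occ = self.make([participant_row()], [("P1", "dinner", 1100, 6200.0)])
        kept, _, log = apply_exclusions(parts, occ)
        assert len(kept) == 0 and log.removed["implausible_energy"] == 1

    def test_energy_floor_boundary_retained(self):
        parts, occ = self.make([participant_row(sex="female")],
                               [("P1", "dinner", 1100, 500.0)])
        kept, _, log = apply_exclusions(parts, occ)
        assert len(kept) == 1 and log.removed["implausible_energy"] == 0

    def test_female_cap_is_5000(self):
        parts, occ = self.make([participant_row(sex="female")],
                               [("P1", "dinner", 1100, 5200.0)])
        kept, _, _ = apply_exclusions(parts, occ)
        assert len(kept) == 0

    def test_age_cutoff(self):
        parts, occ = self.make([participant_row(age=64)], [("P1", "lunch", 720, 900.0)])
        kept, _, log = apply_exclusions(parts, occ)
        assert len(kept) == 0 and log.removed["age"] == 1

    def test_unknown_sex_rejected(self):
        parts, occ = self.make([participant_row(sex="unknown")],
                               [("P1", "lunch", 720, 900.0)])
        with pytest.raises(ValueError, match="sex"):
            apply_exclusions(parts, occ)

    def test_cascade_order_and_reconciliation(self):
        rows = [
            participant_row("A", age=60),                      # age
            participant_row("B"),                              # no recall
            participant_row("C"),                              # energy too low
            participant_row("D", grip1=np.nan, grip2=np.nan, grip3=np.nan),
            participant_row("E"),                              # retained
        ]
        occ = occasions_frame([("C", "lunch", 720, 300.0),
                               ("D", "lunch", 720, 900.0),
                               ("E", "lunch", 720, 900.0)])
        kept, _, log = apply_exclusions(pd.DataFrame(rows), occ)
        assert log.removed == {"age": 1, "no_recall": 1,
                               "implausible_energy": 1, "missing_frailty": 1}
        assert log.retained_n + sum(log.removed.values()) == log.input_n
        assert kept["person_id"].tolist() == ["E"]

    def test_age_removed_before_recall_check(self):
        # a 60-year-old without recall counts against the age step only
        parts, occ = self.make([participant_row(age=60)], [])
        _, _, log = apply_exclusions(parts, pd.DataFrame(
            columns=["person_id", "occasion_type", "clock_min", "energy_kcal"]))
        assert log.removed["age"] == 1 and log.removed["no_recall"] == 0


class TestHourlyProfile:
    def test_single_dinner_spreads_over_window(self):
        prof = build_hourly_profile(occasions_frame([("P1", "dinner", 1130, 600.0)]))
        assert prof[17] == prof[18] == prof[19] == pytest.approx(1 / 3)
        assert prof.sum() == pytest.approx(1.0)

    def test_breakfast_plus_late_snack(self):
        prof = build_hourly_profile(occasions_frame([
            ("P1", "breakfast", 450, 300.0),
            ("P1", "snack", 21 * 60 + 40, 300.0),
        ]))
        assert prof[6] == prof[7] == prof[8] == pytest.approx(1 / 6)
        assert prof[21] == pytest.approx(0.5)

    def test_midnight_snack_floor_rule(self):
        prof = build_hourly_profile(occasions_frame([("P1", "snack", 10, 200.0)]))
        assert prof[0] == pytest.approx(1.0)

    def test_meal_time_ignored_for_meals(self):
        # a dinner reported at 21:30 still lands in the standard window
        prof = build_hourly_profile(occasions_frame([("P1", "dinner", 1290, 600.0)]))
        assert prof[21] == 0.0 and prof[17] == pytest.approx(1 / 3)

    def test_zero_energy_undefined(self):
        with pytest.raises(ValueError, match="zero total"):
            build_hourly_profile(occasions_frame([("P1", "lunch", 720, 0.0)]))

    def test_vectorized_matches_single(self, small_cohort):
        occ = small_cohort.occasions.copy()
        occ["clock_min"] = occ["time_hhmm"].map(parse_hhmm)
        wide = hourly_profiles(occ)
        bins = wide[[f"h{h:02d}" for h in range(24)]]
        for pid in list(bins.index[:20]):
            single = build_hourly_profile(occ[occ.person_id == pid])
            assert np.allclose(bins.loc[pid].to_numpy(), single, atol=1e-12)

    @given(st.lists(
        st.tuples(st.sampled_from(["breakfast", "lunch", "dinner", "snack"]),
                  st.integers(0, 1439), st.floats(1.0, 2000.0)),
        min_size=1, max_size=8))
    @settings(deadline=None, max_examples=60)
    def test_bins_sum_to_one_and_order_invariant(self, rows):
        occ = occasions_frame([("P", k, t, e) for k, t, e in rows])
        prof = build_hourly_profile(occ)
        assert prof.sum() == pytest.approx(1.0, abs=1e-9)
        assert (prof >= 0).all()
        shuffled = occ.sample(frac=1.0, random_state=0)
        assert np.allclose(prof, build_hourly_profile(shuffled), atol=1e-12)


class TestChronoIndicators:
    def test_window_and_midpoint(self):
        ind = chrono_indicators(occasions_frame([
            ("P1", "breakfast", 7 * 60, 300.0), ("P1", "dinner", 19 * 60, 500.0)]))
        row = ind.loc["P1"]
        assert row.eating_window == 12 * 60
        assert row.eat_midpoint == 13 * 60

    def test_night_eating_counts_as_evening(self):
        ind = chrono_indicators(occasions_frame([("P1", "snack", 2 * 60, 400.0)]))
        assert ind.loc["P1", "evening_share"] == 1.0

    def test_skip_flags(self):
        ind = chrono_indicators(occasions_frame([
            ("P1", "breakfast", 420, 300.0), ("P1", "dinner", 1140, 500.0)]))
        row = ind.loc["P1"]
        assert row.skipped_lunch and not row.skipped_breakfast and not row.skipped_dinner

    def test_reported_times_used_not_standardized(self):
        # dinner reported 21:30: eating window runs to 21:30
        ind = chrono_indicators(occasions_frame([
            ("P1", "breakfast", 420, 300.0), ("P1", "dinner", 1290, 500.0)]))
        assert ind.loc["P1", "last_eat"] == 1290

    @given(st.lists(
        st.tuples(st.sampled_from(["breakfast", "lunch", "dinner", "snack"]),
                  st.integers(0, 1439), st.floats(1.0, 2000.0)),
        min_size=1, max_size=8))
    @settings(deadline=None, max_examples=60)
    def test_share_partition_and_window_nonneg(self, rows):
        ind = chrono_indicators(occasions_frame([("P", k, t, e) for k, t, e in rows]))
        row = ind.iloc[0]
        assert row.morning_share + row.daytime_share + row.evening_share == pytest.approx(1.0)
        assert row.eating_window >= 0
        assert row.eat_midpoint == pytest.approx(row.first_eat + row.eating_window / 2)


def test_parse_hhmm_validation():
    assert parse_hhmm("00:10") == 10
    assert parse_hhmm(1439) == 1439
    with pytest.raises(ValueError):
        parse_hhmm(1500)
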