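"""Tumour growth fitting, %TGI and PFS on longitudinal cohorts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mapkdual import TumorCohort, TumorGrowthModel, fit_growth, pfs, tgi
from mapkdual.network import ValidationError


def exponential_cohort(slopes, n_animals=4, days=range(0, 21, 2),
                       baseline=200.0, noise_sd=0.0, seed=0):
    """Noiseless (or lognormal-noised) exponential growth table."""
    rng = np.random.default_rng(seed)
    rows = []
    aid = 0
    for group, slope in slopes.items():
        for _ in range(n_animals):
            for d in days:
                v = baseline * 2.0 ** (slope * d)
                if noise_sd > 0:
                    v *= math.exp(rng.normal(0.0, noise_sd))
                rows.append(dict(animal=f"a{aid}", group=group, day=float(d),
                                 volume_mm3=v))
            aid += 1
    return TumorCohort(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cohort validation
# ---------------------------------------------------------------------------

class TestTumorCohort:
    def test_rejects_nonpositive_volume(self):
        df = pd.DataFrame(dict(animal=["a"], group=["g"], day=[0.0],
                               volume_mm3=[0.0]))
        with pytest.raises(ValidationError):
            TumorCohort(df)

    def test_rejects_animal_in_two_groups(self):
        df = pd.DataFrame(dict(animal=["a", "a"], group=["g1", "g2"],
                               day=[0.0, 1.0], volume_mm3=[1.0, 2.0]))
        with pytest.raises(ValidationError):
            TumorCohort(df)

    def test_csv_round_trip(self, tmp_path):
        cohort = exponential_cohort({"vehicle": 0.2})
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = TumorCohort.from_csv(path)
        pd.testing.assert_frame_equal(back.data, cohort.data)


# ---------------------------------------------------------------------------
# growth fitting
# ---------------------------------------------------------------------------

class TestFitGrowth:
    def test_noiseless_doubling_time_five_days_gives_slope_point_two(self):
        cohort = exponential_cohort({"g": 1.0 / 5.0})
        fit = fit_growth(cohort)
        assert np.allclose(fit.animal_fits["slope"], 0.2, atol=1e-12)

    def test_flat_volumes_give_zero_slope(self):
        cohort = exponential_cohort({"g": 0.0})
        fit = fit_growth(cohort)
        assert np.allclose(fit.animal_fits["slope"], 0.0, atol=1e-12)

    def test_noisy_group_mean_slope_recovered(self):
        cohort = exponential_cohort({"g": 0.2}, n_animals=10, noise_sd=0.1,
                                    seed=5)
        fit = fit_growth(cohort)
        slope = fit.group_fits.set_index("group").loc["g", "slope"]
        assert abs(slope - 0.2) < 0.02

    def test_short_series_excluded_with_warning(self):
        df = exponential_cohort({"g": 0.2}).data
        extra = pd.DataFrame(dict(animal=["short", "short"], group=["g", "g"],
                                  day=[0.0, 2.0], volume_mm3=[200.0, 250.0]))
        with pytest.warns(UserWarning, match="excluded"):
            fit = fit_growth(TumorCohort(pd.concat([df, extra],
                                                   ignore_index=True)))
        assert "short" not in set(fit.animal_fits["animal"])

    def test_summary_reports_doubling_time(self):
        fit = fit_growth(exponential_cohort({"g": 0.2}))
        assert "doubling" in fit.summary()


# ---------------------------------------------------------------------------
# %TGI
# ---------------------------------------------------------------------------

class TestTgi:
    def test_identical_groups_give_zero(self):
        cohort = exponential_cohort({"vehicle": 0.2, "treated": 0.2})
        assert tgi(cohort, "treated", "vehicle") == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_quarter_auc_gives_seventy_five_percent(self):
        # flat groups: AUC ratio equals the volume ratio exactly
        rows = []
        for group, vol in (("vehicle", 400.0), ("treated", 100.0)):
            for a in range(3):
                for d in range(0, 21, 2):
                    rows.append(dict(animal=f"{group}{a}", group=group,
                                     day=float(d), volume_mm3=vol))
        cohort = TumorCohort(pd.DataFrame(rows))
        assert tgi(cohort, "treated", "vehicle") == pytest.approx(75.0,
                                                                  abs=1e-6)

    def test_matches_analytic_value_for_exponential_vs_stasis(self):
        # oracle: AUC/day of V0*2^(bt) over [0,T] = V0 (2^(bT)-1)/(bT ln 2);
        # treated flat at V0 has AUC/day V0, so
        # %TGI = 100 (1 - bT ln2 / (2^(bT)-1)) -- evaluated independently
        b, T = 0.2, 20.0
        expected = 100.0 * (1.0 - b * T * math.log(2.0) / (2.0 ** (b * T) - 1.0))
        cohort = exponential_cohort({"vehicle": b, "treated": 0.0},
                                    days=np.linspace(0, 20, 11))
        value = tgi(cohort, "treated", "vehicle", window=(0.0, 20.0))
        assert value == pytest.approx(expected, rel=5e-3)

    def test_scale_invariance(self):
        cohort = exponential_cohort({"vehicle": 0.2, "treated": 0.05},
                                    noise_sd=0.05, seed=3)
        ref = tgi(cohort, "treated", "vehicle")
        scaled = TumorCohort(cohort.data.assign(
            volume_mm3=cohort.data["volume_mm3"] * 7.3))
        assert tgi(scaled, "treated", "vehicle") == pytest.approx(ref,
                                                                  abs=1e-9)

    def test_missing_group_rejected(self):
        cohort = exponential_cohort({"vehicle": 0.2})
        with pytest.raises(ValidationError):
            tgi(cohort, "nope", "vehicle")


# ---------------------------------------------------------------------------
# PFS
# ---------------------------------------------------------------------------

class TestPfs:
    def test_noiseless_doubling_in_five_days_events_on_day_five(self):
        cohort = exponential_cohort({"g": 0.2}, days=range(0, 22))
        res = pfs(cohort, threshold_fold=2.0)
        assert np.allclose(res.events["time"], 5.0)
        assert res.medians["g"] == pytest.approx(5.0)

    def test_death_before_doubling_is_the_event(self):
        df = exponential_cohort({"g": 0.2}, n_animals=2,
                                days=range(0, 22)).data
        df["death_day"] = np.where(df["animal"] == "a0", 3.0, np.nan)
        res = pfs(TumorCohort(df))
        ev = res.events.set_index("animal")
        assert ev.loc["a0", "time"] == 3.0 and ev.loc["a0", "cause"] == "death"
        assert ev.loc["a1", "cause"] == "progression"

    def test_never_progressing_animal_is_censored(self):
        cohort = exponential_cohort({"g": 0.01}, days=range(0, 22))
        res = pfs(cohort)
        assert not res.events["event"].any()
        assert math.isinf(res.medians["g"])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(thr1=st.floats(1.2, 2.0), bump=st.floats(0.1, 1.5))
    def test_raising_threshold_never_shortens_event_times(self, thr1, bump):
        cohort = exponential_cohort({"g": 0.2}, n_animals=3, noise_sd=0.08,
                                    seed=9)
        t1 = pfs(cohort, threshold_fold=thr1).events.set_index("animal")
        t2 = pfs(cohort, threshold_fold=thr1 + bump).events.set_index("animal")
        for animal in t1.index:
            assert t2.loc[animal, "time"] >= t1.loc[animal, "time"] - 1e-9


# ---------------------------------------------------------------------------
# model/results facade
# ---------------------------------------------------------------------------

def test_growth_model_facade_round_trip():
    cohort = exponential_cohort({"vehicle": 0.2, "treated": 0.05})
    res = TumorGrowthModel(cohort).fit()
    assert res.tgi("treated", "vehicle") > 0
    assert "group" in res.summary() or "vehicle" in res.summary()
    med = res.pfs().medians
    assert med["vehicle"] < med["treated"]
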