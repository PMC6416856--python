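import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormlife import survival
from wormlife.config import Config
from wormlife.survival import (
    NoEventsError,
    adult_lifespan_transform,
    cox_partial_loglik,
    km_fit,
    median_lifespan,
    ph_compare,
)


class TestKaplanMeier:
    def test_point_mass_cohort(self, lifespan_factory):
        curve = km_fit(lifespan_factory([7] * 10))
        assert curve.survival_at(6.9) == 1.0
        assert curve.survival_at(7.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self, lifespan_factory):
        curve = km_fit(lifespan_factory([2, 4, 6, 8]))
        assert np.allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    def test_hand_product_limit_with_censoring(self, lifespan_factory):
        records = lifespan_factory([2, 3, 4], censored=[False, True, False])
        curve = km_fit(records)
        assert np.allclose(curve.event_times, [2, 4])
        assert curve.survival[0] == pytest.approx(2 / 3)
        assert curve.survival[1] == pytest.approx(0.0)

    def test_all_censored_raises(self, lifespan_factory):
        with pytest.raises(NoEventsError):
            km_fit(lifespan_factory([3, 4], censored=[True, True]))

    @given(
        days=st.lists(st.integers(min_value=1, max_value=30), min_size=1,
                      max_size=40)
    )
    @settings(max_examples=50, deadline=None)
    def test_km_matches_empirical_without_censoring(self, days):
        curve = km_fit(
            pd.DataFrame({"day_of_death": days, "censored": False})
        )
        days_arr = np.array(days)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(np.mean(days_arr > t))
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_matches_lifelines(self, lifespan_factory, rng):
        from lifelines import KaplanMeierFitter

        days = rng.integers(1, 25, 120)
        cens = rng.random(120) < 0.2
        curve = km_fit(lifespan_factory(days, censored=cens))
        kmf = KaplanMeierFitter().fit(days, event_observed=~cens)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )


class TestMedianLifespan:
    def test_simple_median(self, lifespan_factory):
        assert median_lifespan(km_fit(lifespan_factory([1, 2, 3, 4]))) == 2

    def test_undefined_median_flagged_as_nan(self, lifespan_factory):
        records = lifespan_factory(
            [5, 6, 7, 8], censored=[False, True, True, True]
        )
        assert np.isnan(median_lifespan(km_fit(records)))


class TestAdultTransform:
    def test_species_offsets_applied(self, lifespan_factory):
        cfg = Config()
        rec = pd.concat(
            [
                lifespan_factory([19], species="C_elegans_fog2"),
                lifespan_factory([20], species="C_inopinata"),
            ],
            ignore_index=True,
        )
        out = adult_lifespan_transform(rec, cfg)
        assert out["day_of_death"].tolist() == [17, 16]

    def test_negative_result_clamped_and_flagged(self, lifespan_factory):
        out = adult_lifespan_transform(lifespan_factory([1]), Config())
        assert out["day_of_death"].tolist() == [0]
        assert out["clamped"].tolist() == [True]

    def test_unknown_species_raises(self, lifespan_factory):
        with pytest.raises(KeyError):
            adult_lifespan_transform(
                lifespan_factory([5], species="C_briggsae"), Config()
            )

    def test_median_commutes_with_offset_without_clamping(
        self, lifespan_factory
    ):
        rec = lifespan_factory([10, 12, 14, 16, 18])
        med_total = median_lifespan(km_fit(rec))
        med_adult = median_lifespan(
            km_fit(adult_lifespan_transform(rec, Config()))
        )
        assert med_adult == med_total - 2


class TestProportionalHazards:
    def test_identical_groups_give_zero_log_hr(self, lifespan_factory):
        rec = lifespan_factory([3, 5, 5, 8, 12])
        res = ph_compare(rec, rec.copy())
        assert res.log_hazard_ratio == 0.0

    def test_recovers_exponential_rate_ratio(self, rng):
        # continuous lifetimes avoid tie attenuation of the estimate;
        # average a few replicates so the check reflects the estimand
        estimates = []
        for _ in range(3):
            a = pd.DataFrame({"day_of_death": rng.exponential(20, 2000)})
            b = pd.DataFrame({"day_of_death": rng.exponential(10, 2000)})
            res = ph_compare(a, b)
            assert res.z_value == pytest.approx(
                res.log_hazard_ratio / res.std_error
            )
            estimates.append(res.log_hazard_ratio)
        assert np.mean(estimates) == pytest.approx(np.log(2), rel=0.05)

    def test_score_vanishes_at_estimate(self, rng):
        days = np.concatenate([rng.integers(5, 25, 80),
                               rng.integers(3, 18, 80)])
        x = np.concatenate([np.zeros(80), np.ones(80)])
        res = ph_compare(
            pd.DataFrame({"day_of_death": days[:80]}),
            pd.DataFrame({"day_of_death": days[80:]}),
        )
        beta = res.log_hazard_ratio
        eps = 1e-6
        obs = np.ones_like(days, bool)
        deriv = (
            cox_partial_loglik(days.astype(float), obs, x, beta + eps)
            - cox_partial_loglik(days.astype(float), obs, x, beta - eps)
        ) / (2 * eps)
        assert abs(deriv) < 1e-4  # numerical-difference resolution
        # the partial log-likelihood is maximized there
        assert cox_partial_loglik(days.astype(float), obs, x, beta) >= max(
            cox_partial_loglik(days.astype(float), obs, x, beta + 0.01),
            cox_partial_loglik(days.astype(float), obs, x, beta - 0.01),
        )

    def test_label_swap_negates_log_hr(self, rng):
        a = pd.DataFrame({"day_of_death": rng.integers(3, 30, 60)})
        b = pd.DataFrame({"day_of_death": rng.integers(2, 20, 60)})
        fwd = ph_compare(a, b).log_hazard_ratio
        rev = ph_compare(b, a).log_hazard_ratio
        assert fwd + rev == pytest.approx(0.0, abs=1e-10)

    def test_matches_lifelines_efron(self, rng):
        from lifelines import CoxPHFitter

        days = rng.integers(1, 20, 150).astype(float)
        grp = rng.integers(0, 2, 150)
        res = ph_compare(
            pd.DataFrame({"day_of_death": days[grp == 0]}),
            pd.DataFrame({"day_of_death": days[grp == 1]}),
        )
        df = pd.DataFrame({"t": days, "g": grp, "e": 1})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        # lifelines' own stopping rule leaves ~1e-5 slack in its estimate
        assert res.log_hazard_ratio == pytest.approx(
            float(cph.params_.iloc[0]), abs=1e-4
        )
        assert res.std_error == pytest.approx(
            float(cph.standard_errors_.iloc[0]), abs=1e-4
        )

    def test_monotone_likelihood_flagged(self, lifespan_factory):
        a = lifespan_factory([10, 11, 12])
        b = lifespan_factory([1, 2, 3])
        res = ph_compare(a, b)
        assert res.monotone_likelihood
        assert np.isinf(res.log_hazard_ratio)
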