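import numpy as np
import pandas as pd
import pytest

from wormlife import demography, simulate
from wormlife.config import Config
from wormlife.demography import (
    LifeTable,
    bootstrap_r_ci,
    build_life_table,
    euler_lotka_r,
    schedules_from_frame,
    viability_summary,
)


def single_age_table(age, lm):
    ages = np.arange(age + 1)
    l_x = np.ones(age + 1)
    m_x = np.zeros(age + 1)
    m_x[age] = lm
    return LifeTable(ages=ages, l_x=l_x, m_x=m_x)


class TestEulerLotka:
    def test_closed_form_single_age_e(self):
        assert euler_lotka_r(single_age_table(1, np.e)) == pytest.approx(
            1.0, abs=1e-10
        )

    def test_closed_form_ln_r0_over_age(self):
        assert euler_lotka_r(single_age_table(3, 8.0)) == pytest.approx(
            np.log(8) / 3, abs=1e-10
        )

    @pytest.mark.parametrize("age,lm", [(1, 0.2), (2, 5.0), (4, 0.5), (6, 40.0)])
    def test_closed_form_grid_including_declining(self, age, lm):
        assert euler_lotka_r(single_age_table(age, lm)) == pytest.approx(
            np.log(lm) / age, abs=1e-10
        )

    def test_r_zero_iff_r0_one(self):
        assert euler_lotka_r(single_age_table(3, 1.0)) == 0.0

    def test_sign_matches_net_reproductive_rate(self, rng):
        for _ in range(20):
            ages = np.arange(0, 8)
            m_x = np.zeros(8)
            m_x[2:] = rng.random(6) * rng.choice([0.1, 3.0])
            l_x = np.minimum.accumulate(
                np.concatenate([[1.0], rng.random(7)])
            )
            table = LifeTable(ages=ages, l_x=l_x, m_x=m_x)
            if table.net_reproductive_rate <= 0:
                continue
            r = euler_lotka_r(table)
            assert np.sign(r) == np.sign(table.net_reproductive_rate - 1.0)

    def test_monotone_in_fecundity_scaling(self):
        ages = np.arange(6)
        l_x = np.array([1, 0.9, 0.8, 0.7, 0.6, 0.5])
        m_x = np.array([0, 0, 3.0, 4.0, 2.0, 1.0])
        base = euler_lotka_r(LifeTable(ages=ages, l_x=l_x, m_x=m_x))
        up = euler_lotka_r(LifeTable(ages=ages, l_x=l_x, m_x=2 * m_x))
        assert up > base

    def test_decreasing_under_schedule_right_shift(self):
        ages = np.arange(10)
        l_x = np.ones(10)
        m_x = np.zeros(10)
        m_x[2:5] = [3.0, 4.0, 2.0]
        early = euler_lotka_r(LifeTable(ages=ages, l_x=l_x, m_x=m_x))
        shifted = np.zeros(10)
        shifted[4:7] = [3.0, 4.0, 2.0]
        late = euler_lotka_r(LifeTable(ages=ages, l_x=l_x, m_x=shifted))
        assert late < early

    def test_no_reproduction_raises(self):
        table = LifeTable(ages=np.arange(3), l_x=np.ones(3), m_x=np.zeros(3))
        with pytest.raises(ValueError):
            euler_lotka_r(table)

    def test_agrees_with_independent_brent_solver(self):
        params = simulate.preset("C_elegans")
        ages, l_x, m_x = simulate._expected_schedule(params)
        r_bisect = euler_lotka_r(LifeTable(ages=ages, l_x=l_x, m_x=m_x))
        assert r_bisect == pytest.approx(simulate.analytic_r(params), abs=1e-9)


class TestLifeTableConstruction:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LifeTable(ages=np.arange(3), l_x=np.array([1.0, 0.5, 0.7]),
                      m_x=np.zeros(3))
        with pytest.raises(ValueError):
            LifeTable(ages=np.arange(2), l_x=np.array([0.9, 0.8]),
                      m_x=np.zeros(2))

    def test_lossless_cohort(self):
        cfg = Config()
        lifespans = pd.DataFrame({"day_of_death": [30, 30, 30]})
        table = build_life_table(1.0, lifespans, [np.array([10.0])], cfg,
                                 maturation_day=2)
        assert np.allclose(table.l_x[: 4], 1.0)
        assert table.m_x[3] == 10.0
        half = build_life_table(
            1.0, lifespans, [np.array([10.0])],
            cfg.with_overrides(offspring_scaling="daughters_half"),
            maturation_day=2,
        )
        assert half.m_x[3] == 5.0

    def test_viability_sets_adult_plateau(self):
        table = build_life_table(
            0.5, pd.DataFrame({"day_of_death": [40] * 5}),
            [np.array([2.0, 2.0])], Config(), maturation_day=2,
        )
        adult = (table.ages > 2) & (table.ages < 40)
        assert np.allclose(table.l_x[adult], 0.5)

    def test_mean_daily_fecundity_excludes_unobserved(self):
        # one female laid [10], the other [4, 6]; day-2 mean uses only her
        table = build_life_table(
            1.0, pd.DataFrame({"day_of_death": [50] * 4}),
            [np.array([10.0]), np.array([4.0, 6.0])], Config(),
            maturation_day=1,
        )
        assert table.m_x[2] == pytest.approx(7.0)
        assert table.m_x[3] == pytest.approx(6.0)


class TestViabilitySummary:
    def test_single_plate(self):
        df = pd.DataFrame(
            {"plate_id": ["p"], "species": ["C_elegans"],
             "temperature": [25.0], "embryos_initial": [100], "matured": [50]}
        )
        out = viability_summary(df)
        assert out.loc[0, "median_viability"] == 0.5
        assert out.loc[0, "n_plates"] == 1

    def test_group_medians(self, inopinata_sim):
        out = viability_summary(inopinata_sim.viability.df)
        assert abs(out.loc[0, "median_viability"] - 0.79) < 0.06


class TestBootstrap:
    def test_degenerate_cohort_gives_zero_width_interval(self):
        cfg = Config(random_seed=1, bootstrap_reps=50)
        lifespans = pd.DataFrame({"day_of_death": [20] * 10})
        scheds = [np.array([6.0, 4.0])] * 10
        via = pd.DataFrame({"embryos_initial": [100] * 5, "matured": [90] * 5})
        est = bootstrap_r_ci(lifespans, scheds, via, cfg, maturation_day=2)
        assert est.ci_low == pytest.approx(est.r, abs=1e-12)
        assert est.ci_high == pytest.approx(est.r, abs=1e-12)
        assert est.n_failed == 0 and not est.flagged

    def test_recovers_analytic_r_of_generative_model(self):
        params = simulate.preset("C_elegans")
        sim = simulate.simulate_cohort(params, n=400, seed=3)
        cfg = Config(random_seed=3, bootstrap_reps=150)
        est = bootstrap_r_ci(
            sim.lifespan.df,
            schedules_from_frame(sim.fecundity.df),
            sim.viability.df, cfg, maturation_day=params.maturation_day,
        )
        truth = sim.truth["analytic_r"]
        assert est.ci_low <= est.r <= est.ci_high
        assert abs(est.r - truth) < 0.08

    def test_ci_coverage_of_generating_truth(self):
        """Percentile-bootstrap coverage of the true r is near nominal.

        Small cohorts (n=60 females) and a reduced replicate budget keep the
        check brisk; coverage of a 95% interval should land in [90%, 99%].
        """
        params = simulate.preset("C_elegans")
        truth = simulate.analytic_r(params)
        hits = 0
        n_sim = 120
        for s in range(n_sim):
            sim = simulate.simulate_cohort(params, n=60, seed=1000 + s,
                                           n_plates=10)
            cfg = Config(random_seed=s, bootstrap_reps=120)
            est = bootstrap_r_ci(
                sim.lifespan.df, schedules_from_frame(sim.fecundity.df),
                sim.viability.df, cfg, maturation_day=params.maturation_day,
            )
            hits += est.ci_low <= truth <= est.ci_high
        assert 0.90 <= hits / n_sim + 1e-9
        assert hits / n_sim <= 0.99 + 1e-9
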