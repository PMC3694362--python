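"""Synthetic cohort generator: determinism, marginal moments, ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from tickburden.errors import ConfigurationError
from tickburden.nb_glm import fit_nb
from tickburden.synthetic import (
    DEFAULT_BETA_FEMALE,
    DEFAULT_BETA_MALE,
    SimConfig,
    generate_cohort,
    generate_environment,
)


def constant_mu_config(mu, k, n, seed=0):
    """Config whose linear predictor is a bare intercept: every host has mean mu."""
    beta = {name: 0.0 for name in DEFAULT_BETA_MALE}
    beta["intercept"] = float(np.log(mu))
    return SimConfig(
        seed=seed,
        n_years=1,
        n_per_year_by_sex={"male": n, "female": 0},
        beta_male=beta,
        beta_female=beta,
        dispersion_k=k,
    )


class TestEnvironment:
    def test_zero_amplitude_zero_noise_gives_constant_temperature(self):
        cfg = SimConfig(temp_amplitude=0.0, temp_noise_sd=0.0)
        meteo, _ = generate_environment(cfg)
        assert (meteo["tmean"] == cfg.temp_mean).all()

    def test_determinism_under_seed(self):
        cfg = SimConfig(seed=42)
        m1, c1 = generate_environment(cfg)
        m2, c2 = generate_environment(SimConfig(seed=42))
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(c1, c2)
        m3, _ = generate_environment(SimConfig(seed=43))
        assert not m3.equals(m1)

    def test_annual_precipitation_in_mediterranean_band(self):
        # the study area's rainfall ranges 300-700 mm/yr; check the simulated
        # long-run annual mean over 100 years
        cfg = SimConfig(n_years=100, seed=7)
        meteo, _ = generate_environment(cfg)
        meteo = meteo.assign(y=pd.to_datetime(meteo["date"]).dt.year)
        annual = meteo.groupby("y")["precip"].sum()
        annual = annual[(annual.index > cfg.start_year - 1)]  # drop partial first year
        assert 300.0 <= annual.mean() <= 700.0

    def test_census_covers_two_prestudy_years(self):
        _, census = generate_environment(SimConfig())
        assert census["year"].min() == 2002
        assert census["year"].max() == 2010
        assert (census[["deer", "boar", "total_ungulates"]] >= 0).all().all()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="dispersion_k"):
            generate_environment(SimConfig(dispersion_k=-1.0))
        with pytest.raises(ConfigurationError, match="wet_prob"):
            generate_environment(SimConfig(wet_prob=1.5))


class TestCohort:
    def test_record_invariants(self, default_cohort):
        _, _, hosts = default_cohort
        assert (hosts["tick_count"] >= 0).all()
        assert hosts["tick_count"].dtype.kind == "i"
        assert (hosts["ticks_collected"] <= hosts["tick_count"]).all()
        assert hosts["age_class"].between(1, 5).all()
        for col in ("total_length", "thoracic_perimeter", "hind_foot", "kidney_fat_index"):
            assert (hosts[col] > 0).all()
        assert set(hosts["season"]) <= {"winter", "spring", "summer", "autumn"}

    def test_cohort_determinism(self, default_cohort):
        cfg, env, hosts = default_cohort
        again = generate_cohort(cfg, env)
        pd.testing.assert_frame_equal(hosts, again)

    def test_study_sample_sizes(self, default_cohort):
        _, _, hosts = default_cohort
        assert len(hosts) == 306
        assert (hosts["sex"] == "male").sum() == 182
        assert (hosts["sex"] == "female").sum() == 124
        assert hosts.groupby("year").size().to_dict() == {
            2004: 12, 2005: 36, 2006: 56, 2007: 64, 2008: 40, 2009: 60, 2010: 38
        }

    def test_poisson_limit_variance_equals_mean(self):
        cfg = constant_mu_config(mu=5.0, k=1e6, n=50_000, seed=1)
        hosts = generate_cohort(cfg, generate_environment(cfg))
        y = hosts["tick_count"].to_numpy()
        assert y.var() == pytest.approx(y.mean(), rel=0.05)

    def test_nb_variance_identity(self):
        # var = mu + mu^2/k = 5 + 25/0.5 = 55 at mu=5, k=0.5
        cfg = constant_mu_config(mu=5.0, k=0.5, n=50_000, seed=2)
        hosts = generate_cohort(cfg, generate_environment(cfg))
        y = hosts["tick_count"].to_numpy()
        assert y.mean() == pytest.approx(5.0, rel=0.05)
        assert y.var() == pytest.approx(55.0, rel=0.05)

    def test_default_sex_means_match_study(self):
        # published sex means: 20.4 ticks/deer (males), 2.4 (hinds); check the
        # generator's expectation at 5,000 per sex (five cohorts of 1,000/sex,
        # which also averages over five environment realisations)
        mm, ff = [], []
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_per_year_by_sex={"male": 143, "female": 143})
            hosts = generate_cohort(cfg, generate_environment(cfg))
            mm.append(hosts.loc[hosts["sex"] == "male", "tick_count"].mean())
            ff.append(hosts.loc[hosts["sex"] == "female", "tick_count"].mean())
        assert np.mean(mm) == pytest.approx(20.4, rel=0.20)
        assert np.mean(ff) == pytest.approx(2.4, rel=0.20)

    def test_aggregation_for_small_k(self):
        # k <= 1 must give variance exceeding the mean by >= 50% at mu >= 2
        for k in (0.3, 1.0):
            cfg = constant_mu_config(mu=3.0, k=k, n=10_000, seed=3)
            y = generate_cohort(cfg, generate_environment(cfg))["tick_count"].to_numpy()
            assert y.var() >= 1.5 * y.mean()

    def test_true_eta_consistent_with_counts(self, default_cohort):
        _, _, hosts = default_cohort
        assert np.allclose(hosts["true_mu"], np.exp(hosts["true_eta"]), rtol=1e-4)
        # counted burdens should track the retained truth
        hi = hosts.nlargest(50, "true_mu")["tick_count"].mean()
        lo = hosts.nsmallest(50, "true_mu")["tick_count"].mean()
        assert hi > lo

    def test_sex_differential_defaults(self):
        assert DEFAULT_BETA_MALE != DEFAULT_BETA_FEMALE


def recovery_config(seed=0, n_per_sex_year=715):
    """Well-identified config for ground-truth recovery: four active effects,
    each contributing ~0.4-0.6 SD to the linear predictor."""
    beta = {name: 0.0 for name in DEFAULT_BETA_MALE}
    beta.update(intercept=-6.0, total_length=0.03, age_class=0.45, avt_m=0.09,
                deer_census=0.010)
    return SimConfig(
        seed=seed,
        n_per_year_by_sex={"male": n_per_sex_year, "female": n_per_sex_year},
        beta_male=beta,
        beta_female=beta,
        dispersion_k=1.0,
    )


PRED_MAP = {
    "total_length": "TL", "age_class": "age_class", "avt_m": "AvT_M",
    "deer_census": "Deer_C",
}


class TestGroundTruthRecovery:
    def test_coefficients_recovered_within_ten_percent(self):
        from tickburden.covariates import build_design

        cfg = recovery_config(seed=17)
        env = generate_environment(cfg)
        hosts = generate_cohort(cfg, env)
        md = build_design(hosts, env[0], env[1])
        males = md.frame[md.frame["sex"] == "male"]
        fit = fit_nb(males, list(PRED_MAP.values()))
        for raw, col in PRED_MAP.items():
            truth = cfg.beta_male[raw]
            assert fit.params[col] == pytest.approx(truth, rel=0.10)
        assert fit.theta == pytest.approx(cfg.dispersion_k, rel=0.15)

    def test_wald_coverage_over_replicates(self):
        # 95% Wald CIs should cover each true coefficient 90-98% of the time
        from tickburden.covariates import build_design

        hits = {col: 0 for col in PRED_MAP.values()}
        n_rep = 200
        for rep in range(n_rep):
            cfg = recovery_config(seed=1000 + rep, n_per_sex_year=60)
            env = generate_environment(cfg)
            hosts = generate_cohort(cfg, env)
            md = build_design(hosts, env[0], env[1])
            males = md.frame[md.frame["sex"] == "male"]
            fit = fit_nb(males, list(PRED_MAP.values()))
            for raw, col in PRED_MAP.items():
                truth = cfg.beta_male[raw]
                lo = fit.params[col] - 1.96 * fit.bse[col]
                hi = fit.params[col] + 1.96 * fit.bse[col]
                hits[col] += lo <= truth <= hi
        for col, h in hits.items():
            assert 0.90 <= h / n_rep <= 0.98, f"coverage for {col}: {h / n_rep:.3f}"
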