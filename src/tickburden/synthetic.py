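"""Synthetic red deer cohorts with known ground truth.

The original individual-level records are not public, so the analysis chain is
exercised on simulated cohorts that reproduce the study's data structure:

* 306 deer over 7 years (182 males / 124 hinds), with the published per-year
  sample sizes and a seasonal sampling mix dominated by autumn and winter;
* sex x age-class morphometrics drawn from the published moments (total
  length, thoracic perimeter, hind foot, kidney fat index);
* daily Mediterranean meteorology (cold winters, hot dry summers, 300-700 mm
  annual rainfall) from a single station, and annual ungulate censuses with
  two pre-study years so census lags exist;
* negative-binomial burdens whose log-mean is a sex-specific linear predictor
  over host, population and environmental covariates.  The default
  coefficient vectors encode the study's headline contrast: individual and
  population terms dominate the linear-predictor variance for males, while
  environmental terms dominate for hinds.  The true linear predictor is kept
  on every record for recovery tests.

The burden response is the COUNTED tick total.  Collected ticks mimic the
field protocol: every tick is collected below 30, and a binomial subsample
above 30.

Default coefficient magnitudes follow the sign structure of the published
models; the two intercepts were calibrated once so the simulated sex means
match the published 20.4 (males) and 2.4 (hinds) ticks/deer.  Conditional
dispersion (NB size given covariates) defaults to k = 1; the *marginal*
aggregation is much stronger (k_eff around 0.2-0.4) because of covariate
heterogeneity, matching the strong aggregation typical of tick burdens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import studydata
from .covariates import attach_windows
from .errors import ConfigurationError, CoverageError

SEASON_MONTHS = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
}

#: Order of the coefficient vector entries (linear predictor on the log scale).
COEF_NAMES = (
    "intercept", "total_length", "age_class", "kfi",
    "avt_m", "ap_m", "aet_m", "deer_census", "boar_census_lag2",
)

# Sex-specific generating coefficients.  Signs follow the published models;
# magnitudes are set so that for males the individual + population terms carry
# most of the linear-predictor variance and for hinds the environmental terms
# do.  Intercepts calibrated to the published sex means (see module docstring).
DEFAULT_BETA_MALE = {
    "intercept": -5.46,
    "total_length": 0.015,
    "age_class": 0.30,
    "kfi": -0.0033,
    "avt_m": 0.05,
    "ap_m": -0.009,
    "aet_m": 0.002,
    "deer_census": 0.010,
    "boar_census_lag2": 0.004,
}
DEFAULT_BETA_FEMALE = {
    "intercept": -3.51,
    "total_length": 0.0105,
    "age_class": 0.21,
    "kfi": -0.0023,
    "avt_m": 0.10,
    "ap_m": -0.018,
    "aet_m": 0.004,
    "deer_census": 0.002,
    "boar_census_lag2": 0.001,
}


def _default_moments() -> dict:
    return {
        (sex, ac): studydata.morphometric_sd(sex, ac)
        for sex in ("male", "female")
        for ac in range(1, 6)
    }


def _default_age_weights() -> dict:
    out = {}
    for sex, counts in studydata.AGE_CLASS_COUNTS.items():
        tot = sum(counts.values())
        out[sex] = {ac: c / tot for ac, c in counts.items()}
    return out


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic study.

    Defaults reproduce the published study conditions; override fields for
    power/recovery experiments (e.g. larger cohorts, different coefficient
    vectors, near-Poisson dispersion).
    """

    n_years: int = 7
    start_year: int = 2004
    #: per-sex sample sizes: either an int per year or a {year: n} mapping
    n_per_year_by_sex: dict = field(default_factory=studydata.default_samples_per_year)
    beta_male: dict = field(default_factory=lambda: dict(DEFAULT_BETA_MALE))
    beta_female: dict = field(default_factory=lambda: dict(DEFAULT_BETA_FEMALE))
    #: NB size given covariates; smaller = more aggregated
    dispersion_k: float = 1.0
    morphometric_moments: dict = field(default_factory=_default_moments)
    age_class_weights: dict = field(default_factory=_default_age_weights)
    season_weights: dict = field(
        default_factory=lambda: {
            s: c / sum(studydata.SEASON_COUNTS.values())
            for s, c in studydata.SEASON_COUNTS.items()
        }
    )
    #: annual census model: mean level and between-year SD per species
    census_base: dict = field(default_factory=lambda: {"deer": 380.0, "boar": 100.0, "other": 75.0})
    census_noise: dict = field(default_factory=lambda: {"deer": 45.0, "boar": 55.0, "other": 25.0})
    #: meteorology: annual temperature sinusoid and a wet-day/gamma rain model
    temp_mean: float = 15.0  # degC
    temp_amplitude: float = 9.5  # degC, peak-to-mean
    temp_peak_doy: int = 207  # late July
    temp_noise_sd: float = 2.0  # degC, day-to-day
    wet_prob: float = 0.22  # mean wet-day probability
    wet_seasonality: float = 0.7  # relative amplitude of the wet-day sinusoid
    wet_peak_doy: int = 330  # late November
    rain_shape: float = 0.8  # gamma shape of wet-day amounts
    rain_scale_mm: float = 8.0  # gamma scale (mm)
    #: field protocol for collected ticks
    collection_cap: int = 30
    collection_thinning: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_years <= 0:
            raise ConfigurationError("n_years must be positive")
        if self.dispersion_k <= 0:
            raise ConfigurationError("dispersion_k must be > 0")
        for sex in ("male", "female"):
            if sex not in self.n_per_year_by_sex:
                raise ConfigurationError(f"n_per_year_by_sex lacks entry for '{sex}'")
            for n in self._per_year(sex).values():
                if n < 0:
                    raise ConfigurationError(f"n_per_year_by_sex[{sex}] has a negative count")
        for beta, name in ((self.beta_male, "beta_male"), (self.beta_female, "beta_female")):
            missing = set(COEF_NAMES) - set(beta)
            if missing:
                raise ConfigurationError(f"{name} lacks coefficient(s): {sorted(missing)}")
        for key, moments in self.morphometric_moments.items():
            for trait, (mean, sd) in moments.items():
                if sd < 0:
                    raise ConfigurationError(
                        f"morphometric_moments[{key}][{trait}] has negative SD"
                    )
        for fieldname in ("temp_noise_sd", "rain_shape", "rain_scale_mm"):
            if getattr(self, fieldname) < 0:
                raise ConfigurationError(f"{fieldname} must be >= 0")
        if not 0.0 <= self.wet_prob <= 1.0:
            raise ConfigurationError("wet_prob must be a probability")
        if not 0.0 <= self.collection_thinning <= 1.0:
            raise ConfigurationError("collection_thinning must be a probability")
        for sp in self.census_base:
            if self.census_noise.get(sp, 0.0) < 0:
                raise ConfigurationError(f"census_noise[{sp}] must be >= 0")

    def _per_year(self, sex: str) -> dict:
        spec = self.n_per_year_by_sex[sex]
        years = range(self.start_year, self.start_year + self.n_years)
        if isinstance(spec, int):
            return {y: spec for y in years}
        return {y: int(spec.get(y, 0)) for y in years}

    @property
    def years(self) -> list:
        return list(range(self.start_year, self.start_year + self.n_years))

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def generate_environment(config: SimConfig):
    """Daily meteorology and annual censuses for the study span.

    Meteorology covers from 1 November two months before the first study year
    through 31 December of the last year, so every possible sampling date has
    a full 30-day window.  Censuses include two pre-study years so lags t-1
    and t-2 exist for year one.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])

    start = date(config.start_year - 1, 11, 1)
    end = date(config.start_year + config.n_years - 1, 12, 31)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    phase = 2.0 * np.pi * (doy - config.temp_peak_doy) / 365.25
    tmean = (
        config.temp_mean
        + config.temp_amplitude * np.cos(phase)
        + rng.normal(0.0, config.temp_noise_sd, len(dates))
        if config.temp_noise_sd > 0
        else config.temp_mean + config.temp_amplitude * np.cos(phase)
    )
    wet_phase = 2.0 * np.pi * (doy - config.wet_peak_doy) / 365.25
    p_wet = np.clip(
        config.wet_prob * (1.0 + config.wet_seasonality * np.cos(wet_phase)), 0.0, 1.0
    )
    wet = rng.random(len(dates)) < p_wet
    amounts = np.zeros(len(dates))
    if config.rain_shape > 0 and config.rain_scale_mm > 0:
        amounts[wet] = rng.gamma(config.rain_shape, config.rain_scale_mm, int(wet.sum()))
    meteo = pd.DataFrame(
        {"date": dates.date.astype(str), "tmean": np.round(tmean, 3), "precip": np.round(amounts, 3)}
    )

    census_years = range(config.start_year - 2, config.start_year + config.n_years)
    rows = []
    for y in census_years:
        counts = {}
        for sp, base in config.census_base.items():
            noise = config.census_noise.get(sp, 0.0)
            val = base + (rng.normal(0.0, noise) if noise > 0 else 0.0)
            counts[sp] = max(int(round(val)), 0)
        rows.append(
            {
                "year": y,
                "deer": counts.get("deer", 0),
                "boar": counts.get("boar", 0),
                "total_ungulates": sum(counts.values()),
            }
        )
    census = pd.DataFrame(rows)
    return meteo, census


def season_of(month: int) -> str:
    for season, months in SEASON_MONTHS.items():
        if month in months:
            return season
    raise ValueError(f"bad month {month}")


def _sample_dates(rng, year: int, n: int, weights: dict) -> list:
    """Sampling dates for one year: season by the study's seasonal mix, then a
    uniform day within the season's months of that calendar year."""
    seasons = list(SEASON_MONTHS)
    probs = np.array([weights.get(s, 0.0) for s in seasons], dtype=float)
    probs = probs / probs.sum()
    out = []
    picks = rng.choice(len(seasons), size=n, p=probs)
    for s_idx in picks:
        months = SEASON_MONTHS[seasons[s_idx]]
        m = int(months[rng.integers(len(months))])
        first = date(year, m, 1)
        next_month = date(year + (m == 12), (m % 12) + 1, 1)
        span = (next_month - first).days
        out.append(first + timedelta(days=int(rng.integers(span))))
    return out


def generate_cohort(config: SimConfig, environment) -> pd.DataFrame:
    """One synthetic cohort: host records with burdens and retained ground truth.

    ``environment`` is the ``(meteo, census)`` pair from
    :func:`generate_environment`.  Draw order is fixed (year-major, males then
    females), so identical seed + config gives byte-identical tables.
    """
    config.validate()
    meteo, census = environment
    rng = np.random.default_rng([config.seed, 202])
    census_idx = census.set_index("year")
    meteo_dates = pd.to_datetime(meteo["date"])
    cover_lo = meteo_dates.min() + pd.Timedelta(days=30)
    cover_hi = meteo_dates.max()

    betas = {"male": config.beta_male, "female": config.beta_female}
    records = []
    for year in config.years:
        for y_lag in (year, year - 1, year - 2):
            if y_lag not in census_idx.index:
                raise CoverageError(f"census series lacks year {y_lag} needed for lags")
        deer_c = float(census_idx.loc[year, "deer"])
        boar_c2 = float(census_idx.loc[year - 2, "boar"])
        for sex in ("male", "female"):
            n = config._per_year(sex)[year]
            if n == 0:
                continue
            ages = rng.choice(
                list(config.age_class_weights[sex]),
                size=n,
                p=list(config.age_class_weights[sex].values()),
            )
            dates = _sample_dates(rng, year, n, config.season_weights)
            for i, (ac, d) in enumerate(zip(ages, dates)):
                ts = pd.Timestamp(d)
                if not cover_lo <= ts <= cover_hi:
                    raise CoverageError(
                        f"sampling date {d} outside meteorology coverage "
                        f"[{cover_lo.date()}, {cover_hi.date()}]"
                    )
                moments = config.morphometric_moments[(sex, int(ac))]
                tl = max(rng.normal(*moments["TL"]), 1.0)
                tp = max(rng.normal(*moments["TP"]), 1.0)
                hf = max(rng.normal(*moments["HF"]), 1.0)
                kfi_mean, kfi_sd = moments["KFI"]
                if kfi_sd > 0:
                    shape = (kfi_mean / kfi_sd) ** 2
                    # floor keeps the index strictly positive after rounding
                    kfi = max(rng.gamma(shape, kfi_sd**2 / kfi_mean), 0.1)
                else:
                    kfi = kfi_mean
                records.append(
                    {
                        "host_id": f"{year}-{sex[0].upper()}{i + 1:03d}",
                        "sampling_date": d.isoformat(),
                        "year": year,
                        "season": season_of(d.month),
                        "sex": sex,
                        "age_class": int(ac),
                        "total_length": round(tl, 1),
                        "thoracic_perimeter": round(tp, 1),
                        "hind_foot": round(hf, 1),
                        "kidney_fat_index": round(float(kfi), 1),
                        "deer_census": deer_c,
                        "boar_census_lag2": boar_c2,
                    }
                )
    hosts = pd.DataFrame(records)
    if hosts.empty:
        raise ConfigurationError("configuration yields an empty cohort")
    hosts = attach_windows(hosts, meteo)

    eta = np.zeros(len(hosts))
    for sex in ("male", "female"):
        mask = (hosts["sex"] == sex).to_numpy()
        b = betas[sex]
        eta[mask] = (
            b["intercept"]
            + b["total_length"] * hosts.loc[mask, "total_length"].to_numpy()
            + b["age_class"] * hosts.loc[mask, "age_class"].to_numpy()
            + b["kfi"] * hosts.loc[mask, "kidney_fat_index"].to_numpy()
            + b["avt_m"] * hosts.loc[mask, "AvT_M"].to_numpy()
            + b["ap_m"] * hosts.loc[mask, "AP_M"].to_numpy()
            + b["aet_m"] * hosts.loc[mask, "AET_M"].to_numpy()
            + b["deer_census"] * hosts.loc[mask, "deer_census"].to_numpy()
            + b["boar_census_lag2"] * hosts.loc[mask, "boar_census_lag2"].to_numpy()
        )
    mu = np.exp(eta)
    k = config.dispersion_k
    counts = rng.negative_binomial(k, k / (k + mu))
    over = np.maximum(counts - config.collection_cap, 0)
    collected = np.minimum(counts, config.collection_cap) + rng.binomial(
        over, config.collection_thinning
    )
    hosts["tick_count"] = counts.astype(int)
    hosts["ticks_collected"] = collected.astype(int)
    hosts["true_eta"] = np.round(eta, 6)
    hosts["true_mu"] = np.round(mu, 6)
    hosts = hosts.drop(columns=["deer_census", "boar_census_lag2"])
    return hosts


def write_outputs(config: SimConfig, environment, hosts: pd.DataFrame, outdir) -> dict:
    """Write hosts.csv, meteo_daily.csv, census.csv and ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meteo, census = environment
    paths = {
        "hosts": outdir / "hosts.csv",
        "meteo": outdir / "meteo_daily.csv",
        "census": outdir / "census.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    hosts.to_csv(paths["hosts"], index=False, lineterminator="\r\n")
    meteo.to_csv(paths["meteo"], index=False, lineterminator="\r\n")
    census.to_csv(paths["census"], index=False, lineterminator="\r\n")
    truth = {
        "seed": config.seed,
        "dispersion_k": config.dispersion_k,
        "beta_male": config.beta_male,
        "beta_female": config.beta_female,
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
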