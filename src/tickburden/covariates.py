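"""Predictor construction for the tick-burden models.

Three ingredients feed the burden models beyond the host's own traits:

* 30-day pre-sampling meteorology windows — the average of daily mean
  temperatures (``AvT_M``, degC) and the accumulated precipitation (``AP_M``,
  mm) over the 30 days strictly before the sampling date (half-open window:
  the sampling day itself is excluded);
* the Turc actual evapotranspiration ``AET_M`` (mm), a hydric-stress index
  computed from those two aggregates;
* annual ungulate censuses at lags 0, 1 and 2 years (tick generations take
  more than one year, so past host abundance carries information about the
  current questing-tick population).

``build_design`` joins everything into one modelling table and tags each
predictor with its factor group (Ind / Pop / Env) for the deviance
partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoverageError, MissingDataError, SchemaError

FACTORS = ("Ind", "Pop", "Env")

#: Default factor-group assignment for the full predictor set.
DEFAULT_GROUPING = {
    "TL": "Ind",
    "age_class": "Ind",
    "KFI": "Ind",
    "sex_female": "Ind",
    "Deer_C": "Pop",
    "Deer_C_t1": "Pop",
    "Deer_C_t2": "Pop",
    "Boar_C": "Pop",
    "Boar_C_t1": "Pop",
    "Boar_C_t2": "Pop",
    "AvT_M": "Env",
    "AP_M": "Env",
    "AET_M": "Env",
    "year": "Env",
}

#: Bookkeeping columns carried through build_design alongside the predictors.
BOOKKEEPING = ["host_id", "sampling_date", "season", "sex", "tick_count"]


def turc_aet(t, p, cap_at_precipitation: bool = False):
    """Turc actual evapotranspiration (mm) from mean temperature and precipitation.

    AET = P / sqrt(0.9 + P^2 / L^2) with the heat term L = 300 + 25 t + 0.05 t^3,
    where ``t`` is the mean temperature (degC) and ``p`` the accumulated
    precipitation (mm) of the period.  At P = 0 the index is 0; it increases
    monotonically in P and is bounded above by P / sqrt(0.9).

    Parameters
    ----------
    t, p
        Scalars or arrays (broadcast together).  ``p`` must be >= 0.
    cap_at_precipitation
        If True, cap the result at P (the classical AET <= P convention).
        Off by default: the raw formula is what the burden models use.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("precipitation must be non-negative")
    heat = 300.0 + 25.0 * t + 0.05 * t**3
    if np.any(heat <= 0):
        bad = np.atleast_1d(t)[np.atleast_1d(heat) <= 0]
        raise ValueError(
            f"Turc heat term L = 300 + 25t + 0.05t^3 is non-positive at t = {bad[0]:.2f} degC"
        )
    aet = p / np.sqrt(0.9 + p**2 / heat**2)
    if cap_at_precipitation:
        aet = np.minimum(aet, p)
    return float(aet) if aet.ndim == 0 else aet


@dataclass(frozen=True)
class MeteoWindow:
    """30-day pre-sampling meteorology aggregates for one host record."""

    avt_m: float  #: mean of daily mean temperatures, degC
    ap_m: float  #: accumulated precipitation, mm
    aet_m: float  #: Turc AET of the window, mm
    heat_term: float  #: Turc L (intermediate), for diagnostics


def window_aggregate(daily: pd.DataFrame, sampling_date, window_days: int = 30) -> MeteoWindow:
    """Aggregate a daily meteorology series over the window before a sampling date.

    The window is half-open: it covers the ``window_days`` days strictly before
    ``sampling_date`` (the sampling day itself is excluded).  Every day in the
    window must be present; missing days raise :class:`MissingDataError` listing
    the dates rather than silently imputing.

    ``daily`` needs columns ``date`` (datetime-like), ``tmean`` (degC) and
    ``precip`` (mm).
    """
    for col in ("date", "tmean", "precip"):
        if col not in daily.columns:
            raise SchemaError(f"daily meteorology series lacks column '{col}'")
    sampling_date = pd.Timestamp(sampling_date).normalize()
    start = sampling_date - pd.Timedelta(days=window_days)
    dates = pd.to_datetime(daily["date"]).dt.normalize()
    mask = (dates >= start) & (dates < sampling_date)
    got = set(dates[mask])
    wanted = {start + pd.Timedelta(days=i) for i in range(window_days)}
    missing = sorted(wanted - got)
    if missing:
        shown = ", ".join(d.date().isoformat() for d in missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise MissingDataError(
            f"meteorology window before {sampling_date.date()} is missing "
            f"{len(missing)} day(s): {shown}{more}"
        )
    sub = daily.loc[mask.values]
    avt = float(sub["tmean"].mean())
    ap = float(sub["precip"].sum())
    heat = 300.0 + 25.0 * avt + 0.05 * avt**3
    return MeteoWindow(avt_m=avt, ap_m=ap, aet_m=turc_aet(avt, ap), heat_term=heat)


def attach_windows(hosts: pd.DataFrame, meteo: pd.DataFrame, window_days: int = 30) -> pd.DataFrame:
    """Vectorised :func:`window_aggregate` over a host table.

    Returns a copy of ``hosts`` with columns AvT_M, AP_M, AET_M.  Uses rolling
    sums over the (gap-free, sorted) daily series; gaps anywhere under a
    sampling window raise as in :func:`window_aggregate`.
    """
    daily = meteo.copy()
    daily["date"] = pd.to_datetime(daily["date"]).dt.normalize()
    daily = daily.sort_values("date").reset_index(drop=True)
    full = pd.date_range(daily["date"].iloc[0], daily["date"].iloc[-1], freq="D")
    gap_free = len(full) == len(daily) and (daily["date"].values == full.values).all()

    out = hosts.copy()
    dates = pd.to_datetime(out["sampling_date"])
    if not gap_free:
        # fall back to the per-record path, which reports missing days precisely
        windows = [window_aggregate(daily, d, window_days) for d in dates]
        out["AvT_M"] = [w.avt_m for w in windows]
        out["AP_M"] = [w.ap_m for w in windows]
        out["AET_M"] = [w.aet_m for w in windows]
        return out

    tsum = daily["tmean"].rolling(window_days).sum().to_numpy()
    psum = daily["precip"].rolling(window_days).sum().to_numpy()
    # rolling value at index i covers days i-window+1 .. i; for a sampling date d
    # the window ends at d-1, i.e. index pos(d) - 1
    pos = full.get_indexer(dates.dt.normalize())
    if np.any(pos < window_days):
        first_bad = dates.iloc[int(np.argmin(pos))].date()
        raise CoverageError(
            f"meteorology series does not cover the {window_days}-day window "
            f"before sampling date {first_bad}"
        )
    avt = tsum[pos - 1] / window_days
    ap = psum[pos - 1]
    out["AvT_M"] = avt
    out["AP_M"] = ap
    out["AET_M"] = turc_aet(avt, ap)
    return out


def lag_census(census: pd.DataFrame, year: int, lag: int, species: str = "deer") -> int:
    """Census count for ``year - lag`` (lag in {0, 1, 2})."""
    if lag not in (0, 1, 2):
        raise ConfigurationError(f"lag must be 0, 1 or 2, got {lag}")
    if species not in census.columns:
        raise SchemaError(f"census table lacks column '{species}'")
    target = year - lag
    row = census.loc[census["year"] == target, species]
    if row.empty:
        raise CoverageError(f"census series has no year {target} (year={year}, lag={lag})")
    return int(row.iloc[0])


@dataclass(frozen=True)
class FactorGrouping:
    """Mapping predictor name -> factor label ('Ind', 'Pop' or 'Env')."""

    mapping: dict = field(default_factory=lambda: dict(DEFAULT_GROUPING))

    def __post_init__(self):
        for name, label in self.mapping.items():
            if label not in FACTORS:
                raise ConfigurationError(
                    f"grouping for predictor '{name}' must be one of {FACTORS}, got '{label}'"
                )

    def group(self, predictor: str) -> str:
        if predictor not in self.mapping:
            raise ConfigurationError(f"predictor '{predictor}' is missing from the factor grouping")
        return self.mapping[predictor]

    def members(self, factor: str, predictors=None) -> list:
        """Predictors assigned to ``factor`` (optionally restricted to a subset)."""
        pool = self.mapping if predictors is None else [p for p in predictors]
        return [p for p in pool if self.group(p) == factor]

    @property
    def predictors(self) -> list:
        return list(self.mapping)


@dataclass
class ModelData:
    """One modelling table: response, predictors and their factor grouping."""

    frame: pd.DataFrame
    grouping: FactorGrouping
    response: str = "tick_count"

    @property
    def predictors(self) -> list:
        return [p for p in self.grouping.predictors if p in self.frame.columns]

    def subset(self, mask) -> "ModelData":
        return ModelData(self.frame.loc[mask].reset_index(drop=True), self.grouping, self.response)


def build_design(
    hosts: pd.DataFrame,
    meteo: pd.DataFrame,
    census: pd.DataFrame,
    grouping: FactorGrouping | None = None,
) -> ModelData:
    """Assemble the modelling table: one row per host, in input order.

    Joins the 30-day meteorology window and the lagged censuses onto the host
    records and renames host traits to the model's predictor names (TL, KFI,
    sex_female with males as reference).  Rows are never dropped or reordered.
    """
    grouping = grouping or FactorGrouping()
    schema = BOOKKEEPING + [p for p in grouping.predictors]
    if hosts.empty:
        return ModelData(pd.DataFrame(columns=schema), grouping)

    required = ["host_id", "sampling_date", "year", "season", "sex", "age_class",
                "total_length", "kidney_fat_index", "tick_count"]
    for col in required:
        if col not in hosts.columns:
            raise SchemaError(f"host table lacks column '{col}'")

    if {"AvT_M", "AP_M", "AET_M"}.issubset(hosts.columns):
        out = hosts.copy()
    else:
        out = attach_windows(hosts, meteo)

    out = out.rename(columns={"total_length": "TL", "kidney_fat_index": "KFI"})
    out["sex_female"] = (out["sex"] == "female").astype(int)
    years = out["year"].astype(int)
    for lag, suffix in ((0, ""), (1, "_t1"), (2, "_t2")):
        for species, label in (("deer", "Deer_C"), ("boar", "Boar_C")):
            lut = dict(zip(census["year"].astype(int), census[species].astype(int)))
            wanted = years - lag
            missing = ~wanted.isin(lut)
            if missing.any():
                bad = out.loc[missing, "host_id"].iloc[0]
                raise CoverageError(
                    f"host '{bad}': census series has no year "
                    f"{int(wanted[missing].iloc[0])} (lag={lag})"
                )
            out[f"{label}{suffix}"] = wanted.map(lut)
    out["year"] = out["year"].astype(float)

    for p in grouping.predictors:
        if p not in out.columns:
            raise ConfigurationError(f"predictor '{p}' from the grouping is not constructible")
    keep = [c for c in schema if c in out.columns] + [
        c for c in ("true_eta", "true_mu", "ticks_collected") if c in out.columns
    ]
    return ModelData(out[keep].reset_index(drop=True), grouping)
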