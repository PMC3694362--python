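"""Negative-binomial GLM engine: fitting, diagnostics and stepwise AIC selection.

Tick burdens are overdispersed counts (aggregated parasites), so the models use
the NB2 negative binomial with a log link.  The dispersion parameter is the
*size* theta, with variance mu + mu^2/theta — smaller theta means stronger
aggregation.  Note that many implementations parameterise by alpha = 1/theta;
everything in this package is on the size scale.

Fitting alternates two steps, as in the classic ecology workflow:

1. given theta, update the coefficients beta by iteratively reweighted least
   squares (delegated to :mod:`statsmodels` with a fixed-size NB family);
2. given the fitted means, update theta by univariate maximum likelihood.

The loop stops when the joint log-likelihood changes by < 1e-8 (or after 100
outer iterations, in which case the fit is flagged, never silently returned).

AIC counts theta as one estimated parameter: AIC = -2 loglik + 2 (|beta| + 1).
The null deviance for the explained-deviance proportion is computed at the
*same* theta as the fitted model, since deviance differences are only
comparable at a common dispersion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from .covariates import ModelData
from .errors import SchemaError, SingularityError, ValidationError

log = logging.getLogger(__name__)

_THETA_MIN, _THETA_MAX = 1e-4, 1e7


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood summed over observations (size ``theta``, mean ``mu``)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    ll = (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )
    return float(np.sum(ll))


def nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB residual deviance 2 sum[y log(y/mu) - (y+theta) log((y+theta)/(mu+theta))],
    with y log(y/mu) taken as 0 at y = 0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    term = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    dev = 2.0 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta)))
    return float(dev)


def _ml_theta(y: np.ndarray, mu: np.ndarray, lo=_THETA_MIN, hi=_THETA_MAX) -> float:
    """Univariate ML update of theta at fixed means, on the log-theta scale."""
    res = optimize.minimize_scalar(
        lambda lt: -nb_loglik(y, mu, float(np.exp(lt))),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


@dataclass
class NBFit:
    """A fitted negative-binomial GLM (log link)."""

    predictors: list
    params: pd.Series  # coefficients on the log scale, 'Intercept' first
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    theta: float
    loglik: float
    deviance: float
    null_deviance: float
    aic: float
    n: int
    fitted: np.ndarray
    converged: bool = True
    status: str = "converged"
    theta_fixed: bool = False
    response: str = "tick_count"

    @property
    def explained_deviance(self) -> float:
        """1 - residual/null deviance; the 'variation explained' that gets partitioned."""
        if self.null_deviance <= 0:
            return 0.0
        return 1.0 - self.deviance / self.null_deviance

    def summary_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "std_errors": {k: float(v) for k, v in self.bse.items()},
            "z_values": {k: float(v) for k, v in self.zvalues.items()},
            "p_values": {k: float(v) for k, v in self.pvalues.items()},
            "theta": float(self.theta),
            "loglik": float(self.loglik),
            "deviance": float(self.deviance),
            "null_deviance": float(self.null_deviance),
            "explained_deviance": float(self.explained_deviance),
            "aic": float(self.aic),
            "n": int(self.n),
            "status": self.status,
            "theta_fixed": bool(self.theta_fixed),
        }


def _design_matrix(frame: pd.DataFrame, predictors) -> np.ndarray:
    missing = [p for p in predictors if p not in frame.columns]
    if missing:
        raise SchemaError(f"data lacks predictor column(s): {missing}")
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[p].to_numpy(dtype=float) for p in predictors]
    )
    return X


def _check_rank(X: np.ndarray, predictors) -> None:
    names = ["Intercept"] + list(predictors)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate dependent columns from the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in range(len(names)) if j < len(diag) and diag[j] <= tol]
        raise SingularityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"suspect collinear columns: {bad or names}"
        )


def _validate_response(y: np.ndarray, response: str) -> None:
    if np.any(y < 0) or np.any(y != np.floor(y)) or not np.all(np.isfinite(y)):
        raise ValidationError(f"response '{response}' must be non-negative integers")


def fit_nb(
    data: ModelData | pd.DataFrame,
    predictors,
    response: str = "tick_count",
    theta: float | None = None,
    max_outer: int = 100,
    tol: float = 1e-8,
) -> NBFit:
    """Fit the NB2 GLM with log link, jointly over (beta, theta).

    Pass ``theta`` to fit at a fixed dispersion (used by the deviance
    partitioning, where all partial models share the full model's theta).
    An all-zero response returns a degenerate fit with status
    ``'degenerate_all_zero'`` rather than crashing; a fit that exhausts
    ``max_outer`` iterations is returned with ``converged=False`` and status
    ``'not_converged'`` and a warning, never silently.
    """
    if isinstance(data, ModelData):
        frame, response = data.frame, data.response
    else:
        frame = data
    predictors = list(predictors)
    if response not in frame.columns:
        raise SchemaError(f"data lacks response column '{response}'")
    y = frame[response].to_numpy(dtype=float)
    _validate_response(y, response)
    n = len(y)
    if n <= len(predictors) + 2:
        raise ValidationError(
            f"need n > p + 2 observations (n={n}, p={len(predictors)})"
        )
    X = _design_matrix(frame, predictors)
    names = ["Intercept"] + predictors
    _check_rank(X, predictors)

    if np.all(y == 0):
        mu = np.full(n, 1e-8)
        zeros = pd.Series(0.0, index=names)
        th = theta if theta is not None else 1.0
        degenerate = pd.Series([-np.inf] + [0.0] * len(predictors), index=names)
        return NBFit(
            predictors=predictors,
            params=degenerate,
            bse=zeros, zvalues=zeros, pvalues=pd.Series(1.0, index=names),
            theta=th, loglik=0.0, deviance=0.0, null_deviance=0.0,
            aic=2.0 * (len(names) + 1), n=n, fitted=mu,
            converged=False, status="degenerate_all_zero",
            theta_fixed=theta is not None, response=response,
        )

    theta_fixed = theta is not None
    if theta_fixed:
        th = float(theta)
        if th <= 0:
            raise ValidationError("theta must be > 0")
        glm_res = _glm_at_theta(y, X, th)
        mu = glm_res.fittedvalues
        ll = nb_loglik(y, mu, th)
        converged, status = bool(glm_res.converged), "converged"
        if not converged:
            status = "not_converged"
            warnings.warn("inner IRLS did not converge at fixed theta", stacklevel=2)
    else:
        ybar, s2 = float(np.mean(y)), float(np.var(y, ddof=1))
        th = ybar**2 / (s2 - ybar) if s2 > ybar else 10.0
        th = float(np.clip(th, 0.01, 1e4))
        ll_prev = -np.inf
        start = None
        converged, status = False, "not_converged"
        for _ in range(max_outer):
            glm_res = _glm_at_theta(y, X, th, start_params=start)
            mu = glm_res.fittedvalues
            start = np.asarray(glm_res.params)
            th = _ml_theta(y, mu)
            ll = nb_loglik(y, mu, th)
            if abs(ll - ll_prev) < tol:
                converged, status = True, "converged"
                break
            ll_prev = ll
        if not converged:
            warnings.warn(
                f"NB fit did not converge in {max_outer} outer iterations "
                f"(last loglik change {abs(ll - ll_prev):.3g})",
                stacklevel=2,
            )

    params = pd.Series(np.asarray(glm_res.params), index=names)
    bse = pd.Series(np.asarray(glm_res.bse), index=names)
    zvals = params / bse.replace(0.0, np.nan)
    from scipy import stats as _st

    pvals = pd.Series(2.0 * _st.norm.sf(np.abs(zvals.to_numpy())), index=names)
    dev = nb_deviance(y, mu, th)
    null_dev = nb_deviance(y, np.full(n, np.mean(y)), th)
    aic = -2.0 * ll + 2.0 * (len(names) + 1)
    return NBFit(
        predictors=predictors, params=params, bse=bse, zvalues=zvals, pvalues=pvals,
        theta=th, loglik=ll, deviance=dev, null_deviance=null_dev, aic=aic, n=n,
        fitted=np.asarray(mu), converged=converged, status=status,
        theta_fixed=theta_fixed, response=response,
    )


def _glm_at_theta(y, X, theta, start_params=None):
    fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=fam)
        return model.fit(start_params=start_params, maxiter=200, tol=1e-10)


def predict_burden(fit: NBFit, newdata: ModelData | pd.DataFrame) -> np.ndarray:
    """Expected burden exp(x . beta) per row of ``newdata`` (strictly positive)."""
    frame = newdata.frame if isinstance(newdata, ModelData) else newdata
    X = _design_matrix(frame, fit.predictors)
    eta = X @ fit.params.to_numpy()
    return np.exp(eta)


def overdispersion_check(
    data: ModelData | pd.DataFrame, predictors, response: str = "tick_count"
) -> float:
    """Pearson chi^2 / df of the Poisson GLM with the same linear predictor.

    Values far above 1 indicate overdispersion (the motivation for the NB
    family); for NB data the statistic approaches 1 + mu/theta.
    """
    if isinstance(data, ModelData):
        frame, response = data.frame, data.response
    else:
        frame = data
    y = frame[response].to_numpy(dtype=float)
    _validate_response(y, response)
    X = _design_matrix(frame, list(predictors))
    _check_rank(X, list(predictors))
    df_resid = len(y) - X.shape[1]
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom for the Poisson check")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu = np.maximum(res.fittedvalues, 1e-300)
    pearson = float(np.sum((y - mu) ** 2 / mu))
    return pearson / df_resid


def vif(data: ModelData | pd.DataFrame, predictors) -> pd.Series:
    """Variance inflation factor per predictor.

    VIF_j = 1 / (1 - R^2_j) from an OLS regression (with intercept) of
    predictor j on all the others.  A constant predictor raises; perfect
    collinearity is reported as ``inf``.
    """
    frame = data.frame if isinstance(data, ModelData) else data
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValidationError("VIF needs at least two predictors")
    Z = {}
    for p in predictors:
        if p not in frame.columns:
            raise SchemaError(f"data lacks predictor column '{p}'")
        v = frame[p].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise ValidationError(f"predictor '{p}' is constant; VIF undefined")
        Z[p] = v
    out = {}
    for p in predictors:
        yj = Z[p]
        X = np.column_stack([np.ones(len(yj))] + [Z[q] for q in predictors if q != p])
        beta, *_ = np.linalg.lstsq(X, yj, rcond=None)
        resid = yj - X @ beta
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        out[p] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class StepwiseResult:
    fit: NBFit
    trace: list = field(default_factory=list)  # (action, term, aic) per accepted move
    skipped: list = field(default_factory=list)  # (action, term, reason) for failed fits


def stepwise_aic(
    data: ModelData | pd.DataFrame,
    candidates,
    scope=None,
    response: str = "tick_count",
) -> StepwiseResult:
    """Forward-backward stepwise selection by AIC over NB fits.

    Starts from the intercept-only model (plus any ``scope`` terms, which are
    always kept) and repeatedly applies the single-term addition or deletion
    with the lowest AIC, provided it is strictly lower than the current AIC.
    Ties are broken by fewer terms, then lexicographic term name.  Any step
    whose fit fails is skipped and logged.  Theta is re-estimated for every
    candidate model, and counts as a parameter in every AIC.
    """
    candidates = list(dict.fromkeys(candidates))
    forced = list(scope) if scope else []
    current = list(forced)
    best = fit_nb(data, current, response=response)
    trace = [("start", None, best.aic)]
    skipped = []

    while True:
        moves = []
        for term in candidates:
            if term in current:
                continue
            trial = current + [term]
            try:
                f = fit_nb(data, trial, response=response)
            except Exception as exc:  # noqa: BLE001 - any fit failure skips the move
                skipped.append(("add", term, repr(exc)))
                log.info("stepwise: skipping add(%s): %s", term, exc)
                continue
            if not f.converged:
                skipped.append(("add", term, f.status))
                continue
            moves.append((f.aic, len(trial), term, "add", f, trial))
        for term in current:
            if term in forced:
                continue
            trial = [t for t in current if t != term]
            try:
                f = fit_nb(data, trial, response=response)
            except Exception as exc:  # noqa: BLE001
                skipped.append(("drop", term, repr(exc)))
                continue
            if not f.converged:
                skipped.append(("drop", term, f.status))
                continue
            moves.append((f.aic, len(trial), term, "drop", f, trial))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        aic, _, term, action, f, trial = moves[0]
        if aic < best.aic - 1e-10:
            best, current = f, trial
            trace.append((action, term, aic))
        else:
            break
    return StepwiseResult(fit=best, trace=trace, skipped=skipped)


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "#"))


def significance_stars(p: float) -> str:
    for level, mark in _STAR_LEVELS:
        if p < level:
            return mark
    return "ns"


def coefficient_table(fits: dict, grouping=None) -> str:
    """Plain-text coefficient/z-value table across models, one row per predictor.

    Mirrors the layout coefficient/test-value with significance marks
    (# 0.1, * 0.05, ** 0.01, *** 0.001); test values are Wald z.
    """
    rows = {}
    order = []
    for model_name, fit in fits.items():
        for name in fit.params.index:
            if name not in rows:
                rows[name] = {}
                order.append(name)
            star = significance_stars(float(fit.pvalues[name]))
            rows[name][model_name] = (
                f"{fit.params[name]:.4f}/{fit.zvalues[name]:.2f} {star}"
            )
    order = [n for n in order if n != "Intercept"] + (
        ["Intercept"] if "Intercept" in rows else []
    )
    headers = list(fits)
    width = 28
    lines = ["Predictor".ljust(20) + "".join(h.ljust(width) for h in headers)]
    for name in order:
        label = name
        if grouping is not None and name in getattr(grouping, "mapping", {}):
            label = f"{name} ({grouping.mapping[name]})"
        lines.append(
            label.ljust(20)
            + "".join(rows[name].get(h, "").ljust(width) for h in headers)
        )
    lines.append("")
    for model_name, fit in fits.items():
        lines.append(
            f"{model_name}: theta={fit.theta:.3f}  AIC={fit.aic:.1f}  "
            f"explained deviance={100 * fit.explained_deviance:.2f}%  n={fit.n}"
        )
    return "\n".join(lines)
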