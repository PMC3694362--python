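"""Cross-sex and split-sample calibration validation.

The design question is whether a burden model fitted on one sex can predict
burdens on the other.  A model is applied unchanged (no recalibration) to the
other dataset, predictions are sorted and split into equal-count bins of
increasing predicted burden, and two aspects are scored:

* precision — does mean observed burden rise monotonically across bins?
  Operationalised as the Spearman rank correlation of bin mean observed
  burden against bin order.
* accuracy — are magnitudes right?  Operationalised as the calibration ratio
  mean(observed) / mean(predicted), overall and per bin (1 = accurate,
  < 1 = overestimation).

"Evenly sized intervals" are read as equal-count (quantile) bins: equal-width
bins on the heavily right-skewed NB predictions would leave most bins empty.
Equal-width binning is available behind a flag.  When a validation set is
small (fewer than 10 records per requested bin) the bin count is halved, to a
minimum of 5, and the reduction is logged — disable with ``auto_reduce=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import ModelData
from .errors import ValidationError
from .nb_glm import NBFit, predict_burden

log = logging.getLogger(__name__)


def split_train_validate(
    data: ModelData | pd.DataFrame,
    train_fraction: float = 0.70,
    seed: int = 0,
    stratify_by: str = "sex",
):
    """Random disjoint, exhaustive train/validation split, stratified by sex.

    Each stratum is permuted and cut at round(fraction * n_stratum), so both
    sets preserve the sex mix to within one record.  Reproducible under seed.
    """
    frame = data.frame if isinstance(data, ModelData) else data
    n = len(frame)
    if n < 10:
        raise ValidationError(f"need at least 10 records to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for _, stratum in frame.groupby(stratify_by, sort=True):
        idx = stratum.index.to_numpy()
        k = int(np.floor(train_fraction * len(idx) + 0.5))
        if k == 0 or k == len(idx):
            raise ValidationError(
                f"stratum of size {len(idx)} too small to appear in both sets "
                f"at fraction {train_fraction}"
            )
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[:k]])
        val_idx.extend(idx[perm[k:]])
    train = frame.loc[sorted(train_idx)].reset_index(drop=True)
    val = frame.loc[sorted(val_idx)].reset_index(drop=True)
    if isinstance(data, ModelData):
        return (
            ModelData(train, data.grouping, data.response),
            ModelData(val, data.grouping, data.response),
        )
    return train, val


@dataclass
class CalibrationTable:
    """Binned observed-vs-predicted burdens plus precision/accuracy metrics."""

    table: pd.DataFrame  # columns: bin, n, mean_predicted, mean_observed, ratio
    n_bins: int
    spearman: float  #: precision: rank corr of bin mean observed vs bin order
    overall_ratio: float  #: accuracy: mean observed / mean predicted
    ols_slope: float
    ols_intercept: float
    reduced: bool = False  #: bin count was auto-halved for sample size
    degenerate: bool = False  #: constant predictions collapsed to one bin

    def metrics_dict(self) -> dict:
        return {
            "n_bins": int(self.n_bins),
            "spearman_precision": float(self.spearman),
            "overall_calibration_ratio": float(self.overall_ratio),
            "ols_slope": float(self.ols_slope),
            "ols_intercept": float(self.ols_intercept),
            "reduced": bool(self.reduced),
            "degenerate": bool(self.degenerate),
        }


def bin_calibration(
    observed,
    predicted,
    n_bins: int = 10,
    auto_reduce: bool = True,
    equal_width: bool = False,
) -> CalibrationTable:
    """Bin records by increasing predicted burden and compare bin means.

    Records are stably sorted by prediction (ties keep input order) and cut
    into ``n_bins`` contiguous equal-count groups (sizes differ by at most 1).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValidationError("observed and predicted must have equal length")
    n = len(observed)
    if n < 5:
        raise ValidationError(f"need at least 5 records to calibrate, got {n}")

    degenerate = bool(np.ptp(predicted) == 0)
    reduced = False
    if degenerate:
        log.warning("constant predictions: calibration collapses to a single bin")
        n_bins_used = 1
    else:
        n_bins_used = min(n_bins, n)
        if auto_reduce:
            while n / n_bins_used < 10 and n_bins_used > 5:
                n_bins_used = max(5, n_bins_used // 2)
                reduced = True
            if reduced:
                log.info(
                    "small validation set (n=%d): bin count reduced from %d to %d",
                    n, n_bins, n_bins_used,
                )

    order = np.argsort(predicted, kind="stable")
    if equal_width and not degenerate:
        edges = np.linspace(predicted.min(), predicted.max(), n_bins_used + 1)
        assign = np.clip(np.digitize(predicted, edges[1:-1]), 0, n_bins_used - 1)
        groups = [np.flatnonzero(assign == b) for b in range(n_bins_used)]
    else:
        groups = np.array_split(order, n_bins_used)

    rows = []
    for b, idx in enumerate(groups):
        if len(idx) == 0:
            continue
        mo = float(observed[idx].mean())
        mp = float(predicted[idx].mean())
        rows.append(
            {
                "bin": b + 1,
                "n": int(len(idx)),
                "mean_predicted": mp,
                "mean_observed": mo,
                "ratio": mo / mp if mp != 0 else np.nan,
            }
        )
    table = pd.DataFrame(rows)

    if len(table) > 1:
        rho = stats.spearmanr(table["bin"], table["mean_observed"]).statistic
        sl, ic, *_ = stats.linregress(table["mean_predicted"], table["mean_observed"])
    else:
        rho, sl, ic = np.nan, np.nan, np.nan
    tot_pred = float(predicted.mean())
    overall = float(observed.mean()) / tot_pred if tot_pred != 0 else np.nan
    return CalibrationTable(
        table=table,
        n_bins=len(table),
        spearman=float(rho),
        overall_ratio=overall,
        ols_slope=float(sl),
        ols_intercept=float(ic),
        reduced=reduced,
        degenerate=degenerate,
    )


def cross_apply(
    fit: NBFit,
    other: ModelData | pd.DataFrame,
    n_bins: int = 10,
    response: str | None = None,
) -> CalibrationTable:
    """Apply a fitted model unchanged to another dataset and score calibration.

    This is the cross-sex validation step: e.g. the male model applied to the
    hind records, or a combined model applied to a held-out 30%.
    """
    frame = other.frame if isinstance(other, ModelData) else other
    response = response or (other.response if isinstance(other, ModelData) else "tick_count")
    pred = predict_burden(fit, frame)
    obs = frame[response].to_numpy(dtype=float)
    return bin_calibration(obs, pred, n_bins=n_bins)


def calibration_plot(calib: CalibrationTable, path, title: str = "") -> None:
    """Observed vs predicted bin means with the 1:1 line (optional figure output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    t = calib.table
    ax.plot(t["mean_predicted"], t["mean_observed"], "o-", color="tab:blue")
    lim = max(t["mean_predicted"].max(), t["mean_observed"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "--", color="grey", lw=1, label="1:1")
    ax.set_xlabel("mean predicted burden (bin)")
    ax.set_ylabel("mean observed burden (bin)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
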