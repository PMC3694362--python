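"""Prevalence estimates and burden summary tables.

Prevalence (fraction of examined deer carrying at least one tick) is reported
with the Wald 95% interval p +/- 1.96 sqrt(p(1-p)/n), expressed in percent and
clamped to [0, 100].  The plain Wald form is the default because it reproduces
the published descriptive intervals; the Wilson interval — better behaved for
small n or extreme p — is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

_GROUP_KEYS = {"sex", "age_class", "year", "season"}


@dataclass(frozen=True)
class PrevalenceEstimate:
    positives: int
    examined: int
    prevalence_pct: float
    ci_low_pct: float
    ci_high_pct: float

    def rounded(self, decimals: int = 1) -> tuple:
        """(p, low, high) rounded half-up to the given decimals, as in reports."""
        def r(x):
            q = 10.0**decimals
            return float(np.floor(x * q + 0.5) / q)

        return r(self.prevalence_pct), r(self.ci_low_pct), r(self.ci_high_pct)


def prevalence_ci(k: int, n: int, wilson: bool = False) -> PrevalenceEstimate:
    """Prevalence with its 95% CI, in percent.

    ``k`` positives out of ``n`` examined.  Default is the Wald interval
    1.96 sqrt(p(1-p)/n); at p = 0 or 1 it collapses to a point.
    """
    if n <= 0:
        raise ValidationError(f"examined count must be positive, got n={n}")
    if not 0 <= k <= n:
        raise ValidationError(f"positives must satisfy 0 <= k <= n, got k={k}, n={n}")
    p = k / n
    if wilson:
        z = 1.959963984540054
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        lo, hi = centre - half, centre + half
    else:
        half = 1.96 * np.sqrt(p * (1.0 - p) / n)
        lo, hi = p - half, p + half
    lo = float(np.clip(lo, 0.0, 1.0)) * 100.0
    hi = float(np.clip(hi, 0.0, 1.0)) * 100.0
    return PrevalenceEstimate(k, n, p * 100.0, lo, hi)


def prevalence_ci_from_proportion(p_pct: float, n: int) -> PrevalenceEstimate:
    """Wald CI from an already-rounded percentage (as printed in reports)."""
    p = p_pct / 100.0
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"proportion must be within [0, 100]%, got {p_pct}")
    if n <= 0:
        raise ValidationError(f"examined count must be positive, got n={n}")
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    lo = float(np.clip(p - half, 0.0, 1.0)) * 100.0
    hi = float(np.clip(p + half, 0.0, 1.0)) * 100.0
    return PrevalenceEstimate(int(round(p * n)), n, p_pct, lo, hi)


def summarize_burdens(
    records: pd.DataFrame,
    by=("sex",),
    count_col: str = "tick_count",
    collected_col: str = "ticks_collected",
) -> pd.DataFrame:
    """Per-group burden summary with a grand-total row.

    Groups by any of sex / age_class / year / season; reports group size,
    prevalence of parasitisation (any tick), mean and range of counted
    burdens, and — when the collected-ticks column is present — of collected
    burdens too.
    """
    if records.empty:
        raise ValidationError("cannot summarise an empty record table")
    by = list(by)
    bad = [k for k in by if k not in _GROUP_KEYS]
    if bad:
        raise ValidationError(f"unknown group key(s) {bad}; allowed: {sorted(_GROUP_KEYS)}")
    has_collected = collected_col in records.columns

    def one(group: pd.DataFrame) -> dict:
        c = group[count_col]
        row = {
            "n": int(len(group)),
            "positives": int((c > 0).sum()),
            "prevalence_pct": float(100.0 * (c > 0).mean()),
            "mean_counted": float(c.mean()),
            "min_counted": int(c.min()),
            "max_counted": int(c.max()),
        }
        if has_collected:
            col = group[collected_col]
            row.update(
                mean_collected=float(col.mean()),
                min_collected=int(col.min()),
                max_collected=int(col.max()),
            )
        return row

    rows = []
    for key, group in records.groupby(by, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        rows.append({**dict(zip(by, key)), **one(group)})
    rows.append({**{k: "TOTAL" for k in by}, **one(records)})
    return pd.DataFrame(rows)
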