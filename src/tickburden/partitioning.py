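"""Deviance partitioning over the three factor groups Ind / Pop / Env.

A full model's explained deviance D(full) is split into seven components by
inclusion-exclusion over seven fitted models (three single-factor, three
pairwise, one full):

* pure effects:      I  = D(full) - D(Pop+Env)
                     P  = D(full) - D(Ind+Env)
                     E  = D(full) - D(Ind+Pop)
* pairwise shared:   IP = D(full) - D(Env) - I - P
                     IE = D(full) - D(Pop) - I - E
                     PE = D(full) - D(Ind) - P - E
* triple shared:     IPE = D(full) - I - P - E - IP - IE - PE

so that I + P + E + IP + IE + PE + IPE = D(full) exactly.  These rules are the
unique solution of the linear system in which each fitted model's explained
deviance equals the sum of every component its factor set touches
(D(S) = sum of c_T over subsets T with T intersecting S); a generic solver for
that system over any number of groups is provided as
:func:`solve_components_linear` and doubles as an independent cross-check.

Shared components can legitimately be negative (suppression); they are
reported as-is, never clamped.

All partial models are fitted with theta fixed at the full model's estimate,
because explained-deviance fractions are only comparable at a common
dispersion.  Per-model re-estimation is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .covariates import FACTORS, FactorGrouping, ModelData
from .errors import ValidationError
from .nb_glm import fit_nb

log = logging.getLogger(__name__)

COMPONENT_NAMES = ("I", "P", "E", "IP", "IE", "PE", "IPE")
MODEL_NAMES = ("Ind", "Pop", "Env", "Ind+Pop", "Ind+Env", "Pop+Env", "Ind+Pop+Env")


@dataclass
class PartitionResult:
    """Seven model deviances, seven components, and the standardized (% of full) view."""

    model_deviance: dict  # explained-deviance fraction per fitted model
    components: dict  # raw components, same scale as the deviances
    standardized: dict | None  # components as % of D(full); None if D(full) == 0
    theta: float | None = None  # dispersion shared by the partial models, if fitted
    empty_groups: tuple = ()

    def as_dict(self) -> dict:
        return {
            "model_deviance": {k: float(v) for k, v in self.model_deviance.items()},
            "components": {k: float(v) for k, v in self.components.items()},
            "standardized_pct": None
            if self.standardized is None
            else {k: float(v) for k, v in self.standardized.items()},
            "theta": None if self.theta is None else float(self.theta),
            "empty_groups": list(self.empty_groups),
        }


def components_from_deviances(
    d_ind: float,
    d_pop: float,
    d_env: float,
    d_ind_pop: float,
    d_ind_env: float,
    d_pop_env: float,
    d_full: float,
) -> PartitionResult:
    """Apply the subtraction rules to seven explained-deviance values."""
    i = d_full - d_pop_env
    p = d_full - d_ind_env
    e = d_full - d_ind_pop
    ip = d_full - d_env - i - p
    ie = d_full - d_pop - i - e
    pe = d_full - d_ind - p - e
    ipe = d_full - i - p - e - ip - ie - pe
    comps = dict(zip(COMPONENT_NAMES, (i, p, e, ip, ie, pe, ipe)))
    model_dev = dict(
        zip(MODEL_NAMES, (d_ind, d_pop, d_env, d_ind_pop, d_ind_env, d_pop_env, d_full))
    )
    if d_full == 0:
        log.warning("full model explains zero deviance; standardized components undefined")
        standardized = None
    else:
        standardized = {k: 100.0 * v / d_full for k, v in comps.items()}
    return PartitionResult(model_deviance=model_dev, components=comps, standardized=standardized)


def solve_components_linear(subset_deviances: dict) -> dict:
    """Solve for the components of an n-group partition as a linear system.

    ``subset_deviances`` maps each non-empty frozenset of group labels to the
    explained deviance of the model fitted with that group set (all 2^n - 1
    subsets must be present).  Each equation states that a model's deviance is
    the sum of the components whose group set intersects the model's groups.
    Returns a mapping frozenset -> component.  For three groups this agrees
    with :func:`components_from_deviances` to machine precision.
    """
    groups = sorted({g for s in subset_deviances for g in s})
    subsets = [
        frozenset(c) for r in range(1, len(groups) + 1) for c in combinations(groups, r)
    ]
    if set(subsets) != set(subset_deviances):
        raise ValidationError("all non-empty group subsets must be supplied")
    A = np.array(
        [[1.0 if s & t else 0.0 for t in subsets] for s in subsets]
    )
    b = np.array([subset_deviances[s] for s in subsets])
    x = np.linalg.solve(A, b)
    return dict(zip(subsets, x))


def partition_deviance(
    data: ModelData,
    final_predictors,
    grouping: FactorGrouping | None = None,
    response: str = "tick_count",
    refit_theta: bool = False,
) -> PartitionResult:
    """Fit the seven models restricted to the final predictor set and partition.

    Each factor's predictor list is the intersection of the final model's
    predictors with that factor's group.  A factor with no predictors in the
    final model contributes structurally zero components (with a warning).
    Unless ``refit_theta`` is set, every partial model is fitted at the full
    model's theta.
    """
    grouping = grouping or data.grouping
    final_predictors = list(final_predictors)
    by_factor = {f: grouping.members(f, final_predictors) for f in FACTORS}
    empty = tuple(f for f in FACTORS if not by_factor[f])
    if len([f for f in FACTORS if by_factor[f]]) < 2:
        raise ValidationError(
            "partitioning needs final predictors from at least two factor groups; "
            f"groups present: {[f for f in FACTORS if by_factor[f]]}"
        )
    if empty:
        log.warning("factor group(s) %s have no predictors in the final model; "
                    "their components are structurally zero", empty)

    full = fit_nb(data, final_predictors, response=response)
    theta = full.theta

    def explained(preds) -> float:
        if not preds:
            return 0.0
        f = fit_nb(data, preds, response=response, theta=None if refit_theta else theta)
        return f.explained_deviance

    d = {}
    factor_sets = {
        "Ind": ("Ind",), "Pop": ("Pop",), "Env": ("Env",),
        "Ind+Pop": ("Ind", "Pop"), "Ind+Env": ("Ind", "Env"), "Pop+Env": ("Pop", "Env"),
    }
    for name, factors in factor_sets.items():
        preds = [p for f in factors for p in by_factor[f]]
        try:
            d[name] = explained(preds)
        except Exception as exc:
            raise ValidationError(f"partial model '{name}' failed to fit: {exc}") from exc
    d_full = (
        explained(final_predictors) if refit_theta else
        1.0 - full.deviance / full.null_deviance if full.null_deviance > 0 else 0.0
    )
    result = components_from_deviances(
        d["Ind"], d["Pop"], d["Env"], d["Ind+Pop"], d["Ind+Env"], d["Pop+Env"], d_full
    )
    result.theta = theta
    result.empty_groups = empty
    return result


def venn_report(result: PartitionResult, title: str = "Deviance partition") -> str:
    """Text report of the partition, Venn style (pure, pairwise, triple)."""
    c = result.components
    s = result.standardized or {k: float("nan") for k in c}
    lines = [
        title,
        "-" * len(title),
        f"explained deviance of the full model: "
        f"{100 * result.model_deviance['Ind+Pop+Env']:.2f}%",
        "",
        "component      raw        % of full",
    ]
    labels = {
        "I": "pure Ind", "P": "pure Pop", "E": "pure Env",
        "IP": "Ind^Pop", "IE": "Ind^Env", "PE": "Pop^Env", "IPE": "Ind^Pop^Env",
    }
    for k in COMPONENT_NAMES:
        lines.append(f"{labels[k]:<12} {c[k]:>9.5f} {s[k]:>12.2f}")
    if result.empty_groups:
        lines.append(f"(structurally zero groups: {', '.join(result.empty_groups)})")
    if any(c[k] < 0 for k in COMPONENT_NAMES):
        lines.append(
            "note: negative shared components indicate suppression among factor "
            "groups; they are reported unclamped, as is standard in variation "
            "partitioning"
        )
    return "\n".join(lines)
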