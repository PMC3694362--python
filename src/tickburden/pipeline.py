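"""End-to-end orchestration: simulate -> covariates -> fit -> partition ->
cross-validate -> report.

The full analysis mirrors the study's design: three stepwise-selected burden
models (males, hinds, combined-with-sex), VIF diagnostics for each final
model, a deviance partition per model, three calibration exercises
(male-model on hind data, hind-model on male data, combined model on a
held-out 30%), and the descriptive tables.  Every stage writes its artifacts
(JSON/CSV) into the run directory, and every number in the text report comes
from one of those artifacts.

All randomness flows from a single run seed, split into fixed per-stage
streams, so two runs with the same config and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .covariates import DEFAULT_GROUPING, FactorGrouping, ModelData, build_design
from .descriptives import prevalence_ci, summarize_burdens
from .errors import ConfigurationError
from .nb_glm import coefficient_table, fit_nb, stepwise_aic, vif
from .partitioning import partition_deviance, venn_report
from .synthetic import SimConfig, generate_cohort, generate_environment, write_outputs
from .validation import calibration_plot, cross_apply, split_train_validate

log = logging.getLogger(__name__)

#: Candidate predictors offered to the stepwise search (sex is forced into the
#: combined model, not offered as a candidate).
DEFAULT_CANDIDATES = [
    "TL", "age_class", "KFI",
    "AvT_M", "AP_M", "AET_M",
    "Deer_C", "Deer_C_t2", "Boar_C_t2",
]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    simulate: SimConfig = field(default_factory=SimConfig)
    #: paths to hosts/meteo/census CSVs; when set, simulation is skipped
    input_paths: dict | None = None
    candidates: list = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    grouping: dict = field(default_factory=lambda: dict(DEFAULT_GROUPING))
    stepwise: bool = True
    n_bins: int = 10
    train_fraction: float = 0.70
    seed: int = 0
    outdir: str = "results/run"
    make_plots: bool = False

    def validate(self) -> None:
        if self.input_paths is not None:
            for key in ("hosts", "meteo", "census"):
                if key not in self.input_paths:
                    raise ConfigurationError(f"input_paths lacks entry '{key}'")
                if not Path(self.input_paths[key]).exists():
                    raise ConfigurationError(
                        f"input path '{self.input_paths[key]}' ({key}) does not exist"
                    )
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        FactorGrouping(self.grouping)
        missing = [c for c in self.candidates if c not in self.grouping]
        if missing:
            raise ConfigurationError(f"candidate(s) {missing} missing from grouping")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        sim = raw.pop("simulate", {})
        cfg = cls(**raw)
        if sim:
            cfg.simulate = SimConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        # repr handles the tuple-keyed morphometric tables; field order is fixed
        payload = repr(dataclasses.asdict(self)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _to_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, lineterminator="\r\n")


def simulate_stage(config: RunConfig, outdir: Path) -> tuple:
    """Generate (or load) hosts, meteorology and censuses."""
    if config.input_paths is not None:
        hosts = pd.read_csv(config.input_paths["hosts"])
        meteo = pd.read_csv(config.input_paths["meteo"])
        census = pd.read_csv(config.input_paths["census"])
        return hosts, meteo, census
    sim = dataclasses.replace(config.simulate, seed=config.seed)
    env = generate_environment(sim)
    hosts = generate_cohort(sim, env)
    write_outputs(sim, env, hosts, outdir)
    return hosts, env[0], env[1]


def covariates_stage(config: RunConfig, hosts, meteo, census, outdir: Path) -> ModelData:
    """Build and persist the modelling table; exclude unusable records loudly."""
    usable = hosts["sex"].isin(["male", "female"]) & hosts["age_class"].between(1, 5)
    excluded = int((~usable).sum())
    if excluded:
        log.warning("excluding %d record(s) with unknown sex or age class", excluded)
    grouping = FactorGrouping(config.grouping)
    data = build_design(hosts.loc[usable].reset_index(drop=True), meteo, census, grouping)
    _to_csv(data.frame, outdir / "design.csv")
    _dump_json(dict(config.grouping), outdir / "grouping.json")
    _dump_json({"excluded_records": excluded}, outdir / "exclusions.json")
    return data


def fit_stage(config: RunConfig, data: ModelData, outdir: Path) -> dict:
    """Fit the three models (males, hinds, combined-with-sex), with diagnostics."""
    males = data.subset(data.frame["sex"] == "male")
    females = data.subset(data.frame["sex"] == "female")
    fits = {}
    for name, subset, scope in (
        ("males", males, None),
        ("females", females, None),
        ("combined", data, ["sex_female"]),
    ):
        if config.stepwise:
            step = stepwise_aic(subset, config.candidates, scope=scope)
            fit, trace = step.fit, step.trace
        else:
            preds = (scope or []) + list(config.candidates)
            fit, trace = fit_nb(subset, preds), []
        fits[name] = fit
        payload = fit.summary_dict()
        payload["stepwise_trace"] = [
            {"action": a, "term": t, "aic": float(aic)} for a, t, aic in trace
        ]
        if len(fit.predictors) >= 2:
            payload["vif"] = {k: float(v) for k, v in vif(subset, fit.predictors).items()}
        _dump_json(payload, outdir / f"fit_{name}.json")
    grouping = FactorGrouping(config.grouping)
    (outdir / "coefficient_table.txt").write_text(coefficient_table(fits, grouping) + "\n")
    return fits


def partition_stage(config: RunConfig, data: ModelData, fits: dict, outdir: Path) -> dict:
    """Deviance partition per model over the full candidate predictor pool.

    Partitions use the complete candidate set (plus the sex term for the
    combined model) rather than each stepwise-selected subset, so the three
    partitions weigh the same factor pools and stay comparable even when a
    final model collapses onto a single factor group.
    """
    males = data.subset(data.frame["sex"] == "male")
    females = data.subset(data.frame["sex"] == "female")
    grouping = FactorGrouping(config.grouping)
    partitions = {}
    reports = []
    for name, subset, preds in (
        ("males", males, config.candidates),
        ("females", females, config.candidates),
        ("combined", data, ["sex_female"] + list(config.candidates)),
    ):
        part = partition_deviance(subset, preds, grouping)
        partitions[name] = part
        _dump_json(part.as_dict(), outdir / f"partition_{name}.json")
        reports.append(venn_report(part, title=f"Deviance partition - {name}"))
    (outdir / "partition_report.txt").write_text("\n\n".join(reports) + "\n")
    return partitions


def crossval_stage(config: RunConfig, data: ModelData, fits: dict, outdir: Path) -> dict:
    """Cross-sex application of each model plus the 70/30 combined validation."""
    males = data.subset(data.frame["sex"] == "male")
    females = data.subset(data.frame["sex"] == "female")
    calibrations = {}

    calibrations["male_model_on_females"] = cross_apply(
        fits["males"], females, n_bins=config.n_bins
    )
    calibrations["female_model_on_males"] = cross_apply(
        fits["females"], males, n_bins=config.n_bins
    )
    train, val = split_train_validate(
        data, train_fraction=config.train_fraction, seed=config.seed + 7
    )
    if config.stepwise:
        holdout_fit = stepwise_aic(train, config.candidates, scope=["sex_female"]).fit
    else:
        holdout_fit = fit_nb(train, ["sex_female"] + list(config.candidates))
    calibrations["combined_holdout"] = cross_apply(holdout_fit, val, n_bins=config.n_bins)

    for name, calib in calibrations.items():
        _to_csv(calib.table, outdir / f"calibration_{name}.csv")
        _dump_json(calib.metrics_dict(), outdir / f"calibration_{name}.json")
        if config.make_plots:
            calibration_plot(calib, outdir / f"calibration_{name}.png", title=name)
    return calibrations


def descriptives_stage(config: RunConfig, data: ModelData, outdir: Path) -> None:
    frame = data.frame
    for key in ("sex", "age_class", "season"):
        _to_csv(summarize_burdens(frame, by=[key]), outdir / f"summary_by_{key}.csv")
    prev = {}
    for sex, group in frame.groupby("sex"):
        est = prevalence_ci(int((group["tick_count"] > 0).sum()), len(group))
        p, lo, hi = est.rounded()
        prev[sex] = {"positives": est.positives, "examined": est.examined,
                     "prevalence_pct": p, "ci_low_pct": lo, "ci_high_pct": hi}
    est = prevalence_ci(int((frame["tick_count"] > 0).sum()), len(frame))
    p, lo, hi = est.rounded()
    prev["total"] = {"positives": est.positives, "examined": est.examined,
                     "prevalence_pct": p, "ci_low_pct": lo, "ci_high_pct": hi}
    _dump_json(prev, outdir / "prevalence.json")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to the run directory)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        hosts, meteo, census = simulate_stage(config, outdir)
        data = covariates_stage(config, hosts, meteo, census, outdir)
        fits = fit_stage(config, data, outdir)
        partitions = partition_stage(config, data, fits, outdir)
        calibrations = crossval_stage(config, data, fits, outdir)
        descriptives_stage(config, data, outdir)
    except Exception as exc:
        log.error("pipeline halted: %s", exc)
        raise
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "n_records": int(len(data.frame)),
        "fits": sorted(fits),
        "partitions": sorted(partitions),
        "calibrations": sorted(calibrations),
        "artifacts": sorted(
            p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
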