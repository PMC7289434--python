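"""End-to-end orchestration: simulate → featurize → select → transfer.

A run is driven by a single :class:`RunConfig` (constructible from YAML);
every source of randomness is an explicit, logged seed, so a rerun with the
same configuration produces byte-identical numeric outputs. The run writes
a bundle directory::

    <out>/
      manifest.json                   seeds, versions, per-file checksums
      <facility>/log.csv              simulated visit log
      <facility>/summary.csv          visits/day, mean delay/wait, utilization
      <facility>/matrix.csv           feature matrix (84 columns + target)
      <facility>/lr_frequency.csv     stepwise selection frequencies
      <facility>/lr_error_curve.csv   mean testing-percentage-error per size
      <facility>/rf_importance.csv    cumulative permutation importance
      catalog.csv                     feature data dictionary
      transfer_linear.csv             cross-facility ratio matrix (LR sets)
      transfer_forest.csv             cross-facility ratio matrix (RF sets)
      report.md                       human-readable summary
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import build_catalog
from .errors import ConfigError
from .events import FacilityType, write_log
from .features import estimate_duration_stats, featurize_log, write_matrix
from .forest import RFHyperparams, cumulative_ranking, rf_importance, tune_rf
from .simulate import FacilityConfig, facility_archetype, generate_log, summarize_log
from .stepwise import (
    forward_stepwise,
    make_splits,
    selection_frequency,
    split_frames,
    testing_percentage_error,
)
from .transfer import FeatureSet, transfer_matrix, union_sets

log = logging.getLogger("queueflow")

__all__ = ["RunConfig", "run_pipeline", "render_report"]


@dataclass
class RunConfig:
    facilities: list[dict]  # each: {"archetype": ..., **FacilityConfig overrides}
    out_dir: str
    seed: Optional[int] = None
    replicates: int = 100
    n_max: int = 20
    folds: int = 10
    top_k: int = 10
    train_months: int = 6
    test_days: int = 14
    reference_days: int = 90
    rf_grid: list[RFHyperparams] = field(default_factory=list)
    rf_replicates: Optional[int] = None  # defaults to `replicates`
    models: tuple[str, ...] = ("linear", "forest")

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("RunConfig.seed must be set explicitly")
        if not self.facilities:
            raise ConfigError("at least one facility is required")
        for m in self.models:
            if m not in ("linear", "forest"):
                raise ConfigError(f"unknown model {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        grid = [RFHyperparams(**g) for g in data.pop("rf_grid", [])]
        models = tuple(data.pop("models", ("linear", "forest")))
        return cls(rf_grid=grid, models=models, **data)


def _facility_config(entry: dict, seed: int) -> FacilityConfig:
    entry = dict(entry)
    archetype = entry.pop("archetype", None)
    entry.setdefault("seed", seed)
    if archetype:
        return facility_archetype(archetype, **entry)
    return FacilityConfig.from_dict(entry)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the manifest (also written to
    ``manifest.json``). Raises with a stage-named message on failure;
    partial outputs are retained for inspection."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {},
        "files": {},
        "facilities": {},
    }
    catalog = build_catalog()
    catalog.to_csv(out / "catalog.csv")

    matrices: dict[str, pd.DataFrame] = {}
    fac_types: dict[str, FacilityType] = {}
    lr_top: dict[str, FeatureSet] = {}
    rf_top: dict[str, FeatureSet] = {}
    splits_by_fac: dict[str, list] = {}
    rf_params_by_fac: dict[str, RFHyperparams] = {}

    for entry in config.facilities:
        stage = "simulate"
        try:
            fac_seed = int(root_rng.integers(0, 2**31 - 1))
            fc = _facility_config(entry, fac_seed)
            fac = fc.facility_id
            fdir = out / fac
            fdir.mkdir(exist_ok=True)
            manifest["stage_seeds"][f"{fac}.simulate"] = fc.seed
            log.info("simulating %s (%s, %d days)", fac, fc.facility_type.value, fc.n_days)
            event_log, _ = generate_log(fc)
            write_log(event_log, fdir / "log.csv")
            summarize_log(event_log).to_csv(fdir / "summary.csv", header=False)

            stage = "featurize"
            stats = estimate_duration_stats(event_log, config.reference_days)
            matrix = featurize_log(
                event_log,
                catalog,
                stats,
                slot_minutes=fc.slot_minutes,
                n_servers=fc.n_servers,
                start=stats.reference_end,
            )
            write_matrix(matrix, fdir / "matrix.csv")
            matrices[fac] = matrix
            fac_types[fac] = fc.facility_type
            manifest["facilities"][fac] = {
                "facility_type": fc.facility_type.value,
                "n_visits": len(event_log),
                "n_rows": len(matrix),
            }

            stage = "select-lr"
            split_seed = int(root_rng.integers(0, 2**31 - 1))
            manifest["stage_seeds"][f"{fac}.splits"] = split_seed
            splits = make_splits(
                matrix,
                config.replicates,
                seed=split_seed,
                train_months=config.train_months,
                test_days=config.test_days,
            )
            splits_by_fac[fac] = splits
            if "linear" in config.models:
                paths = []
                for spec in splits:
                    train, test = split_frames(matrix, spec)
                    paths.append(
                        forward_stepwise(
                            train, test, n_max=config.n_max,
                            folds=config.folds, seed=spec.seed,
                        )
                    )
                summary = selection_frequency(paths, k=config.top_k)
                summary.to_frame().to_csv(fdir / "lr_frequency.csv", index=False)
                curves = np.vstack([testing_percentage_error(p) for p in paths])
                pd.DataFrame(
                    {"model_size": np.arange(curves.shape[1]),
                     "mean_tpe_percent": curves.mean(axis=0)}
                ).to_csv(fdir / "lr_error_curve.csv", index=False)
                lr_top[fac] = FeatureSet(fac, summary.top(config.top_k))

            stage = "select-rf"
            if "forest" in config.models:
                rf_seed = int(root_rng.integers(0, 2**31 - 1))
                manifest["stage_seeds"][f"{fac}.forest"] = rf_seed
                grid = config.rf_grid or [
                    RFHyperparams(max(1, len(catalog) // 3), None, 200)
                ]
                train0, _ = split_frames(matrix, splits[0])
                params = tune_rf(train0, grid, folds=config.folds, seed=rf_seed)
                rf_params_by_fac[fac] = params
                n_rf = config.rf_replicates or config.replicates
                tables = []
                for spec in splits[:n_rf]:
                    train, _ = split_frames(matrix, spec)
                    tables.append(rf_importance(train, params, seed=spec.seed))
                table = cumulative_ranking(tables, k=config.top_k)
                table.cumulative.sort_values(ascending=False).to_csv(
                    fdir / "rf_importance.csv", header=["cumulative_importance"]
                )
                rf_top[fac] = FeatureSet(fac, table.top(config.top_k))
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed for facility entry {entry}: {exc}") from exc

    # cross-facility transferability, one matrix per model family
    try:
        sched = [f for f, t in fac_types.items() if t is not FacilityType.WALKIN]
        for model, tops, fname in (
            ("linear", lr_top, "transfer_linear.csv"),
            ("forest", rf_top, "transfer_forest.csv"),
        ):
            if model not in config.models or not tops:
                continue
            extra = []
            if len(sched) > 1:
                extra = [union_sets([tops[f] for f in sched], source="union")]
            ratios = transfer_matrix(
                matrices,
                fac_types,
                tops,
                extra_sets=extra,
                model=model,
                splits=splits_by_fac,
                catalog=catalog,
                policy="strict" if model == "linear" else "proxy",
                seed=config.seed,
                rf_params=rf_params_by_fac.get(next(iter(rf_params_by_fac), ""), None)
                if model == "forest"
                else None,
            )
            ratios.to_csv(out / fname)
    except Exception as exc:
        raise RuntimeError(f"stage 'transfer' failed: {exc}") from exc

    for path in sorted(out.rglob("*.csv")):
        manifest["files"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    render_report(out)
    return manifest


def render_report(bundle_dir) -> Path:
    """Write ``report.md`` summarizing a completed bundle: the feature
    data dictionary, per-facility selection frequencies (descending),
    error curves, and the transfer-ratio matrices."""
    bundle = Path(bundle_dir)
    manifest_path = bundle / "manifest.json"
    catalog_path = bundle / "catalog.csv"
    if not catalog_path.exists():
        raise FileNotFoundError(f"incomplete bundle: missing {catalog_path}")
    cat = pd.read_csv(catalog_path)
    lines = ["# Workflow prediction run report", ""]
    groups = cat.groupby("group").size().sort_index()
    lines.append(
        f"Feature catalog: {len(cat)} features in {len(groups)} groups "
        f"({', '.join(f'{g}: {n}' for g, n in groups.items())})."
    )
    lines.append("")
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"Seed: {manifest['seed']}; package version {manifest['package_version']}.")
        lines.append("")
    for fdir in sorted(p for p in bundle.iterdir() if p.is_dir()):
        freq_path = fdir / "lr_frequency.csv"
        lines.append(f"## Facility {fdir.name}")
        lines.append("")
        if freq_path.exists():
            freq = pd.read_csv(freq_path).sort_values(
                ["frequency_percent", "mean_step"], ascending=[False, True]
            )
            lines.append("Stepwise-LR selection frequency (top 10):")
            lines.append("")
            for _, row in freq.head(10).iterrows():
                lines.append(
                    f"- {row['feature']}: {row['frequency_percent']:.0f}% "
                    f"(mean step {row['mean_step']:.1f})"
                )
            lines.append("")
        curve_path = fdir / "lr_error_curve.csv"
        if curve_path.exists():
            curve = pd.read_csv(curve_path)
            final = curve["mean_tpe_percent"].iloc[-1]
            lines.append(
                f"Testing percentage error: 100% (intercept) → "
                f"{final:.1f}% at {int(curve['model_size'].iloc[-1])} features."
            )
            lines.append("")
        rf_path = fdir / "rf_importance.csv"
        if rf_path.exists():
            imp = pd.read_csv(rf_path, index_col=0)
            top = imp.head(10)
            lines.append("Random-forest cumulative importance (top 10):")
            lines.append("")
            for name, row in top.iterrows():
                lines.append(f"- {name}: {row['cumulative_importance']:.2f}")
            lines.append("")
    for model in ("linear", "forest"):
        tpath = bundle / f"transfer_{model}.csv"
        if tpath.exists():
            ratios = pd.read_csv(tpath, index_col=0)
            lines.append(f"## Transfer ratios ({model} model)")
            lines.append("")
            lines.append("Rows: data facility; columns: feature-set source.")
            lines.append("")
            lines.append(ratios.round(3).to_csv(sep="\t").rstrip())
            lines.append("")
    report = bundle / "report.md"
    report.write_text("\n".join(lines))
    return report
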