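"""End-to-end orchestration: ingest/simulate -> filters -> feature selection ->
model comparison -> trait gradient analysis, with a serializable run report.

Each stage writes plain CSV/JSON, so any stage can be rerun or inspected in
isolation, and a full report regenerated from the same config and seed is
byte-identical (all randomness flows through named streams derived from the
one master seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import model_selection as msel
from . import synthetic
from . import trait_gradient as tga
from .dataset import TRAITS, Dataset, aggregate_sites, filter_np_outliers, log_transform, read_dataset


@dataclass
class RunConfig:
    """Everything a pipeline run consumes; serialized alongside the outputs."""

    scenario: str | None = None  # a synthetic.make_scenario name ...
    input_csv: str | None = None  # ... or a CSV path (exactly one required)
    seed: int = 0
    traits: tuple = TRAITS
    np_threshold: float = 70.0
    min_sites_per_species: int = 5
    min_species_per_site: int = 5
    rfe_tol: float = 0.01
    n_trees: int = 200
    min_node_size: int = 5
    n_folds: int = 5
    log_traits: bool = True
    lmm_transform: str | None = "yeo-johnson"
    range_norm: str = "range"
    iterate_occurrence_filter: bool = False
    skip: tuple = ()  # any of "select_features", "compare_models", "tga"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("traits", "skip"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def validate(self) -> None:
        if (self.scenario is None) == (self.input_csv is None):
            raise ValueError("exactly one of scenario / input_csv must be set")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["traits"] = list(self.traits)
        d["skip"] = list(self.skip)
        return d


@dataclass
class RunReport:
    """Structured result of one pipeline run."""

    config: dict
    stages: dict = field(default_factory=dict)
    ok: bool = True

    def to_dict(self) -> dict:
        return {"config": self.config, "stages": self.stages, "ok": self.ok,
                "digest": self.digest()}

    def digest(self) -> str:
        payload = json.dumps(
            {"config": self.config, "stages": self.stages, "ok": self.ok},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str)


def _load_input(config: RunConfig) -> tuple[Dataset, object]:
    if config.scenario is not None:
        scen = synthetic.make_scenario(config.scenario, seed=config.seed)
        return synthetic.generate(scen)
    return read_dataset(config.input_csv), None


def select_features(
    ds: Dataset, config: RunConfig, traits=None
) -> tuple[dict[str, list[str]], dict[str, msel.RFEPath]]:
    """RFE per trait on the log-scale site-aggregated data."""
    traits = traits or config.traits
    scheme = msel.CVScheme(n_folds=config.n_folds, seed=config.seed)
    work = log_transform(ds, traits=traits) if config.log_traits else ds
    site = aggregate_sites(work)
    selected, paths = {}, {}
    for trait in traits:
        path = msel.rfe(
            site[list(ds.covariate_names)], site[trait], scheme=scheme,
            min_node_size=config.min_node_size, n_trees=config.n_trees, seed=config.seed,
        )
        selected[trait] = list(msel.select_final_set(path, tol=config.rfe_tol))
        paths[trait] = path
    return selected, paths


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the stages in order and return the structured report.

    Stage failures (degenerate cells, non-convergence) are recorded in the
    report with ``ok=False`` rather than aborting the run.
    """
    config.validate()
    report = RunReport(config=config.to_dict())

    ds, truth = _load_input(config)
    report.stages["input"] = {
        "n_records": ds.n_records, "n_species": ds.n_species, "n_sites": ds.n_sites,
        "covariates": list(ds.covariate_names),
    }
    if truth is not None:
        report.stages["input"]["true_within_fraction"] = truth.true_within_fraction

    ds, np_report = filter_np_outliers(ds, threshold=config.np_threshold)
    report.stages["np_filter"] = json.loads(np_report.to_json())

    if "select_features" not in config.skip and len(ds.covariate_names) >= 2:
        selected, paths = select_features(ds, config)
        report.stages["feature_selection"] = {
            t: {"selected": selected[t],
                "path": paths[t].to_frame().to_dict(orient="records")}
            for t in selected
        }
    else:
        selected = {t: list(ds.covariate_names) for t in config.traits}
        report.stages["feature_selection"] = {"skipped": True}

    if "compare_models" not in config.skip and all(selected[t] for t in config.traits):
        scheme = msel.CVScheme(n_folds=config.n_folds, seed=config.seed)
        grid = msel.compare_models(
            ds, selected, traits=config.traits, scheme=scheme,
            n_trees=config.n_trees, min_node_size=config.min_node_size,
            seed=config.seed, log_traits=config.log_traits,
            lmm_transform=config.lmm_transform,
        )
        report.stages["model_comparison"] = {
            "grid": grid.to_frame().to_dict(orient="records"),
            "env_contribution": grid.env_contribution,
            "n_flagged": grid.n_flagged,
        }
        if grid.n_flagged:
            report.ok = False

    if "tga" not in config.skip:
        result = tga.run_tga(
            ds, traits=config.traits,
            min_sites_per_species=config.min_sites_per_species,
            min_species_per_site=config.min_species_per_site,
            iterate_filter=config.iterate_occurrence_filter,
            norm=config.range_norm,
        )
        report.stages["tga"] = result.summary()
        report.stages["tga"]["occurrence_filter"] = json.loads(result.filter_report.to_json())
    return report


def render_report(report: RunReport, outdir) -> list[str]:
    """Write a text summary and figures from an existing report (no recomputation)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    lines = [f"stoichflex run (seed {report.config.get('seed')})", ""]
    stages = report.stages
    if "input" in stages:
        i = stages["input"]
        lines.append(f"input: {i['n_records']} records, {i['n_species']} species, {i['n_sites']} sites")
    if "np_filter" in stages:
        f = stages["np_filter"]
        lines.append(f"N:P filter: removed {f['n_removed']} ({f['fraction_removed']:.4%})")
    mc = stages.get("model_comparison")
    if mc and mc.get("grid"):
        lines.append("model comparison:")
        for row in mc["grid"]:
            val = "flagged" if row["value"] is None else f"{row['value']:.3f}"
            lines.append(f"  {row['trait']:>9} {row['data_version']:>6} {row['model']:>16} {row['metric']}: {val}")
    else:
        lines.append("no models fitted")
    t = stages.get("tga")
    if t:
        lines.append("trait gradient analysis:")
        for trait, mode in t["slope_modes"].items():
            lines.append(f"  {trait}: slope mode {mode:.3f}, median normalized range "
                         f"{t['range_medians'][trait]:.3f}")
        for trait, d in t["decomposition"].items():
            lines.append(f"  {trait}: R2_across {d['r2_across']:.3f}, R2_within {d['r2_within']:.3f}")
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(str(summary))

    fs = stages.get("feature_selection")
    if fs and "skipped" not in fs:
        fig, axes = plt.subplots(1, len(fs), figsize=(4 * len(fs), 3), squeeze=False)
        for ax, (trait, info) in zip(axes[0], fs.items()):
            path = info["path"]
            ax.barh([p["eliminated"] for p in path], [p["cv_r2"] for p in path])
            ax.set_title(trait)
            ax.set_xlabel("CV R2 before elimination")
        fig.tight_layout()
        f = outdir / "rfe_path.png"
        fig.savefig(f)
        plt.close(fig)
        written.append(str(f))

    if t:
        fig, ax = plt.subplots(figsize=(5, 3))
        for trait, mode in t["slope_modes"].items():
            ax.axvline(mode, linestyle="--", alpha=0.6, label=f"{trait} mode {mode:.2f}")
        ax.legend()
        ax.set_xlabel("TGA slope")
        fig.tight_layout()
        f = outdir / "tga_modes.png"
        fig.savefig(f)
        plt.close(fig)
        written.append(str(f))
    return written
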