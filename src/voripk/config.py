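"""Run configuration and the staged replication pipeline.

A run config (YAML or dict) names the stages to execute in order and the
shared settings (seeds, replicate counts, thresholds, output directory).
Stages: simulate-data, fit, stepwise, bootstrap, vpc, pta.  Each stage's
inputs must be produced by an earlier stage (or given as files); the
pipeline validates this before executing anything.  A manifest records
package version, seeds and output hashes for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import CohortSpec, generate_cohort
from .covariates import CovariateCandidate, stepwise
from .data import read_dataset, write_dataset
from .dosing import (CRP1, CRP2, compare_to_empirical, loading_table,
                     maintenance_table)
from .estimation import fit
from .model import PopulationModel, final_model
from .validation import bootstrap, ebe_crp_analysis, gof_table, vpc

__all__ = ["RunConfig", "run_pipeline", "load_model_file", "save_model_file"]

log = logging.getLogger(__name__)

STAGES = ("simulate-data", "fit", "stepwise", "bootstrap", "vpc", "pta")
#: stages that require a fitted model first
_NEEDS_FIT = {"bootstrap", "vpc"}
#: stages that require a dataset
_NEEDS_DATA = {"fit", "stepwise", "bootstrap", "vpc"}


@dataclass
class RunConfig:
    stages: list = field(default_factory=lambda: list(STAGES))
    outdir: str = "voripk_run"
    seed: int = 1
    dataset: str | None = None        # CSV path; else simulate-data must run
    model: str | None = None          # model YAML; else built-in final model
    n_subjects: int = 69
    n_bootstrap: int = 1000
    n_vpc: int = 2000
    n_pta: int = 1000
    loading_thresholds: tuple = (1.0, 5.0)
    maintenance_thresholds: tuple = (1.0, 5.5)
    fit_options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        have_data = self.dataset is not None
        have_fit = False
        for s in self.stages:
            if s == "simulate-data":
                have_data = True
            if s in _NEEDS_DATA and not have_data:
                raise ValueError(f"stage {s!r} needs a dataset: provide "
                                 "'dataset' or run simulate-data first")
            if s in _NEEDS_FIT and not (have_fit or self.model):
                raise ValueError(f"stage {s!r} needs a fitted model: run "
                                 "'fit' first or provide 'model'")
            if s == "fit":
                have_fit = True


def load_model_file(path) -> PopulationModel:
    with open(path) as fh:
        return PopulationModel.from_dict(yaml.safe_load(fh))


def save_model_file(model: PopulationModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    Stage failures halt the run; artifacts already written are preserved.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "stages": list(config.stages), "artifacts": {}}

    model = load_model_file(config.model) if config.model else final_model()
    dataset = read_dataset(config.dataset) if config.dataset else None
    fitres = None

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha(path)}

    for stage in config.stages:
        log.info("pipeline stage: %s", stage)
        if stage == "simulate-data":
            ds = generate_cohort(CohortSpec(n_subjects=config.n_subjects),
                                 model, seed=config.seed)
            p = out / "simulated_data.csv"
            write_dataset(ds, p)
            record("dataset", p)
            dataset = ds
        elif stage == "fit":
            fitres = fit(dataset, model, **config.fit_options)
            model = fitres.model
            p = out / "final_model.yaml"
            save_model_file(model, p)
            record("model", p)
            gof = gof_table(dataset, fitres)
            p = out / "gof.csv"
            gof.to_csv(p, index=False)
            record("gof", p)
            from .plots import plot_gof
            plot_gof(gof, out / "gof.png")
            post = ebe_crp_analysis(fitres, dataset)
            (out / "ebe_crp.json").write_text(json.dumps(post, indent=2))
            record("ebe_crp", out / "ebe_crp.json")
        elif stage == "stepwise":
            base = fitres if fitres is not None else model
            meds = _cov_medians(dataset)
            candidates = [
                CovariateCandidate("CL", c, "exponential", center=meds[c])
                for c in ("CRP", "WT", "ALB") if c in meds]
            fitres, trace = stepwise(dataset, base, candidates,
                                     **config.fit_options)
            model = fitres.model
            p = out / "selection_trace.csv"
            trace.to_csv(p, index=False)
            record("selection_trace", p)
        elif stage == "bootstrap":
            rep = bootstrap(dataset, model, n=config.n_bootstrap,
                            seed=config.seed, **config.fit_options)
            p = out / "bootstrap.csv"
            rep.summary.to_csv(p, index=False)
            record("bootstrap", p)
        elif stage == "vpc":
            rep = vpc(dataset, model, n_sim=config.n_vpc, seed=config.seed)
            p = out / "vpc.csv"
            rep.table.to_csv(p, index=False)
            record("vpc", p)
            from .plots import plot_vpc
            plot_vpc(rep, out / "vpc.png")
        elif stage == "pta":
            ldf, best = loading_table(model, n=config.n_pta, seed=config.seed,
                                      thresholds=config.loading_thresholds)
            p = out / "loading_pta.csv"
            ldf.to_csv(p, index=False)
            record("loading_pta", p)
            loading = {"CRP-1": best[("CRP-1", "iv")],
                       "CRP-2": best[("CRP-2", "iv")]}
            mdf, rec, results = maintenance_table(
                loading, model, n=config.n_pta, seed=config.seed,
                thresholds=config.maintenance_thresholds)
            p = out / "maintenance_pta.csv"
            mdf.to_csv(p, index=False)
            record("maintenance_pta", p)
            from .plots import plot_trough_distributions
            plot_trough_distributions(results, out / "trough_distributions.png")
            cmp = compare_to_empirical(
                model, {k: (v["loading_mg"], v["maintenance_mg"])
                        for (k, r), v in rec.items() if r == "iv"},
                n=config.n_pta, seed=config.seed)
            p = out / "empirical_comparison.csv"
            cmp.to_csv(p, index=False)
            record("empirical_comparison", p)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _cov_medians(dataset) -> dict:
    cols: dict[str, list] = {}
    for s in dataset:
        for k, v in s.covariates.items():
            if isinstance(v, (int, float)) and np.isfinite(v):
                cols.setdefault(k, []).append(float(v))
    return {k: float(np.median(v)) for k, v in cols.items()}
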