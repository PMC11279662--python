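"""Pipeline orchestration: simulate -> nca -> fit -> select -> diagnose.

Each stage writes its artifacts into the run directory and is resumable: a
stage whose output file already exists is loaded instead of recomputed
(unless ``force``).  A manifest records the package version, seeds and a
content hash of every artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import default_popmodel, default_virtual_cohort, simulate_dataset
from .config import RunConfig, popmodel_to_dict, save_model
from .covariates import stepwise_select
from .data import PKDataset
from .diagnostics import residual_table, vpc
from .io import read_cohort, read_dataset, write_dataset
from .nca import nca_dataset
from .nlme import fit_saem

__all__ = ["run_pipeline"]


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, force: bool = False) -> Path:
    """Execute the configured stages in order; returns the artifact dir.

    A stage failure raises after flushing the manifest, so partial outputs
    are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    manifest_path = out / "manifest.json"

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {p.name: _hash(p) for p in paths}
        manifest_path.write_text(json.dumps(manifest, indent=2))

    try:
        # ---- data stage ----
        data_path = out / "dataset.csv"
        if config.dataset:
            dataset = read_dataset(config.dataset)
            write_dataset(dataset, data_path)
        elif "simulate" in config.stages:
            if not data_path.exists() or force:
                cohort = (
                    default_virtual_cohort()
                    if config.cohort == "default"
                    else read_cohort(config.cohort)
                )
                model = config.popmodel() or default_popmodel()
                dataset = simulate_dataset(
                    cohort, model, config.design_spec(), seed=config.seed
                )
                write_dataset(dataset, data_path)
            dataset = read_dataset(data_path)
        else:
            raise FileNotFoundError("no dataset path and no simulate stage")
        record("data", data_path)

        if "nca" in config.stages:
            nca_path = out / "nca.csv"
            if not nca_path.exists() or force:
                nca_dataset(dataset).to_csv(nca_path, index=False)
            record("nca", nca_path)

        fit = None
        if "fit" in config.stages:
            est_path = out / "estimates.csv"
            model_path = out / "final_model.yaml"
            model = config.popmodel()
            if model is None:
                from .initials import nca_informed_initials

                model = nca_informed_initials(dataset)
            fit = fit_saem(dataset, model, config.settings())
            fit.estimates_frame().to_csv(est_path, index=False)
            save_model(fit.model, model_path)
            (out / "fit_summary.json").write_text(
                json.dumps(
                    {
                        "minus2ll": fit.minus2ll,
                        "aic": fit.aic,
                        "bic": fit.bic,
                        "bicc": fit.bicc,
                        "flags": {k: str(v) for k, v in fit.flags.items()},
                    },
                    indent=2,
                )
            )
            record("fit", est_path, model_path, out / "fit_summary.json")

        if "select" in config.stages and config.candidates:
            if fit is None:
                raise RuntimeError("select stage requires the fit stage")
            cands = [tuple(c) for c in config.candidates]
            fit, trace = stepwise_select(
                dataset, fit.model, cands, settings=config.settings()
            )
            trace.to_frame().to_csv(out / "selection_trace.csv", index=False)
            save_model(fit.model, out / "final_model.yaml")
            record("select", out / "selection_trace.csv", out / "final_model.yaml")

        if "diagnose" in config.stages and fit is not None:
            res_path = out / "residuals.csv"
            residual_table(fit, k_sim=config.ksim, seed=config.seed + 2).to_csv(
                res_path, index=False
            )
            record("diagnose", res_path)

        if "vpc" in config.stages and fit is not None:
            vpc_path = out / "vpc.csv"
            bands = vpc(
                fit, k_sim=config.ksim, seed=config.seed + 3, level=config.level
            )
            bands.table.to_csv(vpc_path, index=False)
            record("vpc", vpc_path)
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return out
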