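"""YAML (de)serialization of population models, designs and run configs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .covariates import CovariateEffect
from .data import DesignSpec
from .nlme import PopModel, SaemSettings

__all__ = [
    "popmodel_to_dict",
    "popmodel_from_dict",
    "load_model",
    "save_model",
    "RunConfig",
    "load_config",
]


def popmodel_to_dict(model: PopModel) -> dict:
    return {
        "structural": model.structural,
        "theta": dict(model.theta),
        "omega": dict(model.omega),
        "correlations": [
            {"pair": [p1, p2], "rho": float(r)}
            for (p1, p2), r in model.correlations.items()
        ],
        "error": {"model": model.error_model, "a": model.a, "b": model.b},
        "effects": [
            {
                "parameter": e.parameter,
                "covariate": e.covariate,
                "kind": e.kind,
                "beta": e.beta,
                "reference": e.reference,
                "level": e.level,
            }
            for e in model.effects
        ],
    }


def popmodel_from_dict(d: dict) -> PopModel:
    err = d.get("error", {})
    return PopModel(
        structural=d.get("structural", "two_compartment"),
        theta={k: float(v) for k, v in d["theta"].items()},
        omega={k: float(v) for k, v in d.get("omega", {}).items()},
        correlations={
            tuple(c["pair"]): float(c["rho"]) for c in d.get("correlations", [])
        },
        a=float(err.get("a", 0.05)),
        b=float(err.get("b", 0.10)),
        error_model=err.get("model", "combined1"),
        effects=tuple(
            CovariateEffect(
                parameter=e["parameter"],
                covariate=e["covariate"],
                kind=e["kind"],
                beta=float(e.get("beta", 0.0)),
                reference=e.get("reference", 1.0),
                level=e.get("level"),
            )
            for e in d.get("effects", [])
        ),
    )


def load_model(path) -> PopModel:
    with open(path) as fh:
        return popmodel_from_dict(yaml.safe_load(fh))


def save_model(model: PopModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(popmodel_to_dict(model), fh, sort_keys=False)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "salbupop_run"
    seed: int = 20240630
    dataset: str | None = None  # path; when absent, simulate
    cohort: str = "default"  # "default" or a cohort CSV path
    design: dict = field(default_factory=dict)  # times / dose_ug overrides
    model: dict | str | None = None  # inline dict or model YAML path
    fit: dict = field(default_factory=dict)  # SaemSettings overrides
    stages: tuple[str, ...] = ("simulate", "nca", "fit", "diagnose", "vpc")
    candidates: list = field(default_factory=list)  # [[param, covariate], ...]
    ksim: int = 500
    level: float = 0.90

    def design_spec(self) -> DesignSpec:
        return DesignSpec(**self.design) if self.design else DesignSpec()

    def settings(self) -> SaemSettings:
        return SaemSettings(seed=self.seed, **self.fit)

    def popmodel(self) -> PopModel | None:
        if self.model is None:
            return None
        if isinstance(self.model, str):
            return load_model(self.model)
        return popmodel_from_dict(self.model)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    base = Path(path).parent
    if isinstance(cfg.model, str) and not Path(cfg.model).is_absolute():
        cfg.model = str(base / cfg.model)
    if cfg.dataset and not Path(cfg.dataset).is_absolute():
        cfg.dataset = str(base / cfg.dataset)
    return cfg
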