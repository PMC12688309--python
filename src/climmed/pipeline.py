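"""End-to-end pipeline: simulate (or load) → describe → model ladder →
mediate → bootstrap → report, with a reproducibility manifest.

A single mapping (usually a YAML file) drives the whole run; every
random draw traces to a seed recorded in the manifest, and re-running
from the manifest's config snapshot regenerates byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .descriptives import describe_by_outcome
from .estimation import ModelSpec, fit_logistic_ri
from .exceptions import InvalidArgumentError, PipelineError
from .io import load_cohort_csv, write_cohort_csv
from .mediation import (
    DEFAULT_COVARIATES,
    assemble_path_model,
    bootstrap_effects,
    decompose_effects,
    effects_frame,
    filter_analysis_set,
    replicates_frame,
)
from .synthetic import GeneratorConfig, default_config, simulate_cohort

logger = logging.getLogger("climmed")

__all__ = ["run_pipeline", "load_config", "RunManifest", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "data": None,  # path to a cohort CSV; None → simulate
    "generator": {"n_individuals": 5000, "seed": 20180401},
    "outcome": "overweight",
    "covariates": list(DEFAULT_COVARIATES),
    "covariates_in_mediators": True,
    "quadrature_points": 7,
    "temperature_column": "mean_temp_c",
    "bootstrap": {
        "n_reps": 200,
        "resample_size": 2000,
        "seed": 20180402,
        "quadrature_points": 7,
    },
    "decimals": 4,
    "output_dir": "climmed_run",
}


@dataclasses.dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seeds: dict[str, int]
    version: str
    input_checksums: dict[str, str]
    stage_seconds: dict[str, float]
    outputs: dict[str, str]  # file name -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    """Load a YAML run config, filling unspecified keys with defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if key not in cfg:
            raise InvalidArgumentError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _generator_config(block: dict) -> GeneratorConfig:
    block = dict(block)
    calibrate = block.pop("calibrate", True)
    targets = block.pop("targets", None)
    if calibrate:
        return default_config(targets=targets, **block)
    return GeneratorConfig(**block)


def run_pipeline(config: dict | str | Path, output_dir=None) -> RunManifest:
    """Execute the full analysis described by ``config`` (mapping or YAML
    path); writes all tables plus ``manifest.json`` into the output
    directory and returns the manifest."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        for key, value in (config or {}).items():
            if key not in merged:
                raise InvalidArgumentError(f"unknown config key {key!r}")
            if isinstance(merged[key], dict) and isinstance(value, dict):
                merged[key].update(value)
            else:
                merged[key] = value
        config = merged
    out_dir = Path(output_dir if output_dir is not None else config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    seeds: dict[str, int] = {}
    checksums: dict[str, str] = {}
    timings: dict[str, float] = {}
    outputs: list[Path] = []
    manifest = RunManifest(config, seeds, __version__, checksums, timings, {})

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise PipelineError(
                        f"stage {name!r} failed: {exc}", stage=name, manifest=manifest
                    ) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _Timer()

    # --- simulate or load -------------------------------------------------
    with stage("data"):
        if config["data"]:
            checksums[str(config["data"])] = _sha256(Path(config["data"]))
            cohort = load_cohort_csv(config["data"])
            provinces = (
                cohort[["province_id", "mean_temp_c"]]
                .drop_duplicates()
                .sort_values("province_id")
                .reset_index(drop=True)
            )
        else:
            gen_cfg = _generator_config(config["generator"])
            seeds["generator"] = gen_cfg.seed
            provinces, cohort = simulate_cohort(gen_cfg)
            write_cohort_csv(cohort, out_dir / "cohort.csv")
            provinces.to_csv(out_dir / "provinces.csv", index=False)
            outputs += [out_dir / "cohort.csv", out_dir / "provinces.csv"]
        tcol = config["temperature_column"]
        if tcol != "mean_temp_c":
            if tcol not in cohort.columns:
                raise InvalidArgumentError(f"temperature column missing: {tcol!r}")
            cohort = cohort.assign(mean_temp_c=cohort[tcol])
    outcome = config["outcome"]
    covariates = tuple(config["covariates"])

    # --- descriptives -----------------------------------------------------
    with stage("describe"):
        desc = describe_by_outcome(
            cohort, outcome, ["age", "sex", "education", "pa_level", "fv_adequate"]
        )
        desc.to_csv(out_dir / "descriptives.csv", index=False)
        outputs.append(out_dir / "descriptives.csv")

    # --- sequential model ladder -----------------------------------------
    with stage("model_ladder"):
        analysis = filter_analysis_set(cohort)
        qp = config["quadrature_points"]
        ladder_specs = {
            "model1": ["mean_temp_c"],
            "model2": ["mean_temp_c", *covariates],
            "model3": ["mean_temp_c", *covariates, "pa_level", "fv_adequate"],
        }
        ladder_rows = []
        for name, predictors in ladder_specs.items():
            fit = fit_logistic_ri(
                analysis,
                ModelSpec(outcome, "binary", predictors, cluster="province_id",
                          quadrature_points=qp),
            )
            fit.summary_frame().to_csv(out_dir / f"{name}_coefficients.csv")
            outputs.append(out_dir / f"{name}_coefficients.csv")
            ladder_rows.append(
                {
                    "model": name, "loglik": fit.loglik, "n_params": fit.n_params,
                    "aic": fit.aic, "bic": fit.bic,
                    "sigma2": fit.variance_component,
                    "sigma2_se": fit.variance_component_se,
                }
            )

    # --- mediation (Model 4) ----------------------------------------------
    with stage("mediate"):
        path = assemble_path_model(
            cohort, outcome=outcome, covariates=covariates,
            quadrature_points=qp,
            covariates_in_mediators=config["covariates_in_mediators"],
        )
        decomp = decompose_effects(path)
        fit4 = path.fits["outcome"]
        ladder_rows.append(
            {
                "model": "model4", "loglik": fit4.loglik, "n_params": fit4.n_params,
                "aic": fit4.aic, "bic": fit4.bic,
                "sigma2": fit4.variance_component,
                "sigma2_se": fit4.variance_component_se,
            }
        )
        pd.DataFrame(ladder_rows).to_csv(out_dir / "model_ladder.csv", index=False)
        outputs.append(out_dir / "model_ladder.csv")
        for eq, fit in path.fits.items():
            fit.summary_frame().to_csv(out_dir / f"model4_{eq}_coefficients.csv")
            outputs.append(out_dir / f"model4_{eq}_coefficients.csv")
        coef_json = {
            "a1": path.a1, "a21": path.a21, "a22": path.a22,
            "b1": path.b1, "b21": path.b21, "b22": path.b22,
            "c": path.c, "sigma2": path.sigma2,
            "decomposition": decomp.to_frame().set_index("estimand")["value"].to_dict(),
        }
        (out_dir / "path_coefficients.json").write_text(
            json.dumps(coef_json, indent=2, sort_keys=True)
        )
        outputs.append(out_dir / "path_coefficients.json")

    # --- bootstrap --------------------------------------------------------
    with stage("bootstrap"):
        boot_cfg = config["bootstrap"]
        seeds["bootstrap"] = int(boot_cfg["seed"])
        results = bootstrap_effects(
            cohort,
            outcome=outcome,
            n_reps=int(boot_cfg["n_reps"]),
            resample_size=int(boot_cfg["resample_size"]),
            seed=int(boot_cfg["seed"]),
            quadrature_points=int(boot_cfg["quadrature_points"]),
            covariates=covariates,
            covariates_in_mediators=config["covariates_in_mediators"],
        )
        effects_frame(results).round(6).to_csv(out_dir / "effects.csv", index=False)
        replicates_frame(results).to_csv(out_dir / "replicates.csv", index=False)
        outputs += [out_dir / "effects.csv", out_dir / "replicates.csv"]

    # --- manifest ---------------------------------------------------------
    with stage("report"):
        manifest.outputs = {p.name: _sha256(p) for p in outputs}
        (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
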