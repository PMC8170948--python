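"""Run configuration and end-to-end pipeline orchestration.

A run is described by a plain YAML file; all model defaults mirror the
method's settings (inner 10-fold CV for lambda, outer 5-fold validation,
at least 10 predictors, the >500-person municipality filter, septile
grouping).  ``run_full_pipeline`` ties the stages together and writes, per
disease and model variant, the selected-fit CSV and the map-ready
municipality estimates, plus the cross-validated evaluation report and a
run manifest; a rerun with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path


import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .evaluation import WpeConfig, crossvalidated_municipal_wpe
from .features import VARIANTS, build_design_matrix, schema_from_population
from .lasso import lasso_logit_cv, predict_probabilities
from .small_area import municipality_estimates
from .synthetic import (
    DX_PREFIX,
    SynthConfig,
    benchmark_config,
    demo_config,
    generate_population,
    read_population,
    true_municipal_prevalence,
    write_population,
)

__all__ = ["ModelSettings", "RunConfig", "run_full_pipeline", "generate_demo_data"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSettings:
    k_inner: int = 10
    k_outer: int = 5
    min_predictors: int = 10
    threshold: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-2

    def validate(self) -> None:
        if self.k_inner < 2 or self.k_outer < 2:
            raise ConfigError("fold counts must be >= 2")
        if self.min_predictors < 0:
            raise ConfigError("min_predictors must be >= 0")
        if not (0 < self.threshold < 1):
            raise ConfigError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    output_dir: str = "prevmap_out"
    population_csv: str | None = None  # if None, the synth preset is generated
    synth_preset: str = "demo"  # "demo" | "benchmark"
    synth_overrides: dict = field(default_factory=dict)
    code_list_csv: str | None = None
    diseases: tuple[str, ...] = ()  # empty: all dx_ columns found
    variants: tuple[str, ...] = VARIANTS
    model: ModelSettings = ModelSettings()
    wpe: WpeConfig = WpeConfig()
    standardization_reference: str = "national"  # or a CSV of reference ages
    seed: int = 0

    def validate(self) -> None:
        self.model.validate()
        for v in self.variants:
            if v not in VARIANTS:
                raise ConfigError(f"unknown variant {v!r}")
        if self.synth_preset not in ("demo", "benchmark"):
            raise ConfigError(f"unknown synth preset {self.synth_preset!r}")
        if self.population_csv and not Path(self.population_csv).exists():
            raise ConfigError(f"population CSV not found: {self.population_csv}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        model = ModelSettings(**raw.pop("model", {}))
        wpe = WpeConfig(**raw.pop("wpe", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        for key in ("diseases", "variants"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(model=model, wpe=wpe, **raw)
        cfg.validate()
        return cfg

    def synth_config(self) -> SynthConfig:
        base = demo_config(self.seed) if self.synth_preset == "demo" else benchmark_config(self.seed)
        overrides = dict(self.synth_overrides)
        overrides.setdefault("seed", self.seed)
        cfg = replace(base, **overrides)
        cfg.validate()
        return cfg


def _load_or_generate(cfg: RunConfig) -> pd.DataFrame:
    if cfg.population_csv:
        logger.info("loading population from %s", cfg.population_csv)
        return read_population(cfg.population_csv)
    synth = cfg.synth_config()
    logger.info(
        "generating synthetic population: %d persons, %d municipalities, seed %d",
        synth.n_individuals, synth.n_municipalities, synth.seed,
    )
    return generate_population(synth)


def generate_demo_data(cfg: RunConfig, out_dir=None) -> dict[str, Path]:
    """Write the synthetic population CSV and per-municipality truth CSV."""
    out = Path(out_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pop = _load_or_generate(cfg)
    paths = {"population": out / "population.csv", "truth": out / "municipal_truth.csv"}
    write_population(pop, paths["population"])
    diseases = cfg.diseases or tuple(
        c[len(DX_PREFIX):] for c in pop.columns if c.startswith(DX_PREFIX)
    )
    truth = pd.DataFrame({"municipality_id": sorted(pop["municipality_id"].unique())})
    truth["n"] = pop.groupby("municipality_id", sort=True).size().to_numpy()
    for d in diseases:
        truth[f"true_prev_{d}"] = true_municipal_prevalence(pop, d).to_numpy()
    truth.to_csv(paths["truth"], index=False)
    logger.info("wrote %s and %s", paths["population"], paths["truth"])
    return paths


def run_full_pipeline(
    cfg: RunConfig, do_estimate: bool = True, do_evaluate: bool = True
) -> dict[str, Path]:
    """Run simulate/fit/estimate/evaluate end to end; returns output paths.

    ``do_estimate``/``do_evaluate`` switch off the later stages for partial
    runs.  On any stage error the partial outputs written by this run are
    removed and the error is re-raised with a stage tag.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    paths: dict[str, Path] = {}
    stage = "load"
    try:
        pop = _load_or_generate(cfg)
        diseases = cfg.diseases or tuple(
            c[len(DX_PREFIX):] for c in pop.columns if c.startswith(DX_PREFIX)
        )
        if not diseases:
            raise ConfigError("no diseases configured and no dx_ columns found")
        train = pop[pop["in_training"] == 1]
        logger.info(
            "population: %d rows, %d municipalities, %d training rows",
            len(pop), pop["municipality_id"].nunique(), len(train),
        )
        ref_ages = None
        if cfg.standardization_reference != "national":
            ref_ages = pd.read_csv(cfg.standardization_reference)["age"].to_numpy()

        stage = "fit"
        ms = cfg.model
        fits = {}
        for variant in cfg.variants:
            schema = schema_from_population(pop, variant)
            X_train = build_design_matrix(train, schema)
            X_all = build_design_matrix(pop, schema)
            for disease in diseases:
                y = train[DX_PREFIX + disease].to_numpy(float)
                fit, _, _ = lasso_logit_cv(
                    X_train, y,
                    k=ms.k_inner, threshold=ms.threshold,
                    min_predictors=ms.min_predictors,
                    seed=cfg.seed, n_lambda=ms.n_lambda,
                    lambda_min_ratio=ms.lambda_min_ratio,
                )
                logger.info(
                    "fit %s/%s: lambda=%.5g branch=%s nnz=%d",
                    disease, variant, fit.lambda_, fit.branch, fit.nnz,
                )
                fp = out / f"fit_{disease}_{variant}.csv"
                fit.to_csv(fp)
                written.append(fp)
                paths[f"fit_{disease}_{variant}"] = fp
                fits[(disease, variant)] = (fit, X_all)

        if do_estimate:
            stage = "estimate"
            for (disease, variant), (fit, X_all) in fits.items():
                probs = predict_probabilities(fit, X_all)
                est = municipality_estimates(pop, probs, disease, reference_ages=ref_ages)
                ep = out / f"municipality_estimates_{disease}_{variant}.csv"
                est.to_csv(ep, index=False)
                written.append(ep)
                paths[f"estimates_{disease}_{variant}"] = ep

        if do_evaluate:
            stage = "evaluate"
            report = crossvalidated_municipal_wpe(
                pop, diseases, cfg.variants,
                k=ms.k_outer, seed=cfg.seed, cfg=cfg.wpe,
                k_inner=ms.k_inner, min_predictors=ms.min_predictors,
                threshold=ms.threshold, n_lambda=ms.n_lambda,
                lambda_min_ratio=ms.lambda_min_ratio,
            )
            rp = out / "evaluation_report.csv"
            report.to_csv(rp)
            written.append(rp)
            paths["evaluation_report"] = rp

        stage = "manifest"
        manifest = {
            "config": _config_dict(cfg),
            "seed": cfg.seed,
            "prevmap_version": __version__,
            "diseases": list(diseases),
            "variants": list(cfg.variants),
            "n_individuals": int(len(pop)),
            "n_municipalities": int(pop["municipality_id"].nunique()),
            "n_training": int(len(train)),
        }
        mp = out / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(mp)
        paths["manifest"] = mp
        return paths
    except Exception as exc:
        for f in written:
            f.unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["model"] = dataclasses.asdict(cfg.model)
    d["wpe"] = dataclasses.asdict(cfg.wpe)
    d["variants"] = list(cfg.variants)
    d["diseases"] = list(cfg.diseases)
    return d
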