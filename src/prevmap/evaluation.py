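"""Validation of municipal prevalence estimates.

The headline statistic is the weighted percentage error (WPE): the
municipality-level relative error (P_m - O_m) / O_m averaged with weights
proportional to each municipality's training subpopulation.  Municipalities
with at most ``min_training_n`` (default 500) training persons are excluded
— observed prevalence is unstable or zero there — and the weights are
renormalized over the included municipalities so they sum to one.  The WPE
is reported as a percentage; the default is the absolute-error form, with
the signed form retained for bias diagnosis.

Discrimination is summarized by the AUC in its Mann-Whitney rank
formulation (ties receive half credit).

``crossvalidated_municipal_wpe`` orchestrates the internal-validity check:
the training rows are split into k outer folds; for each fold the full
penalized-regression procedure (path fit, 10-fold internal CV, composite
lambda selection) is run on the remaining folds and the held-out rows
receive out-of-fold predicted probabilities, which are then aggregated per
municipality and compared with observed prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import InputError
from .features import build_design_matrix, schema_from_population
from .lasso import lasso_logit_cv, predict_probabilities
from .small_area import aggregate_prevalence
from .synthetic import DX_PREFIX

__all__ = [
    "WpeConfig",
    "EvaluationReport",
    "observed_prevalence",
    "weighted_percentage_error",
    "auc",
    "crossvalidated_municipal_wpe",
]


@dataclass(frozen=True)
class WpeConfig:
    """WPE settings: inclusion filter and error mode."""

    min_training_n: int = 500
    mode: str = "absolute"  # "absolute" | "signed"

    def __post_init__(self):
        if self.min_training_n < 0:
            raise InputError("min_training_n must be >= 0")
        if self.mode not in ("absolute", "signed"):
            raise InputError(f"unknown WPE mode {self.mode!r}")


def observed_prevalence(diagnoses, municipality_ids) -> pd.DataFrame:
    """Observed prevalence per municipality among (training) rows.

    Returns columns municipality_id, O_m, n_m_training.
    """
    dx = np.asarray(diagnoses, float)
    if not np.isin(dx, (0.0, 1.0)).all():
        raise InputError("diagnoses must be strictly 0/1")
    muni = np.asarray(municipality_ids)
    if muni.shape[0] != dx.shape[0]:
        raise InputError("diagnoses and municipality ids are not aligned")
    df = pd.DataFrame({"municipality_id": muni, "dx": dx})
    out = (
        df.groupby("municipality_id", sort=True)["dx"]
        .agg(O_m="mean", n_m_training="size")
        .reset_index()
    )
    out["n_m_training"] = out["n_m_training"].astype(np.int64)
    return out


def weighted_percentage_error(
    P_m, O_m, n_m_training, cfg: WpeConfig = WpeConfig()
) -> float:
    """WPE in percent over municipalities passing the training-size filter.

    Weights are training-subpopulation shares renormalized over the
    included municipalities (training count strictly greater than
    ``cfg.min_training_n``) so they sum to one.
    """
    P = np.asarray(P_m, float)
    O = np.asarray(O_m, float)
    n = np.asarray(n_m_training, float)
    if not (P.shape == O.shape == n.shape):
        raise InputError("P_m, O_m and n_m_training are not aligned")
    include = n > cfg.min_training_n
    if not include.any():
        raise InputError(
            f"no municipality has more than {cfg.min_training_n} training persons"
        )
    if np.any(O[include] <= 0):
        raise InputError("observed prevalence is zero in an included municipality")
    w = n[include] / n[include].sum()
    err = (P[include] - O[include]) / O[include]
    if cfg.mode == "absolute":
        err = np.abs(err)
    return float(100.0 * np.sum(w * err))


def auc(probabilities, outcomes) -> float:
    """Area under the ROC curve, Mann-Whitney form with tie half-credit."""
    p = np.asarray(probabilities, float)
    y = np.asarray(outcomes, float)
    if p.shape != y.shape:
        raise InputError("probabilities and outcomes are not aligned")
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise InputError("outcomes must be 0/1")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise InputError("AUC requires both classes")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class EvaluationReport:
    """Cross-validated comparison of model variants.

    ``table`` holds one row per (disease, variant) with WPE (absolute and
    signed), AUC on pooled out-of-fold predictions, and the municipality
    filter count.  ``oof`` maps (disease, variant) to the out-of-fold
    probability Series aligned to training-row index; ``municipal`` maps to
    the per-municipality comparison frame.
    """

    table: pd.DataFrame
    k: int
    seed: int
    oof: dict = field(default_factory=dict)
    municipal: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def crossvalidated_municipal_wpe(
    pop: pd.DataFrame,
    diseases,
    variants,
    k: int = 5,
    seed: int = 0,
    cfg: WpeConfig = WpeConfig(),
    k_inner: int = 10,
    min_predictors: int = 10,
    threshold: float = 0.5,
    covariate_levels: dict | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-2,
) -> EvaluationReport:
    """Out-of-fold municipal validation for each disease x variant.

    The outer split is by individual, stratified by outcome, and shared
    across variants of the same disease so their comparison is paired.
    Every training row receives exactly one out-of-fold probability.
    """
    if "in_training" not in pop.columns:
        raise InputError("population has no in_training column")
    train = pop[pop["in_training"] == 1]
    if train.empty:
        raise InputError("population has no training rows")
    muni = train["municipality_id"].to_numpy()

    rows = []
    oof_store: dict = {}
    municipal_store: dict = {}
    matrices = {
        v: build_design_matrix(
            train, schema_from_population(pop, v, covariate_levels=covariate_levels)
        )
        for v in variants
    }
    for d_i, disease in enumerate(diseases):
        dx_col = DX_PREFIX + disease
        if dx_col not in train.columns:
            raise InputError(f"training rows lack diagnosis column {dx_col!r}")
        y = train[dx_col].to_numpy(float)
        if np.unique(y).size < 2:
            raise InputError(f"disease {disease!r} has a single class in training")
        outer_seed = int(
            np.random.SeedSequence([seed, d_i]).generate_state(1)[0] % (2**31)
        )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=outer_seed)
        folds = list(skf.split(np.zeros(y.size), y))
        obs = observed_prevalence(y, muni)
        for variant in variants:
            fm = matrices[variant]
            oof = np.full(y.size, np.nan)
            for f, (tr, te) in enumerate(folds):
                fit, _, _ = lasso_logit_cv(
                    fm.data.iloc[tr],
                    y[tr],
                    k=k_inner,
                    threshold=threshold,
                    min_predictors=min_predictors,
                    seed=(outer_seed + 1 + f) % (2**31),
                    n_lambda=n_lambda,
                    lambda_min_ratio=lambda_min_ratio,
                )
                oof[te] = predict_probabilities(fit, fm.data.iloc[te])
            assert not np.isnan(oof).any()
            agg = aggregate_prevalence(oof, muni).rename(
                columns={"n_m": "n_m_oof", "P_m": "P_m"}
            )
            comp = agg.merge(obs, on="municipality_id")
            wpe_abs = weighted_percentage_error(
                comp["P_m"], comp["O_m"], comp["n_m_training"],
                WpeConfig(cfg.min_training_n, "absolute"),
            )
            wpe_signed = weighted_percentage_error(
                comp["P_m"], comp["O_m"], comp["n_m_training"],
                WpeConfig(cfg.min_training_n, "signed"),
            )
            included = int((comp["n_m_training"] > cfg.min_training_n).sum())
            rows.append(
                {
                    "disease": disease,
                    "variant": variant,
                    "k": k,
                    "seed": seed,
                    "n_municipalities_included": included,
                    "wpe_absolute_pct": wpe_abs,
                    "wpe_signed_pct": wpe_signed,
                    "auc": auc(oof, y),
                }
            )
            oof_store[(disease, variant)] = pd.Series(oof, index=train.index)
            municipal_store[(disease, variant)] = comp
    return EvaluationReport(
        table=pd.DataFrame(rows), k=k, seed=seed, oof=oof_store, municipal=municipal_store
    )
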