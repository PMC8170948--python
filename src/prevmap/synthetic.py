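"""Synthetic linked-administrative population generator.

Emulates the kind of national registry extract the estimation pipeline
consumes: one row per person with municipality and GP-practice membership,
socio-demographic covariates, income/wealth percentile scores, binary ATC3
medication-dispensing indicators, a cluster-sampled training subset carrying
diagnoses, and known per-municipality ground-truth prevalence so that
downstream recovery is testable.

Disease ground truth follows a logistic model with a Normal municipality
random effect; medication indicators are drawn conditionally on disease
status (high use probability for linked drug groups, background use
otherwise).  All randomness derives from a single master seed via named
child streams, so each stage is individually reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .errors import ConfigError, InputError

__all__ = [
    "CovariateSpec",
    "AtcCodeSpec",
    "DiseaseModel",
    "SynthConfig",
    "CodeList",
    "generate_population",
    "assign_disease",
    "assign_medication",
    "sample_training_set",
    "flag_disease_from_codes",
    "atc_user_counts",
    "retained_atc_codes",
    "excluded_atc_codes",
    "true_municipal_prevalence",
    "default_code_lists",
    "load_code_lists",
    "write_code_lists",
    "expand_code_range",
    "benchmark_config",
    "demo_config",
    "write_population",
    "read_population",
]

# Sub-stream tags hashed into the master SeedSequence, one per stochastic stage.
_STREAM_SIZES = 1
_STREAM_AGE = 2
_STREAM_FEMALE = 3
_STREAM_COVARIATE = 4
_STREAM_PERCENTILE = 5
_STREAM_PRACTICE = 6
_STREAM_DISEASE = 7
_STREAM_MEDICATION = 8
_STREAM_TRAINING = 9

ATC_PREFIX = "atc_"
DX_PREFIX = "dx_"

#: Minimum annual users for an ATC3 code to enter the predictor set.
MIN_ATC_USERS = 50


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


def _check_prob(p: float, what: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{what} must be in [0, 1], got {p!r}")


@dataclass(frozen=True)
class CovariateSpec:
    """A categorical socio-demographic covariate with declared level marginals."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    #: sd of a per-municipality Normal perturbation of the level logits
    municipality_tilt_sd: float = 0.0

    def validate(self) -> None:
        if len(self.levels) != len(self.probs) or not self.levels:
            raise ConfigError(f"covariate {self.name!r}: levels/probs mismatch")
        for p in self.probs:
            _check_prob(p, f"covariate {self.name!r} level probability")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ConfigError(
                f"covariate {self.name!r}: level probabilities sum to "
                f"{sum(self.probs):.6f}, expected 1"
            )
        if self.municipality_tilt_sd < 0:
            raise ConfigError(f"covariate {self.name!r}: negative tilt sd")


@dataclass(frozen=True)
class AtcCodeSpec:
    """One synthetic ATC3 code: optionally linked to a disease.

    A linked code is dispensed with probability ``use_prob_diseased`` to
    persons having the linked disease and ``use_prob_healthy`` otherwise;
    an unlinked (noise) code uses ``use_prob_healthy`` for everyone.
    """

    code: str
    linked_disease: str | None = None
    use_prob_diseased: float = 0.0
    use_prob_healthy: float = 0.05

    def validate(self) -> None:
        if not self.code:
            raise ConfigError("ATC code name must be non-empty")
        _check_prob(self.use_prob_diseased, f"ATC {self.code} use_prob_diseased")
        _check_prob(self.use_prob_healthy, f"ATC {self.code} use_prob_healthy")


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic ground-truth model for one chronic disease.

    ``coefficients`` maps feature names to slopes on the generator's scaled
    basis: ``age_s`` (= age/100), ``age_s2``, ``female``, ``income_pct_s``
    (= percentile/100), ``wealth_pct_s``, or ``"<covariate>=<level>"``
    indicators.  ``municipality_sd`` is the sd of an additive Normal
    municipality random effect on the logit scale.
    """

    name: str
    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)
    municipality_sd: float = 0.0

    def validate(self) -> None:
        if not self.name:
            raise ConfigError("disease name must be non-empty")
        if self.municipality_sd < 0:
            raise ConfigError(f"disease {self.name!r}: negative municipality sd")


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of a synthetic population."""

    n_individuals: int
    n_municipalities: int
    #: sd of log municipality-size weights (0 = equal-sized municipalities)
    municipality_size_dispersion: float = 0.0
    #: (lo, hi, prob) bands; ages drawn uniformly on the integers [lo, hi)
    age_bands: tuple[tuple[int, int, float], ...] = ()
    female_prob: float = 0.505
    covariates: tuple[CovariateSpec, ...] = ()
    #: sd of the municipality shift of the latent normal behind percentiles
    percentile_tilt_sd: float = 0.0
    atc_codes: tuple[AtcCodeSpec, ...] = ()
    disease_models: tuple[DiseaseModel, ...] = ()
    training_fraction: float = 0.1
    n_practices_per_municipality: int = 4
    #: sample whole GP practices into the training set (else simple random)
    cluster_training: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigError("n_individuals must be positive")
        if self.n_municipalities <= 0:
            raise ConfigError("n_municipalities must be positive")
        if self.municipality_size_dispersion < 0:
            raise ConfigError("municipality_size_dispersion must be >= 0")
        if self.n_individuals < self.n_municipalities:
            raise ConfigError("need at least one person per municipality")
        if not self.age_bands:
            raise ConfigError("age_bands must be non-empty")
        for lo, hi, p in self.age_bands:
            if not (0 <= lo < hi):
                raise ConfigError(f"invalid age band [{lo}, {hi})")
            _check_prob(p, "age band probability")
        if abs(sum(p for _, _, p in self.age_bands) - 1.0) > 1e-9:
            raise ConfigError("age band probabilities must sum to 1")
        _check_prob(self.female_prob, "female_prob")
        for cov in self.covariates:
            cov.validate()
        if self.percentile_tilt_sd < 0:
            raise ConfigError("percentile_tilt_sd must be >= 0")
        for code in self.atc_codes:
            code.validate()
        names = [c.code for c in self.atc_codes]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate ATC code names")
        diseases = {m.name for m in self.disease_models}
        for code in self.atc_codes:
            if code.linked_disease is not None and code.linked_disease not in diseases:
                raise ConfigError(
                    f"ATC {code.code} linked to unknown disease {code.linked_disease!r}"
                )
        for m in self.disease_models:
            m.validate()
        if not (0.0 < self.training_fraction <= 1.0):
            raise ConfigError("training_fraction must be in (0, 1]")
        if self.n_practices_per_municipality <= 0:
            raise ConfigError("n_practices_per_municipality must be positive")

    def disease_names(self) -> list[str]:
        return [m.name for m in self.disease_models]

    def atc_names(self) -> list[str]:
        return [c.code for c in self.atc_codes]


# ---------------------------------------------------------------------------
# default study conditions


def _dutch_age_bands() -> tuple[tuple[int, int, float], ...]:
    # Band shares resembling the 2012 Dutch population pyramid; implied
    # population mean age 40.29 (national mean ~40.3).
    return (
        (0, 20, 0.233),
        (20, 25, 0.061),
        (25, 30, 0.062),
        (30, 35, 0.061),
        (35, 40, 0.063),
        (40, 45, 0.072),
        (45, 50, 0.081),
        (50, 55, 0.070),
        (55, 60, 0.064),
        (60, 65, 0.062),
        (65, 70, 0.055),
        (70, 75, 0.042),
        (75, 80, 0.032),
        (80, 85, 0.022),
        (85, 100, 0.020),
    )


def _dutch_covariates() -> tuple[CovariateSpec, ...]:
    # Marginals follow published national percentages; columns that print to
    # slightly more than 100% due to rounding are renormalized.
    marital = CovariateSpec(
        "marital_status",
        ("Unmarried", "Divorced", "Widowed", "Married"),
        (0.470, 0.071, 0.052, 0.407),
    )
    ethnic = CovariateSpec(
        "ethnic_group",
        (
            "Moroccan",
            "Turkish",
            "Surinam",
            "Antilles_Aruba",
            "Native",
            "Other_western",
            "Other_non_western",
        ),
        (0.022, 0.024, 0.021, 0.009, 0.788, 0.042, 0.094),
    )
    immigrant = CovariateSpec(
        "immigrant_generation",
        ("Native", "First_generation", "Second_generation"),
        (0.789, 0.107, 0.104),
    )
    hh_raw = (0.165, 0.392, 0.198, 0.083, 0.063, 0.079, 0.014, 0.014)
    hh_total = sum(hh_raw)
    household = CovariateSpec(
        "household_type",
        (
            "One_person",
            "Married_with_children",
            "Married_no_children",
            "Unmarried_with_children",
            "Unmarried_no_children",
            "One_parent",
            "Institutional",
            "Other",
        ),
        tuple(round(p / hh_total, 12) for p in hh_raw[:-1])
        + (round(1 - sum(round(p / hh_total, 12) for p in hh_raw[:-1]), 12),),
    )
    income_source = CovariateSpec(
        "income_source",
        (
            "Labor",
            "Own_company",
            "Wealth",
            "Social_benefits",
            "Pension",
            "Study_grants",
            "Other",
            "No_income",
        ),
        (0.571, 0.147, 0.004, 0.081, 0.178, 0.008, 0.001, 0.010),
    )
    return (marital, ethnic, immigrant, household, income_source)


def _default_atc_codes(
    n_codes: int, linked: Mapping[str, Sequence[int]]
) -> tuple[AtcCodeSpec, ...]:
    owner: dict[int, str] = {}
    for disease, idxs in linked.items():
        for i in idxs:
            if i in owner:
                raise ConfigError(f"ATC index {i} linked to two diseases")
            owner[i] = disease
    specs = []
    for i in range(n_codes):
        code = f"A{i + 1:02d}"
        if i in owner:
            specs.append(AtcCodeSpec(code, owner[i], 0.7, 0.05))
        else:
            specs.append(AtcCodeSpec(code, None, 0.0, 0.05))
    return tuple(specs)


def benchmark_config(seed: int = 0) -> SynthConfig:
    """Reference study conditions for method evaluation.

    50 municipalities of ~2,000 persons, one chronic disease with a
    municipality random effect (sd 0.3 on the logit scale), 30 ATC3 codes
    of which 3 are disease-linked (use probability 0.7 when diseased vs
    0.05 background), and a ~10% whole-practice training subset.
    """
    cfg = SynthConfig(
        n_individuals=100_000,
        n_municipalities=50,
        municipality_size_dispersion=0.0,
        age_bands=_dutch_age_bands(),
        covariates=_dutch_covariates(),
        atc_codes=_default_atc_codes(30, {"diabetes": [0, 1, 2]}),
        disease_models=(
            DiseaseModel(
                "diabetes",
                intercept=-6.0,
                coefficients={"age_s": 6.5, "female": -0.15},
                municipality_sd=0.3,
            ),
        ),
        training_fraction=0.1,
        n_practices_per_municipality=4,
        seed=seed,
    )
    cfg.validate()
    return cfg


def demo_config(seed: int = 0) -> SynthConfig:
    """Desk-scale demo: 40,000 persons, 50 municipalities, two diseases."""
    cfg = SynthConfig(
        n_individuals=40_000,
        n_municipalities=50,
        municipality_size_dispersion=0.3,
        age_bands=_dutch_age_bands(),
        covariates=_dutch_covariates(),
        atc_codes=_default_atc_codes(30, {"diabetes": [0, 1, 2], "copd": [3, 4, 5]}),
        disease_models=(
            DiseaseModel(
                "diabetes",
                intercept=-6.0,
                coefficients={"age_s": 6.5, "female": -0.15},
                municipality_sd=0.3,
            ),
            DiseaseModel(
                "copd",
                intercept=-6.5,
                coefficients={"age_s": 6.0, "income_pct_s": -0.5},
                municipality_sd=0.3,
            ),
        ),
        training_fraction=0.1,
        n_practices_per_municipality=4,
        seed=seed,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation


def _municipality_sizes(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    m = cfg.n_municipalities
    if cfg.municipality_size_dispersion > 0:
        w = np.exp(rng.normal(0.0, cfg.municipality_size_dispersion, m))
    else:
        w = np.ones(m)
    w = w / w.sum()
    # largest-remainder apportionment with a floor of one person each
    raw = w * (cfg.n_individuals - m)
    sizes = np.floor(raw).astype(np.int64) + 1
    rem = cfg.n_individuals - sizes.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    sizes[order[: int(rem)]] += 1
    assert sizes.sum() == cfg.n_individuals and sizes.min() >= 1
    return sizes


def _sample_ages(cfg: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    bands = cfg.age_bands
    probs = np.array([p for _, _, p in bands])
    probs = probs / probs.sum()
    which = rng.choice(len(bands), size=n, p=probs)
    lo = np.array([b[0] for b in bands])[which]
    hi = np.array([b[1] for b in bands])[which]
    return lo + np.floor(rng.random(n) * (hi - lo)).astype(np.int64)


def _sample_categorical(
    spec: CovariateSpec,
    muni_idx: np.ndarray,
    n_muni: int,
    rng: np.random.Generator,
) -> np.ndarray:
    probs = np.asarray(spec.probs, dtype=float)
    if spec.municipality_tilt_sd > 0:
        logits = np.log(np.maximum(probs, 1e-300))
        tilts = rng.normal(0.0, spec.municipality_tilt_sd, (n_muni, probs.size))
        local = np.exp(logits[None, :] + tilts)
        local = local / local.sum(axis=1, keepdims=True)
        u = rng.random(muni_idx.size)
        cdf = np.cumsum(local, axis=1)
        which = (u[:, None] > cdf[muni_idx]).sum(axis=1)
    else:
        which = rng.choice(probs.size, size=muni_idx.size, p=probs)
    return np.asarray(spec.levels, dtype=object)[which]


def _sample_percentiles(
    muni_idx: np.ndarray, n_muni: int, tilt_sd: float, rng: np.random.Generator
) -> np.ndarray:
    if tilt_sd > 0:
        shift = rng.normal(0.0, tilt_sd, n_muni)
        u = ndtr(rng.normal(0.0, 1.0, muni_idx.size) + shift[muni_idx])
        return np.clip(np.ceil(u * 100).astype(np.int64), 1, 100)
    return rng.integers(1, 101, size=muni_idx.size)


def generate_population(config: SynthConfig) -> pd.DataFrame:
    """Generate the full synthetic population table.

    Returns one row per person with municipality and practice membership,
    covariates, percentile scores, ``dx_<disease>`` truth flags,
    ``atc_<code>`` indicators, and the ``in_training`` marker.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    seed = config.seed
    sizes = _municipality_sizes(config, _rng(seed, _STREAM_SIZES))
    n = config.n_individuals
    muni_idx = np.repeat(np.arange(config.n_municipalities), sizes)
    width = max(3, len(str(config.n_municipalities)))
    muni_ids = np.array(
        [f"M{i + 1:0{width}d}" for i in range(config.n_municipalities)], dtype=object
    )

    pop = pd.DataFrame(
        {
            "person_id": np.arange(n, dtype=np.int64),
            "municipality_id": muni_ids[muni_idx],
            "age": _sample_ages(config, n, _rng(seed, _STREAM_AGE)),
            "female": (
                _rng(seed, _STREAM_FEMALE).random(n) < config.female_prob
            ).astype(np.int8),
        }
    )

    prac_rng = _rng(seed, _STREAM_PRACTICE)
    local_practice = prac_rng.integers(0, config.n_practices_per_municipality, n)
    pop.insert(
        2,
        "practice_id",
        np.array(
            [
                f"{m}_P{k + 1}"
                for m, k in zip(pop["municipality_id"], local_practice)
            ],
            dtype=object,
        ),
    )

    for j, spec in enumerate(config.covariates):
        pop[spec.name] = _sample_categorical(
            spec, muni_idx, config.n_municipalities, _rng(seed, _STREAM_COVARIATE, j)
        )
    pop["income_percentile"] = _sample_percentiles(
        muni_idx, config.n_municipalities, config.percentile_tilt_sd,
        _rng(seed, _STREAM_PERCENTILE, 0),
    )
    pop["wealth_percentile"] = _sample_percentiles(
        muni_idx, config.n_municipalities, config.percentile_tilt_sd,
        _rng(seed, _STREAM_PERCENTILE, 1),
    )

    for j, model in enumerate(config.disease_models):
        pop[DX_PREFIX + model.name] = assign_disease(pop, model, (seed, _STREAM_DISEASE, j))

    med = assign_medication(pop, config.atc_codes, (seed, _STREAM_MEDICATION))
    pop = pd.concat([pop, med], axis=1)

    pop["in_training"] = sample_training_set(
        pop,
        config.training_fraction,
        (seed, _STREAM_TRAINING),
        cluster=config.cluster_training,
    )
    return pop


def _seeded(seed) -> np.random.Generator:
    if isinstance(seed, tuple):
        return _rng(*seed)
    return _rng(seed)


_GEN_FEATURES = {
    "age_s": lambda pop: pop["age"].to_numpy(float) / 100.0,
    "age_s2": lambda pop: (pop["age"].to_numpy(float) / 100.0) ** 2,
    "female": lambda pop: pop["female"].to_numpy(float),
    "income_pct_s": lambda pop: pop["income_percentile"].to_numpy(float) / 100.0,
    "wealth_pct_s": lambda pop: pop["wealth_percentile"].to_numpy(float) / 100.0,
}


def _resolve_feature(pop: pd.DataFrame, name: str) -> np.ndarray:
    if name in _GEN_FEATURES:
        return _GEN_FEATURES[name](pop)
    if "=" in name:
        col, level = name.split("=", 1)
        if col not in pop.columns:
            raise ConfigError(f"unknown covariate {col!r} in disease model")
        return (pop[col].to_numpy() == level).astype(float)
    if name in pop.columns and pd.api.types.is_numeric_dtype(pop[name]):
        return pop[name].to_numpy(float)
    raise ConfigError(f"unknown feature {name!r} in disease model")


def assign_disease(pop: pd.DataFrame, model: DiseaseModel, seed) -> np.ndarray:
    """Draw 0/1 disease status from the logistic ground-truth model."""
    model.validate()
    rng = _seeded(seed)
    lp = np.full(len(pop), float(model.intercept))
    for name, coef in model.coefficients.items():
        lp += float(coef) * _resolve_feature(pop, name)
    if model.municipality_sd > 0:
        munis, inverse = np.unique(pop["municipality_id"].to_numpy(), return_inverse=True)
        effects = rng.normal(0.0, model.municipality_sd, munis.size)
        lp += effects[inverse]
    else:
        # keep the draw count identical whether or not effects are used
        pass
    prob = expit(lp)
    return (rng.random(len(pop)) < prob).astype(np.int8)


def assign_medication(
    pop: pd.DataFrame, atc_codes: Sequence[AtcCodeSpec], seed
) -> pd.DataFrame:
    """Draw ATC3 dispensing indicators conditional on disease status."""
    rng = _seeded(seed)
    out = {}
    for spec in atc_codes:
        spec.validate()
        if spec.linked_disease is not None:
            dx_col = DX_PREFIX + spec.linked_disease
            if dx_col not in pop.columns:
                raise ConfigError(
                    f"ATC {spec.code} linked to disease without a {dx_col} column"
                )
            dx = pop[dx_col].to_numpy()
            p = np.where(dx == 1, spec.use_prob_diseased, spec.use_prob_healthy)
        else:
            p = np.full(len(pop), spec.use_prob_healthy)
        out[ATC_PREFIX + spec.code] = (rng.random(len(pop)) < p).astype(np.int8)
    return pd.DataFrame(out, index=pop.index)


def atc_user_counts(pop: pd.DataFrame) -> pd.Series:
    cols = [c for c in pop.columns if c.startswith(ATC_PREFIX)]
    return pop[cols].sum(axis=0).rename(lambda c: c[len(ATC_PREFIX):])


def retained_atc_codes(pop: pd.DataFrame, min_users: int = MIN_ATC_USERS) -> list[str]:
    """ATC codes dispensed to more than ``min_users`` persons (the rest are
    excluded from the predictor set)."""
    counts = atc_user_counts(pop)
    return [code for code, cnt in counts.items() if cnt > min_users]


def excluded_atc_codes(pop: pd.DataFrame, min_users: int = MIN_ATC_USERS) -> list[str]:
    counts = atc_user_counts(pop)
    return [code for code, cnt in counts.items() if cnt <= min_users]


def sample_training_set(
    pop: pd.DataFrame, training_fraction: float, seed, cluster: bool = True
) -> np.ndarray:
    """Mark a ~``training_fraction`` subset as the diagnosed training set.

    With ``cluster=True`` (default) whole GP practices are selected, in a
    random order, for as long as adding the next practice brings the selected
    share closer to the target — emulating a practice-based registry.  The
    achieved share therefore deviates from the target by at most one
    practice.  ``cluster=False`` gives simple random sampling of persons.
    """
    if not (0.0 < training_fraction <= 1.0):
        raise ConfigError("training_fraction must be in (0, 1]")
    rng = _seeded(seed)
    n = len(pop)
    target = training_fraction * n
    flag = np.zeros(n, dtype=np.int8)
    if cluster:
        practices = pop["practice_id"].to_numpy()
        uniq = np.unique(practices)
        order = rng.permutation(uniq.size)
        sizes = pd.Series(practices).value_counts()
        chosen: list[str] = []
        cum = 0
        for idx in order:
            prac = uniq[idx]
            size = int(sizes[prac])
            if abs(cum + size - target) <= abs(cum - target):
                chosen.append(prac)
                cum += size
            else:
                break
        flag[np.isin(practices, np.asarray(chosen, dtype=object))] = 1
    else:
        k = int(round(target))
        idx = rng.choice(n, size=min(k, n), replace=False)
        flag[idx] = 1
    return flag


def true_municipal_prevalence(pop: pd.DataFrame, disease: str) -> pd.Series:
    """Ground-truth prevalence per municipality (mean of the truth flags)."""
    col = DX_PREFIX + disease
    if col not in pop.columns:
        raise InputError(f"no truth column {col!r} in population")
    return pop.groupby("municipality_id", sort=True)[col].mean()


# ---------------------------------------------------------------------------
# diagnosis code lists and record flagging


@dataclass(frozen=True)
class CodeList:
    """Diagnostic code prefixes defining one disease across coding systems."""

    disease: str
    icpc_codes: tuple[str, ...]
    icd9_codes: tuple[str, ...]
    icd10_codes: tuple[str, ...]

    def validate(self) -> None:
        codes = self.icpc_codes + self.icd9_codes + self.icd10_codes
        if not codes:
            raise ConfigError(f"disease {self.disease!r}: no codes")
        if any(not c for c in codes):
            raise ConfigError(f"disease {self.disease!r}: empty code string")


def expand_code_range(start: str, end: str) -> tuple[str, ...]:
    """Expand an inclusive code range like I20–I25 or 430–434 to prefixes."""
    m1 = re.fullmatch(r"([A-Z]*)(\d+)", start)
    m2 = re.fullmatch(r"([A-Z]*)(\d+)", end)
    if not m1 or not m2 or m1.group(1) != m2.group(1):
        raise InputError(f"cannot expand code range {start!r}-{end!r}")
    prefix = m1.group(1)
    a, b = int(m1.group(2)), int(m2.group(2))
    if b < a:
        raise InputError(f"descending code range {start!r}-{end!r}")
    width = len(m1.group(2))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(a, b + 1))


def default_code_lists() -> tuple[CodeList, ...]:
    """Standard GP (ICPC-1) and hospital (ICD-9/ICD-10) case definitions for
    the four diseases: coronary heart disease, stroke, diabetes, COPD."""
    return (
        CodeList(
            "chd",
            icpc_codes=expand_code_range("K74", "K76"),
            icd9_codes=expand_code_range("410", "414"),
            icd10_codes=expand_code_range("I20", "I25"),
        ),
        CodeList(
            "stroke",
            icpc_codes=("K90",),
            icd9_codes=expand_code_range("430", "434") + expand_code_range("436", "438"),
            icd10_codes=expand_code_range("I60", "I69"),
        ),
        CodeList(
            "diabetes",
            icpc_codes=("T90",),
            icd9_codes=("250", "648"),
            icd10_codes=expand_code_range("E10", "E14"),
        ),
        CodeList(
            "copd",
            icpc_codes=("R91", "R95"),
            icd9_codes=expand_code_range("490", "492") + ("496",),
            icd10_codes=expand_code_range("J40", "J44"),
        ),
    )


_SOURCE_SYSTEM = {
    "gp_icpc": "ICPC1",
    "hospital_icd9": "ICD9",
    "hospital_icd10": "ICD10",
}


def flag_disease_from_codes(
    records: Mapping[object, Iterable[tuple[str, str]]],
    code_lists: Sequence[CodeList],
) -> pd.DataFrame:
    """Union-rule disease flags from per-person diagnosis records.

    ``records`` maps person id to an iterable of ``(source, code)`` pairs
    with source one of ``gp_icpc``, ``hospital_icd9``, ``hospital_icd10``.
    A person is flagged for a disease iff any record's code starts with one
    of that disease's prefixes in the record's coding system; persons with
    no matching record are disease-free.  Order-independent and idempotent.
    """
    for cl in code_lists:
        cl.validate()
    by_system = {
        cl.disease: {
            "ICPC1": tuple(cl.icpc_codes),
            "ICD9": tuple(cl.icd9_codes),
            "ICD10": tuple(cl.icd10_codes),
        }
        for cl in code_lists
    }
    out = {}
    for pid, recs in records.items():
        flags = dict.fromkeys(by_system, 0)
        for source, code in recs:
            if source not in _SOURCE_SYSTEM:
                raise InputError(
                    f"unknown record source {source!r}; expected one of "
                    f"{sorted(_SOURCE_SYSTEM)}"
                )
            system = _SOURCE_SYSTEM[source]
            code = str(code)
            for disease, prefixes in by_system.items():
                if any(code.startswith(p) for p in prefixes[system]):
                    flags[disease] = 1
        out[pid] = flags
    return pd.DataFrame.from_dict(out, orient="index", dtype=np.int8).reindex(
        columns=list(by_system)
    )


def write_code_lists(code_lists: Sequence[CodeList], path) -> None:
    rows = []
    for cl in code_lists:
        for system, codes in (
            ("ICPC1", cl.icpc_codes),
            ("ICD9", cl.icd9_codes),
            ("ICD10", cl.icd10_codes),
        ):
            rows.extend(
                {"disease": cl.disease, "code_system": system, "code": c} for c in codes
            )
    pd.DataFrame(rows, columns=["disease", "code_system", "code"]).to_csv(
        path, index=False
    )


def load_code_lists(path) -> tuple[CodeList, ...]:
    df = pd.read_csv(path, dtype=str)
    expected = {"disease", "code_system", "code"}
    if set(df.columns) != expected:
        raise InputError(f"code-list CSV must have columns {sorted(expected)}")
    out = []
    for disease in df["disease"].drop_duplicates():
        sub = df[df["disease"] == disease]

        def codes(system: str) -> tuple[str, ...]:
            return tuple(sub.loc[sub["code_system"] == system, "code"])

        cl = CodeList(disease, codes("ICPC1"), codes("ICD9"), codes("ICD10"))
        cl.validate()
        out.append(cl)
    return tuple(out)


# ---------------------------------------------------------------------------
# population CSV round-trip


def write_population(pop: pd.DataFrame, path) -> None:
    pop.to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    pop = pd.read_csv(
        path, dtype={"municipality_id": str, "practice_id": str}
    )
    for col in pop.columns:
        if col.startswith((ATC_PREFIX, DX_PREFIX)) or col in ("female", "in_training"):
            pop[col] = pop[col].astype(np.int8)
    return pop
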