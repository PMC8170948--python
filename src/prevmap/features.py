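"""Design-matrix construction for the four prediction-model variants.

Variants:

``age_gender``
    rescaled age, age squared, and a female indicator (3 columns).
``medication_only``
    the retained ATC3 dispensing indicators, unmodified.
``sociodemographic_only``
    every level of each categorical covariate as its own indicator (no
    reference level dropped), degree 1-3 polynomials of the income and
    wealth percentile scores, the female indicator, the two age terms, and
    the interaction of every base column with age and age squared.
``complete``
    the socio-demographic block plus the ATC block, all interacted with the
    age terms.

Ages and percentile scores are divided by 100 before any powers or products
are taken, so all columns live on a comparable scale for penalized fitting;
coefficients are reported on this rescaled basis.  Interactions are taken
with the age terms only — never between socio-demographic variables or
between ATC codes.

Column names carry a provenance prefix (``base:``, ``poly2:``, ``poly3:``,
``age:``, ``xage:``, ``xage2:``) so an exported matrix is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError
from .synthetic import ATC_PREFIX, retained_atc_codes

__all__ = [
    "VARIANTS",
    "ColumnSpec",
    "FeatureSchema",
    "FeatureMatrix",
    "expand_categorical",
    "percentile_polynomials",
    "age_terms",
    "add_age_interactions",
    "build_design_matrix",
    "schema_from_population",
]

VARIANTS = ("complete", "medication_only", "sociodemographic_only", "age_gender")

SCALE = 100.0  # divisor applied to ages and percentile scores


@dataclass(frozen=True)
class ColumnSpec:
    """One socio-demographic source column and how to expand it."""

    name: str
    kind: str  # categorical | percentile | binary
    levels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("categorical", "percentile", "binary"):
            raise SchemaError(f"unknown column kind {self.kind!r}")
        if self.kind == "categorical" and not self.levels:
            raise SchemaError(f"categorical column {self.name!r} needs levels")


@dataclass(frozen=True)
class FeatureSchema:
    """Declarative recipe for one model variant's design matrix."""

    variant: str
    sociodemo_columns: tuple[ColumnSpec, ...] = ()
    atc_columns: tuple[str, ...] = ()
    include_age_interactions: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise SchemaError(f"unknown variant {self.variant!r}")
        names = [c.name for c in self.sociodemo_columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate socio-demographic column names")
        if len(set(self.atc_columns)) != len(self.atc_columns):
            raise SchemaError("duplicate ATC column names")

    def n_base_columns(self) -> int:
        """Base (pre-interaction, non-age) column count implied by the schema."""
        n = 0
        if self.variant in ("complete", "sociodemographic_only"):
            for col in self.sociodemo_columns:
                if col.kind == "categorical":
                    n += len(col.levels)
                elif col.kind == "percentile":
                    n += 3
                else:
                    n += 1
        if self.variant in ("complete", "medication_only"):
            n += len(self.atc_columns)
        return n

    def n_columns(self) -> int:
        """Closed-form total column count."""
        if self.variant == "age_gender":
            return 3
        n = self.n_base_columns()
        if self.variant == "medication_only":
            return n
        if self.include_age_interactions:
            return 3 * n + 2
        return n + 2


@dataclass
class FeatureMatrix:
    """A named numeric design matrix aligned to population rows."""

    data: pd.DataFrame
    schema: FeatureSchema

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=True, index_label="row_id")


def expand_categorical(column: pd.Series, levels: Sequence[str]) -> pd.DataFrame:
    """One 0/1 indicator per declared level; every level kept, row sums 1."""
    values = column.to_numpy()
    known = set(levels)
    observed = pd.unique(values)
    bad = [v for v in observed if v not in known]
    if bad:
        raise InputError(
            f"column {column.name!r}: undeclared level(s) {sorted(map(str, bad))}"
        )
    out = {
        f"base:{column.name}={lvl}": (values == lvl).astype(np.float64)
        for lvl in levels
    }
    return pd.DataFrame(out, index=column.index)


def percentile_polynomials(column: pd.Series) -> pd.DataFrame:
    """Degree 1-3 polynomial columns of a percentile score rescaled to (0,1]."""
    v = column.to_numpy(float)
    if np.any((v < 1) | (v > 100)) or not np.all(np.isfinite(v)):
        raise InputError(f"column {column.name!r}: percentile scores must be in [1,100]")
    p = v / SCALE
    return pd.DataFrame(
        {
            f"base:{column.name}": p,
            f"poly2:{column.name}": p**2,
            f"poly3:{column.name}": p**3,
        },
        index=column.index,
    )


def age_terms(age: pd.Series) -> pd.DataFrame:
    """Rescaled age and its square: (age/100, (age/100)^2)."""
    v = age.to_numpy(float)
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise InputError("ages must be non-negative and finite")
    a = v / SCALE
    return pd.DataFrame({"age:age_s": a, "age:age_s2": a**2}, index=age.index)


def add_age_interactions(base: pd.DataFrame, age: pd.DataFrame) -> pd.DataFrame:
    """Interact every base column with age_s and age_s2.

    Output holds the bases, both interaction blocks and the two age terms:
    3 * n_base + 2 columns.
    """
    if not base.index.equals(age.index):
        raise InputError("base and age blocks are not row-aligned")
    a1 = age["age:age_s"].to_numpy()
    a2 = age["age:age_s2"].to_numpy()
    blocks = {name: base[name].to_numpy() for name in base.columns}
    out = dict(blocks)
    for name, col in blocks.items():
        out[f"xage:{name}"] = col * a1
    for name, col in blocks.items():
        out[f"xage2:{name}"] = col * a2
    out["age:age_s"] = a1
    out["age:age_s2"] = a2
    return pd.DataFrame(out, index=base.index)


def _sociodemo_block(pop: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    parts = []
    for col in schema.sociodemo_columns:
        if col.name not in pop.columns:
            raise SchemaError(f"population lacks required column {col.name!r}")
        if col.kind == "categorical":
            parts.append(expand_categorical(pop[col.name], col.levels))
        elif col.kind == "percentile":
            parts.append(percentile_polynomials(pop[col.name]))
        else:
            v = pop[col.name].to_numpy(float)
            if not np.isin(v, (0.0, 1.0)).all():
                raise InputError(f"binary column {col.name!r} is not strictly 0/1")
            parts.append(pd.DataFrame({f"base:{col.name}": v}, index=pop.index))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=pop.index)


def _atc_block(pop: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    out = {}
    for code in schema.atc_columns:
        col = ATC_PREFIX + code
        if col not in pop.columns:
            raise SchemaError(f"population lacks ATC column {col!r}")
        v = pop[col].to_numpy(float)
        if not np.isin(v, (0.0, 1.0)).all():
            raise InputError(f"ATC column {col!r} is not strictly 0/1")
        out[f"base:{col}"] = v
    return pd.DataFrame(out, index=pop.index)


def build_design_matrix(pop: pd.DataFrame, schema: FeatureSchema) -> FeatureMatrix:
    """Assemble the design matrix for one variant; see the module docstring."""
    for required in ("age", "female"):
        if required not in pop.columns:
            raise SchemaError(f"population lacks required column {required!r}")
    ages = age_terms(pop["age"])
    if schema.variant == "age_gender":
        data = pd.DataFrame(
            {
                "age:age_s": ages["age:age_s"],
                "age:age_s2": ages["age:age_s2"],
                "base:female": pop["female"].to_numpy(float),
            },
            index=pop.index,
        )
    elif schema.variant == "medication_only":
        data = _atc_block(pop, schema)
    else:
        base = _sociodemo_block(pop, schema)
        if schema.variant == "complete":
            base = pd.concat([base, _atc_block(pop, schema)], axis=1)
        if schema.include_age_interactions:
            data = add_age_interactions(base, ages)
        else:
            data = pd.concat([base, ages], axis=1)
    if data.isna().to_numpy().any():
        raise InputError("design matrix contains missing values")
    assert data.shape[1] == schema.n_columns()
    return FeatureMatrix(data=data, schema=schema)


def schema_from_population(
    pop: pd.DataFrame,
    variant: str,
    covariate_levels: dict[str, Sequence[str]] | None = None,
    min_atc_users: int = 50,
) -> FeatureSchema:
    """Derive a schema from a population table.

    Categorical levels are taken from ``covariate_levels`` when given
    (recommended: the generator config is explicit about levels), else from
    the sorted observed values.  ATC codes dispensed to at most
    ``min_atc_users`` persons in ``pop`` are excluded from the predictor set.
    """
    known_categoricals = (
        "marital_status",
        "ethnic_group",
        "immigrant_generation",
        "household_type",
        "income_source",
    )
    cols: list[ColumnSpec] = [ColumnSpec("female", "binary")]
    for name in known_categoricals:
        if name in pop.columns:
            if covariate_levels and name in covariate_levels:
                levels = tuple(covariate_levels[name])
            else:
                levels = tuple(sorted(map(str, pd.unique(pop[name]))))
            cols.append(ColumnSpec(name, "categorical", levels))
    for name in ("income_percentile", "wealth_percentile"):
        if name in pop.columns:
            cols.append(ColumnSpec(name, "percentile"))
    atc = tuple(retained_atc_codes(pop, min_users=min_atc_users))
    return FeatureSchema(
        variant=variant, sociodemo_columns=tuple(cols), atc_columns=atc
    )
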