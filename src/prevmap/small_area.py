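"""Municipal aggregation, direct age standardization, septile grouping.

Municipal prevalence is the average of predicted individual disease
probabilities, P_m = (1/n_m) * sum of p_i over the municipality's members.
Age standardization is direct: each person receives the weight
(reference share of their age band) / (municipality share of that band),
and the standardized prevalence is the weighted average of the
probabilities.  The age bands are the single under-20 band, five-year bands
from 20 to 85, and a single 85-plus band (15 bands, half-open [lo, hi)
on integer ages).

When an age band is occupied in the reference but empty in a municipality,
the reference shares over the municipality's occupied bands are
renormalized — equivalent to dropping the band from the standard for that
municipality; a warning is logged whenever this happens.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "AGE_BAND_EDGES",
    "AGE_BAND_LABELS",
    "age_band",
    "aggregate_prevalence",
    "standardization_weights",
    "standardized_prevalence",
    "group_septiles",
    "municipality_estimates",
]

logger = logging.getLogger(__name__)

#: lower edges: under-20, fourteen five-year bands 20..85, then 85+
AGE_BAND_EDGES = np.array([0, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85])
AGE_BAND_LABELS = (
    ["<20"]
    + [f"[{lo},{lo + 5})" for lo in range(20, 85, 5)]
    + ["85+"]
)
N_BANDS = len(AGE_BAND_EDGES)


def age_band(age) -> np.ndarray:
    """Band index (0..14) for each age; bands are half-open [lo, hi)."""
    a = np.asarray(age, float)
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise InputError("ages must be non-negative and finite")
    idx = np.searchsorted(AGE_BAND_EDGES, a, side="right") - 1
    return idx if idx.ndim else int(idx)


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InputError("probabilities must lie in [0, 1]")
    return p


def aggregate_prevalence(probabilities, municipality_ids) -> pd.DataFrame:
    """Crude municipal prevalence: columns municipality_id, n_m, P_m.

    Conserves mass: sum over municipalities of n_m * P_m equals the sum of
    the individual probabilities.
    """
    p = _check_probs(probabilities)
    muni = np.asarray(municipality_ids)
    if muni.shape[0] != p.shape[0]:
        raise InputError("probabilities and municipality ids are not aligned")
    df = pd.DataFrame({"municipality_id": muni, "p": p})
    g = df.groupby("municipality_id", sort=True)["p"]
    out = g.agg(n_m="size", P_m="mean").reset_index()
    out["n_m"] = out["n_m"].astype(np.int64)
    return out


def _band_shares(bands: np.ndarray) -> np.ndarray:
    counts = np.bincount(bands, minlength=N_BANDS).astype(float)
    return counts / counts.sum()


def standardization_weights(ages, municipality_ids, reference_ages) -> np.ndarray:
    """Direct-standardization weight per individual.

    w_i = ref_share(band(age_i)) / local_share(band(age_i)), renormalized
    within each municipality over its occupied bands so the weights average
    to one.  Raises if a band occupied in some municipality carries no
    reference mass.
    """
    bands = age_band(ages)
    muni = np.asarray(municipality_ids)
    if muni.shape[0] != bands.shape[0]:
        raise InputError("ages and municipality ids are not aligned")
    ref = _band_shares(age_band(reference_ages))
    w = np.empty(bands.shape[0])
    for m in pd.unique(muni):
        mask = muni == m
        local = _band_shares(bands[mask])
        occupied = local > 0
        if np.any(occupied & (ref == 0)):
            bad = [AGE_BAND_LABELS[i] for i in np.nonzero(occupied & (ref == 0))[0]]
            raise InputError(
                f"municipality {m!r}: band(s) {bad} occupied locally but absent "
                "from the reference population"
            )
        mass = ref[occupied].sum()
        if mass < 1.0 - 1e-12:
            logger.warning(
                "municipality %r: empty age band(s); reference shares "
                "renormalized over occupied bands (mass %.4f)", m, mass,
            )
        ratio = np.zeros(N_BANDS)
        ratio[occupied] = ref[occupied] / local[occupied] / mass
        w[mask] = ratio[bands[mask]]
    return w


def standardized_prevalence(probabilities, weights, municipality_ids) -> pd.DataFrame:
    """Weighted municipal prevalence: sum(w*p)/sum(w) within municipality."""
    p = _check_probs(probabilities)
    w = np.asarray(weights, float)
    muni = np.asarray(municipality_ids)
    if not (w.shape == p.shape == muni.shape):
        raise InputError("probabilities, weights and municipality ids misaligned")
    if np.any(w <= 0):
        raise InputError("weights must be strictly positive")
    df = pd.DataFrame({"municipality_id": muni, "wp": w * p, "w": w})
    g = df.groupby("municipality_id", sort=True).sum()
    out = (g["wp"] / g["w"]).rename("P_m_std").reset_index()
    return out


def group_septiles(values, municipality_ids=None) -> np.ndarray:
    """Rank municipalities into 7 groups (1..7) of near-equal size.

    Ties are broken by municipality id, so the labelling is deterministic.
    """
    v = np.asarray(values, float)
    if v.size < 7:
        raise InputError("need at least 7 municipalities for septiles")
    if municipality_ids is None:
        ids = np.arange(v.size)
    else:
        ids = np.asarray(municipality_ids)
        if ids.shape != v.shape:
            raise InputError("values and municipality ids misaligned")
    order = np.lexsort((ids, v))  # by value, then id
    ranks = np.empty(v.size, dtype=np.int64)
    ranks[order] = np.arange(v.size)
    return (ranks * 7 // v.size + 1).astype(np.int64)


def municipality_estimates(
    pop: pd.DataFrame,
    probabilities,
    disease: str,
    reference_ages=None,
) -> pd.DataFrame:
    """Map-ready municipal table for one disease's predicted probabilities.

    Columns: municipality_id, n, P (crude model prevalence), P_std
    (age-standardized, national reference by default), O (observed training
    prevalence, NaN where no training rows), n_training, septile,
    septile_std.
    """
    p = _check_probs(probabilities)
    muni = pop["municipality_id"].to_numpy()
    crude = aggregate_prevalence(p, muni).rename(columns={"n_m": "n", "P_m": "P"})
    ref = pop["age"].to_numpy() if reference_ages is None else reference_ages
    w = standardization_weights(pop["age"].to_numpy(), muni, ref)
    std = standardized_prevalence(p, w, muni).rename(columns={"P_m_std": "P_std"})
    out = crude.merge(std, on="municipality_id")

    dx_col = f"dx_{disease}"
    if "in_training" in pop.columns and dx_col in pop.columns:
        train = pop[pop["in_training"] == 1]
        obs = (
            train.groupby("municipality_id", sort=True)[dx_col]
            .agg(O="mean", n_training="size")
            .reset_index()
        )
        out = out.merge(obs, on="municipality_id", how="left")
        out["n_training"] = out["n_training"].fillna(0).astype(np.int64)
    else:
        out["O"] = np.nan
        out["n_training"] = 0
    out["septile"] = group_septiles(out["P"].to_numpy(), out["municipality_id"].to_numpy())
    out["septile_std"] = group_septiles(
        out["P_std"].to_numpy(), out["municipality_id"].to_numpy()
    )
    return out
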