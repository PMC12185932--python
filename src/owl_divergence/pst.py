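"""Phenotypic differentiation (Pst) from REML variance components.

Pst for a trait is the between-population share of variance,

    Pst = sigma2_pop / (sigma2_pop + sigma2_res),

computed from a mixed model on per-individual trait means (one value per
individual and feather side) with population (and optionally year) as random
effects.  The ratio deliberately uses only the population and residual
components even when a year component is in the model; the year share is
reported separately through the full variance-proportion table.  No c/h^2
scaling of the generalised Pst literature is applied.

Uncertainty of the ratio comes from the delta method on the REML estimates:
with a = sigma2_pop, b = sigma2_res and gradient g = (b, -a) / (a + b)^2,
SE = sqrt(g' C g) with C the 2x2 block of the average-information covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import TraitTable
from .reml import RESIDUAL, MixedModelSpec, VarianceComponents, reml_fit

POPULATION = "population_id"


@dataclass
class PstEstimate:
    """Pst for one trait and side, with delta-method SE and the full fit."""

    trait: str
    side: str
    pst: float
    pst_se: float
    prop_v: dict[str, float]
    prop_v_se: dict[str, float]
    source_fit: VarianceComponents

    def __post_init__(self) -> None:
        if not (0.0 <= self.pst <= 1.0):
            raise ValueError(f"pst out of [0, 1]: {self.pst}")
        total = sum(self.prop_v.values())
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"variance proportions sum to {total}, not 1")


def individual_trait_means(
    table: TraitTable, trait: str, side: str
) -> pd.DataFrame:
    """Average repeated measurements into one row per individual.

    Keeps the individual's population, morph, collection year and measurer,
    the mean trait value over that side's measurements, the mean total
    feather length, and its standardisation ``z(total_length)`` across
    retained individuals.  Individuals without a non-missing measurement of
    the trait on that side are dropped (reported via a warning).
    """
    df = table.data
    sub = df[df["side"] == side]
    if sub.empty:
        raise ValueError(f"no measurements for side {side!r}")
    grouped = sub.groupby("individual_id", sort=True)
    out = grouped.agg(
        population_id=("population_id", "first"),
        morph=("morph", "first"),
        year=("year", "first"),
        measurer_id=("measurer_id", "first"),
        total_length=("total_length", "mean"),
        **{trait: (trait, "mean")},
    ).reset_index()
    dropped = out[out[trait].isna()]["individual_id"].tolist()
    if dropped:
        warnings.warn(
            f"{len(dropped)} individual(s) without {trait} on {side} side "
            f"dropped: {dropped[:5]}",
            stacklevel=2,
        )
        out = out[out[trait].notna()].reset_index(drop=True)
    sd = out["total_length"].std(ddof=1)
    if pd.notna(sd) and sd > 0:
        out["z(total_length)"] = (out["total_length"] - out["total_length"].mean()) / sd
    else:
        out["z(total_length)"] = 0.0
    return out


def pst_from_components(sigma2_pop: float, sigma2_res: float) -> float:
    """Between-population share of (population + residual) variance."""
    if sigma2_pop < 0 or sigma2_res < 0:
        raise ValueError("variance components must be >= 0")
    total = sigma2_pop + sigma2_res
    if total == 0:
        raise ValueError("both components zero: Pst undefined")
    return sigma2_pop / total


def variance_proportions(
    fit: VarianceComponents | Mapping[str, float],
) -> dict[str, float]:
    """Each component's share of the total variance (all terms + residual)."""
    estimates = fit.estimates if isinstance(fit, VarianceComponents) else dict(fit)
    if RESIDUAL not in estimates:
        raise ValueError("residual component required")
    total = sum(estimates.values())
    if total == 0:
        raise ValueError("total variance zero: proportions undefined")
    return {k: v / total for k, v in estimates.items()}


def variance_proportion_se(
    fit: VarianceComponents,
) -> dict[str, float]:
    """Delta-method SEs for each variance proportion.

    For p_k = s_k / T with T the total, the gradient in the component vector
    is d p_k / d s_j = (delta_kj * T - s_k) / T^2.
    """
    terms = list(fit.estimates)
    s = np.array([fit.estimates[t] for t in terms])
    T = s.sum()
    C = fit.vc_cov_block(terms)
    out = {}
    for k, t in enumerate(terms):
        g = (np.eye(len(terms))[k] * T - s[k]) / T**2
        out[t] = float(np.sqrt(max(g @ C @ g, 0.0)))
    return out


def pst_se_delta(
    fit: VarianceComponents, population_term: str = POPULATION
) -> float:
    """Delta-method SE of Pst from the (population, residual) covariance."""
    if population_term not in fit.estimates:
        raise ValueError(f"no {population_term!r} component in fit")
    a = fit.estimates[population_term]
    b = fit.estimates[RESIDUAL]
    C = fit.vc_cov_block([population_term, RESIDUAL])
    if not np.all(np.isfinite(C)):
        raise ValueError("variance-component covariance unavailable")
    g = np.array([b, -a]) / (a + b) ** 2
    return float(np.sqrt(max(g @ C @ g, 0.0)))


def default_pst_spec(trait: str, include_year: bool = True) -> MixedModelSpec:
    """Study-style model for a per-individual means table.

    Plumulaceous length adjusts for the (standardised) mean total feather
    length; the count traits adjust for the measurer.  Population (and, by
    default, year) enter as random effects.
    """
    if trait == "plumulaceous_length":
        fixed = ("1", "morph", "z(total_length)")
    else:
        fixed = ("1", "morph", "C(measurer_id)")
    random = (POPULATION, "year") if include_year else (POPULATION,)
    return MixedModelSpec(response=trait, fixed_terms=fixed, random_terms=random)


def pst_pipeline(
    table: TraitTable,
    trait: str,
    side: str,
    spec: MixedModelSpec | None = None,
) -> PstEstimate:
    """Individual means -> REML fit -> Pst with delta-method SE."""
    if spec is None:
        spec = default_pst_spec(trait)
    means = individual_trait_means(table, trait, side)
    fit = reml_fit(means, spec)
    pst = pst_from_components(fit.estimates[POPULATION], fit.estimates[RESIDUAL])
    return PstEstimate(
        trait=trait,
        side=side,
        pst=pst,
        pst_se=pst_se_delta(fit),
        prop_v=variance_proportions(fit),
        prop_v_se=variance_proportion_se(fit),
        source_fit=fit,
    )
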