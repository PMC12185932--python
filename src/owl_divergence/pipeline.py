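"""Full divergence analysis: Pst per trait/side, latent morph Pst, Fst,
the Pst-versus-Fst exceedance comparison, and climate correlations.

The exceedance rule is strict: a trait's Pst point estimate must be strictly
greater than the upper bound of the Fst 95% CI to be flagged.  Climate
correlations are plain Pearson product-moment correlations between
per-population trait means (two-stage averaging: individual means averaged
within populations) and per-population winter climate values; no
multiple-testing correction is applied across the twelve correlations.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as core_io
from .fst import FstEstimate, fst_analysis
from .glmm import (
    glmm_binomial_fit,
    latent_proportion_se,
    latent_scale_proportion,
)
from .io import AnalysisConfig, ClimateTable, GenotypeTable, TraitTable
from .pst import PstEstimate, individual_trait_means, pst_pipeline
from .reml import MixedModelSpec


@dataclass
class ComparisonReport:
    """Everything the divergence analysis produces, in one serialisable bundle."""

    pst_estimates: list[PstEstimate] = field(default_factory=list)
    morph: dict | None = None
    fst: FstEstimate | None = None
    exceedance: dict[str, dict] = field(default_factory=dict)
    climate_correlations: dict[str, dict] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def pst_dict(e: PstEstimate) -> dict:
            d = dataclasses.asdict(e)
            fit = d.pop("source_fit")
            d["variance_components"] = fit["estimates"]
            d["reml_loglik"] = fit["reml_loglik"]
            d["fixed_effects"] = {
                k: {"estimate": v[0], "se": v[1]}
                for k, v in fit["fixed_estimates"].items()
            }
            d["n_obs"] = fit["n_obs"]
            return d

        return {
            "pst_estimates": [pst_dict(e) for e in self.pst_estimates],
            "morph": self.morph,
            "fst": dataclasses.asdict(self.fst) if self.fst else None,
            "exceedance": self.exceedance,
            "climate_correlations": self.climate_correlations,
            "status": self.status,
        }


def compare_pst_fst(
    pst: PstEstimate | float, fst: FstEstimate
) -> tuple[bool, float]:
    """Strict exceedance of the Fst CI upper bound; returns (flag, margin)."""
    value = pst.pst if isinstance(pst, PstEstimate) else float(pst)
    margin = value - fst.ci95[1]
    return margin > 0.0, margin


def population_trait_means(
    table: TraitTable, trait: str, side: str
) -> pd.Series:
    """Population means of individual means (two-stage averaging)."""
    means = individual_trait_means(table, trait, side)
    out = means.groupby("population_id")[trait].mean()
    empty = out.isna()
    if empty.any():
        warnings.warn(
            f"populations without data dropped: {list(out.index[empty])}",
            stacklevel=2,
        )
        out = out[~empty]
    return out


def correlation_p(r: float, n: int) -> float:
    """Two-sided p for a sample Pearson r via t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def climate_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, int]:
    """Pearson correlation between paired per-population values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, correlation_p(r, n), n


def run_full_analysis(
    traits: TraitTable,
    genotypes: GenotypeTable | None,
    climate: ClimateTable | None,
    cfg: AnalysisConfig | None = None,
) -> ComparisonReport:
    """Run every stage and assemble the report.

    Genotypes and climate are optional: without genotypes the Fst and
    exceedance blocks are marked unavailable; without climate the
    correlations are.  Stage failures are caught and recorded in
    ``report.status`` so a partial report is still produced.
    """
    cfg = cfg or AnalysisConfig()
    report = ComparisonReport()

    if genotypes is not None:
        geno_pops = set(genotypes.populations)
        trait_pops = set(traits.populations)
        extra = geno_pops - trait_pops
        if extra:
            warnings.warn(
                f"genotype populations absent from trait table: {sorted(extra)}",
                stacklevel=2,
            )

    for trait in cfg.traits:
        for side in cfg.sides:
            key = f"{trait}:{side}"
            try:
                spec = MixedModelSpec(
                    response=trait,
                    fixed_terms=tuple(cfg.fixed_terms[trait]),
                    random_terms=tuple(cfg.random_terms[trait]),
                )
                report.pst_estimates.append(
                    pst_pipeline(traits, trait, side, spec=spec)
                )
                report.status[f"pst:{key}"] = "ok"
            except Exception as exc:  # noqa: BLE001 - partial-report contract
                report.status[f"pst:{key}"] = f"failed: {exc}"

    try:
        per_ind = (
            traits.data.groupby("individual_id")
            .agg(
                morph=("morph", "first"),
                population_id=("population_id", "first"),
                year=("year", "first"),
            )
            .reset_index()
        )
        fit = glmm_binomial_fit(
            per_ind["morph"].to_numpy(),
            {
                "population_id": per_ind["population_id"],
                "year": per_ind["year"],
            },
        )
        prop = latent_scale_proportion(
            fit.sigma2["population_id"],
            {k: v for k, v in fit.sigma2.items() if k != "population_id"},
        )
        prop_se = latent_proportion_se(
            fit.sigma2["population_id"],
            {k: v for k, v in fit.sigma2.items() if k != "population_id"},
            fit.sigma2_se["population_id"],
        )
        report.morph = {
            "intercept": fit.intercept,
            "intercept_se": fit.intercept_se,
            "sigma2": fit.sigma2,
            "sigma2_se": fit.sigma2_se,
            "z_ratio": fit.z_ratio,
            "p_value": fit.p_value,
            "latent_proportion": prop,
            "latent_proportion_se": prop_se,
            "n_individuals": fit.n_individuals,
        }
        report.status["morph"] = "ok"
    except Exception as exc:  # noqa: BLE001
        report.status["morph"] = f"failed: {exc}"

    if genotypes is None:
        report.status["fst"] = "unavailable: no genotypes supplied"
        report.status["exceedance"] = "unavailable: no genotypes supplied"
    else:
        try:
            report.fst = fst_analysis(
                genotypes,
                max_missing=cfg.max_missing,
                n_perm=cfg.n_permutations,
                seed=cfg.seed,
            )
            report.status["fst"] = "ok"
        except Exception as exc:  # noqa: BLE001
            report.status["fst"] = f"failed: {exc}"
        if report.fst is not None:
            for est in report.pst_estimates:
                flag, margin = compare_pst_fst(est, report.fst)
                report.exceedance[f"{est.trait}:{est.side}"] = {
                    "exceeds": flag,
                    "margin": margin,
                }
            if report.morph is not None:
                flag, margin = compare_pst_fst(
                    report.morph["latent_proportion"], report.fst
                )
                report.exceedance["morph"] = {"exceeds": flag, "margin": margin}
            report.status["exceedance"] = "ok"

    if climate is None:
        report.status["climate"] = "unavailable: no climate table supplied"
    else:
        cdf = climate.data.set_index("population_id")
        for trait in cfg.traits:
            for side in cfg.sides:
                try:
                    pmeans = population_trait_means(traits, trait, side)
                    joined = pd.concat([pmeans, cdf], axis=1, join="inner")
                    for covariate in ("mean_winter_temp", "mean_winter_precip"):
                        r, p, n = climate_correlation(
                            joined[trait], joined[covariate]
                        )
                        report.climate_correlations[
                            f"{trait}:{side}:{covariate}"
                        ] = {"r": r, "p": p, "n": n}
                    report.status[f"climate:{trait}:{side}"] = "ok"
                except Exception as exc:  # noqa: BLE001
                    report.status[f"climate:{trait}:{side}"] = f"failed: {exc}"
        report.status.setdefault("climate", "ok")

    return report


def write_report(report: ComparisonReport, outdir: str) -> list:
    return core_io.write_results(report, outdir)
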