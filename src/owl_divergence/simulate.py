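"""Synthetic trait tables, morph labels and microsatellite genotypes.

The generators emulate the nine-population tawny owl study design: an
unbalanced hierarchy of populations, individuals and repeated feather
measurements on two body sides for the Gaussian traits; a binomial morph with
population-level variance on the logit (liability) scale; and diploid
genotypes under the Balding-Nichols island model, in which population allele
frequencies are Dirichlet-distributed around ancestral frequencies with
concentration (1 - theta) / theta so that the expected differentiation among
populations equals theta.

Every generator is a pure function of its config (including the seed): a
fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import study
from .io import MISSING, SIDES, RESPONSE_TRAITS, ClimateTable, GenotypeTable, TraitTable


def _per_pop_counts(n_populations: int, n_per_pop: int | Sequence[int]) -> np.ndarray:
    if np.isscalar(n_per_pop):
        counts = np.full(n_populations, int(n_per_pop))
    else:
        counts = np.asarray(list(n_per_pop), dtype=int)
        if len(counts) != n_populations:
            raise ValueError(
                f"n_per_pop has {len(counts)} entries for "
                f"{n_populations} populations"
            )
    if (counts < 1).any():
        raise ValueError("every population needs at least one individual")
    return counts


@dataclass
class TraitSimConfig:
    """Ground-truth parameters for the Gaussian trait hierarchy.

    The same generative law
    ``y = grand_mean + year + morph_effect*morph + length_slope*z(total)
    + u_pop + v_ind + eps``
    is applied independently (fresh random effects) to each response trait and
    each feather side.  Defaults mirror the study conditions: nine populations
    with the published per-population individual counts, two measurements per
    individual and side, and variance components on the scale of the ventral
    plumulaceous-length analysis.
    """

    n_populations: int = 9
    n_individuals_per_pop: int | Sequence[int] = field(
        default_factory=study.individuals_per_population
    )
    n_measurements: int = 2
    grand_mean: float = 6.0
    sigma2_pop: float = 0.09
    sigma2_ind: float = 0.10
    sigma2_year: float = 0.02
    sigma2_res: float = 0.12
    morph_effect: float = 0.1
    length_slope: float = 0.3
    years: Sequence[int] = (2018, 2019, 2020, 2021, 2022, 2023)
    #: morph prevalence on the logit scale (defaults match the study: ~60%
    #: brown overall with population-level logit variance 0.18)
    morph_intercept: float = 0.405
    morph_sigma2_logit: float = 0.18
    total_length_mean: float = 10.0
    total_length_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_pop", "sigma2_ind", "sigma2_year", "sigma2_res",
                     "morph_sigma2_logit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_measurements < 1 or self.n_populations < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class TraitGroundTruth:
    """Drawn effects underlying a simulated trait table."""

    population_effects: dict[str, np.ndarray]  # (trait, side) keyed as "trait:side"
    individual_effects: dict[str, np.ndarray]
    year_effects: dict[str, dict[int, float]]
    morph: np.ndarray
    morph_population_effects: np.ndarray
    population_of_individual: np.ndarray
    year_of_individual: np.ndarray
    config: TraitSimConfig


def simulate_morph_labels(
    n_per_pop: Sequence[int],
    intercept: float,
    sigma2_pop_logit: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli morph draws with population-specific prevalence.

    Each population i gets prevalence inverse-logit(intercept + u_i) with
    u_i ~ N(0, sigma2_pop_logit); individuals are independent Bernoulli.

    Returns (morph per individual, u per population).
    """
    if sigma2_pop_logit < 0:
        raise ValueError("sigma2_pop_logit must be >= 0")
    rng = np.random.default_rng(seed)
    n_per_pop = np.asarray(list(n_per_pop), dtype=int)
    u = rng.normal(0.0, np.sqrt(sigma2_pop_logit), size=len(n_per_pop))
    eta = intercept + u
    p = 1.0 / (1.0 + np.exp(-eta))
    morph = np.concatenate(
        [rng.binomial(1, p[i], size=n) for i, n in enumerate(n_per_pop)]
    )
    return morph, u


def simulate_trait_table(cfg: TraitSimConfig) -> tuple[TraitTable, TraitGroundTruth]:
    """Simulate a long-format trait table plus its ground-truth record."""
    rng = np.random.default_rng(cfg.seed)
    counts = _per_pop_counts(cfg.n_populations, cfg.n_individuals_per_pop)
    n_ind = int(counts.sum())
    pop_names = [f"pop{i + 1}" for i in range(cfg.n_populations)]
    pop_of_ind = np.repeat(np.arange(cfg.n_populations), counts)

    years = list(cfg.years)
    year_of_ind = rng.choice(years, size=n_ind)
    morph, morph_u = simulate_morph_labels(
        counts, cfg.morph_intercept, cfg.morph_sigma2_logit,
        seed=int(rng.integers(2**31 - 1)),
    )
    # one measurer covers the first five populations, a second the rest,
    # mirroring the two-observer counting protocol of the study
    measurer_of_pop = np.where(np.arange(cfg.n_populations) < 5, "obs1", "obs2")

    pop_eff: dict[str, np.ndarray] = {}
    ind_eff: dict[str, np.ndarray] = {}
    year_eff: dict[str, dict[int, float]] = {}

    rows: dict[str, list] = {c: [] for c in (
        "individual_id", "population_id", "year", "side", "morph",
        "measurer_id", "total_length", "plumulaceous_length",
        "barbs_per_cm", "barbules_per_mm", "measurement_id",
    )}

    responses: dict[str, dict[str, np.ndarray]] = {}
    totals: dict[str, np.ndarray] = {}
    n_meas = cfg.n_measurements
    for side in SIDES:
        totals[side] = rng.normal(
            cfg.total_length_mean, cfg.total_length_sd, size=(n_ind, n_meas)
        )
        responses[side] = {}
        for trait in RESPONSE_TRAITS:
            key = f"{trait}:{side}"
            u = rng.normal(0, np.sqrt(cfg.sigma2_pop), size=cfg.n_populations)
            v = rng.normal(0, np.sqrt(cfg.sigma2_ind), size=n_ind)
            w = {y: rng.normal(0, np.sqrt(cfg.sigma2_year)) for y in years}
            eps = rng.normal(0, np.sqrt(cfg.sigma2_res), size=(n_ind, n_meas))
            z_len = (totals[side] - cfg.total_length_mean) / cfg.total_length_sd
            slope = cfg.length_slope if trait == "plumulaceous_length" else 0.0
            y = (
                cfg.grand_mean
                + u[pop_of_ind][:, None]
                + v[:, None]
                + np.array([w[yy] for yy in year_of_ind])[:, None]
                + cfg.morph_effect * morph[:, None]
                + slope * z_len
                + eps
            )
            pop_eff[key] = u
            ind_eff[key] = v
            year_eff[key] = w
            responses[side][trait] = y

    for side in SIDES:
        # plumulaceous part cannot exceed the whole feather
        plum = np.minimum(responses[side]["plumulaceous_length"], totals[side])
        for i in range(n_ind):
            for m in range(n_meas):
                rows["individual_id"].append(f"ind{i + 1}")
                rows["population_id"].append(pop_names[pop_of_ind[i]])
                rows["year"].append(int(year_of_ind[i]))
                rows["side"].append(side)
                rows["morph"].append(int(morph[i]))
                rows["measurer_id"].append(str(measurer_of_pop[pop_of_ind[i]]))
                rows["total_length"].append(totals[side][i, m])
                rows["plumulaceous_length"].append(plum[i, m])
                rows["barbs_per_cm"].append(responses[side]["barbs_per_cm"][i, m])
                rows["barbules_per_mm"].append(
                    responses[side]["barbules_per_mm"][i, m]
                )
                rows["measurement_id"].append(f"ind{i + 1}_{side}_{m + 1}")

    table = TraitTable(data=pd.DataFrame(rows))
    truth = TraitGroundTruth(
        population_effects=pop_eff,
        individual_effects=ind_eff,
        year_effects=year_eff,
        morph=morph,
        morph_population_effects=morph_u,
        population_of_individual=pop_of_ind,
        year_of_individual=year_of_ind,
        config=cfg,
    )
    return table, truth


@dataclass
class GenoSimConfig:
    """Balding-Nichols island-model genotype simulation parameters.

    ``theta`` is the differentiation parameter: population allele frequencies
    are drawn Dirichlet(ancestral * (1 - theta) / theta), so the expected
    among-population fixation index equals theta.  ``theta = 0`` means all
    populations share the ancestral frequencies exactly.  Defaults mirror the
    study scale: nine populations, an eight-locus microsatellite panel, and
    theta at the reported global differentiation of 0.022.
    """

    n_populations: int = 9
    n_per_pop: int | Sequence[int] = 30
    n_loci: int = study.N_LOCI
    n_alleles: int = 8
    theta: float = 0.022
    ancestral_freqs: str | Sequence[Sequence[float]] = "uniform"
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise ValueError("theta must lie in [0, 1)")
        if self.n_alleles < 2:
            raise ValueError("need at least 2 alleles per locus")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    def ancestral(self) -> np.ndarray:
        """(n_loci, n_alleles) ancestral frequency matrix."""
        if isinstance(self.ancestral_freqs, str):
            if self.ancestral_freqs != "uniform":
                raise ValueError(f"unknown ancestral spec {self.ancestral_freqs!r}")
            return np.full((self.n_loci, self.n_alleles), 1.0 / self.n_alleles)
        anc = np.asarray(self.ancestral_freqs, dtype=float)
        if anc.shape != (self.n_loci, self.n_alleles):
            raise ValueError("ancestral_freqs must be (n_loci, n_alleles)")
        if not np.allclose(anc.sum(axis=1), 1.0):
            raise ValueError("ancestral frequencies must sum to 1 per locus")
        return anc


def simulate_genotypes(cfg: GenoSimConfig) -> tuple[GenotypeTable, np.ndarray]:
    """Simulate diploid genotypes; returns (table, true population freqs).

    True frequencies have shape (n_populations, n_loci, n_alleles).  Genotypes
    are random unions of gametes drawn from the population frequencies; the
    missing mask is Bernoulli(missing_rate) per individual x locus.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = _per_pop_counts(cfg.n_populations, cfg.n_per_pop)
    anc = cfg.ancestral()
    K, L, A = cfg.n_populations, cfg.n_loci, cfg.n_alleles

    if cfg.theta == 0.0:
        freqs = np.broadcast_to(anc, (K, L, A)).copy()
    else:
        conc = anc * (1.0 - cfg.theta) / cfg.theta
        freqs = np.empty((K, L, A))
        for k in range(K):
            for l in range(L):
                freqs[k, l] = rng.dirichlet(conc[l])

    n_ind = int(counts.sum())
    calls = np.empty((n_ind, L, 2), dtype=np.int64)
    pop_ids = []
    ind_ids = [f"ind{i + 1}" for i in range(n_ind)]
    row = 0
    for k in range(K):
        for _ in range(counts[k]):
            pop_ids.append(f"pop{k + 1}")
        for l in range(L):
            gametes = rng.choice(
                A, size=(counts[k], 2), p=freqs[k, l]
            )
            calls[row : row + counts[k], l, :] = gametes + 1
        row += counts[k]

    if cfg.missing_rate > 0:
        mask = rng.random((n_ind, L)) < cfg.missing_rate
        calls[mask] = MISSING

    table = GenotypeTable(
        individual_ids=ind_ids,
        population_ids=np.array(pop_ids, dtype=object),
        loci=[f"locus{l + 1}" for l in range(L)],
        calls=calls,
    )
    return table, freqs


def simulate_climate_table(
    populations: Sequence[str],
    seed: int = 0,
    temp_range: tuple[float, float] = (-6.0, 12.0),
    precip_range: tuple[float, float] = (30.0, 160.0),
) -> ClimateTable:
    """Plausible per-population mean winter climate values (independent draws).

    A convenience for end-to-end runs on synthetic data; values span typical
    European winter means and carry no built-in correlation with the traits.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "population_id": list(populations),
            "mean_winter_temp": np.round(
                rng.uniform(*temp_range, size=len(populations)), 2
            ),
            "mean_winter_precip": np.round(
                rng.uniform(*precip_range, size=len(populations)), 1
            ),
        }
    )
    return ClimateTable(data=df)
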