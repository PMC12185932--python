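"""Multi-locus global Fst from diploid microsatellite genotypes.

Per locus, Fst is a two-level analysis of molecular variance over gene copies
with the allele-identity distance (0 for the same allele code, 1 otherwise):
with n_i non-missing gene copies in population i, N = sum n_i, and k
populations carrying data,

    SSD_within = sum_i (n_i^2 - sum_a c_ia^2) / (2 n_i),
    SSD_total  = (N^2 - sum_a C_a^2) / (2 N),
    SSD_among  = SSD_total - SSD_within,
    s2_w = SSD_within / (N - k),
    n0   = (N - sum_i n_i^2 / N) / (k - 1),
    s2_a = (SSD_among / (k - 1) - s2_w) / n0,
    Fst  = s2_a / (s2_a + s2_w),

where c_ia counts allele a in population i and C_a globally.  A monomorphic
locus has zero total variance and its Fst is undefined (NaN).  No
within-individual (F_IS) level is modelled.  Negative per-locus estimates are
retained in the global average.

The global estimate is the unweighted mean over defined per-locus values; its
95% CI is mean +/- 1.96 SD / sqrt(L) across the L defined loci (an
across-loci dispersion interval).  Significance is a whole-individual
permutation test: individuals are shuffled among populations, keeping
population sizes, and the global mean recomputed; p = (1 + #{perm >= obs}) /
(n_perm + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeTable


@dataclass
class FstEstimate:
    """Per-locus and global Fst with across-loci CI and permutation p."""

    per_locus: dict[str, float]
    global_mean: float
    loci_sd: float
    ci95: tuple[float, float]
    perm_p: float | None
    n_perm: int
    n_loci_used: int

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.global_mean <= self.ci95[1]):
            raise ValueError("global mean outside its CI")


def filter_loci_missing(
    g: GenotypeTable, max_missing: float = 0.20
) -> GenotypeTable:
    """Retain loci with overall missing fraction strictly below the threshold.

    The fraction is computed over all individuals pooled.  A locus missing in
    exactly ``max_missing`` of individuals is removed (strict inequality).
    """
    if not (0.0 < max_missing <= 1.0):
        raise ValueError("max_missing must lie in (0, 1]")
    frac = g.missing_mask.mean(axis=0)
    keep = [l for l, f in zip(g.loci, frac) if f < max_missing]
    if not keep:
        raise ValueError("all loci removed by the missing-data filter")
    if len(keep) == len(g.loci):
        return g
    return g.subset_loci(keep)


def _counts_tensor(g: GenotypeTable) -> tuple[np.ndarray, list[str]]:
    """Allele counts (k_pops, n_loci, n_alleles) from gene copies."""
    pops = g.populations
    pop_idx = {p: i for i, p in enumerate(pops)}
    codes = np.array([pop_idx[p] for p in g.population_ids])
    a_max = int(g.calls.max())
    counts = np.zeros((len(pops), len(g.loci), a_max), dtype=np.int64)
    for copy in range(2):
        alleles = g.calls[:, :, copy]
        valid = alleles != MISSING
        ii, ll = np.nonzero(valid)
        np.add.at(counts, (codes[ii], ll, alleles[valid] - 1), 1)
    return counts, pops


def _fst_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorised per-locus AMOVA Fst from a (k, L, A) allele-count tensor."""
    counts = counts.astype(float)
    n_i = counts.sum(axis=2)  # (k, L) gene copies per pop
    N = n_i.sum(axis=0)  # (L,)
    k_eff = (n_i > 0).sum(axis=0)  # populations with data

    with np.errstate(divide="ignore", invalid="ignore"):
        ssw_i = np.where(
            n_i > 0, (n_i**2 - (counts**2).sum(axis=2)) / (2.0 * n_i), 0.0
        )
        ssw = ssw_i.sum(axis=0)
        C_a = counts.sum(axis=0)  # (L, A)
        sst = (N**2 - (C_a**2).sum(axis=1)) / (2.0 * N)
        ssa = sst - ssw

        df_within = N - k_eff
        df_among = k_eff - 1.0
        s2w = ssw / df_within
        n0 = (N - (n_i**2).sum(axis=0) / N) / df_among
        s2a = (ssa / df_among - s2w) / n0
        fst = s2a / (s2a + s2w)

    fst = np.where(
        (sst <= 0) | (k_eff < 2) | (df_within <= 0) | ((s2a + s2w) == 0),
        np.nan,
        fst,
    )
    return fst


def locus_fst(g: GenotypeTable, locus: str) -> float:
    """AMOVA Fst at one locus; NaN when the locus is monomorphic."""
    if locus not in g.loci:
        raise ValueError(f"no such locus: {locus!r}")
    counts, _ = _counts_tensor(g)
    l = g.loci.index(locus)
    return float(_fst_from_counts(counts[:, [l], :])[0])


def all_locus_fst(g: GenotypeTable) -> dict[str, float]:
    counts, _ = _counts_tensor(g)
    vals = _fst_from_counts(counts)
    return {l: float(v) for l, v in zip(g.loci, vals)}


def global_fst(per_locus: dict[str, float]) -> FstEstimate:
    """Across-loci mean, SD and 95% CI from per-locus Fst values.

    Undefined (NaN) loci are excluded and counted out of ``n_loci_used``.
    With a single defined locus the SD is reported as 0 and the CI collapses
    to the point estimate.
    """
    defined = [v for v in per_locus.values() if not math.isnan(v)]
    if not defined:
        raise ValueError("no defined per-locus Fst values")
    L = len(defined)
    mean = float(np.mean(defined))
    sd = float(np.std(defined, ddof=1)) if L > 1 else 0.0
    half = 1.96 * sd / math.sqrt(L)
    return FstEstimate(
        per_locus=dict(per_locus),
        global_mean=mean,
        loci_sd=sd,
        ci95=(mean - half, mean + half),
        perm_p=None,
        n_perm=0,
        n_loci_used=L,
    )


def _per_individual_counts(g: GenotypeTable) -> tuple[np.ndarray, int]:
    """(n_individuals, n_loci * n_alleles) allele counts per individual."""
    a_max = int(g.calls.max())
    n, L = g.n_individuals, len(g.loci)
    C = np.zeros((n, L, a_max), dtype=np.float64)
    for copy in range(2):
        alleles = g.calls[:, :, copy]
        valid = alleles != MISSING
        ii, ll = np.nonzero(valid)
        np.add.at(C, (ii, ll, alleles[valid] - 1), 1.0)
    return C.reshape(n, L * a_max), a_max


def permutation_test_fst(
    g: GenotypeTable, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Permutation p-value for the observed global mean Fst.

    Whole individuals are permuted among populations (sizes preserved); the
    +1 convention keeps the p-value strictly positive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    C, a_max = _per_individual_counts(g)
    pops = g.populations
    pop_idx = {p: i for i, p in enumerate(pops)}
    codes = np.array([pop_idx[p] for p in g.population_ids])
    order = np.argsort(codes, kind="stable")
    sizes = np.bincount(codes, minlength=len(pops))
    bounds = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    L = len(g.loci)

    def mean_fst(rows: np.ndarray) -> float:
        grouped = np.add.reduceat(C[rows], bounds, axis=0)
        counts = grouped.reshape(len(pops), L, a_max)
        vals = _fst_from_counts(counts)
        return float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan

    observed = mean_fst(order)
    if math.isnan(observed):
        raise ValueError("observed global Fst undefined (all loci monomorphic)")
    n = g.n_individuals
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if mean_fst(perm) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def fst_analysis(
    g: GenotypeTable,
    max_missing: float = 0.20,
    n_perm: int = 10_000,
    seed: int = 0,
) -> FstEstimate:
    """Filter loci, estimate per-locus and global Fst, and permute."""
    filtered = filter_loci_missing(g, max_missing)
    per_locus = all_locus_fst(filtered)
    est = global_fst(per_locus)
    est.perm_p = permutation_test_fst(filtered, n_perm=n_perm, seed=seed)
    est.n_perm = n_perm
    return est
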