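"""AMOVA Fst: oracles, invariances, filtering and the permutation test."""

import math

import numpy as np
import pytest

from owl_divergence import (
    GenoSimConfig,
    GenotypeTable,
    all_locus_fst,
    filter_loci_missing,
    global_fst,
    locus_fst,
    permutation_test_fst,
    simulate_genotypes,
)
from owl_divergence.io import MISSING
from helpers import brute_force_amova_fst


def make_table(calls, pops, loci=None):
    calls = np.asarray(calls, dtype=np.int64)
    if calls.ndim == 2:
        calls = calls[:, None, :]
    loci = loci or [f"L{i+1}" for i in range(calls.shape[1])]
    return GenotypeTable(
        individual_ids=[f"i{j}" for j in range(len(pops))],
        population_ids=np.array(pops, dtype=object),
        loci=loci,
        calls=calls,
    )


class TestLocusFst:
    def test_fixed_differences_give_one(self):
        g = make_table(
            [[1, 1], [1, 1], [2, 2], [2, 2]], ["a", "a", "b", "b"]
        )
        assert locus_fst(g, "L1") == pytest.approx(1.0)

    def test_monomorphic_locus_is_undefined(self):
        g = make_table(
            [[1, 1], [1, 1], [1, 1], [1, 1]], ["a", "a", "b", "b"]
        )
        assert math.isnan(locus_fst(g, "L1"))

    def test_unknown_locus_rejected(self):
        g = make_table([[1, 2], [2, 2]], ["a", "b"])
        with pytest.raises(ValueError, match="no such locus"):
            locus_fst(g, "nope")

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_matches_brute_force_pairwise_distance_amova(self, seed):
        g, _ = simulate_genotypes(
            GenoSimConfig(
                n_populations=3,
                n_per_pop=4,
                n_loci=2,
                n_alleles=3,
                theta=0.2,
                missing_rate=0.15,
                seed=seed,
            )
        )
        for locus in g.loci:
            got = locus_fst(g, locus)
            want = brute_force_amova_fst(g, locus)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_allele_relabelling(self, small_genotypes):
        g, _ = small_genotypes
        relabel = np.arange(0, 20)[::-1]  # allele code c -> 19 - c
        calls = g.calls.copy()
        ok = calls != MISSING
        calls[ok] = relabel[calls[ok]] + 1
        g2 = GenotypeTable(
            individual_ids=list(g.individual_ids),
            population_ids=g.population_ids.copy(),
            loci=list(g.loci),
            calls=calls,
        )
        for locus in g.loci:
            a, b = locus_fst(g, locus), locus_fst(g2, locus)
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(
                b, abs=1e-12
            )

    def test_invariant_to_individual_order(self, small_genotypes):
        g, _ = small_genotypes
        rng = np.random.default_rng(3)
        perm = rng.permutation(g.n_individuals)
        g2 = GenotypeTable(
            individual_ids=[g.individual_ids[i] for i in perm],
            population_ids=g.population_ids[perm],
            loci=list(g.loci),
            calls=g.calls[perm],
        )
        for locus in g.loci:
            a, b = locus_fst(g, locus), locus_fst(g2, locus)
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(
                b, abs=1e-12
            )

    def test_individual_with_missing_call_does_not_change_fst(self):
        g = make_table(
            [[1, 2], [1, 1], [2, 2], [2, 1]], ["a", "a", "b", "b"]
        )
        base = locus_fst(g, "L1")
        g2 = make_table(
            [[1, 2], [1, 1], [2, 2], [2, 1], [MISSING, MISSING]],
            ["a", "a", "b", "b", "a"],
        )
        assert locus_fst(g2, "L1") == pytest.approx(base, abs=1e-12)


class TestFiltering:
    def _with_missing(self, n_missing, n_ind=10):
        calls = np.ones((n_ind, 2, 2), dtype=np.int64)
        calls[:, 0, 1] = 2
        calls[:n_missing, 1, :] = MISSING
        return make_table(
            calls, ["a"] * (n_ind // 2) + ["b"] * (n_ind // 2),
            loci=["keep", "shaky"],
        )

    def test_locus_above_threshold_removed(self):
        g = self._with_missing(3)  # 30% missing
        kept = filter_loci_missing(g, 0.20)
        assert kept.loci == ["keep"]

    def test_exactly_at_threshold_removed_strictly(self):
        g = self._with_missing(2)  # exactly 20%
        kept = filter_loci_missing(g, 0.20)
        assert kept.loci == ["keep"]

    def test_just_below_threshold_retained(self):
        g = self._with_missing(1)  # 10%
        kept = filter_loci_missing(g, 0.20)
        assert kept.loci == ["keep", "shaky"]

    def test_no_missing_data_is_identity(self, small_genotypes):
        g, _ = small_genotypes
        assert filter_loci_missing(g, 1.0) is g

    def test_all_loci_removed_is_an_error(self):
        g = self._with_missing(10)
        calls = g.calls.copy()
        calls[:, 0, :] = MISSING
        g = make_table(calls, list(g.population_ids), loci=g.loci)
        with pytest.raises(ValueError, match="all loci removed"):
            filter_loci_missing(g, 0.20)


class TestGlobalFst:
    def test_single_locus_ci_collapses_to_point(self):
        est = global_fst({"L1": 0.05})
        assert est.loci_sd == 0.0
        assert est.ci95 == (0.05, 0.05)

    def test_equal_values_have_zero_sd(self):
        est = global_fst({f"L{i}": 0.03 for i in range(5)})
        assert est.global_mean == pytest.approx(0.03)
        assert est.loci_sd == pytest.approx(0.0, abs=1e-15)

    def test_study_scale_ci_reconstruction(self):
        """8 loci with mean 0.022 and SD 0.026 give a CI of ~(0.004, 0.040)."""
        d = 0.026 * math.sqrt(7.0 / 8.0)
        values = [0.022 - d] * 4 + [0.022 + d] * 4
        est = global_fst({f"L{i}": v for i, v in enumerate(values)})
        assert est.global_mean == pytest.approx(0.022, abs=1e-12)
        assert est.loci_sd == pytest.approx(0.026, abs=1e-12)
        assert est.ci95[0] == pytest.approx(0.004, abs=5e-4)
        assert est.ci95[1] == pytest.approx(0.040, abs=5e-4)

    def test_undefined_loci_excluded_and_counted(self):
        est = global_fst({"L1": 0.02, "L2": float("nan"), "L3": 0.04})
        assert est.n_loci_used == 2
        assert est.global_mean == pytest.approx(0.03)

    def test_no_defined_loci_is_an_error(self):
        with pytest.raises(ValueError, match="no defined"):
            global_fst({"L1": float("nan")})


class TestRecovery:
    def test_balding_nichols_theta_recovered(self):
        """Mean global Fst across replicates matches theta = 0.1."""
        vals = []
        for s in range(60):
            g, _ = simulate_genotypes(
                GenoSimConfig(theta=0.10, n_per_pop=30, seed=2000 + s)
            )
            vals.append(np.nanmean(list(all_locus_fst(g).values())))
        vals = np.array(vals)
        mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.10) < 3 * mc_se


class TestPermutation:
    def test_same_seed_gives_same_p(self, small_genotypes):
        g, _ = small_genotypes
        p1 = permutation_test_fst(g, n_perm=99, seed=7)
        p2 = permutation_test_fst(g, n_perm=99, seed=7)
        assert p1 == p2

    def test_p_is_never_zero(self):
        g, _ = simulate_genotypes(GenoSimConfig(theta=0.3, n_per_pop=20, seed=5))
        p = permutation_test_fst(g, n_perm=99, seed=1)
        assert p >= 1.0 / 100.0

    def test_strong_structure_is_significant(self):
        g, _ = simulate_genotypes(
            GenoSimConfig(theta=0.2, n_per_pop=30, seed=11)
        )
        p = permutation_test_fst(g, n_perm=999, seed=2)
        assert p <= 0.001

    def test_type_one_error_near_nominal_under_panmixia(self):
        """Permutation p-values are uniform when populations are exchangeable."""
        rejections = 0
        n_datasets = 150
        for s in range(n_datasets):
            g, _ = simulate_genotypes(
                GenoSimConfig(
                    n_populations=6,
                    n_per_pop=12,
                    n_loci=6,
                    n_alleles=4,
                    theta=0.0,
                    seed=4000 + s,
                )
            )
            p = permutation_test_fst(g, n_perm=99, seed=s)
            rejections += p <= 0.05
        rate = rejections / n_datasets
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_datasets)
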