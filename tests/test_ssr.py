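"""Microsatellite estimators against hand values and independent oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize

from divcomp import ssr
from divcomp.formats import SSRGenotypeTable
from divcomp.ssr import (
    _gis_statistic,
    expected_heterozygosity,
    fst_wc84_pairwise,
    gis_fis,
    null_allele_em,
    observed_heterozygosity,
    ssr_diversity,
)


def make_table(pop_genotypes: dict[str, list[list[tuple[int, int]]]],
               loci: list[str] | None = None,
               locus_class: dict | None = None) -> SSRGenotypeTable:
    """Build a table from {pop: [per-individual list of (a1, a2) per locus]}."""
    pops = list(pop_genotypes)
    rows, pop_index, individuals = [], [], []
    for p, pop in enumerate(pops):
        for i, geno in enumerate(pop_genotypes[pop]):
            rows.append([list(g) for g in geno])
            pop_index.append(p)
            individuals.append(f"{pop}_{i + 1}")
    n_loci = len(rows[0])
    return SSRGenotypeTable(
        populations=pops,
        pop_index=np.array(pop_index),
        individuals=individuals,
        loci=loci or [f"L{k + 1}" for k in range(n_loci)],
        genotypes=np.array(rows),
        locus_class=locus_class or {},
    )


class TestDiversity:
    def test_nei_small_sample_heterozygosity(self):
        """Two diploids (1,2),(1,2): p = (.5,.5), unbiased He = 4/3 * .5."""
        g = np.array([[1, 2], [1, 2]])
        assert expected_heterozygosity(g) == pytest.approx(2 / 3)
        assert expected_heterozygosity(g, "raw") == pytest.approx(0.5)
        assert observed_heterozygosity(g) == 1.0

    def test_monomorphic_locus(self):
        g = np.array([[1, 1]] * 5)
        assert expected_heterozygosity(g) == 0.0

    @given(st.integers(1, 10**6))
    def test_relabeling_invariance(self, offset):
        g = np.array([[1, 2], [2, 3], [1, 1], [3, 2]])
        base = expected_heterozygosity(g)
        relabeled = expected_heterozygosity(g + offset)
        assert relabeled == pytest.approx(base)
        assert len(np.unique(g)) == len(np.unique(g + offset))

    def test_missing_genotypes_complete_case(self):
        table = make_table({
            "A": [[(1, 2)], [(0, 0)], [(1, 1)]],
        })
        locus_df, _ = ssr_diversity(table)
        assert locus_df.loc[0, "n_typed"] == 2

    def test_empty_locus_population_excluded_with_warning(self):
        table = make_table({
            "A": [[(1, 2), (0, 0)]],
            "B": [[(1, 1), (3, 4)]],
        })
        with pytest.warns(UserWarning, match="no typed"):
            locus_df, _ = ssr_diversity(table)
        assert len(locus_df) == 3

    def test_marker_set_is_locus_weighted_combination(self, small_ssr_table):
        """Per-population means over 'all' equal the locus-count-weighted
        combination of the two class subsets."""
        table, _ = small_ssr_table
        _, all_df = ssr_diversity(table, "all")
        _, cross = ssr_diversity(table, "cross-species")
        _, spec = ssr_diversity(table, "species-specific")
        for df in (all_df, cross, spec):
            df.set_index("population", inplace=True)
        for col in ("a_r", "ssr_he"):
            combined = (
                cross[col] * cross["n_loci"] + spec[col] * spec["n_loci"]
            ) / (cross["n_loci"] + spec["n_loci"])
            pd.testing.assert_series_equal(
                all_df[col], combined, check_names=False, atol=1e-12
            )

    def test_rarefied_allele_count_matches_enumeration(self):
        # 3 alleles with counts (4, 3, 1) in 4 diploids; rarefy to 2 diploids
        g = np.array([[1, 1], [1, 2], [1, 2], [2, 3]])
        from math import comb

        N, k = 8, 4
        expected = sum(
            1 - comb(N - c, k) / comb(N, k) for c in (4, 3, 1)
        )
        assert ssr.rarefied_allele_count(g, 2) == pytest.approx(expected)


def enumerate_pairings(alleles: list[int]):
    """All labelled perfect matchings of an even-length allele list."""
    if not alleles:
        yield []
        return
    first, rest = alleles[0], alleles[1:]
    for i in range(len(rest)):
        pair = (first, rest[i])
        remaining = rest[:i] + rest[i + 1:]
        for tail in enumerate_pairings(remaining):
            yield [pair] + tail


class TestGis:
    def test_excess_heterozygosity_is_negative(self):
        table = make_table({"A": [[(1, 2)]] * 6})
        res = gis_fis(table, "A", n_permutations=99, seed=0)
        assert res.gis < 0

    def test_zero_when_ho_equals_hs(self):
        # p = 0.5, Ho = 0.5 equals the raw gene diversity exactly
        geno = [np.array([[1, 2], [1, 1], [2, 2], [1, 2]])]
        assert _gis_statistic(geno, bias_correction="raw") == pytest.approx(0.0)

    def test_all_monomorphic_flagged(self):
        table = make_table({"A": [[(1, 1)], [(1, 1)]]})
        res = gis_fis(table, "A", n_permutations=9, seed=0)
        assert res.flag == "all loci monomorphic"
        assert np.isnan(res.gis)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """Four diploids at one locus: the permutation null equals the
        exhaustive distribution over all 105 labelled allele pairings."""
        table = make_table({"A": [[(1, 1)], [(1, 2)], [(2, 2)], [(2, 3)]]})
        observed = _gis_statistic(
            [np.array([[1, 1], [1, 2], [2, 2], [2, 3]])]
        )
        alleles = [1, 1, 1, 2, 2, 2, 2, 3]
        stats = []
        for pairing in enumerate_pairings(alleles):
            stats.append(_gis_statistic([np.array(pairing)]))
        stats = np.array(stats)
        p_exact = (stats >= observed).mean()
        res = gis_fis(table, "A", n_permutations=999, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert res.p_value == pytest.approx(p_exact, abs=3 * se + 2e-3)


class TestNullAlleleEM:
    def test_null_free_hwe_data_gives_near_zero(self):
        # exact HWE counts for p = (0.5, 0.5), n = 100, no blanks; the MLE
        # sits at r = 0 and EM decays towards it (boundary convergence is
        # linear, so the attained r scales with the likelihood tolerance)
        res = null_allele_em(
            np.array([[1, 1]] * 25 + [[1, 2]] * 50 + [[2, 2]] * 25),
            tol=1e-10, max_iter=20_000,
        )
        assert res.converged
        assert res.null_freq < 1e-4

    def test_blanks_drive_estimate_up(self):
        g = np.array([[1, 1]] * 40 + [[1, 2]] * 30 + [[2, 2]] * 10 + [[0, 0]] * 5)
        res = null_allele_em(g)
        assert 0.05 < res.null_freq < 0.5

    def test_warns_below_ten_typed(self):
        g = np.array([[1, 2]] * 5)
        with pytest.warns(UserWarning, match="unreliable"):
            null_allele_em(g)

    def test_em_matches_grid_search_mle(self, rng):
        """EM r-hat equals a brute-force profile-likelihood grid search
        (independent likelihood code, scipy simplex optimisation) within
        0.002 on random small datasets."""

        def neg_loglik(theta, r, het, hom, blank, A):
            z = np.concatenate([[0.0], theta])
            p = (1 - r) * np.exp(z) / np.exp(z).sum()
            ll = 0.0
            for (i, j), c in het.items():
                ll += c * np.log(2 * p[i] * p[j])
            for i, c in hom.items():
                ll += c * np.log(p[i] ** 2 + 2 * p[i] * r)
            if blank:
                ll += blank * 2 * np.log(r) if r > 0 else -1e9
            return -ll

        for _ in range(10):
            A = int(rng.integers(2, 5))
            r_true = float(rng.uniform(0.0, 0.3))
            p = rng.dirichlet(np.ones(A)) * (1 - r_true)
            ext = np.concatenate([p, [r_true]])
            draws = rng.choice(A + 1, size=(60, 2), p=ext)
            g = draws + 1
            one_null = (draws == A).sum(axis=1) == 1
            vis = np.where(draws[one_null, 0] == A, g[one_null, 1], g[one_null, 0])
            g[one_null] = vis[:, None]
            g[(draws == A).all(axis=1)] = 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = null_allele_em(g)
            # profile likelihood over a coarse-to-fine r grid
            typed = g[(g > 0).all(axis=1)]
            blank = int(((g == 0).any(axis=1)).sum())
            alleles = {a: i for i, a in enumerate(np.unique(typed))}
            het, hom = {}, {}
            for a1, a2 in typed:
                i, j = sorted((alleles[a1], alleles[a2]))
                if i == j:
                    hom[i] = hom.get(i, 0) + 1
                else:
                    het[(i, j)] = het.get((i, j), 0) + 1

            def profile(r):
                best = np.inf
                x0 = np.zeros(len(alleles) - 1)
                res_ = minimize(neg_loglik, x0,
                                args=(r, het, hom, blank, len(alleles)),
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
                return res_.fun

            coarse = np.arange(0.0, 0.5, 0.01) + 1e-9
            vals = [profile(r) for r in coarse]
            r0 = coarse[int(np.argmin(vals))]
            fine = np.clip(np.arange(r0 - 0.01, r0 + 0.01, 0.001), 1e-9, 0.499)
            vals = [profile(r) for r in fine]
            r_grid = fine[int(np.argmin(vals))]
            assert res.null_freq == pytest.approx(r_grid, abs=2e-3)


def wc84_theta_reference(geno_pops):
    """Independent scalar-loop evaluation of the Weir-Cockerham (1984)
    variance components for one locus (written against the textbook
    definitions, kept separate from the package implementation)."""
    r = len(geno_pops)
    n = [len(g) for g in geno_pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    alleles = sorted({a for g in geno_pops for pair in g for a in pair})
    num = den = 0.0
    for allele in alleles:
        p = []
        h = []
        for g in geno_pops:
            copies = sum((pair[0] == allele) + (pair[1] == allele) for pair in g)
            hets = sum(
                ((pair[0] == allele) + (pair[1] == allele)) == 1 for pair in g
            )
            p.append(copies / (2 * len(g)))
            h.append(hets / len(g))
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestWc84:
    def test_identical_populations_near_zero(self):
        geno = [[(1, 2), (2, 3)], [(1, 1), (3, 3)], [(1, 3), (2, 2)]]
        table = make_table({"A": geno, "B": geno})
        matrix, _ = fst_wc84_pairwise(table)
        assert matrix.values[0, 1] <= 0 + 1e-12

    def test_complete_fixation_is_one(self):
        table = make_table({
            "A": [[(1, 1), (5, 5)]] * 4,
            "B": [[(2, 2), (7, 7)]] * 4,
        })
        matrix, _ = fst_wc84_pairwise(table)
        assert matrix.values[0, 1] == pytest.approx(1.0)

    def test_matches_independent_variance_components(self):
        """Fixed 2 pops x 6 diploids x 1 locus x 3 alleles table."""
        pop_a = [(1, 2), (1, 1), (2, 3), (3, 3), (1, 3), (2, 2)]
        pop_b = [(1, 1), (1, 2), (1, 1), (2, 2), (1, 2), (1, 1)]
        table = make_table({"A": [[g] for g in pop_a], "B": [[g] for g in pop_b]})
        matrix, per_locus = fst_wc84_pairwise(table)
        expected = wc84_theta_reference([pop_a, pop_b])
        assert matrix.values[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_symmetry_and_all_missing_locus_is_noop(self, small_ssr_table):
        table, _ = small_ssr_table
        matrix, _ = fst_wc84_pairwise(table)
        assert np.allclose(matrix.values, matrix.values.T, equal_nan=True)
        padded = SSRGenotypeTable(
            populations=table.populations,
            pop_index=table.pop_index,
            individuals=table.individuals,
            loci=table.loci + ["empty"],
            genotypes=np.concatenate(
                [table.genotypes,
                 np.zeros((len(table.individuals), 1, 2), dtype=int)],
                axis=1,
            ),
            locus_class={},
        )
        matrix2, _ = fst_wc84_pairwise(padded)
        np.testing.assert_allclose(matrix.values, matrix2.values, atol=1e-12)

    def test_needs_two_populations(self):
        table = make_table({"A": [[(1, 2)], [(2, 2)]]})
        with pytest.raises(ValueError, match="two populations"):
            fst_wc84_pairwise(table)


class TestScreenLoci:
    def test_flags_null_ridden_deviating_locus(self):
        rng = np.random.default_rng(1)
        # locus 1: clean HWE; locus 2: strong null allele (apparent
        # homozygote excess plus blanks)
        p = np.array([0.5, 0.5])
        clean = rng.choice([1, 2], size=(60, 2), p=p)
        r = 0.25
        ext = np.array([0.375, 0.375, r])
        draws = rng.choice(3, size=(60, 2), p=ext)
        noisy = draws + 1
        one = (draws == 2).sum(axis=1) == 1
        vis = np.where(draws[one, 0] == 2, noisy[one, 1], noisy[one, 0])
        noisy[one] = vis[:, None]
        noisy[(draws == 2).all(axis=1)] = 0
        table = make_table({
            "A": [[tuple(clean[i]), tuple(noisy[i])] for i in range(60)]
        })
        report = ssr.screen_loci(table, n_permutations=199, seed=0)
        assert not report.loc[report["locus"] == "L1", "flagged"].item()
        assert report.loc[report["locus"] == "L2", "flagged"].item()
        assert report.loc[report["locus"] == "L2", "null_freq"].item() > 0.10
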