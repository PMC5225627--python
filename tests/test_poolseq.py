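"""Pool-Seq estimators: SNP calling, detection weighting, theta, D, F_ST."""

import io
import math
from dataclasses import replace

import numpy as np
import pytest

from divcomp import poolseq
from divcomp.formats import ExonAnnotation, read_sync
from divcomp.poolseq import (
    FilterParams,
    SiteCountMatrix,
    SNPFrequencyTable,
    call_biallelic_snps,
    detection_weight,
    fst_pool_pairwise,
    maf_thresholds,
    snp_he,
    tajima_coverage_floor,
    tajimas_d_pool,
    watterson_theta_pool,
)
from divcomp.synthio import SimConfig, simulate_gene_pools


def sites_from(counts4, start_pos=1, chrom="c1"):
    """Build a SiteCountMatrix from an (S, P, 4) nucleotide count array."""
    counts4 = np.asarray(counts4)
    S, P = counts4.shape[:2]
    counts = np.zeros((S, P, 6), dtype=np.int64)
    counts[:, :, :4] = counts4
    return SiteCountMatrix(
        chrom=np.full(S, chrom),
        pos=np.arange(start_pos, start_pos + S),
        counts=counts,
    )


SMALL = FilterParams(min_coverage=20, max_coverage=400,
                     min_minor_count_within=2, min_minor_count_joint=4,
                     pool_size=40)


class TestSnpCalling:
    def test_joint_minor_count_threshold(self):
        # A:T = (30,0) and (28,2): joint minor 2 < 4 -> rejected
        sites = sites_from([[[30, 0, 0, 0], [28, 2, 0, 0]]])
        table, report = call_biallelic_snps(sites, SMALL)
        assert table.n_snps == 0
        assert report["not_biallelic"] == 1

    def test_direct_frequency_computation(self):
        # A:T = (25,5), (20,10): retained; minor freqs 5/30 and 10/30
        sites = sites_from([[[25, 5, 0, 0], [20, 10, 0, 0]]])
        table, report = call_biallelic_snps(sites, SMALL)
        assert table.n_snps == 1
        assert report["retained"] == 1
        assert table.major[0] == "A" and table.minor[0] == "T"
        np.testing.assert_allclose(table.freq[0], [5 / 30, 10 / 30])
        np.testing.assert_array_equal(table.coverage[0], [30, 30])

    def test_hand_built_fixture_filters_as_designed(self):
        """Twelve sites, one violation of each rule; the designed subset
        survives and the rejection report matches the design."""
        ok = [[25, 5, 0, 0], [20, 10, 0, 0]]
        sites = sites_from([
            ok,                                        # 1 retained
            [[10, 5, 0, 0], [20, 10, 0, 0]],           # 2 low coverage pop1
            [[300, 200, 0, 0], [20, 10, 0, 0]],        # 3 high coverage pop1
            [[30, 0, 0, 0], [28, 2, 0, 0]],            # 4 joint minor 2 < 4
            [[30, 0, 0, 0], [30, 0, 0, 0]],            # 5 monomorphic
            [[20, 6, 4, 0], [20, 10, 0, 0]],           # 6 tri-allelic (C joint 4)
            ok,                                        # 7 retained
            [[25, 5, 1, 0], [20, 10, 0, 0]],           # 8 stray C below joint min
            [[0, 25, 5, 0], [0, 20, 10, 0]],           # 9 retained (T/C)
            [[19, 0, 0, 0], [30, 0, 0, 0]],            # 10 low coverage
            [[25, 2, 0, 0], [25, 2, 0, 0]],            # 11 joint minor 4 retained
            [[500, 0, 0, 0], [30, 5, 0, 0]],           # 12 high coverage
        ])
        table, report = call_biallelic_snps(sites, SMALL)
        assert table.pos.tolist() == [1, 7, 8, 9, 11]
        assert report == {
            "total": 12, "coverage_low": 2, "coverage_high": 2,
            "not_biallelic": 2, "multiallelic": 1, "retained": 5,
        }

    def test_minor_allele_defined_jointly(self):
        # pop2 has the joint-minor allele at frequency > 0.5
        sites = sites_from([[[40, 5, 0, 0], [5, 25, 0, 0]]])
        table, _ = call_biallelic_snps(sites, SMALL)
        assert table.minor[0] == "T"
        np.testing.assert_allclose(table.freq[0], [5 / 45, 25 / 30])

    def test_population_permutation_consistency(self, small_snp_sim):
        params = FilterParams()
        table, _ = call_biallelic_snps(small_snp_sim, params)
        perm = [2, 0, 3, 1]
        shuffled = SiteCountMatrix(
            chrom=small_snp_sim.chrom, pos=small_snp_sim.pos,
            counts=small_snp_sim.counts[:, perm, :],
        )
        table2, _ = call_biallelic_snps(shuffled, params)
        np.testing.assert_array_equal(table.pos, table2.pos)
        np.testing.assert_allclose(table.freq[:, perm], table2.freq)


class TestSnpHe:
    def test_printed_equation_examples(self):
        table = SNPFrequencyTable(
            chrom=np.array(["c", "c"]), pos=np.array([1, 2]),
            major=np.array(["A", "A"]), minor=np.array(["T", "T"]),
            freq=np.array([[0.5, 0.1, 0.0], [0.5, 0.2, 0.0]]),
            coverage=np.full((2, 3), 30), populations=["a", "b", "c"],
        )
        means, _ = snp_he(table)
        assert means["a"] == pytest.approx(0.5)           # 2*.5*.5
        assert means["b"] == pytest.approx(0.25)          # (.18+.32)/2
        assert means["c"] == pytest.approx(0.0)           # fixed -> 0

    def test_empty_table_errors(self):
        table = SNPFrequencyTable(
            chrom=np.array([]), pos=np.array([]), major=np.array([]),
            minor=np.array([]), freq=np.zeros((0, 2)),
            coverage=np.zeros((0, 2)), populations=["a", "b"],
        )
        with pytest.raises(ValueError, match="empty"):
            snp_he(table)

    def test_bounded_by_half(self, small_snp_sim):
        table, _ = call_biallelic_snps(small_snp_sim, FilterParams())
        _, he = snp_he(table)
        assert np.nanmin(he) >= 0 and np.nanmax(he) <= 0.5


class TestDetectionWeight:
    def test_perfect_detection_recovers_watterson_denominator(self):
        """b = 1, C -> infinity: D equals a1 = sum 1/i (n = 4: 1.8333)."""
        assert detection_weight(4, 100_000, 1) == pytest.approx(
            1 + 1 / 2 + 1 / 3, abs=1e-3
        )

    def test_exact_enumeration_small_case(self):
        """n=4, C=2, b=1 by explicit binomial enumeration: 0.75."""
        expected = 0.0
        for i in (1, 2, 3):
            p = i / 4
            mass = sum(
                math.comb(2, k) * p**k * (1 - p) ** (2 - k) for k in (1,)
            )
            expected += mass / i
        assert expected == pytest.approx(0.75)
        assert detection_weight(4, 2, 1) == pytest.approx(expected, abs=1e-12)

    def test_undetectable_configuration_errors(self):
        with pytest.raises(ValueError, match="detectable"):
            detection_weight(40, 3, 2)

    def test_vector_coverage(self):
        out = detection_weight(40, np.array([60, 60, 20]), 2)
        assert out.shape == (3,)
        assert out[0] == out[1] != out[2]


def annotation_for(genes: dict[str, tuple[int, int]], chrom="c1"):
    return {
        g: ExonAnnotation(gene_id=g, chrom=chrom, exons=[span])
        for g, span in genes.items()
    }


class TestWatterson:
    def test_gene_without_segregating_sites_has_zero_theta(self):
        counts = np.tile([[60, 0, 0, 0]], (10, 1, 1))
        sites = sites_from(counts)
        ann = annotation_for({"g1": (1, 10)})
        result = watterson_theta_pool(sites, ann, FilterParams())
        assert result.genome_wide.iloc[0] == 0.0
        assert result.table["n_seg"].sum() == 0

    def test_theta_monotone_in_segregating_sites(self):
        base = np.tile([[60, 0, 0, 0]], (10, 1, 1)).copy()
        more = base.copy()
        base[0, 0] = [55, 5, 0, 0]
        more[0, 0] = [55, 5, 0, 0]
        more[1, 0] = [50, 10, 0, 0]
        ann = annotation_for({"g1": (1, 10)})
        t1 = watterson_theta_pool(sites_from(base), ann, FilterParams())
        t2 = watterson_theta_pool(sites_from(more), ann, FilterParams())
        assert t2.genome_wide.iloc[0] > t1.genome_wide.iloc[0] > 0

    def test_gene_retention_requires_valid_fraction_in_all_pops(self):
        counts = np.tile([[60, 0, 0, 0], [60, 0, 0, 0]], (10, 1, 1))
        counts[4:, 1] = [5, 0, 0, 0]  # pop2 under-covered at 60% of the gene
        sites = sites_from(counts)
        ann = annotation_for({"g1": (1, 10)})
        result = watterson_theta_pool(sites, ann, FilterParams())
        assert not result.table["retained"].any()

    def test_doubling_coverage_changes_theta_by_under_two_percent(self):
        """The detection weighting removes the coverage dependence.

        Error-free reads isolate the property: with sequencing error the
        false-positive rate itself scales with coverage and would
        confound the comparison.
        """
        config = SimConfig(
            n_populations=2, n_genes=800, seed=21, sequencing_error=0.0
        )
        a = simulate_gene_pools(config)
        b = simulate_gene_pools(config, coverage_scale=2.0)
        params = FilterParams()
        ta = watterson_theta_pool(a, a.annotation, params).genome_wide
        tb = watterson_theta_pool(b, b.annotation, params).genome_wide
        assert np.all(np.abs(tb / ta - 1) < 0.02)

    def test_streamed_and_stacked_inputs_agree(self, tmp_path, small_config):
        config = replace(small_config, n_genes=10)
        sim = simulate_gene_pools(config)
        path = tmp_path / "g.sync"
        from divcomp.formats import write_sync

        write_sync(sim.to_records(), path)
        params = FilterParams()
        from_stream = watterson_theta_pool(
            read_sync(path), sim.annotation, params
        )
        from_arrays = watterson_theta_pool(sim, sim.annotation, params)
        np.testing.assert_allclose(
            from_stream.genome_wide.to_numpy(),
            from_arrays.genome_wide.to_numpy(),
        )


class TestTajima:
    def test_crafted_gene_matches_independent_evaluation(self):
        """One gene, uniform coverage: D recomputed in the test from the
        textbook constants and the detection-weighted theta."""
        C, n = 60, 40
        counts = np.tile([[C, 0, 0, 0]], (50, 1, 1)).copy()
        minors = {3: 10, 17: 4, 30: 25}
        for pos0, m in minors.items():
            counts[pos0, 0] = [C - m, m, 0, 0]
        sites = sites_from(counts)
        ann = annotation_for({"g1": (1, 50)})
        params = FilterParams()
        result = tajimas_d_pool(sites, ann, params)
        d_pkg = result.table["tajimas_d"].iloc[0]

        pi_tot = sum(
            (C / (C - 1)) * (n / (n - 1)) * 2 * (m / C) * (1 - m / C)
            for m in minors.values()
        )
        S = len(minors)
        dsum = 50 * detection_weight(n, C, 2)
        theta_tot = S * 50 / dsum
        m_eff = min(n, C)
        i = np.arange(1, m_eff)
        a1, a2 = (1 / i).sum(), (1 / i**2).sum()
        b1 = (m_eff + 1) / (3 * (m_eff - 1))
        b2 = 2 * (m_eff**2 + m_eff + 3) / (9 * m_eff * (m_eff - 1))
        c1, c2 = b1 - 1 / a1, b2 - (m_eff + 2) / (a1 * m_eff) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        d_ref = (pi_tot - theta_tot) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert d_pkg == pytest.approx(d_ref, abs=1e-10)

    def test_rare_variant_excess_gives_negative_mean(self):
        neutral = SimConfig(n_populations=1, n_genes=400, seed=6)
        skewed = replace(neutral, gene_sfs_skew=1.6)
        params = FilterParams()
        sims = {k: simulate_gene_pools(c) for k, c in
                [("neutral", neutral), ("skewed", skewed)]}
        means = {
            k: tajimas_d_pool(s, s.annotation, params).genome_wide.iloc[0]
            for k, s in sims.items()
        }
        assert means["skewed"] < -0.3
        assert means["skewed"] < means["neutral"]

    def test_gene_with_too_few_valid_sites_excluded(self):
        counts = np.tile([[60, 0, 0, 0]], (1, 1, 1))
        sites = sites_from(counts)
        ann = annotation_for({"g1": (1, 1)})
        result = tajimas_d_pool(sites, ann, FilterParams())
        assert result.report["genes_excluded"] == 1


class TestPoolFst:
    def test_equal_frequencies_zero(self):
        t = SNPFrequencyTable(
            chrom=np.array(["c"] * 3), pos=np.arange(1, 4),
            major=np.array(["A"] * 3), minor=np.array(["T"] * 3),
            freq=np.array([[0.1, 0.1], [0.3, 0.3], [0.5, 0.5]]),
            coverage=np.full((3, 2), 50), populations=["a", "b"],
        )
        assert fst_pool_pairwise(t).values[0, 1] == pytest.approx(0.0)

    def test_fixation_is_one(self):
        t = SNPFrequencyTable(
            chrom=np.array(["c"]), pos=np.array([1]),
            major=np.array(["A"]), minor=np.array(["T"]),
            freq=np.array([[0.0, 1.0]]), coverage=np.full((1, 2), 50),
            populations=["a", "b"],
        )
        assert fst_pool_pairwise(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_evaluated_definition(self):
        # p = 0.2 vs 0.4: Hs = .40, Ht = .42, F_ST = .02/.42
        t = SNPFrequencyTable(
            chrom=np.array(["c"]), pos=np.array([1]),
            major=np.array(["A"]), minor=np.array(["T"]),
            freq=np.array([[0.2, 0.4]]), coverage=np.full((1, 2), 50),
            populations=["a", "b"],
        )
        assert fst_pool_pairwise(t).values[0, 1] == pytest.approx(
            0.02 / 0.42
        )

    def test_low_frequency_snps_reduce_mean_fst(self, small_snp_sim):
        """Admitting SNPs just above the joint-count threshold lowers the
        mean pooled F_ST at fixed simulated differentiation."""
        strict = FilterParams(min_minor_count_joint=20)
        lenient = FilterParams(min_minor_count_joint=4)
        t_strict, _ = call_biallelic_snps(small_snp_sim, strict)
        t_lenient, _ = call_biallelic_snps(small_snp_sim, lenient)
        assert t_lenient.n_snps > t_strict.n_snps
        assert (
            fst_pool_pairwise(t_lenient).mean()
            < fst_pool_pairwise(t_strict).mean()
        )

    def test_no_informative_snps_flagged(self):
        t = SNPFrequencyTable(
            chrom=np.array(["c"]), pos=np.array([1]),
            major=np.array(["A"]), minor=np.array(["T"]),
            freq=np.array([[0.0, 0.0]]), coverage=np.full((1, 2), 50),
            populations=["a", "b"],
        )
        matrix = fst_pool_pairwise(t)
        assert np.isnan(matrix.values[0, 1])
        assert matrix.flags == {("a", "b"): "no informative SNPs"}


class TestAnalyticThresholds:
    def test_implied_maf_thresholds(self):
        params = FilterParams()
        thresholds = maf_thresholds(params, n_populations=9)
        assert thresholds["joint"] == pytest.approx(4 / 360)
        assert round(thresholds["joint"], 3) == 0.011
        assert thresholds["within"] == pytest.approx(0.05)

    def test_tajima_coverage_floor(self):
        assert tajima_coverage_floor(40) == 13
        assert FilterParams().tajima_min_coverage == tajima_coverage_floor(40)


class TestGeneFractionBasis:
    def test_snps_basis_retains_gene_with_sparse_coverage_outside_snps(self):
        """With the SNP-position denominator, a gene whose non-SNP tail is
        under-covered is still retained as long as its SNP positions are
        validly covered everywhere."""
        counts = np.tile([[60, 0, 0, 0]], (10, 1, 1)).copy()
        counts[0, 0] = [50, 10, 0, 0]          # the gene's single SNP
        counts[4:, 0] = [5, 0, 0, 0]           # 60% of positions under-covered
        sites = sites_from(counts)
        ann = annotation_for({"g1": (1, 10)})
        by_positions = watterson_theta_pool(sites, ann, FilterParams())
        by_snps = watterson_theta_pool(
            sites, ann, FilterParams(), gene_fraction_basis="snps"
        )
        assert not by_positions.table["retained"].any()
        assert by_snps.table["retained"].all()

    def test_unknown_basis_rejected(self):
        with pytest.raises(ValueError, match="gene_fraction_basis"):
            watterson_theta_pool(
                sites_from(np.zeros((1, 1, 4), dtype=int)),
                annotation_for({"g": (1, 1)}), FilterParams(),
                gene_fraction_basis="genes",
            )
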