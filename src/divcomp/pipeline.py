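"""End-to-end orchestration of the marker-comparison workflow.

Stages: simulate (optional) -> SSR statistics -> Pool-Seq statistics ->
comparison battery -> SNP down-sampling.  Every stage reads and writes
plain TSV intermediates under the run directory, is idempotent (existing
outputs are reused unless ``force``), and derives its randomness from
the single run seed, so any stage can be re-run alone and reproduce its
outputs bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, formats, poolseq, rarefaction, ssr
from .results import FstMatrix
from .synthio import SimConfig, simulate_gene_pools, simulate_snp_pools, simulate_ssr_genotypes

log = logging.getLogger("divcomp")


@dataclass
class RunConfig:
    """Inputs and options for one pipeline run.

    Exactly one of {real input paths, simulation config} drives the run:
    set ``simulate`` to a :class:`SimConfig` or supply paths.  The seed
    is recorded in every output's metadata preamble.
    """

    out_dir: Path
    simulate: SimConfig | None = None
    sync_path: Path | None = None
    gff_path: Path | None = None
    genepop_path: Path | None = None
    classes_path: Path | None = None
    params: poolseq.FilterParams = field(default_factory=poolseq.FilterParams)
    gene_fraction_basis: str = "positions"
    he_bias_correction: str = "nei1978"
    rarefy_allele_counts: bool = False
    tajima_one_sample: bool = False
    n_permutations: int = 999
    mantel_permutations: int = 1001
    rarefaction_replicates: int = 1000
    rarefaction_grid: np.ndarray | None = None
    tie_tolerance: float = 0.0005
    seed: int = 0
    force: bool = False

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        real = any([self.sync_path, self.genepop_path])
        if self.simulate is not None and real:
            raise ValueError("provide either real inputs or a simulation config")


def _meta(config: RunConfig, **extra) -> dict:
    meta = {"seed": config.seed}
    meta.update(extra)
    return meta


def _fst_matrix_to_df(m: FstMatrix) -> pd.DataFrame:
    df = m.to_dataframe().reset_index(names="population")
    df.insert(0, "estimator", m.estimator)
    return df


def _fst_matrix_from_df(df: pd.DataFrame) -> FstMatrix:
    labels = list(df["population"])
    return FstMatrix(
        labels=labels,
        values=df[labels].to_numpy(dtype=float),
        estimator=str(df["estimator"].iloc[0]),
    )


def _have(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def stage_simulate(config: RunConfig) -> dict[str, Path]:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "snp_sync": out / "snp_pools.sync",
        "gene_sync": out / "gene_pools.sync",
        "gff": out / "genes.gff3",
        "genepop": out / "genotypes.gen",
        "classes": out / "marker_classes.tsv",
        "truth": out / "simulation_truth.tsv",
    }
    if not config.force and _have(list(paths.values())):
        log.info("simulate: outputs present, skipping")
        return paths
    sim = config.simulate
    assert sim is not None
    log.info("simulate: %d SNPs, %d genes, %d populations",
             sim.n_snps, sim.n_genes, sim.n_populations)
    snp = simulate_snp_pools(sim)
    formats.write_sync(snp.to_records(), paths["snp_sync"])
    genes = simulate_gene_pools(sim)
    formats.write_sync(genes.to_records(), paths["gene_sync"])
    formats.write_gff3(genes.annotation, paths["gff"])
    table, truth = simulate_ssr_genotypes(sim)
    formats.write_genepop(table, paths["genepop"])
    formats.write_marker_classes(table.locus_class, paths["classes"])
    truth_df = pd.DataFrame(
        {
            "population": sim.pop_labels,
            "expected_ssr_he": truth.expected_he,
            "pop_drift": truth.pop_drift,
            "snp_fst": sim.fst,
            "theta": sim.theta,
            "expected_snp_he": snp.truth.expected_he,
        }
    )
    formats.write_table(truth_df, paths["truth"], _meta(config))
    return paths


def stage_ssr(config: RunConfig, genepop: Path, classes: Path | None) -> dict[str, Path]:
    out = config.out_dir
    paths = {
        "locus": out / "ssr_locus_stats.tsv",
        "pops": out / "ssr_pop_summary.tsv",
        "fis": out / "ssr_fis.tsv",
        "null": out / "null_alleles.tsv",
    }
    table = formats.read_genepop(genepop, classes)
    marker_sets = ["all"]
    if table.locus_class:
        marker_sets += list(formats.MARKER_CLASSES)
    for ms in marker_sets:
        paths[f"fst_{ms}"] = out / f"ssr_fst_matrix_{ms}.tsv"
    if not config.force and _have(list(paths.values())):
        log.info("ssr: outputs present, skipping")
        return paths
    log.info("ssr: %d individuals, %d loci", len(table.individuals), len(table.loci))
    locus_df, pop_df = ssr.ssr_diversity(
        table, bias_correction=config.he_bias_correction,
        rarefy=config.rarefy_allele_counts,
    )
    formats.write_table(locus_df, paths["locus"], _meta(config))
    formats.write_table(pop_df, paths["pops"], _meta(config))
    fis_rows = []
    for pop in table.populations:
        res = ssr.gis_fis(
            table, pop, n_permutations=config.n_permutations, seed=config.seed
        )
        fis_rows.append(
            {"population": pop, "gis": res.gis, "p_value": res.p_value,
             "n_permutations": res.n_permutations, "flag": res.flag}
        )
    formats.write_table(pd.DataFrame(fis_rows), paths["fis"],
                        _meta(config, n_permutations=config.n_permutations))
    null_rows = []
    for k, locus in enumerate(table.loci):
        for j, pop in enumerate(table.populations):
            g = ssr._locus_pop_genotypes(table, k, j)
            if len(g) == 0:
                continue
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                try:
                    res = ssr.null_allele_em(g)
                    null_rows.append(
                        {"locus": locus, "population": pop,
                         "null_freq": res.null_freq, "converged": res.converged}
                    )
                except ssr.EMConvergenceError as err:
                    null_rows.append(
                        {"locus": locus, "population": pop,
                         "null_freq": err.last.null_freq, "converged": False}
                    )
    formats.write_table(pd.DataFrame(null_rows), paths["null"], _meta(config))
    for ms in marker_sets:
        matrix, _ = ssr.fst_wc84_pairwise(table, marker_set=ms)
        formats.write_table(_fst_matrix_to_df(matrix), paths[f"fst_{ms}"],
                            _meta(config, marker_set=ms))
    return paths


def stage_pool(config: RunConfig, sync: Path, gff: Path | None,
               gene_sync: Path | None = None) -> dict[str, Path]:
    out = config.out_dir
    paths = {
        "snp_table": out / "snp_table.tsv",
        "filter_report": out / "filter_report.tsv",
        "pool_fst": out / "pool_fst_matrix.tsv",
    }
    if gff is not None:
        paths["gene_theta"] = out / "gene_theta.tsv"
        paths["gene_tajima"] = out / "gene_tajima_d.tsv"
        paths["pool_summary"] = out / "pool_pop_summary.tsv"
    if not config.force and _have(list(paths.values())):
        log.info("pool: outputs present, skipping")
        return paths
    params = config.params
    sites = poolseq.stack_sites(formats.read_sync(sync))
    log.info("pool: %d sites, %d populations", len(sites.pos), sites.n_populations)
    table, report = poolseq.call_biallelic_snps(sites, params)
    formats.write_table(table.to_dataframe(), paths["snp_table"],
                        _meta(config, **{f"filter_{k}": v for k, v in report.items()}))
    formats.write_table(
        pd.DataFrame([report]), paths["filter_report"], _meta(config)
    )
    matrix = poolseq.fst_pool_pairwise(table)
    formats.write_table(_fst_matrix_to_df(matrix), paths["pool_fst"], _meta(config))
    if gff is not None:
        annotation, _ = formats.read_gff3_exons(gff)
        gene_sites = (
            poolseq.stack_sites(formats.read_sync(gene_sync))
            if gene_sync is not None
            else sites
        )
        theta = poolseq.watterson_theta_pool(
            gene_sites, annotation, params, populations=table.populations,
            gene_fraction_basis=config.gene_fraction_basis,
        )
        formats.write_table(theta.table, paths["gene_theta"],
                            _meta(config, **theta.report))
        taj = poolseq.tajimas_d_pool(
            gene_sites, annotation, params, populations=table.populations
        )
        formats.write_table(
            taj.table, paths["gene_tajima"],
            _meta(config, note="approximate pooled Tajima's D", **taj.report),
        )
        he, _ = poolseq.snp_he(table)
        summary = pd.DataFrame(
            {"population": table.populations, "snp_he": he.to_numpy(),
             "theta_watterson": theta.genome_wide.to_numpy(),
             "tajimas_d": taj.genome_wide.to_numpy()}
        )
        formats.write_table(summary, paths["pool_summary"], _meta(config))
    return paths


def stage_compare(config: RunConfig, ssr_paths: dict[str, Path] | None,
                  pool_paths: dict[str, Path] | None) -> Path:
    out_path = config.out_dir / "comparison_report.tsv"
    if not config.force and out_path.exists():
        log.info("compare: output present, skipping")
        return out_path
    results: list[compare.TestResult] = []
    ssr_pop = locus_df = None
    if ssr_paths is not None:
        ssr_pop = formats.read_table(ssr_paths["pops"]).set_index("population")
        locus_df = formats.read_table(ssr_paths["locus"])
        he_matrix = locus_df.pivot(index="locus", columns="population", values="he")
        if len(he_matrix) >= 6:
            results.extend(compare.pairwise_wilcoxon(he_matrix))
        if "class" in locus_df.columns and locus_df["class"].notna().all() and \
                locus_df["class"].nunique() == 2:
            by_class = locus_df.groupby(["population", "class"]).agg(
                a_r=("n_alleles", "mean"), he=("he", "mean")
            ).reset_index().pivot(index="population", columns="class")
            for metric, label in (("a_r", "A_r"), ("he", "SSR-He")):
                cs = by_class[(metric, "cross-species")]
                sp = by_class[(metric, "species-specific")]
                res = compare.paired_t_test(
                    sp, cs, name=f"paired t {label} species-specific vs cross-species"
                )
                results.append(res)
            res = compare.correlation_test(
                by_class[("he", "cross-species")],
                by_class[("he", "species-specific")],
                name="pearson SSR-He cross-species vs species-specific",
            )
            results.append(res)
    if pool_paths is not None and "pool_summary" in pool_paths and ssr_pop is not None:
        pool_pop = formats.read_table(pool_paths["pool_summary"]).set_index("population")
        common = [p for p in ssr_pop.index if p in pool_pop.index]
        sp, pp = ssr_pop.loc[common], pool_pop.loc[common]
        results.append(compare.correlation_test(
            sp["ssr_he"], pp["snp_he"], name="pearson SSR-He vs SNP-He"))
        results.append(compare.correlation_test(
            sp["ssr_he"], pp["theta_watterson"], name="pearson SSR-He vs theta"))
        results.append(compare.correlation_test(
            sp["a_r"], pp["theta_watterson"], name="pearson A_r vs theta"))
        results.append(compare.correlation_test(
            sp["a_r"], pp["theta_watterson"], method="spearman",
            name="spearman A_r vs theta"))
        results.append(compare.correlation_test(
            pp["snp_he"], pp["theta_watterson"], name="pearson SNP-He vs theta"))
        results.append(compare.paired_t_test(
            sp["ssr_he"], pp["snp_he"], name="paired t SSR-He vs SNP-He"))
    if pool_paths is not None and ssr_paths is not None:
        pool_fst = _fst_matrix_from_df(formats.read_table(pool_paths["pool_fst"]))
        for ms in ("all", "cross-species", "species-specific"):
            key = f"fst_{ms}"
            if key not in ssr_paths or not ssr_paths[key].exists():
                continue
            ssr_fst = _fst_matrix_from_df(formats.read_table(ssr_paths[key]))
            if ssr_fst.labels != pool_fst.labels:
                continue
            res = compare.mantel_test(
                pool_fst, ssr_fst, n_permutations=config.mantel_permutations,
                seed=config.seed,
            )
            res.name = f"mantel pool-FST vs SSR-FST ({ms})"
            results.append(res)
            res = compare.paired_t_test(
                ssr_fst.condensed(), pool_fst.condensed(),
                name=f"paired t SSR-FST vs pool-FST ({ms})",
            )
            results.append(res)
    if pool_paths is not None and "gene_tajima" in pool_paths:
        taj = formats.read_table(pool_paths["gene_tajima"])
        for pop, sub in taj[taj["retained"]].groupby("population", sort=False):
            d = sub["tajimas_d"].dropna()
            if len(d) >= 10:
                res = compare.tajima_zero_test(
                    d, seed=config.seed, one_sample=config.tajima_one_sample
                )
                res.name = f"tajima-vs-zero {pop}"
                results.append(res)
    if not results:
        log.warning("compare: nothing to compare")
    df = compare.results_table(results)
    formats.write_table(df, out_path, _meta(config))
    return out_path


def stage_downsample(config: RunConfig, pool_paths: dict[str, Path]) -> dict[str, Path]:
    out = config.out_dir
    paths = {
        "curves": out / "rarefaction_curves.tsv",
        "thresholds": out / "rarefaction_thresholds.tsv",
    }
    if not config.force and _have(list(paths.values())):
        log.info("downsample: outputs present, skipping")
        return paths
    table = poolseq.SNPFrequencyTable.from_dataframe(
        formats.read_table(pool_paths["snp_table"])
    )
    result = rarefaction.downsample_he(
        table, grid=config.rarefaction_grid,
        n_replicates=config.rarefaction_replicates, seed=config.seed,
    )
    formats.write_table(
        result.to_dataframe(), paths["curves"],
        _meta(config, n_replicates=result.n_replicates,
              grid=f"{result.k[0]}..{result.k[-1]}"),
    )
    ci = rarefaction.k_for_ci_thresholds(result)
    rank = rarefaction.k_for_ranking(result, tie_tolerance=config.tie_tolerance)
    rows = [
        {"criterion": f"ci_half_width<={h}", "k": k}
        for h, k in ci.k_by_threshold.items()
    ]
    rows.append({"criterion": "ranking_non_overlapping_ci", "k": rank.ranking_k})
    formats.write_table(
        pd.DataFrame(rows), paths["thresholds"],
        _meta(config, indistinguishable=rank.indistinguishable,
              vacuous=rank.vacuous, tie_tolerance=config.tie_tolerance),
    )
    return paths


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all applicable stages; returns the paths of all outputs."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    genepop = config.genepop_path
    classes = config.classes_path
    sync = config.sync_path
    gene_sync = None
    gff = config.gff_path
    if config.simulate is not None:
        sim_paths = stage_simulate(config)
        outputs.update({f"sim_{k}": v for k, v in sim_paths.items()})
        genepop, classes = sim_paths["genepop"], sim_paths["classes"]
        sync, gff = sim_paths["snp_sync"], sim_paths["gff"]
        gene_sync = sim_paths["gene_sync"]
    if genepop is None and sync is None:
        raise ValueError("no inputs: provide paths or a simulation config")
    ssr_paths = pool_paths = None
    if genepop is not None:
        ssr_paths = stage_ssr(config, genepop, classes)
        outputs.update(ssr_paths)
    else:
        log.info("no SSR inputs; skipping SSR stages")
    if sync is not None:
        pool_paths = stage_pool(config, sync, gff, gene_sync)
        outputs.update(pool_paths)
        outputs.update(stage_downsample(config, pool_paths))
    else:
        log.info("no Pool-Seq inputs; skipping pool stages")
    outputs["comparison"] = stage_compare(config, ssr_paths, pool_paths)
    return outputs
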