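"""Pool-Seq estimators from per-site read counts.

Implements SNP calling from sync-format count data, genome-wide expected
heterozygosity from pooled allele frequencies, a pool- and
coverage-corrected Watterson estimator of the population mutation rate
computed gene-by-gene over exons, an approximate pooled Tajima's D, and
the pooled pairwise F_ST of read frequencies.

The Watterson correction is a detection weighting: under the neutral
frequency spectrum a site with i of n pool copies occurs with intensity
theta/i and is detected only if binomial read sampling at coverage C
yields at least b minor reads on either side.  The expected number of
detected segregating sites per unit theta per site is therefore

    D(n, C, b) = sum_{i=1..n-1} (1/i) * P(b <= X <= C - b),
                 X ~ Binomial(C, i/n),

which replaces the classical harmonic-number denominator a1 = sum 1/i
(and reduces to it as C -> infinity, b = 1).  theta_hat per site for a
gene is S / sum_{valid sites} D(n, C_site, b).  The correctness
reference for this correction is exact enumeration and Monte Carlo
simulation, not any third-party tool.

Conventions: coverage counts A+T+C+G reads only (N/deletion columns are
ignored); the minor allele of a retained SNP is defined jointly across
populations so per-population frequencies are comparable; sites with
three or more above-threshold alleles are dropped entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ExonAnnotation, NUCLEOTIDES
from .results import FstMatrix


@dataclass(frozen=True)
class FilterParams:
    """Site-filtering thresholds for SNP calling and gene-wise estimates.

    Defaults follow the emulated study: per-population coverage in
    [20x, 400x], within-population minor count 2 (a minor-allele
    frequency floor of 2/40 = 0.05 for a pool of 40), joint minor count
    4 across all pools (4 / (9 x 40) ~ 0.011), Tajima coverage floor
    pool_size // 3 = 13x, and gene retention when at least half of the
    exonic positions are validly covered in every population.
    """

    min_coverage: int = 20
    max_coverage: int = 400
    min_minor_count_within: int = 2
    min_minor_count_joint: int = 4
    pool_size: int = 40
    tajima_min_coverage: int = 13
    gene_valid_fraction: float = 0.5

    def __post_init__(self):
        if not 0 < self.min_coverage <= self.max_coverage:
            raise ValueError("need 0 < min_coverage <= max_coverage")
        if self.min_minor_count_within < 1 or self.min_minor_count_joint < 1:
            raise ValueError("minor-count thresholds must be >= 1")
        if self.pool_size < 2:
            raise ValueError("pool size must be >= 2")
        if not 0 < self.gene_valid_fraction <= 1:
            raise ValueError("gene_valid_fraction must be in (0, 1]")


def tajima_coverage_floor(pool_size: int) -> int:
    """Minimum coverage for Tajima's D: a third of the pool size."""
    return pool_size // 3


def maf_thresholds(params: FilterParams, n_populations: int) -> dict[str, float]:
    """Implied minor-allele frequency thresholds of the count filters.

    The joint threshold divides the joint minor count by the total
    number of pooled genomes across populations; the within-population
    threshold divides by the pool size.
    """
    return {
        "joint": params.min_minor_count_joint / (n_populations * params.pool_size),
        "within": params.min_minor_count_within / params.pool_size,
    }


# ---------------------------------------------------------------------------
# array plumbing
# ---------------------------------------------------------------------------

@dataclass
class SiteCountMatrix:
    """Dense per-site count representation of a sync stream."""

    chrom: np.ndarray                # (S,)
    pos: np.ndarray                  # (S,)
    counts: np.ndarray               # (S, P, 6)
    populations: list[str] | None = None

    @property
    def nucleotides(self) -> np.ndarray:
        return self.counts[:, :, :4]

    @property
    def n_populations(self) -> int:
        return self.counts.shape[1]


def stack_sites(source) -> SiteCountMatrix:
    """Materialize a sync record stream (or pass through a matrix/sim)."""
    if isinstance(source, SiteCountMatrix):
        return source
    if hasattr(source, "counts") and hasattr(source, "pos"):
        return SiteCountMatrix(
            chrom=np.asarray(source.chrom),
            pos=np.asarray(source.pos),
            counts=np.asarray(source.counts),
            populations=list(getattr(source, "populations", [])) or None,
        )
    chroms, poss, counts = [], [], []
    for rec in source:
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        counts.append(rec.counts)
    if not counts:
        return SiteCountMatrix(
            chrom=np.array([], dtype=str),
            pos=np.array([], dtype=np.int64),
            counts=np.zeros((0, 0, 6), dtype=np.int64),
        )
    return SiteCountMatrix(
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        counts=np.stack(counts),
    )


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------

@dataclass
class SNPFrequencyTable:
    """Biallelic sites with per-population minor-allele frequencies."""

    chrom: np.ndarray                # (S,)
    pos: np.ndarray                  # (S,)
    major: np.ndarray                # (S,) base characters
    minor: np.ndarray                # (S,)
    freq: np.ndarray                 # (S, P) per-population minor frequency
    coverage: np.ndarray             # (S, P) retained-allele coverage
    populations: list[str]

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def he_matrix(self) -> np.ndarray:
        """Per-SNP expected heterozygosity 2p(1-p), shape (S, P)."""
        return 2 * self.freq * (1 - self.freq)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "major": self.major,
             "minor": self.minor}
        )
        for j, p in enumerate(self.populations):
            df[f"freq_{p}"] = self.freq[:, j]
            df[f"cov_{p}"] = self.coverage[:, j]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SNPFrequencyTable":
        pops = [c[len("freq_"):] for c in df.columns if c.startswith("freq_")]
        return cls(
            chrom=df["chrom"].to_numpy(),
            pos=df["pos"].to_numpy(),
            major=df["major"].to_numpy(),
            minor=df["minor"].to_numpy(),
            freq=df[[f"freq_{p}" for p in pops]].to_numpy(dtype=float),
            coverage=df[[f"cov_{p}" for p in pops]].to_numpy(),
            populations=pops,
        )

    def subset(self, idx) -> "SNPFrequencyTable":
        return SNPFrequencyTable(
            chrom=self.chrom[idx], pos=self.pos[idx], major=self.major[idx],
            minor=self.minor[idx], freq=self.freq[idx],
            coverage=self.coverage[idx], populations=self.populations,
        )


def call_biallelic_snps(
    source, params: FilterParams, populations: list[str] | None = None
) -> tuple[SNPFrequencyTable, dict[str, int]]:
    """Filter sites to biallelic SNPs and compute minor-allele frequencies.

    A site is retained iff (i) every population's nucleotide coverage is
    within [min_coverage, max_coverage]; (ii) exactly two bases have a
    joint (summed across populations) count at or above the joint
    minor-count threshold while sub-threshold stray bases are treated as
    sequencing noise; sites with three or more above-threshold bases are
    dropped as multi-allelic.  Frequencies are computed from the two
    retained alleles' counts, with the minor allele defined by the joint
    counts.  Rejected sites are tallied by reason.
    """
    sites = stack_sites(source)
    if populations is None:
        populations = sites.populations or [
            f"pop{j + 1}" for j in range(sites.n_populations)
        ]
    nuc = sites.nucleotides                       # (S, P, 4)
    cov = nuc.sum(axis=2)                         # (S, P)
    cov_low = (cov < params.min_coverage).any(axis=1)
    cov_high = (cov > params.max_coverage).any(axis=1) & ~cov_low
    cov_ok = ~(cov_low | cov_high)

    joint = nuc.sum(axis=1)                       # (S, 4)
    above = joint >= params.min_minor_count_joint
    n_alleles = above.sum(axis=1)
    not_biallelic = cov_ok & (n_alleles < 2)
    multiallelic = cov_ok & (n_alleles > 2)
    keep = cov_ok & (n_alleles == 2)

    report = {
        "total": int(len(cov)),
        "coverage_low": int(cov_low.sum()),
        "coverage_high": int(cov_high.sum()),
        "not_biallelic": int(not_biallelic.sum()),
        "multiallelic": int(multiallelic.sum()),
        "retained": int(keep.sum()),
    }

    joint_k = joint[keep]
    order = np.argsort(joint_k, axis=1)           # ascending
    minor_idx = np.where(above[keep], np.arange(4), -1)
    # the two above-threshold alleles: take by joint count among them
    top2 = order[:, -2:]                          # columns of the two largest
    # ensure both selected columns are the above-threshold ones
    maj_col = top2[:, 1]
    min_col = top2[:, 0]
    rows = np.arange(keep.sum())
    nuc_k = nuc[keep]
    major_counts = nuc_k[rows, :, maj_col]
    minor_counts = nuc_k[rows, :, min_col]
    denom = major_counts + minor_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, minor_counts / np.maximum(denom, 1), np.nan)
    bases = np.array(NUCLEOTIDES)
    table = SNPFrequencyTable(
        chrom=sites.chrom[keep],
        pos=sites.pos[keep],
        major=bases[maj_col],
        minor=bases[min_col],
        freq=freq,
        coverage=denom,
        populations=list(populations),
    )
    return table, report


def snp_he(table: SNPFrequencyTable) -> tuple[pd.Series, np.ndarray]:
    """Mean SNP expected heterozygosity per population.

    SNP-H_e = (1/n) sum_i 2 p_i (1 - p_i) over the n retained SNPs,
    where p_i is the population's frequency of the jointly defined minor
    allele.  Returns the per-population means and the per-SNP matrix.
    """
    if table.n_snps == 0:
        raise ValueError("empty SNP table")
    he = table.he_matrix()
    means = pd.Series(np.nanmean(he, axis=0), index=table.populations, name="snp_he")
    return means, he


# ---------------------------------------------------------------------------
# detection-weighted Watterson estimator
# ---------------------------------------------------------------------------

_DW_CACHE: dict[tuple[int, int, int], float] = {}


def detection_weight(n: int, coverage, min_count: int):
    """Expected detected segregating sites per unit theta per site.

    D(n, C, b) = sum_{i=1..n-1} (1/i) P(b <= X <= C-b) with
    X ~ Binomial(C, i/n).  As C -> infinity with b = 1 this recovers the
    classical Watterson denominator a1 = sum_{i<n} 1/i.  Accepts a
    scalar or array coverage; scalar input with b > C/2 raises (no
    detectable configuration).
    """
    scalar = np.isscalar(coverage)
    cov = np.atleast_1d(np.asarray(coverage, dtype=np.int64))
    if n < 2:
        raise ValueError("pool size must be >= 2")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if scalar and min_count > cov[0] / 2:
        raise ValueError(
            f"min_count {min_count} > coverage/2 ({cov[0]}/2): nothing detectable"
        )
    out = np.empty(cov.shape, dtype=float)
    i_vals = np.arange(1, n)
    p = i_vals / n
    for C in np.unique(cov):
        key = (n, int(C), min_count)
        if key not in _DW_CACHE:
            if C < 2 * min_count:
                _DW_CACHE[key] = 0.0
            else:
                upper = stats.binom.cdf(C - min_count, C, p)
                lower = stats.binom.cdf(min_count - 1, C, p)
                _DW_CACHE[key] = float(np.sum((upper - lower) / i_vals))
        out[cov == C] = _DW_CACHE[key]
    return float(out[0]) if scalar else out


def _top_two_counts(nuc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per site/population largest and second-largest base counts."""
    part = np.sort(nuc, axis=-1)
    return part[..., -1], part[..., -2]


def _gene_site_slices(
    sites: SiteCountMatrix, annotation: Mapping[str, ExonAnnotation]
) -> tuple[np.ndarray, list[tuple[str, np.ndarray, int]]]:
    """Sort sites and map each gene to its exonic site indices."""
    order = np.lexsort((sites.pos, sites.chrom))
    chrom_sorted = sites.chrom[order]
    pos_sorted = sites.pos[order]
    genes = []
    # per-chromosome searchsorted ranges
    uchrom, starts = np.unique(chrom_sorted, return_index=True)
    bounds = dict(
        zip(uchrom, zip(starts, np.append(starts[1:], len(chrom_sorted))))
    )
    for gene_id, ann in annotation.items():
        if ann.chrom not in bounds:
            genes.append((gene_id, np.array([], dtype=np.int64), ann.length))
            continue
        lo, hi = bounds[ann.chrom]
        seg = pos_sorted[lo:hi]
        idx = []
        for s, e in ann.exons:
            a = np.searchsorted(seg, s, side="left")
            b = np.searchsorted(seg, e, side="right")
            idx.append(np.arange(lo + a, lo + b))
        genes.append((gene_id, np.concatenate(idx), ann.length))
    return order, genes


@dataclass
class GeneDiversity:
    """Per-gene, per-population diversity output."""

    table: pd.DataFrame              # gene, population, theta, n_valid, n_seg, ...
    genome_wide: pd.Series           # per-population unweighted mean over genes
    report: dict[str, int] = field(default_factory=dict)


def watterson_theta_pool(
    source,
    annotation: Mapping[str, ExonAnnotation],
    params: FilterParams,
    populations: list[str] | None = None,
    gene_fraction_basis: str = "positions",
) -> GeneDiversity:
    """Gene-by-gene pool-corrected Watterson's theta per population.

    Valid positions are exonic positions with coverage within
    [min_coverage, max_coverage] in the given population; segregating
    positions are valid positions whose within-population second-largest
    base count reaches the within-population minor-count threshold.
    theta per site = S / sum over valid positions of D(n, C_site, b).
    A gene enters the genome-wide (unweighted mean) estimate only if its
    valid fraction reaches ``gene_valid_fraction`` in every population.
    The fraction's basis is exonic *positions* by default (the
    alternative, fraction of the gene's SNP positions — positions whose
    raw within-population minor count reaches the threshold anywhere —
    is available via ``gene_fraction_basis="snps"``; a SNP-based
    denominator is partly circular since SNP status depends on the same
    filters, which is why positions is the default).
    """
    if gene_fraction_basis not in ("positions", "snps"):
        raise ValueError(f"unknown gene_fraction_basis {gene_fraction_basis!r}")
    sites = stack_sites(source)
    if populations is None:
        populations = sites.populations or [
            f"pop{j + 1}" for j in range(sites.n_populations)
        ]
    nuc = sites.nucleotides
    cov = nuc.sum(axis=2)
    _, minor = _top_two_counts(nuc)
    valid = (cov >= params.min_coverage) & (cov <= params.max_coverage)
    seg = valid & (minor >= params.min_minor_count_within)
    dw = np.zeros_like(cov, dtype=float)
    dw[valid] = detection_weight(params.pool_size, cov[valid], params.min_minor_count_within)
    # SNP positions regardless of coverage validity (snps fraction basis)
    is_snp = (minor >= params.min_minor_count_within).any(axis=1)

    order, genes = _gene_site_slices(sites, annotation)
    valid_s, seg_s, dw_s, snp_s = valid[order], seg[order], dw[order], is_snp[order]

    rows = []
    excluded_empty = 0
    for gene_id, idx, length in genes:
        if len(idx) == 0:
            excluded_empty += 1
            continue
        v = valid_s[idx].sum(axis=0)
        if (v == 0).all():
            excluded_empty += 1
            continue
        s = seg_s[idx].sum(axis=0)
        dsum = dw_s[idx].sum(axis=0)
        if gene_fraction_basis == "positions":
            frac = v / length
        else:
            n_snp = snp_s[idx].sum()
            frac = (
                (valid_s[idx] & snp_s[idx][:, None]).sum(axis=0) / n_snp
                if n_snp else np.ones_like(v, dtype=float)
            )
        retained = bool((frac >= params.gene_valid_fraction).all())
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where(dsum > 0, s / np.maximum(dsum, 1e-300), np.nan)
        for j, p in enumerate(populations):
            rows.append(
                {"gene": gene_id, "population": p, "theta": theta[j],
                 "n_valid": int(v[j]), "n_seg": int(s[j]),
                 "valid_fraction": frac[j], "retained": retained}
            )
    table = pd.DataFrame(rows)
    if len(table):
        kept = table[table["retained"]]
        genome = kept.groupby("population", sort=False)["theta"].mean()
        genome = genome.reindex(populations)
    else:
        genome = pd.Series(np.nan, index=populations)
    genome.name = "theta_watterson"
    report = {
        "genes_total": len(genes),
        "genes_retained": int(table["retained"].sum() // max(len(populations), 1))
        if len(table) else 0,
        "genes_excluded_no_valid_sites": excluded_empty,
    }
    return GeneDiversity(table=table, genome_wide=genome, report=report)


# ---------------------------------------------------------------------------
# pooled Tajima's D (approximate)
# ---------------------------------------------------------------------------

def _tajima_constants(m: int) -> tuple[float, float, float]:
    """Classical a1 and variance coefficients e1, e2 at sample size m."""
    if m < 4:
        raise ValueError("effective sample size must be >= 4")
    i = np.arange(1, m)
    a1 = float(np.sum(1 / i))
    a2 = float(np.sum(1 / i**2))
    b1 = (m + 1) / (3 * (m - 1))
    b2 = 2 * (m**2 + m + 3) / (9 * m * (m - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    return a1, c1 / a1, c2 / (a1**2 + a2)


def tajimas_d_pool(
    source,
    annotation: Mapping[str, ExonAnnotation],
    params: FilterParams,
    populations: list[str] | None = None,
) -> GeneDiversity:
    """Approximate per-gene pooled Tajima's D for each population.

    Pairwise diversity per site uses the read frequencies with the pool
    correction n/(n-1) and the read-sampling correction C/(C-1); the
    Watterson term uses the detection weighting of
    :func:`watterson_theta_pool`.  D standardizes their difference with
    the classical variance approximation evaluated at an effective
    sample size min(pool size, mean valid coverage); values are
    approximate by construction and labelled as such in output headers.
    Coverage filtering uses ``tajima_min_coverage``.
    """
    sites = stack_sites(source)
    if populations is None:
        populations = sites.populations or [
            f"pop{j + 1}" for j in range(sites.n_populations)
        ]
    n = params.pool_size
    nuc = sites.nucleotides
    cov = nuc.sum(axis=2)
    _, minor = _top_two_counts(nuc)
    valid = (cov >= params.tajima_min_coverage) & (cov <= params.max_coverage)
    seg = valid & (minor >= params.min_minor_count_within)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = np.where(seg, minor / np.maximum(cov, 1), 0.0)
        pi_site = np.where(
            valid & (cov > 1),
            (cov / np.maximum(cov - 1, 1)) * (n / (n - 1)) * 2 * p_hat * (1 - p_hat),
            0.0,
        )
    dw = np.zeros_like(cov, dtype=float)
    dw[valid] = detection_weight(n, cov[valid], params.min_minor_count_within)

    order, genes = _gene_site_slices(sites, annotation)
    valid_s, seg_s, dw_s, pi_s, cov_s = (
        valid[order], seg[order], dw[order], pi_site[order], cov[order]
    )

    rows = []
    excluded = 0
    for gene_id, idx, length in genes:
        if len(idx) < 2:
            excluded += 1
            continue
        v = valid_s[idx].sum(axis=0)
        s = seg_s[idx].sum(axis=0)
        dsum = dw_s[idx].sum(axis=0)
        pi_tot = pi_s[idx].sum(axis=0)
        covsum = (cov_s[idx] * valid_s[idx]).sum(axis=0)
        frac = v / length
        retained = bool((frac >= params.gene_valid_fraction).all())
        for j, p in enumerate(populations):
            if v[j] < 2 or s[j] == 0 or dsum[j] <= 0:
                rows.append(
                    {"gene": gene_id, "population": p, "tajimas_d": np.nan,
                     "pi": pi_tot[j], "n_valid": int(v[j]), "n_seg": int(s[j]),
                     "retained": retained}
                )
                continue
            theta_tot = s[j] * v[j] / dsum[j]
            mean_cov = covsum[j] / v[j]
            m_eff = int(min(n, max(4, math.floor(mean_cov))))
            _, e1, e2 = _tajima_constants(m_eff)
            var = e1 * s[j] + e2 * s[j] * (s[j] - 1)
            d = (pi_tot[j] - theta_tot) / math.sqrt(var) if var > 0 else np.nan
            rows.append(
                {"gene": gene_id, "population": p, "tajimas_d": d,
                 "pi": pi_tot[j], "n_valid": int(v[j]), "n_seg": int(s[j]),
                 "retained": retained}
            )
    table = pd.DataFrame(rows)
    if len(table):
        kept = table[table["retained"] & table["tajimas_d"].notna()]
        summary = kept.groupby("population", sort=False)["tajimas_d"].agg(
            ["mean", "std", "count"]
        ).reindex(populations)
    else:
        summary = pd.DataFrame(index=populations, columns=["mean", "std", "count"])
    genome = summary["mean"]
    genome.name = "tajimas_d"
    return GeneDiversity(
        table=table,
        genome_wide=genome,
        report={"genes_total": len(genes), "genes_excluded": excluded},
    )


# ---------------------------------------------------------------------------
# pooled pairwise F_ST
# ---------------------------------------------------------------------------

def fst_pool_pairwise(
    table: SNPFrequencyTable, return_per_snp: bool = False,
    combine: str = "mean",
):
    """Pairwise F_ST from pooled read frequencies.

    Per SNP and population pair, F_ST = (H_T - mean(H_S)) / H_T with
    H_S = 2 p_j (1 - p_j) per population and H_T = 2 pbar (1 - pbar) at
    the mean of the two frequencies.  With ``combine="mean"`` (default)
    the pairwise value is the unweighted mean over SNPs with H_T > 0;
    with ``combine="ratio_of_sums"`` it is sum(H_T - H_S) / sum(H_T),
    the Weir-style combination whose expectation equals the
    Balding-Nichols differentiation parameter up to sampling terms.
    The per-SNP mean sits systematically below it when rare variants
    dominate the frequency spectrum (low-frequency SNPs pull individual
    ratios toward zero).  Pairs with no informative SNP yield a
    missing, flagged entry.
    """
    if combine not in ("mean", "ratio_of_sums"):
        raise ValueError(f"unknown combine mode {combine!r}")
    P = len(table.populations)
    if P < 2:
        raise ValueError("need at least two populations")
    f = table.freq
    values = np.zeros((P, P))
    flags: dict[tuple[str, str], str] = {}
    per_snp: dict[tuple[str, str], np.ndarray] = {}
    for i in range(1, P):
        for j in range(i):
            fi, fj = f[:, i], f[:, j]
            hs = (2 * fi * (1 - fi) + 2 * fj * (1 - fj)) / 2
            pbar = (fi + fj) / 2
            ht = 2 * pbar * (1 - pbar)
            mask = np.isfinite(ht) & (ht > 0)
            if not mask.any():
                values[i, j] = values[j, i] = np.nan
                flags[(table.populations[j], table.populations[i])] = (
                    "no informative SNPs"
                )
                continue
            snp_fst = (ht[mask] - hs[mask]) / ht[mask]
            if combine == "mean":
                values[i, j] = values[j, i] = snp_fst.mean()
            else:
                values[i, j] = values[j, i] = (
                    (ht[mask] - hs[mask]).sum() / ht[mask].sum()
                )
            if return_per_snp:
                per_snp[(table.populations[j], table.populations[i])] = snp_fst
    matrix = FstMatrix(
        labels=list(table.populations), values=values, estimator="pool", flags=flags
    )
    return (matrix, per_snp) if return_per_snp else matrix
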