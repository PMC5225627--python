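"""Synthetic SNP-pool and microsatellite data with known ground truth.

The generator emulates the structure of the study design the pipeline is
built for: nine populations of 20 diploid individuals (pools of n = 40
haploid genomes), ~50-70x pooled coverage, weak differentiation
(pairwise F_ST of a few percent), genome-wide SNP heterozygosity around
0.12-0.16 and exonic Watterson's theta near 0.009.

Two SNP generators are provided:

* :func:`simulate_snp_pools` draws sites conditioned on being
  polymorphic: an ancestral minor-allele frequency from a neutral-like
  law (density proportional to 1/p, truncated), per-population
  frequencies from the Balding-Nichols Beta model, pool allele counts
  binomially, and reads binomially with sequencing error.  Closed-form
  expectations (E[F_ST] = F, E[H_e] from the SFS law) make it the
  parameter-recovery oracle for the SNP table / F_ST / down-sampling
  stages.
* :func:`simulate_gene_pools` lays out genes of exonic sequence and
  draws *every* position, monomorphic or segregating, with segregation
  probability theta/i for a pool sample frequency of i/n copies (the
  neutral frequency spectrum of a sample of n).  It is the recovery
  oracle for the pool-corrected Watterson and Tajima's D estimators.

Microsatellites (:func:`simulate_ssr_genotypes`) use a Dirichlet
analogue of Balding-Nichols with a population-specific drift parameter
chosen so that the expected per-population mean heterozygosity follows a
configured ladder, plus optional null alleles and inbreeding.

All randomness flows from one global seed; per-stage child seeds are
derived deterministically from the stage name, so identical configs give
byte-identical outputs and stages can be re-run in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .formats import ExonAnnotation, PoolSiteCounts, SSRGenotypeTable

_BASES = np.array(["A", "T", "C", "G"])


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named stage, derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the emulated study conditions: 9 pools of 40 haploid
    genomes (20 diploids), mean coverage 60x, differentiation F = 0.05,
    an ancestral site-frequency law with density ~ 1/p truncated at
    p_min = 1/(9 n), exonic theta = 0.009 over 2000 genes of 500 bp, and
    19 microsatellite loci in two ascertainment classes whose expected
    per-population heterozygosities span 0.32-0.46.
    """

    n_populations: int = 9
    pool_size: int = 40          # haploid genomes per pool
    n_snps: int = 50_000
    mean_coverage: float = 60.0
    sequencing_error: float = 0.001
    fst: float = 0.05            # Balding-Nichols differentiation parameter
    sfs_law: str = "1/p"         # "1/p" or "beta"
    sfs_beta: tuple[float, float] = (0.5, 0.5)
    p_min: float | None = None   # default 1/(n_populations * pool_size)

    # gene-mode (Watterson / Tajima) parameters
    theta: float = 0.009
    n_genes: int = 2000
    gene_length: int = 500
    # exponent on the copy number in the gene-mode frequency spectrum:
    # intensity ~ theta / i**skew.  1.0 is the neutral constant-size
    # spectrum; > 1 enriches rare variants (negative Tajima's D), < 1
    # depletes them (positive D)
    gene_sfs_skew: float = 1.0

    # microsatellites
    n_individuals: int = 20
    ssr_loci_cross: int = 12
    ssr_loci_specific: int = 8
    ssr_alleles_cross: tuple[int, int] = (2, 4)
    ssr_alleles_specific: tuple[int, int] = (4, 6)
    ssr_target_he: tuple[float, ...] | None = None  # default linspace(.32,.46)
    ssr_pop_f: tuple[float, ...] | None = None      # overrides the He ladder
    # locus-level drift heterogeneity: per locus x population the effective
    # drift is Beta(F_j nu, (1-F_j) nu), preserving E = F_j.  The default
    # nu = 1 reproduces the wide per-locus differentiation spread typical of
    # microsatellite panels (locus-wise F_ST from ~0.02 to ~0.4).
    ssr_drift_dispersion: float = 1.0
    # null-allele rate; the default reproduces the ~0.3% missing-data rate of
    # a typical curated panel (null/null homozygotes blank at rate r^2)
    null_rate: float = 0.05
    inbreeding: float = 0.0

    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fst < 1:
            raise ValueError("differentiation parameter F must be in (0, 1)")
        if not 0 <= self.sequencing_error < 0.01:
            raise ValueError("sequencing error must be in [0, 0.01)")
        if not 0 <= self.null_rate < 0.5:
            raise ValueError("null-allele rate must be in [0, 0.5)")
        if not 0 <= self.inbreeding < 1:
            raise ValueError("inbreeding coefficient must be in [0, 1)")
        if self.pool_size % 2 or self.pool_size < 2:
            raise ValueError("pool size must be even and >= 2")
        if self.sfs_law not in ("1/p", "beta"):
            raise ValueError("sfs_law must be '1/p' or 'beta'")

    @property
    def effective_p_min(self) -> float:
        if self.p_min is not None:
            return self.p_min
        return 1.0 / (self.n_populations * self.pool_size)

    @property
    def pop_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    def target_he_ladder(self) -> np.ndarray:
        if self.ssr_target_he is not None:
            ladder = np.asarray(self.ssr_target_he, dtype=float)
            if ladder.shape != (self.n_populations,):
                raise ValueError("ssr_target_he length != n_populations")
            return ladder
        return np.linspace(0.32, 0.46, self.n_populations)


# ---------------------------------------------------------------------------
# SNP pools (polymorphic sites)
# ---------------------------------------------------------------------------

@dataclass
class SnpTruth:
    """Ground truth for a :func:`simulate_snp_pools` draw."""

    ancestral_freq: np.ndarray       # (S,)
    pop_freq: np.ndarray             # (S, P) true per-population frequencies
    fst: float
    expected_he: float               # E[2p(1-p)] under the SFS law


@dataclass
class SnpPoolSim:
    chrom: np.ndarray                # (S,) str
    pos: np.ndarray                  # (S,) int
    ref: np.ndarray                  # (S,) str, the major base
    counts: np.ndarray               # (S, P, 6) int
    populations: list[str]
    truth: SnpTruth

    def to_records(self) -> Iterator[PoolSiteCounts]:
        for i in range(len(self.pos)):
            yield PoolSiteCounts(
                chrom=str(self.chrom[i]),
                pos=int(self.pos[i]),
                ref=str(self.ref[i]),
                counts=self.counts[i],
            )


def _draw_ancestral(config: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    if config.sfs_law == "1/p":
        p_min = config.effective_p_min
        u = rng.random(size)
        return p_min * (0.5 / p_min) ** u  # inverse CDF of density ~ 1/p
    a, b = config.sfs_beta
    p = rng.beta(a, b, size)
    return np.minimum(p, 1 - p).clip(config.effective_p_min, 0.5)


def _expected_he(config: SimConfig) -> float:
    """E[2 p (1-p)] under the configured ancestral SFS law."""
    if config.sfs_law == "1/p":
        p_min = config.effective_p_min
        c = 1.0 / np.log(0.5 / p_min)
        # int c/p * 2p(1-p) dp = 2c [ (p - p^2/2) ]
        f = lambda p: p - p * p / 2.0
        return float(2 * c * (f(0.5) - f(p_min)))
    grid = np.linspace(config.effective_p_min, 0.5, 20001)
    a, b = config.sfs_beta
    from scipy import stats

    dens = stats.beta.pdf(grid, a, b) + stats.beta.pdf(1 - grid, a, b)
    dens /= np.trapezoid(dens, grid)
    return float(np.trapezoid(2 * grid * (1 - grid) * dens, grid))


def _add_sequencing_error(
    counts4: np.ndarray, eps: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each read to a uniformly chosen different base with prob eps."""
    if eps <= 0:
        return counts4
    out = counts4.copy()
    for b in range(4):
        errs = rng.binomial(counts4[..., b], eps)
        if errs.sum() == 0:
            continue
        out[..., b] -= errs
        others = [o for o in range(4) if o != b]
        dest = rng.multinomial(errs.ravel(), [1 / 3] * 3).reshape(errs.shape + (3,))
        for k, o in enumerate(others):
            out[..., o] += dest[..., k]
    return out


def simulate_snp_pools(config: SimConfig) -> SnpPoolSim:
    """Draw a panel of polymorphic sites as pooled read counts.

    Sampling chain per site: ancestral minor frequency p0 from the SFS
    law; population frequency p_j ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F);
    pool allele count a_j ~ Binomial(n, p_j); coverage C_j ~
    Poisson(mean coverage); minor-allele reads ~ Binomial(C_j, a_j / n);
    each read then flips to a random other base with the configured
    error probability (so tri-allelic artifacts occur and the biallelic
    filter has something real to reject).
    """
    S, P, n = config.n_snps, config.n_populations, config.pool_size
    rng_anc = stage_rng(config.seed, "snp-ancestral")
    rng_pop = stage_rng(config.seed, "snp-population")
    rng_reads = stage_rng(config.seed, "snp-reads")
    rng_bases = stage_rng(config.seed, "snp-bases")

    p0 = _draw_ancestral(config, rng_anc, S)
    F = config.fst
    shape = (1 - F) / F
    pop_freq = rng_pop.beta(p0[:, None] * shape, (1 - p0)[:, None] * shape, (S, P))
    pool_count = rng_pop.binomial(n, pop_freq)
    coverage = rng_reads.poisson(config.mean_coverage, (S, P))
    minor_reads = rng_reads.binomial(coverage, pool_count / n)
    major_reads = coverage - minor_reads

    major_idx = rng_bases.integers(0, 4, S)
    minor_off = rng_bases.integers(1, 4, S)
    minor_idx = (major_idx + minor_off) % 4

    counts4 = np.zeros((S, P, 4), dtype=np.int64)
    rows = np.arange(S)
    counts4[rows[:, None], np.arange(P)[None, :], major_idx[:, None]] = major_reads
    counts4[rows[:, None], np.arange(P)[None, :], minor_idx[:, None]] += minor_reads
    counts4 = _add_sequencing_error(counts4, config.sequencing_error, rng_reads)

    counts = np.zeros((S, P, 6), dtype=np.int64)
    counts[:, :, :4] = counts4
    return SnpPoolSim(
        chrom=np.full(S, "sim1"),
        pos=np.arange(1, S + 1) * 10,  # spaced positions on one scaffold
        ref=_BASES[major_idx],
        counts=counts,
        populations=config.pop_labels,
        truth=SnpTruth(
            ancestral_freq=p0,
            pop_freq=pop_freq,
            fst=F,
            expected_he=_expected_he(config),
        ),
    )


# ---------------------------------------------------------------------------
# gene-structured pools (every position drawn; Watterson / Tajima oracle)
# ---------------------------------------------------------------------------

@dataclass
class GeneTruth:
    theta: float                     # per-site population mutation rate
    seg_copies: np.ndarray           # (S, P) pool sample copies of derived allele


@dataclass
class GenePoolSim:
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray               # (S, P, 6)
    populations: list[str]
    annotation: dict[str, ExonAnnotation]
    truth: GeneTruth

    def to_records(self) -> Iterator[PoolSiteCounts]:
        for i in range(len(self.pos)):
            yield PoolSiteCounts(
                chrom=str(self.chrom[i]),
                pos=int(self.pos[i]),
                ref=str(self.ref[i]),
                counts=self.counts[i],
            )


def simulate_gene_pools(
    config: SimConfig, coverage_scale: float = 1.0
) -> GenePoolSim:
    """Simulate exonic genes position-by-position under the neutral SFS.

    Each exonic position, in each population independently, is
    segregating with i of n pool copies carrying the derived allele with
    probability theta / i (i = 1 .. n-1); reads are then drawn
    binomially at Poisson coverage with sequencing error.
    ``coverage_scale`` rescales the mean coverage while leaving the
    underlying pool allele configurations untouched (the allele and read
    stages use separate child seeds), which supports paired
    coverage-sensitivity experiments.
    """
    n, P = config.pool_size, config.n_populations
    L = config.n_genes * config.gene_length
    theta = config.theta
    rng_alleles = stage_rng(config.seed, "gene-alleles")
    rng_reads = stage_rng(config.seed, "gene-reads")
    rng_bases = stage_rng(config.seed, "gene-bases")

    i_vals = np.arange(1, n)
    seg_prob = theta / i_vals**config.gene_sfs_skew
    total_seg = seg_prob.sum()
    if total_seg >= 1:
        raise ValueError("theta too large for per-site SFS sampling")
    # per site/pop: 0 = monomorphic, else index into i_vals
    u = rng_alleles.random((L, P))
    cum = np.concatenate([[0.0], np.cumsum(seg_prob)])
    cls = np.searchsorted(cum, u, side="right") - 1
    cls[u >= total_seg] = -1
    copies = np.where(cls >= 0, cls + 1, 0)  # derived copies in the pool

    coverage = rng_reads.poisson(config.mean_coverage * coverage_scale, (L, P))
    derived_reads = rng_reads.binomial(coverage, copies / n)
    major_reads = coverage - derived_reads

    major_idx = rng_bases.integers(0, 4, L)
    minor_idx = (major_idx + rng_bases.integers(1, 4, L)) % 4
    counts4 = np.zeros((L, P, 4), dtype=np.int64)
    rows = np.arange(L)
    counts4[rows[:, None], np.arange(P)[None, :], major_idx[:, None]] = major_reads
    counts4[rows[:, None], np.arange(P)[None, :], minor_idx[:, None]] += derived_reads
    counts4 = _add_sequencing_error(counts4, config.sequencing_error, rng_reads)

    counts = np.zeros((L, P, 6), dtype=np.int64)
    counts[:, :, :4] = counts4

    # genes laid out consecutively with a 100 bp spacer, one exon per gene
    gene_len, spacer = config.gene_length, 100
    gene_starts = 1 + np.arange(config.n_genes) * (gene_len + spacer)
    pos = (gene_starts[:, None] + np.arange(gene_len)[None, :]).ravel()
    annotation = {
        f"gene{g + 1:05d}": ExonAnnotation(
            gene_id=f"gene{g + 1:05d}",
            chrom="sim1",
            exons=[(int(gene_starts[g]), int(gene_starts[g] + gene_len - 1))],
            strand="+",
        )
        for g in range(config.n_genes)
    }
    return GenePoolSim(
        chrom=np.full(L, "sim1"),
        pos=pos,
        ref=_BASES[major_idx],
        counts=counts,
        populations=config.pop_labels,
        annotation=annotation,
        truth=GeneTruth(theta=theta, seg_copies=copies),
    )


# ---------------------------------------------------------------------------
# microsatellites
# ---------------------------------------------------------------------------

@dataclass
class SsrTruth:
    ancestral_freqs: list[np.ndarray]     # per locus, visible-allele frequencies
    pop_freqs: list[np.ndarray]           # per locus, (P, A) per-population freqs
    pop_drift: np.ndarray                 # (P,) population-specific drift F_j
    expected_he: np.ndarray               # (P,) target mean heterozygosity ladder
    null_rate: float
    locus_class: dict[str, str]


def simulate_ssr_genotypes(config: SimConfig) -> tuple[SSRGenotypeTable, SsrTruth]:
    """Simulate diploid microsatellite genotypes for all populations.

    Per locus, ancestral allele frequencies over A alleles are a
    symmetric Dirichlet draw (A is larger for species-specific than for
    cross-species loci, emulating ascertainment of the most polymorphic
    markers).  Per-population frequencies follow a Dirichlet
    Balding-Nichols model with a population-specific drift parameter F_j
    solved from the configured expected-heterozygosity ladder, since
    E[H_e,j] = (1 - F_j) x (ancestral gene diversity).  Genotypes are
    drawn with inbreeding f (identical-by-state pair forced with
    probability f).  With null-allele rate r an unamplifiable allele
    segregates at frequency r: null/visible renders as an apparent
    homozygote for the visible allele and null/null as missing data.
    """
    rng_loci = stage_rng(config.seed, "ssr-loci")
    rng_pops = stage_rng(config.seed, "ssr-pops")
    rng_geno = stage_rng(config.seed, "ssr-genotypes")

    n_loci = config.ssr_loci_cross + config.ssr_loci_specific
    classes = ["cross-species"] * config.ssr_loci_cross + [
        "species-specific"
    ] * config.ssr_loci_specific
    loci = [f"ssr{k + 1:02d}" for k in range(n_loci)]
    locus_class = dict(zip(loci, classes))

    ancestral: list[np.ndarray] = []
    allele_labels: list[np.ndarray] = []
    for k in range(n_loci):
        lo, hi = (
            config.ssr_alleles_cross
            if classes[k] == "cross-species"
            else config.ssr_alleles_specific
        )
        A = int(rng_loci.integers(lo, hi + 1))
        p0 = rng_loci.dirichlet(np.ones(A))
        ancestral.append(p0)
        # fragment lengths: motif-spaced ladder around 100 + 10k
        allele_labels.append(100 + 10 * k + 2 * np.arange(1, A + 1))

    he0 = np.array([1 - (p0**2).sum() for p0 in ancestral])
    mean_he0 = he0.mean()
    if config.ssr_pop_f is not None:
        pop_drift = np.asarray(config.ssr_pop_f, dtype=float)
        if pop_drift.shape != (config.n_populations,):
            raise ValueError("ssr_pop_f length != n_populations")
        ladder = (1 - pop_drift) * mean_he0
    else:
        ladder = config.target_he_ladder()
        # under pure drift a population cannot exceed the ancestral gene
        # diversity: drift is floored at 1%, compressing unattainable targets
        pop_drift = np.clip(1 - ladder / mean_he0, 0.01, 0.9)
        ladder = (1 - pop_drift) * mean_he0  # realizable expectation ladder

    P, N = config.n_populations, config.n_individuals
    r = config.null_rate
    f = config.inbreeding
    pop_freqs: list[np.ndarray] = []
    genotypes = np.zeros((P * N, n_loci, 2), dtype=np.int64)
    for k in range(n_loci):
        p0 = ancestral[k]
        A = len(p0)
        freqs = np.empty((P, A))
        nu = config.ssr_drift_dispersion
        for j in range(P):
            Fj = pop_drift[j]
            if nu and np.isfinite(nu):
                Fjl = float(
                    np.clip(rng_pops.beta(Fj * nu, (1 - Fj) * nu), 1e-3, 0.95)
                )
            else:
                Fjl = Fj
            conc = p0 * (1 - Fjl) / Fjl
            freqs[j] = rng_pops.dirichlet(conc)
        pop_freqs.append(freqs)
        # extended allele space: visible alleles scaled by (1-r), plus null
        for j in range(P):
            ext = np.concatenate([freqs[j] * (1 - r), [r]])
            draws = rng_geno.choice(A + 1, size=(N, 2), p=ext)
            if f > 0:
                force = rng_geno.random(N) < f
                draws[force, 1] = draws[force, 0]
            null = A  # index of the null allele
            labels = np.concatenate([allele_labels[k], [0]])
            g = labels[draws]
            # null/visible -> apparent homozygote for the visible allele
            one_null = (draws == null).sum(axis=1) == 1
            vis = np.where(draws[one_null, 0] == null, g[one_null, 1], g[one_null, 0])
            g[one_null, 0] = vis
            g[one_null, 1] = vis
            # null/null -> missing (both labels already 0)
            both_null = (draws == null).all(axis=1)
            g[both_null] = 0
            genotypes[j * N : (j + 1) * N, k] = g

    individuals = [
        f"{label}_{i + 1:03d}" for label in config.pop_labels for i in range(N)
    ]
    table = SSRGenotypeTable(
        populations=config.pop_labels,
        pop_index=np.repeat(np.arange(P), N),
        individuals=individuals,
        loci=loci,
        genotypes=genotypes,
        locus_class=locus_class,
    )
    truth = SsrTruth(
        ancestral_freqs=ancestral,
        pop_freqs=pop_freqs,
        pop_drift=pop_drift,
        expected_he=ladder,
        null_rate=r,
        locus_class=locus_class,
    )
    return table, truth
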