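"""Microsatellite (SSR) estimators on diploid genotype tables.

Covers per-locus allele frequencies, expected heterozygosity with the
Nei (1978) small-sample correction, allelic richness as the raw mean
allele count (with an optional hypergeometric rarefaction variant for
unequal samples), the heterozygosity-based G_IS permutation test for
inbreeding / heterozygote deficiency, an EM maximum-likelihood estimator
of null-allele frequencies, and the Weir & Cockerham (1984)
variance-components pairwise F_ST.

Missing-data policy is complete-case per locus: an individual with a
missing genotype is dropped at that locus only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .formats import SSRGenotypeTable
from .results import FstMatrix


# ---------------------------------------------------------------------------
# per-locus summaries and diversity
# ---------------------------------------------------------------------------

def _locus_pop_genotypes(
    table: SSRGenotypeTable, locus_idx: int, pop_idx: int
) -> np.ndarray:
    """Non-missing genotypes (n_typed, 2) of one locus in one population."""
    rows = np.flatnonzero(table.pop_index == pop_idx)
    g = table.genotypes[rows, locus_idx]
    return g[(g > 0).all(axis=1)]


def allele_frequencies(genotypes: np.ndarray) -> dict[int, float]:
    """Allele frequencies from an (n, 2) array of typed genotypes."""
    alleles, counts = np.unique(genotypes.ravel(), return_counts=True)
    total = counts.sum()
    return {int(a): c / total for a, c in zip(alleles, counts)}


def expected_heterozygosity(
    genotypes: np.ndarray, bias_correction: str = "nei1978"
) -> float:
    """Gene diversity 1 - sum p^2, optionally Nei (1978)-corrected.

    With ``bias_correction='nei1978'`` the small-sample unbiased form
    (2n / (2n - 1)) (1 - sum p^2) is returned, n being the number of
    typed diploid individuals.
    """
    n = len(genotypes)
    if n == 0:
        raise ValueError("no typed genotypes")
    freqs = np.array(list(allele_frequencies(genotypes).values()))
    raw = 1 - (freqs**2).sum()
    if bias_correction == "nei1978":
        return float(2 * n / (2 * n - 1) * raw)
    if bias_correction == "raw":
        return float(raw)
    raise ValueError(f"unknown bias correction {bias_correction!r}")


def observed_heterozygosity(genotypes: np.ndarray) -> float:
    if len(genotypes) == 0:
        raise ValueError("no typed genotypes")
    return float((genotypes[:, 0] != genotypes[:, 1]).mean())


def rarefied_allele_count(genotypes: np.ndarray, k: int) -> float:
    """Hypergeometric expectation of the allele count in 2k gene copies."""
    alleles, counts = np.unique(genotypes.ravel(), return_counts=True)
    N = counts.sum()
    g = 2 * k
    if g > N:
        raise ValueError("rarefaction size exceeds sample")
    # E[A_g] = sum_a 1 - C(N - N_a, g) / C(N, g)
    log_denom = gammaln(N + 1) - gammaln(g + 1) - gammaln(N - g + 1)
    out = 0.0
    for c in counts:
        if N - c < g:
            out += 1.0
            continue
        log_num = gammaln(N - c + 1) - gammaln(g + 1) - gammaln(N - c - g + 1)
        out += 1.0 - np.exp(log_num - log_denom)
    return float(out)


def ssr_diversity(
    table: SSRGenotypeTable,
    marker_set: str = "all",
    bias_correction: str = "nei1978",
    rarefy: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus and per-population SSR diversity summaries.

    Returns ``(locus_df, pop_df)``.  ``locus_df`` has one row per locus x
    population with the typed sample size, allele count, observed and
    expected heterozygosity.  ``pop_df`` aggregates per population:
    allelic richness A_r (mean allele count over loci; raw by default —
    rarefaction to the smallest sample is applied only when
    ``rarefy=True``), mean/median/quartiles of per-locus H_e.
    Locus x population cells with zero typed individuals are excluded
    with a warning.
    """
    loci_idx = table.locus_indices(marker_set)
    rows = []
    min_typed = None
    if rarefy:
        sizes = [
            len(_locus_pop_genotypes(table, k, j))
            for k in loci_idx for j in range(table.n_populations)
        ]
        min_typed = min(s for s in sizes if s > 0)
    for k in loci_idx:
        locus = table.loci[k]
        for j, pop in enumerate(table.populations):
            g = _locus_pop_genotypes(table, k, j)
            if len(g) == 0:
                warnings.warn(
                    f"locus {locus} has no typed individuals in {pop}; excluded",
                    stacklevel=2,
                )
                continue
            n_alleles = (
                rarefied_allele_count(g, min_typed)
                if rarefy
                else float(len(np.unique(g)))
            )
            rows.append(
                {
                    "locus": locus,
                    "population": pop,
                    "class": table.locus_class.get(locus, ""),
                    "n_typed": len(g),
                    "n_alleles": n_alleles,
                    "ho": observed_heterozygosity(g),
                    "he": expected_heterozygosity(g, bias_correction),
                }
            )
    locus_df = pd.DataFrame(rows)
    grouped = locus_df.groupby("population", sort=False)
    pop_df = grouped.agg(
        a_r=("n_alleles", "mean"),
        ssr_he=("he", "mean"),
        he_median=("he", "median"),
        he_q25=("he", lambda s: s.quantile(0.25)),
        he_q75=("he", lambda s: s.quantile(0.75)),
        n_loci=("locus", "count"),
    ).reset_index()
    return locus_df, pop_df


# ---------------------------------------------------------------------------
# G_IS permutation test (heterozygote deficiency)
# ---------------------------------------------------------------------------

@dataclass
class FisResult:
    """Inbreeding statistic G_IS = 1 - H_o / H_s with a permutation p."""

    scope: str
    gis: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    flag: str | None = None


def _gis_statistic(
    geno_per_locus: Sequence[np.ndarray], bias_correction: str = "nei1978"
) -> float:
    ho_sum = hs_sum = 0.0
    n_loci = 0
    for g in geno_per_locus:
        if len(g) == 0:
            continue
        hs = expected_heterozygosity(g, bias_correction)
        ho_sum += observed_heterozygosity(g)
        hs_sum += hs
        n_loci += 1
    if n_loci == 0 or hs_sum == 0:
        return np.nan
    return 1 - ho_sum / hs_sum


def gis_fis(
    table: SSRGenotypeTable,
    population: str,
    loci: Sequence[str] | None = None,
    marker_set: str = "all",
    n_permutations: int = 999,
    seed: int | None = 0,
) -> FisResult:
    """Permutation test of heterozygote deficiency within a population.

    The observed G_IS = 1 - H_o / H_s (ratio of locus sums; H_s is the
    Nei-corrected gene diversity) is compared against a null
    distribution obtained by re-pairing alleles at random among the
    typed individuals of each locus (allele frequencies preserved,
    genotypic association destroyed).  The one-sided p-value is the
    (+1/+1)-corrected proportion of permuted statistics at least as
    large as the observed one (large G_IS = heterozygote deficiency).
    """
    pop_idx = table.populations.index(population)
    if loci is None:
        loci_idx = table.locus_indices(marker_set)
    else:
        loci_idx = [table.loci.index(l) for l in loci]
    geno = [_locus_pop_genotypes(table, k, pop_idx) for k in loci_idx]
    if all(len(np.unique(g)) <= 1 for g in geno):
        return FisResult(
            scope=f"pop:{population}", gis=np.nan, p_value=np.nan,
            n_permutations=n_permutations, seed=seed, flag="all loci monomorphic",
        )
    n_typed = max((len(g) for g in geno), default=0)
    if n_typed < 2:
        raise ValueError("need at least two typed individuals")
    observed = _gis_statistic(geno)
    rng = np.random.default_rng(seed)
    count = 0
    pools = [g.ravel().copy() for g in geno]
    for _ in range(n_permutations):
        permuted = []
        for alleles in pools:
            rng.shuffle(alleles)
            permuted.append(alleles.reshape(-1, 2))
        if _gis_statistic(permuted) >= observed:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return FisResult(
        scope=f"pop:{population}", gis=float(observed), p_value=float(p),
        n_permutations=n_permutations, seed=seed,
    )


# ---------------------------------------------------------------------------
# null-allele EM (maximum likelihood under HWE with one null allele)
# ---------------------------------------------------------------------------

@dataclass
class NullAlleleResult:
    null_freq: float
    visible_freqs: dict[int, float]
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_typed: int
    n_blank: int


class EMConvergenceError(RuntimeError):
    """EM failed to converge; carries the last iterate."""

    def __init__(self, message: str, last: NullAlleleResult):
        super().__init__(message)
        self.last = last


def null_allele_em(
    genotypes: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> NullAlleleResult:
    """EM estimate of the null-allele frequency at one locus/population.

    Model: true alleles are the visible set plus one null allele; the
    population is at Hardy-Weinberg equilibrium.  Observable classes are
    heterozygotes (i, j), apparent homozygotes (i) — a mixture of true
    (i, i) and (i, null) — and blanks, interpreted as (null, null)
    (missing genotypes are treated as candidate null homozygotes).  The
    EM iterates expected class memberships until the log-likelihood
    change drops below ``tol``.
    """
    g = np.asarray(genotypes)
    blank = (g == 0).any(axis=1)
    typed = g[~blank]
    n_blank = int(blank.sum())
    n_typed = len(typed)
    if n_typed < 10:
        warnings.warn(
            f"only {n_typed} typed individuals; null-allele EM is unreliable",
            stacklevel=2,
        )
    if n_typed == 0:
        raise ValueError("no typed genotypes")
    alleles = np.unique(typed)
    A = len(alleles)
    a_index = {int(a): i for i, a in enumerate(alleles)}
    het_counts = np.zeros((A, A))
    hom_counts = np.zeros(A)
    for a1, a2 in typed:
        i, j = a_index[int(a1)], a_index[int(a2)]
        if i == j:
            hom_counts[i] += 1
        else:
            het_counts[min(i, j), max(i, j)] += 1
    N = n_typed + n_blank

    het_allele_counts = het_counts.sum(axis=0) + het_counts.sum(axis=1)
    obs_counts = 2 * hom_counts + het_allele_counts
    r = 0.05
    p = obs_counts / obs_counts.sum() * (1 - r)

    def loglik(p: np.ndarray, r: float) -> float:
        ll = 0.0
        iu, ju = np.triu_indices(A, k=1)
        hc = het_counts[iu, ju]
        mask = hc > 0
        ll += float(np.sum(hc[mask] * np.log(2 * p[iu[mask]] * p[ju[mask]])))
        mask = hom_counts > 0
        ll += float(np.sum(hom_counts[mask] * np.log(p[mask] ** 2 + 2 * p[mask] * r)))
        if n_blank:
            ll += n_blank * 2 * np.log(max(r, 1e-300))
        return ll

    last_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split apparent homozygotes between (i,i) and (i,null)
        denom = p**2 + 2 * p * r
        with np.errstate(invalid="ignore", divide="ignore"):
            w_ii = np.where(denom > 0, p**2 / np.maximum(denom, 1e-300), 0.0)
        exp_ii = hom_counts * w_ii
        exp_inull = hom_counts * (1 - w_ii)
        # M-step: allele counting
        counts = 2 * exp_ii + het_allele_counts + exp_inull
        null_count = exp_inull.sum() + 2 * n_blank
        total = counts.sum() + null_count
        p = counts / total
        r = null_count / total
        ll = loglik(p, r)
        if abs(ll - last_ll) < tol:
            converged = True
            last_ll = ll
            break
        last_ll = ll
    result = NullAlleleResult(
        null_freq=float(r),
        visible_freqs={int(a): float(p[a_index[int(a)]]) for a in alleles},
        log_likelihood=float(last_ll),
        n_iterations=it,
        converged=converged,
        n_typed=n_typed,
        n_blank=n_blank,
    )
    if not converged:
        raise EMConvergenceError(
            f"null-allele EM did not converge in {max_iter} iterations", result
        )
    return result


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) pairwise F_ST
# ---------------------------------------------------------------------------

def _wc84_components(
    geno_pops: Sequence[np.ndarray],
) -> tuple[float, float, float]:
    """Sum of WC84 variance components a, b, c over alleles at one locus."""
    r = len(geno_pops)
    n_i = np.array([len(g) for g in geno_pops], dtype=float)
    if (n_i == 0).any() or n_i.sum() < r + 1:
        return 0.0, 0.0, 0.0
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in geno_pops]))
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array([(g == allele).sum() / (2 * len(g)) for g in geno_pops])
        h_i = np.array(
            [((g == allele).sum(axis=1) == 1).mean() for g in geno_pops]
        )
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def fst_wc84_pairwise(
    table: SSRGenotypeTable, marker_set: str = "all"
) -> tuple[FstMatrix, pd.DataFrame]:
    """Weir & Cockerham (1984) theta for every population pair.

    Per locus and allele, the among-population (a), among-individual (b)
    and within-individual (c) variance components are accumulated; the
    pairwise multi-locus estimate is the ratio of sums
    sum(a) / sum(a + b + c) over alleles and loci.  Values are reported
    as computed (slightly negative estimates are not clamped).  Returns
    the matrix and a per-locus, per-pair table.
    """
    loci_idx = table.locus_indices(marker_set)
    P = table.n_populations
    if P < 2:
        raise ValueError("need at least two populations")
    values = np.zeros((P, P))
    flags: dict[tuple[str, str], str] = {}
    per_locus_rows = []
    for i in range(1, P):
        for j in range(i):
            num = den = 0.0
            informative = False
            for k in loci_idx:
                gi = _locus_pop_genotypes(table, k, i)
                gj = _locus_pop_genotypes(table, k, j)
                if len(gi) == 0 or len(gj) == 0:
                    continue
                a, b, c = _wc84_components([gj, gi])
                if a + b + c == 0:
                    continue
                informative = True
                num += a
                den += a + b + c
                per_locus_rows.append(
                    {"locus": table.loci[k],
                     "pop_a": table.populations[j],
                     "pop_b": table.populations[i],
                     "theta": a / (a + b + c)}
                )
            if not informative or den == 0:
                values[i, j] = values[j, i] = np.nan
                flags[(table.populations[j], table.populations[i])] = (
                    "no co-typed polymorphic locus"
                )
            else:
                values[i, j] = values[j, i] = num / den
    matrix = FstMatrix(
        labels=list(table.populations), values=values, estimator="WC84", flags=flags
    )
    return matrix, pd.DataFrame(per_locus_rows)


# ---------------------------------------------------------------------------
# marker screening (HWE deviation + null alleles)
# ---------------------------------------------------------------------------

def screen_loci(
    table: SSRGenotypeTable,
    alpha: float = 0.05,
    null_threshold: float = 0.10,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag loci with significant HWE deviation AND high null-allele rate.

    For every locus: the smallest Bonferroni-adjusted one-sided G_IS
    p-value across populations and the mean EM null-allele frequency.
    A locus is flagged for user review when the adjusted p is below
    ``alpha`` and the null frequency is at or above ``null_threshold``;
    the drop decision stays with the user.
    """
    rows = []
    m = table.n_populations
    for locus in table.loci:
        p_vals, null_freqs = [], []
        for pop in table.populations:
            res = gis_fis(
                table, pop, loci=[locus], n_permutations=n_permutations, seed=seed
            )
            if np.isfinite(res.p_value):
                p_vals.append(res.p_value)
            k = table.loci.index(locus)
            g = _locus_pop_genotypes(table, k, table.populations.index(pop))
            if len(g):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        null_freqs.append(null_allele_em(g).null_freq)
                    except EMConvergenceError as err:
                        null_freqs.append(err.last.null_freq)
        p_adj = min(1.0, m * min(p_vals)) if p_vals else np.nan
        null_mean = float(np.mean(null_freqs)) if null_freqs else np.nan
        rows.append(
            {"locus": locus, "hwe_p_adj": p_adj, "null_freq": null_mean,
             "flagged": bool(p_adj < alpha and null_mean >= null_threshold)}
        )
    return pd.DataFrame(rows)
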