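"""SNP down-sampling: heterozygosity accuracy as a function of panel size.

For each panel size k on a grid, random subsamples of k SNPs (without
replacement, the same SNP indices applied to every population within a
replicate) yield a distribution of per-population mean expected
heterozygosities; the 2.5-97.5 percentile band of the replicate means is
the 95% confidence interval.  From the curves one reads off (a) the
smallest k at which the CI half-width falls below +-0.01, +-0.005 and
+-0.001 simultaneously for all populations, and (b) the smallest k at
which all population pairs that genuinely differ have non-overlapping
CIs (pairs whose full-data heterozygosities differ by at most a tie
tolerance are exempted as indistinguishable).

Implementation note: within a replicate the subsets for increasing k are
the prefixes of one random permutation of the SNP panel.  Each prefix of
a uniform random permutation is a uniform random subset of its size, so
the per-k distribution of replicate means is exactly that of independent
uniform subsamples, at a fraction of the cost; replicates are mutually
independent.  SNP keys are sorted (chrom, pos) before sampling so curves
are identical across runs and platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .poolseq import SNPFrequencyTable

#: the default down-sampling grid: 100..10,000 by 100, then to 400,000 by 1,000
def default_grid(n_total: int | None = None) -> np.ndarray:
    grid = np.concatenate(
        [np.arange(100, 10_000, 100), np.arange(10_000, 400_001, 1000)]
    )
    if n_total is not None:
        grid = grid[grid <= n_total]
    return grid


@dataclass
class RarefactionResult:
    """Replicate-mean heterozygosity curves on a shared k grid."""

    populations: list[str]
    k: np.ndarray                    # (G,)
    mean: np.ndarray                 # (G, P)
    ci_low: np.ndarray               # (G, P) 2.5 percentile
    ci_high: np.ndarray              # (G, P) 97.5 percentile
    n_replicates: int
    seed: int
    full_he: pd.Series | None = None

    def half_width(self) -> np.ndarray:
        return (self.ci_high - self.ci_low) / 2

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for j, pop in enumerate(self.populations):
            for g, k in enumerate(self.k):
                rows.append(
                    {"population": pop, "k": int(k), "he_mean": self.mean[g, j],
                     "ci_low": self.ci_low[g, j], "ci_high": self.ci_high[g, j]}
                )
        return pd.DataFrame(rows)


@dataclass
class ThresholdReport:
    """Smallest panel sizes satisfying the accuracy / ranking criteria."""

    k_by_threshold: dict[float, int | None]
    per_population: dict[str, dict[float, int | None]]
    ranking_k: int | None = None
    indistinguishable: list[tuple[str, str]] = field(default_factory=list)
    vacuous: bool = False


def downsample_he(
    table: SNPFrequencyTable,
    grid: np.ndarray | None = None,
    n_replicates: int = 1000,
    seed: int = 0,
) -> RarefactionResult:
    """Down-sampling curves of mean SNP-H_e for every population.

    Grid values beyond the table size are truncated with a warning.
    """
    he = table.he_matrix()
    order = np.lexsort((table.pos, table.chrom))
    he = he[order]
    S, P = he.shape
    if grid is None:
        grid = default_grid(S)
    grid = np.asarray(grid, dtype=np.int64)
    if (np.diff(grid) <= 0).any():
        raise ValueError("grid must be strictly increasing")
    if (grid > S).any():
        import warnings

        warnings.warn(
            f"grid truncated to the {S} available SNPs", stacklevel=2
        )
        grid = grid[grid <= S]
    if len(grid) == 0:
        raise ValueError("empty grid")
    rng = np.random.default_rng(seed)
    means = np.empty((n_replicates, len(grid), P))
    for rep in range(n_replicates):
        perm = rng.permutation(S)
        csum = np.cumsum(he[perm], axis=0)
        means[rep] = csum[grid - 1] / grid[:, None]
    mean = means.mean(axis=0)
    lo = np.percentile(means, 2.5, axis=0)
    hi = np.percentile(means, 97.5, axis=0)
    full = pd.Series(he.mean(axis=0), index=table.populations, name="snp_he")
    return RarefactionResult(
        populations=list(table.populations), k=grid, mean=mean,
        ci_low=lo, ci_high=hi, n_replicates=n_replicates, seed=seed,
        full_he=full,
    )


def k_for_ci_thresholds(
    result: RarefactionResult,
    thresholds: tuple[float, ...] = (0.01, 0.005, 0.001),
) -> ThresholdReport:
    """Smallest k at which every population's CI half-width is within h.

    Reported per threshold; ``None`` when never satisfied on the grid.
    A per-population breakdown is included.
    """
    half = result.half_width()             # (G, P)
    worst = half.max(axis=1)
    k_by: dict[float, int | None] = {}
    for h in thresholds:
        ok = np.flatnonzero(worst <= h)
        k_by[h] = int(result.k[ok[0]]) if len(ok) else None
    per_pop: dict[str, dict[float, int | None]] = {}
    for j, pop in enumerate(result.populations):
        per_pop[pop] = {}
        for h in thresholds:
            ok = np.flatnonzero(half[:, j] <= h)
            per_pop[pop][h] = int(result.k[ok[0]]) if len(ok) else None
    return ThresholdReport(k_by_threshold=k_by, per_population=per_pop)


def k_for_ranking(
    result: RarefactionResult,
    full_he: pd.Series | None = None,
    tie_tolerance: float = 0.0005,
) -> ThresholdReport:
    """Smallest k at which all genuinely different populations separate.

    Population pairs whose full-data mean heterozygosities differ by at
    most ``tie_tolerance`` are declared indistinguishable and exempted;
    the reported k is the smallest grid value at which every non-exempt
    pair has non-overlapping 95% CIs.  With no non-exempt pairs the
    first grid point is reported and the result flagged vacuous.
    """
    if full_he is None:
        full_he = result.full_he
    if full_he is None:
        raise ValueError("full-data heterozygosities required")
    pops = result.populations
    ties: list[tuple[str, str]] = []
    active: list[tuple[int, int]] = []
    for i in range(1, len(pops)):
        for j in range(i):
            if abs(full_he[pops[i]] - full_he[pops[j]]) <= tie_tolerance:
                ties.append((pops[j], pops[i]))
            else:
                active.append((j, i))
    report = ThresholdReport(
        k_by_threshold={}, per_population={}, indistinguishable=ties
    )
    if not active:
        report.ranking_k = int(result.k[0])
        report.vacuous = True
        return report
    lo, hi = result.ci_low, result.ci_high
    for g in range(len(result.k)):
        separated = all(
            lo[g, i] > hi[g, j] or lo[g, j] > hi[g, i] for j, i in active
        )
        if separated:
            report.ranking_k = int(result.k[g])
            break
    return report
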