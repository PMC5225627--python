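"""Statistical comparison battery between marker types and estimators.

Thin, explicit wrappers over scipy primitives plus two permutation
procedures implemented here: the Mantel test on distance/differentiation
matrices and the against-zero test for Tajima's D that compares the
observed per-gene values with a pseudo-sample drawn from a normal
distribution with mean zero and the observed standard deviation (a
deliberately literal implementation of the emulated workflow; a
conventional one-sample t-test is available via ``one_sample=True``).

Every permutation or pseudo-sample operation records its seed so results
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .results import FstMatrix


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: int
    sidedness: str
    p_adjusted: float | None = None
    adjust_method: str | None = None
    seed: int | None = None
    flag: str | None = None

    def to_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "adjust_method": self.adjust_method,
            "n": self.n,
            "sidedness": self.sidedness,
            "seed": self.seed,
            "flag": self.flag,
        }


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment min(1, m * p); monotone in p."""
    return min(1.0, m * p)


def correlation_test(
    x: Sequence[float], y: Sequence[float], method: str = "pearson",
    name: str | None = None,
) -> TestResult:
    """Pearson r or Spearman rho (midranks for ties), two-sided p.

    The p-value uses the t approximation with n - 2 degrees of freedom.
    Zero variance in either variable yields a flagged, undefined result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    label = name or f"{method} correlation"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(label, np.nan, np.nan, len(x), "two-sided",
                          flag="zero variance")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(label, float(r), float(p), len(x), "two-sided")


def paired_t_test(
    a: Sequence[float], b: Sequence[float], name: str = "paired t"
) -> TestResult:
    """Two-sided paired t-test on per-unit differences (df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = a - b
    if np.ptp(d) == 0:
        return TestResult(name, np.nan, np.nan, len(a), "two-sided",
                          flag="zero-variance differences")
    t, p = stats.ttest_rel(a, b)
    return TestResult(name, float(t), float(p), len(a), "two-sided")


def pairwise_wilcoxon(
    values: pd.DataFrame, adjust: str = "bonferroni"
) -> list[TestResult]:
    """Wilcoxon signed-rank tests on per-locus values for every column pair.

    ``values`` is a loci x populations table (rows paired across
    columns).  Zero differences are dropped; ties get midranks; the p is
    exact for n <= 25 pairs and a continuity-corrected normal
    approximation otherwise.  With ``adjust='bonferroni'`` each p is
    multiplied by the number of pairs (capped at 1).
    """
    cols = list(values.columns)
    if len(values) < 6:
        raise ValueError("need at least 6 paired loci for a meaningful test")
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    m = len(pairs)
    results = []
    for a, b in pairs:
        d = values[a].to_numpy(dtype=float) - values[b].to_numpy(dtype=float)
        d = d[d != 0]
        if len(d) == 0:
            res = TestResult(f"wilcoxon {a} vs {b}", np.nan, 1.0, 0, "two-sided",
                             flag="all differences zero")
        else:
            method = "exact" if len(d) <= 25 else "approx"
            stat, p = stats.wilcoxon(
                d, zero_method="wilcox", correction=True, method=method
            )
            res = TestResult(f"wilcoxon {a} vs {b}", float(stat), float(p),
                             len(d), "two-sided")
        if adjust == "bonferroni":
            res.p_adjusted = bonferroni(res.p_value, m) if np.isfinite(res.p_value) else 1.0
            res.adjust_method = "bonferroni"
        results.append(res)
    return results


def mantel_test(
    a: FstMatrix,
    b: FstMatrix,
    n_permutations: int = 1001,
    seed: int = 0,
    alternative: str = "greater",
) -> TestResult:
    """Mantel permutation test between two differentiation matrices.

    The statistic is the Pearson correlation of the n(n-1)/2
    lower-triangle entries; the null distribution permutes the row and
    column labels of the second matrix jointly.  One-sided (positive
    association) by default, with p = (1 + #{r_perm >= r}) /
    (1 + n_permutations), which can never be zero.
    """
    if a.labels != b.labels:
        raise ValueError("matrices must share labels in the same order")
    k = len(a.labels)
    tri = np.tril_indices(k, k=-1)
    x = a.values[tri]
    vb = b.values
    y = vb[tri]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("mantel", np.nan, np.nan, len(x), alternative,
                          seed=seed, flag="zero variance")
    observed = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        yp = vb[np.ix_(perm, perm)][tri]
        r = stats.pearsonr(x, yp)[0]
        if alternative == "greater":
            extreme = r >= observed
        elif alternative == "two-sided":
            extreme = abs(r) >= abs(observed)
        else:
            extreme = r <= observed
        count += bool(extreme)
    p = (count + 1) / (n_permutations + 1)
    return TestResult("mantel", observed, float(p), len(x), alternative, seed=seed)


def tajima_zero_test(
    per_gene_d: Sequence[float],
    seed: int = 0,
    one_sample: bool = False,
) -> TestResult:
    """Test whether the per-gene Tajima's D distribution departs from zero.

    Default behaviour: Welch two-sample t-test between the observed
    values and an equal-size pseudo-sample drawn from
    Normal(0, sd(observed)) with the recorded seed — the procedure is
    stochastic by design.  ``one_sample=True`` gives the conventional
    one-sample t-test against zero instead.
    """
    d = np.asarray(per_gene_d, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 10:
        raise ValueError("need at least 10 genes")
    if d.std(ddof=1) == 0:
        return TestResult("tajima-vs-zero", np.nan, np.nan, len(d), "two-sided",
                          seed=seed, flag="zero variance")
    if one_sample:
        t, p = stats.ttest_1samp(d, 0.0)
        return TestResult("tajima-vs-zero (one-sample)", float(t), float(p),
                          len(d), "two-sided")
    rng = np.random.default_rng(seed)
    pseudo = rng.normal(0.0, d.std(ddof=1), size=len(d))
    t, p = stats.ttest_ind(d, pseudo, equal_var=False)
    return TestResult("tajima-vs-zero", float(t), float(p), len(d), "two-sided",
                      seed=seed)


def results_table(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
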