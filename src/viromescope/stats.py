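"""Two-group hypothesis tests: Mann-Whitney U, 2x2 chi-squared, Bonferroni,
and a Metastats-style two-part differential-abundance test.

The chi-squared test deliberately applies NO Yates continuity correction by
default: the uncorrected Pearson statistic is the convention for cohort
demographics tables of the kind this module targets (a corrected variant is
available by flag).

The differential-abundance test follows the classic two-part design for
sparse microbiome features: common features get an unequal-variance t
statistic with a group-label permutation p-value; features with too few
nonzero observations fall back to Fisher's exact test on detection counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "mann_whitney",
    "chi_squared_2x2",
    "fisher_exact_2x2",
    "bonferroni",
    "metastats_test",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b / c,d with optional margin labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("grand total must be >= 1")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class TestResult:
    method: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    group_summary: dict | None = None
    n_permutations: int | None = None


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test with midrank ties.

    Exact p by enumeration when the combined sample size is at most 12 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return TestResult(
        method=f"mann_whitney_{method}",
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        group_summary={
            "median_x": float(np.median(x)),
            "median_y": float(np.median(y)),
            "n_x": int(x.size),
            "n_y": int(y.size),
        },
    )


def chi_squared_2x2(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    continuity_correction: bool = False,
) -> TestResult:
    """Pearson chi-squared test of independence on a 2x2 table (df = 1).

    Expected counts are derived from the margins and must all be positive.
    No Yates correction by default.
    """
    arr = table.to_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if arr.sum() <= 0 or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    chi2, p, dof, expected = sps.chi2_contingency(arr, correction=continuity_correction)
    if (expected <= 0).any():
        raise ValueError("all expected counts must be positive")
    return TestResult(method="chi_squared_pearson", statistic=float(chi2), p_raw=float(p))


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> TestResult:
    arr = table.to_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(method="fisher_exact", statistic=float(odds), p_raw=float(p))


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)``; order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(1.0, p * p.size)


# ---------------------------------------------------------------------------
# Metastats-style differential abundance


def _welch_t(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Vectorized unequal-variance t statistic per feature (columns)."""
    n1, n2 = X1.shape[0], X2.shape[0]
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    v1 = X1.var(axis=0, ddof=1) / n1
    v2 = X2.var(axis=0, ddof=1) / n2
    denom = np.sqrt(v1 + v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    t[np.isnan(t)] = 0.0  # identical values in both groups -> no evidence
    return t


def metastats_test(
    matrix: pd.DataFrame,
    groups: Sequence[str] | pd.Series,
    n_perm: int = 1000,
    sparse_min_nonzero: int = 4,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Two-part differential-abundance test over a samples x features matrix.

    Non-sparse features (at least ``sparse_min_nonzero`` nonzero samples
    overall) are tested with a Welch t statistic whose two-sided p-value
    comes from ``n_perm`` group-label permutations (add-one estimator, all
    features sharing each permutation). Sparse features use Fisher's exact
    test on the 2x2 table of group x detected/undetected. All-zero features
    are reported with method "none" and NaN p.

    Returns a DataFrame indexed by feature with columns ``method``,
    ``statistic``, ``p_raw``, ``mean_<group1>``, ``mean_<group2>``.
    """
    groups = pd.Series(np.asarray(groups), index=matrix.index) if not isinstance(groups, pd.Series) else groups
    labels = groups.loc[matrix.index].to_numpy()
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = uniq
    mask1 = labels == g1
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    X = matrix.to_numpy(dtype=float)
    nonzero = (X != 0).sum(axis=0)
    common = nonzero >= sparse_min_nonzero
    sparse = (nonzero > 0) & ~common

    out = pd.DataFrame(
        index=matrix.columns,
        data={
            "method": "none",
            "statistic": np.nan,
            "p_raw": np.nan,
            f"mean_{g1}": X[mask1].mean(axis=0),
            f"mean_{g2}": X[~mask1].mean(axis=0),
        },
    )

    if common.any():
        Xc = X[:, common]
        t_obs = _welch_t(Xc[mask1], Xc[~mask1])
        rng = np.random.default_rng(rng_seed)
        extreme = np.zeros(Xc.shape[1], dtype=int)
        for _ in range(n_perm):
            pm = rng.permutation(mask1)
            t_b = _welch_t(Xc[pm], Xc[~pm])
            extreme += np.abs(t_b) >= np.abs(t_obs)
        p = (1 + extreme) / (1 + n_perm)
        cols = matrix.columns[common]
        out.loc[cols, "method"] = "welch_permutation"
        out.loc[cols, "statistic"] = t_obs
        out.loc[cols, "p_raw"] = p

    for f in matrix.columns[sparse]:
        col = matrix[f].to_numpy(dtype=float)
        det1, det2 = int((col[mask1] != 0).sum()), int((col[~mask1] != 0).sum())
        tab = [[det1, int(mask1.sum()) - det1], [det2, int((~mask1).sum()) - det2]]
        res = fisher_exact_2x2(tab)
        out.loc[f, "method"] = "fisher_exact"
        out.loc[f, "statistic"] = res.statistic
        out.loc[f, "p_raw"] = res.p_raw

    out.attrs["n_permutations"] = n_perm
    out.attrs["groups"] = (str(g1), str(g2))
    return out
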