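"""Community ecology statistics: diversity, ordination, permutation fits.

Covers the between-group comparison toolkit of a two-group virome study:
alpha diversity (richness, Shannon's H in nats, Pielou's J), Bray-Curtis
dissimilarity, principal coordinates analysis, envfit-style permutation
fitting of factors and continuous vectors onto the ordination, Spearman
Mantel tests between distance matrices, UPGMA dendrograms, and the
metabolomics preprocessing steps (autoscaling, >=50%-presence filter).

All permutation p-values use the add-one estimator
``p = (1 + #extreme) / (1 + n_perm)``, so they are never zero and are
bounded below by ``1/(n_perm + 1)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaDiversity",
    "DistanceMatrix",
    "OrdinationResult",
    "FitResult",
    "alpha_diversity",
    "alpha_diversity_table",
    "bray_curtis",
    "euclidean_distance",
    "pcoa",
    "factor_fit",
    "vector_fit",
    "mantel",
    "upgma",
    "autoscale",
    "presence_filter",
]


# ---------------------------------------------------------------------------
# Containers


@dataclass(frozen=True)
class AlphaDiversity:
    richness: int
    shannon_h: float  # nats
    pielou_j: float


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample ids."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        self.data = d

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def subset(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in keep]
        return DistanceMatrix(list(keep), self.data[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    proportion_explained: np.ndarray  # over positive eigenvalues

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class FitResult:
    """Effect size and permutation p-value of one fitted factor/vector/test."""

    name: str
    effect: float  # r^2 or correlation r
    p_raw: float
    n_permutations: int
    p_adjusted: float | None = None
    direction: np.ndarray | None = None  # vector fits only


# ---------------------------------------------------------------------------
# Alpha diversity


def alpha_diversity(abundance_row: Sequence[float]) -> AlphaDiversity:
    """Richness, Shannon's H (nats) and Pielou's J of one abundance profile.

    The row is normalized to proportions internally; J = H / ln(S) for
    S >= 2 and 0 otherwise.
    """
    x = np.asarray(abundance_row, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        warnings.warn("all-zero abundance row: diversity set to 0")
        return AlphaDiversity(0, 0.0, 0.0)
    p = x[x > 0] / total
    s = int(p.size)
    h = float(-(p * np.log(p)).sum())
    j = float(h / np.log(s)) if s >= 2 else 0.0
    return AlphaDiversity(s, h, j)


def alpha_diversity_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha diversity of a samples x features matrix."""
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid, row in matrix.iterrows():
            a = alpha_diversity(row.to_numpy())
            rows[sid] = {"richness": a.richness, "shannon_h": a.shannon_h, "pielou_j": a.pielou_j}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Distances


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample rows.

    ``d(x, y) = sum|x - y| / sum(x + y)``; a pair of all-zero rows is
    assigned distance 0 with a warning. Negative entries are rejected —
    autoscaled intensity data should be min-shifted per feature first.
    """
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError(
            "Bray-Curtis requires non-negative data; min-shift scaled intensities per feature first"
        )
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(vals, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero row pair(s): Bray-Curtis distance defined as 0")
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(list(matrix.index), d)


def euclidean_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    return DistanceMatrix(list(matrix.index), squareform(pdist(matrix.to_numpy(dtype=float))))


# ---------------------------------------------------------------------------
# Ordination


def pcoa(D: DistanceMatrix, eig_tol_rel: float = 1e-12) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    ``B = -1/2 J (D o D) J`` is eigendecomposed; axes with eigenvalues above
    a relative tolerance are retained and scaled by the square root of their
    eigenvalue. Negative eigenvalues are reported in ``eigenvalues`` but
    contribute no axes. Each axis's sign is fixed so its largest-magnitude
    loading is positive.
    """
    n = len(D)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    a = -0.5 * D.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0e-300) * eig_tol_rel
    keep = eigvals > tol
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    for ax in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, ax]))
        if coords[i, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    pos_sum = eigvals[keep].sum()
    prop = eigvals[keep] / pos_sum if pos_sum > 0 else np.array([])
    return OrdinationResult(list(D.ids), coords, eigvals, prop)


# ---------------------------------------------------------------------------
# Permutation fitting (envfit-style)


def _check_axes(ordination: OrdinationResult, n_axes: int) -> np.ndarray:
    if ordination.n_axes == 0:
        raise ValueError("ordination has no retained axes")
    return ordination.coordinates[:, : min(n_axes, ordination.n_axes)]


def _factor_r2(X: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss_total = ((X - X.mean(axis=0)) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_within = 0.0
    for g in range(n_groups):
        sub = X[codes == g]
        ss_within += ((sub - sub.mean(axis=0)) ** 2).sum()
    return 1.0 - ss_within / ss_total


def factor_fit(
    ordination: OrdinationResult,
    labels: Sequence[str],
    n_perm: int = 9999,
    n_axes: int = 2,
    rng_seed: int = 0,
    name: str = "factor",
) -> FitResult:
    """Permutation test of group-centroid separation in ordination space.

    The statistic is ``r^2 = 1 - SS_within / SS_total`` of the first
    ``n_axes`` coordinates; the null distribution shuffles group labels.
    """
    X = _check_axes(ordination, n_axes)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels length does not match ordination")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("factor_fit needs at least 2 groups")
    if (np.bincount(codes) < 2).any():
        raise ValueError("each group needs at least 2 samples")
    r2_obs = _factor_r2(X, codes, len(uniq))
    rng = np.random.default_rng(rng_seed)
    extreme = 0
    for _ in range(n_perm):
        if _factor_r2(X, rng.permutation(codes), len(uniq)) >= r2_obs:
            extreme += 1
    p = (1 + extreme) / (1 + n_perm)
    return FitResult(name=name, effect=r2_obs, p_raw=p, n_permutations=n_perm)


def vector_fit(
    ordination: OrdinationResult,
    variable: Sequence[float],
    n_perm: int = 9999,
    n_axes: int = 2,
    rng_seed: int = 0,
    name: str = "vector",
) -> FitResult:
    """Permutation test of a continuous variable's fit to ordination axes.

    Least-squares regression of the variable on the first ``n_axes``
    coordinates; effect is the regression r^2 and ``direction`` the unit
    coefficient vector. The variable is permuted across samples.
    """
    X = _check_axes(ordination, n_axes)
    y = np.asarray(variable, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("variable length does not match ordination")
    if np.ptp(y) == 0:
        raise ValueError("variable is constant")
    Xc = X - X.mean(axis=0)
    q, _ = np.linalg.qr(Xc)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    proj = q.T @ yc
    r2_obs = float(proj @ proj) / ss_tot
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    norm = np.linalg.norm(coef)
    direction = coef / norm if norm > 0 else coef
    rng = np.random.default_rng(rng_seed)
    extreme = 0
    for _ in range(n_perm):
        yp = yc[rng.permutation(len(yc))]
        pr = q.T @ yp
        if float(pr @ pr) / ss_tot >= r2_obs:
            extreme += 1
    p = (1 + extreme) / (1 + n_perm)
    return FitResult(name=name, effect=r2_obs, p_raw=p, n_permutations=n_perm, direction=direction)


# ---------------------------------------------------------------------------
# Mantel test


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    rng_seed: int = 0,
    name: str = "mantel",
) -> FitResult:
    """Mantel correlation between two distance matrices over the same samples.

    The statistic correlates upper-triangle entries (Spearman by default);
    the null distribution simultaneously permutes rows and columns of the
    second matrix. The p-value is one-sided for ``r >= r_obs``.
    """
    if D1.ids != D2.ids:
        raise ValueError("distance matrices must share ids in the same order")
    n = len(D1)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    iu = np.triu_indices(n, k=1)
    x = D1.data[iu]
    if method == "spearman":
        x = rankdata(x)
    x = x - x.mean()
    x_norm = np.sqrt((x**2).sum())

    def corr_with(d2: np.ndarray) -> float:
        y = d2[iu]
        if method == "spearman":
            y = rankdata(y)
        y = y - y.mean()
        denom = x_norm * np.sqrt((y**2).sum())
        return float(x @ y / denom) if denom > 0 else 0.0

    r_obs = corr_with(D2.data)
    rng = np.random.default_rng(rng_seed)
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(D2.data[np.ix_(perm, perm)]) >= r_obs:
            extreme += 1
    p = (1 + extreme) / (1 + n_perm)
    return FitResult(name=name, effect=r_obs, p_raw=p, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Hierarchical clustering (UPGMA)


def upgma(D: DistanceMatrix) -> str:
    """Average-linkage agglomerative tree of the distance matrix, as Newick.

    Deterministic: at every step the pair with the smallest distance is
    merged, ties broken by the lexicographically smallest pair of cluster
    labels (a cluster is labelled by its smallest leaf id). Ultrametric
    branch lengths place each merge at half the cluster distance.
    """
    n = len(D)
    if n == 1:
        return f"{D.ids[0]};"
    # active clusters: label -> (newick, size, height, index set)
    clusters: dict[str, tuple[str, int, float]] = {i: (i, 1, 0.0) for i in D.ids}
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((D.ids[i], D.ids[j]))] = float(D.data[i, j])
    newick = {i: i for i in D.ids}
    size = {i: 1 for i in D.ids}
    height = {i: 0.0 for i in D.ids}
    active = sorted(D.ids)
    while len(active) > 1:
        best = None
        for a_i in range(len(active)):
            for a_j in range(a_i + 1, len(active)):
                a, b = active[a_i], active[a_j]
                d = dist[frozenset((a, b))]
                key = (d, *sorted((a, b)))
                if best is None or key < best:
                    best = key
        d, a, b = best
        h = d / 2.0
        la, lb = h - height[a], h - height[b]
        merged = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        label = min(a, b)
        other = [c for c in active if c not in (a, b)]
        for c in other:
            dc = (
                size[a] * dist[frozenset((a, c))] + size[b] * dist[frozenset((b, c))]
            ) / (size[a] + size[b])
            dist[frozenset((label, c))] = dc
        newick[label] = merged
        size[label] = size[a] + size[b]
        height[label] = h
        active = sorted(other + [label])
    return f"{newick[active[0]]};"


# ---------------------------------------------------------------------------
# Intensity-matrix preprocessing


def autoscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean-centering and unit (sample) standard deviation.

    Constant features cannot be scaled and are dropped with a warning.
    """
    sd = matrix.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature(s): {constant[:5]}")
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(constant)
    return (matrix - matrix.mean(axis=0)) / sd


def presence_filter(
    matrix: pd.DataFrame, min_fraction: float = 0.5, sentinel: float = 0.0
) -> pd.DataFrame:
    """Keep features detected in at least ``min_fraction`` of samples.

    Detection means a value different from ``sentinel`` (and not NaN); the
    boundary is inclusive, so a feature present in exactly half the samples
    is retained at the default threshold.
    """
    detected = matrix.notna() & (matrix != sentinel)
    frac = detected.sum(axis=0) / len(matrix)
    return matrix.loc[:, frac >= min_fraction]
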