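"""Compositional co-occurrence networks: CLR transform + Meinshausen-Buhlmann
neighborhood selection.

Relative-abundance data are compositional, so raw correlations are
spurious; the centered log-ratio (CLR) transform removes the per-sample
scale before any association is estimated. The network is then built by
regressing each feature on all others with an L1 penalty: feature i is a
neighbor of j when its coefficient in j's lasso model is nonzero, and the
two directed neighborhoods are symmetrized by OR (default) or AND.

The penalty is either supplied or picked from a fixed log-spaced grid
(10 values spanning two decades below the smallest penalty that empties
the graph) at the knee of the edge-count curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

__all__ = [
    "ClrMatrix",
    "AdjacencyMatrix",
    "ClusterResult",
    "clr_transform",
    "default_pseudocount",
    "lambda_grid",
    "mb_network",
    "select_lambda_knee",
    "detect_clusters",
]


@dataclass
class ClrMatrix:
    """Samples x features CLR-transformed matrix (rows sum to ~0)."""

    data: pd.DataFrame
    pseudocount: float

    def __post_init__(self) -> None:
        rs = self.data.to_numpy().sum(axis=1)
        if np.abs(rs).max() > 1e-9 * max(1.0, np.abs(self.data.to_numpy()).max()):
            raise ValueError("CLR rows must sum to 0")


@dataclass
class AdjacencyMatrix:
    """Boolean feature x feature adjacency with the penalty that produced it."""

    data: pd.DataFrame  # bool, symmetric, zero diagonal
    lambda_: float
    symmetrize: str

    def __post_init__(self) -> None:
        a = self.data.to_numpy()
        if not (a == a.T).all():
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_edges(self) -> int:
        return int(self.data.to_numpy().sum() // 2)

    def edge_list(self) -> list[tuple[str, str]]:
        feats = list(self.data.columns)
        a = self.data.to_numpy()
        return [
            (feats[i], feats[j])
            for i in range(len(feats))
            for j in range(i + 1, len(feats))
            if a[i, j]
        ]


@dataclass
class ClusterResult:
    labels: pd.Series  # feature -> component label, -1 for singletons ("noise")
    sizes: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def default_pseudocount(matrix: pd.DataFrame) -> float:
    """Pseudocount heuristic: 1 for count-like data, half the smallest nonzero
    value for relative data."""
    vals = matrix.to_numpy(dtype=float)
    nz = vals[vals > 0]
    if nz.size == 0:
        raise ValueError("matrix has no positive entries")
    if np.allclose(vals, np.round(vals)) and nz.min() >= 1:
        return 1.0
    return float(nz.min()) / 2.0


def clr_transform(matrix: pd.DataFrame, pseudocount: float | None = None) -> ClrMatrix:
    """Centered log-ratio transform ``z = ln(x + pc) - mean_row(ln(x + pc))``."""
    if pseudocount is None:
        pseudocount = default_pseudocount(matrix)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("matrix must be non-negative")
    logs = np.log(vals + pseudocount)
    z = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(pd.DataFrame(z, index=matrix.index, columns=matrix.columns), pseudocount)


def _as_frame(clr: "ClrMatrix | pd.DataFrame") -> pd.DataFrame:
    """Accept either a ClrMatrix or an already-transformed feature DataFrame."""
    return clr.data if isinstance(clr, ClrMatrix) else clr


def _standardized(clr: "ClrMatrix | pd.DataFrame") -> tuple[np.ndarray, np.ndarray]:
    X = _as_frame(clr).to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    ok = sd > 0
    Xs = np.zeros_like(Xc)
    Xs[:, ok] = Xc[:, ok] / sd[ok]
    return Xs, ok


def lambda_grid(clr: "ClrMatrix | pd.DataFrame", n_values: int = 10, decades: float = 2.0) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max (empty graph) down ``decades``.

    ``lambda_max = max_j max_{i != j} |x_i^T x_j| / n`` on standardized
    columns — the smallest penalty at which every lasso neighborhood is empty.
    """
    Xs, _ = _standardized(clr)
    n = Xs.shape[0]
    corr = np.abs(Xs.T @ Xs) / n
    np.fill_diagonal(corr, 0.0)
    lam_max = float(corr.max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 10.0**-decades, n_values)


def _neighborhoods(Xs: np.ndarray, ok: np.ndarray, lam: float, tol: float = 1e-6) -> np.ndarray:
    """Directed neighborhood matrix: entry (i, j) True when feature i has a
    nonzero coefficient in feature j's lasso regression."""
    n, p = Xs.shape
    nb = np.zeros((p, p), dtype=bool)
    model = Lasso(alpha=lam, fit_intercept=False, tol=tol, max_iter=5000)
    others_cache = np.arange(p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for j in range(p):
            if not ok[j]:
                continue
            others = others_cache[(others_cache != j) & ok]
            if others.size == 0:
                continue
            model.fit(Xs[:, others], Xs[:, j])
            nz = others[np.abs(model.coef_) > 1e-8]
            nb[nz, j] = True
    return nb


def mb_network(
    clr: "ClrMatrix | pd.DataFrame",
    lambda_: float | str = "auto",
    symmetrize: str = "or",
    tol: float = 1e-6,
) -> AdjacencyMatrix:
    """Neighborhood-selection association network on CLR data.

    Each feature is regressed on all others with an L1 penalty
    (coordinate-descent lasso on standardized predictors); an undirected
    edge joins i and j when either (OR, default) or both (AND) directed
    neighborhoods contain the other. ``lambda_="auto"`` picks the knee of
    the edge-count curve over the default grid.
    """
    if symmetrize not in ("or", "and"):
        raise ValueError("symmetrize must be 'or' or 'and'")
    frame = _as_frame(clr)
    if frame.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    if lambda_ == "auto":
        lam = select_lambda_knee(clr)
    else:
        lam = float(lambda_)
        if lam < 0:
            raise ValueError("lambda must be >= 0")
    Xs, ok = _standardized(frame)
    nb = _neighborhoods(Xs, ok, lam, tol=tol)
    adj = (nb | nb.T) if symmetrize == "or" else (nb & nb.T)
    np.fill_diagonal(adj, False)
    feats = list(frame.columns)
    return AdjacencyMatrix(pd.DataFrame(adj, index=feats, columns=feats), lam, symmetrize)


def select_lambda_knee(clr: "ClrMatrix | pd.DataFrame", grid: np.ndarray | None = None) -> float:
    """Pick the penalty at the knee of the edge-count-vs-penalty curve.

    Edge counts are computed over the decreasing penalty grid. Because the
    path always ends dense (noise edges explode at small penalties), the
    knee is sought only in the sparse regime — the initial run of grid
    points whose edge count is at most twice the feature count (average
    degree <= 4). Within that prefix the knee is the end of the longest
    plateau: the longest run of consecutive grid points with an identical
    edge count, ties resolved toward larger penalties. A stable edge set
    across a stretch of penalties indicates real structure; for
    structure-free data the longest plateau is the initial empty stretch,
    so the selected graph stays (near-)empty.
    """
    if grid is None:
        grid = lambda_grid(clr)
    Xs, ok = _standardized(clr)
    counts = []
    for lam in grid:
        nb = _neighborhoods(Xs, ok, lam)
        adj = nb | nb.T
        counts.append(int(adj.sum() // 2))
    counts = np.asarray(counts, dtype=int)
    p = Xs.shape[1]
    budget = 2 * p  # sparse regime: average degree <= 4
    over = np.flatnonzero(counts > budget)
    prefix_end = int(over[0]) if over.size else len(counts)  # initial sparse run
    if prefix_end == 0:
        return float(grid[0])
    y = counts[:prefix_end]
    best_start, best_len = 0, 1
    run_start = 0
    for i in range(1, len(y)):
        if y[i] != y[run_start]:
            run_start = i
        run_len = i - run_start + 1
        if run_len > best_len:
            best_start, best_len = run_start, run_len
    return float(grid[best_start + best_len - 1])


def detect_clusters(adjacency: AdjacencyMatrix) -> ClusterResult:
    """Connected components of the association graph.

    Singletons are labelled -1 (noise); multi-feature components get
    consecutive labels ordered by decreasing size.
    """
    a = adjacency.data.to_numpy()
    n_comp, raw = connected_components(a, directed=False)
    feats = list(adjacency.data.columns)
    sizes_raw = np.bincount(raw)
    multi = [c for c in range(n_comp) if sizes_raw[c] >= 2]
    multi.sort(key=lambda c: -sizes_raw[c])
    relabel = {c: i for i, c in enumerate(multi)}
    labels = pd.Series(
        [relabel.get(c, -1) for c in raw], index=feats, name="cluster", dtype=int
    )
    sizes = {relabel[c]: int(sizes_raw[c]) for c in multi}
    return ClusterResult(labels=labels, sizes=sizes)
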