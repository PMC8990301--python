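"""Coarse-graining of lattice dynamics and causal-network inference.

The full excitation history of the tissue lattice is reduced to a small
regular grid of sample nodes (default ``10 x 10``), each summarizing the
mean activity of a ``3 x 3`` neighborhood of cells.  A directed functional
network is then inferred between node time series: an edge ``i -> j`` is
retained when the lagged partial correlation between ``i``'s past and
``j``'s present — conditioning on ``j``'s own past, the classic bivariate
Granger-causality construction — exceeds a threshold (default 0.001, i.e.
0.1%).  Each retained edge is weighted by the cross-correlation of the two
node series, maximized in absolute value over non-negative lags with the
sign preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cardioergm.simulator import StateSeries

__all__ = [
    "NodeSeries",
    "CausalNetwork",
    "coarse_grain",
    "causal_links",
    "edge_weights",
    "cross_correlation",
    "spatial_support",
    "build_network",
]


@dataclass
class NodeSeries:
    """Activity of the coarse-grained sample nodes over time.

    ``activity[i, t]`` is the mean encoded cell state over node ``i``'s
    neighborhood block at step ``t`` and lies in ``[0, 1]``.
    ``node_coords[i]`` holds the (row, col) lattice coordinates of the
    node's center cell.
    """

    activity: np.ndarray  # (n_nodes, T) float
    node_coords: np.ndarray  # (n_nodes, 2) int
    grid_shape: tuple[int, int]
    encoding: str = "binary"

    @property
    def n_nodes(self) -> int:
        return self.activity.shape[0]

    @property
    def n_steps(self) -> int:
        return self.activity.shape[1]


@dataclass
class CausalNetwork:
    """Directed weighted functional network on grid-embedded nodes.

    ``edges`` has one row per retained directed edge with columns
    ``src, dst, score, weight, lag``: the causality score (partial
    correlation magnitude), the signed cross-correlation weight in
    ``[-1, 1]``, and the lag at which the weight is attained.
    """

    node_coords: np.ndarray  # (n_nodes, 2) int
    edges: pd.DataFrame
    threshold: float
    grid_shape: tuple[int, int] | None = None

    EDGE_COLUMNS = ("src", "dst", "score", "weight", "lag")

    def __post_init__(self) -> None:
        self.edges = self.edges.reset_index(drop=True)
        missing = set(self.EDGE_COLUMNS) - set(self.edges.columns)
        if missing:
            raise ValueError(f"edge table missing columns: {sorted(missing)}")
        if len(self.edges) and (self.edges.src == self.edges.dst).any():
            raise ValueError("causal network must not contain self-loops")

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense binary adjacency matrix (src -> dst)."""
        A = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        if len(self.edges):
            A[self.edges.src.to_numpy(), self.edges.dst.to_numpy()] = 1
        return A

    def weight_matrix(self) -> np.ndarray:
        """Dense signed weight matrix (zero where no edge)."""
        W = np.zeros((self.n_nodes, self.n_nodes), dtype=float)
        if len(self.edges):
            W[self.edges.src.to_numpy(), self.edges.dst.to_numpy()] = (
                self.edges.weight.to_numpy()
            )
        return W

    def restrict(self, mask: np.ndarray) -> "CausalNetwork":
        """Network restricted to candidate edges allowed by ``mask``."""
        mask = np.asarray(mask, dtype=bool)
        keep = mask[self.edges.src.to_numpy(), self.edges.dst.to_numpy()] if len(self.edges) else np.zeros(0, bool)
        return CausalNetwork(
            node_coords=self.node_coords.copy(),
            edges=self.edges[keep].reset_index(drop=True),
            threshold=self.threshold,
            grid_shape=self.grid_shape,
        )

    def to_networkx(self):
        import networkx as nx

        G = nx.DiGraph(threshold=self.threshold)
        if self.grid_shape is not None:
            G.graph["grid_rows"], G.graph["grid_cols"] = self.grid_shape
        for i, (r, c) in enumerate(self.node_coords):
            G.add_node(i, row=int(r), col=int(c))
        for row in self.edges.itertuples(index=False):
            G.add_edge(
                int(row.src),
                int(row.dst),
                score=float(row.score),
                weight=float(row.weight),
                lag=int(row.lag),
            )
        return G


def coarse_grain(
    series: StateSeries,
    grid_rows: int = 10,
    grid_cols: int = 10,
    neighborhood: int = 3,
    encoding: str = "binary",
) -> NodeSeries:
    """Subsample the lattice onto a regular node grid.

    Sample points are placed at uniform spacing (node ``(a, b)`` centered
    at lattice cell ``(a * L/rows + L/(2 rows), ...)``); each node's
    activity at ``t`` is the mean of the encoded cell state over its
    ``neighborhood x neighborhood`` block, truncated at the open
    left/right lattice edges.

    ``encoding="binary"`` uses the fired/not-fired indicator;
    ``encoding="graded"`` uses the refractory counter scaled to ``[0, 1]``
    and requires the series to have been simulated with
    ``record_phase=True``.
    """
    if neighborhood % 2 != 1 or neighborhood < 1:
        raise ValueError("neighborhood must be a positive odd integer")
    L = series.config.L
    if grid_rows > L or grid_cols > L:
        raise ValueError(
            f"grid ({grid_rows}x{grid_cols}) larger than lattice (L={L})"
        )
    if encoding == "binary":
        data = series.excitation.astype(np.float64)
    elif encoding == "graded":
        if series.phase is None:
            raise ValueError(
                "graded encoding requires a series simulated with "
                "record_phase=True"
            )
        tau = series.lattice.tau_cell.astype(np.float64)
        data = series.phase.astype(np.float64) / (tau + 1.0)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")

    half = neighborhood // 2
    r_centers = (np.arange(grid_rows) * L) // grid_rows + L // (2 * grid_rows)
    c_centers = (np.arange(grid_cols) * L) // grid_cols + L // (2 * grid_cols)
    T = data.shape[0]
    n_nodes = grid_rows * grid_cols
    activity = np.empty((n_nodes, T), dtype=np.float64)
    coords = np.empty((n_nodes, 2), dtype=np.int64)
    k = 0
    for r in r_centers:
        r0, r1 = max(0, r - half), min(L, r + half + 1)
        for c in c_centers:
            c0, c1 = max(0, c - half), min(L, c + half + 1)
            activity[k] = data[:, r0:r1, c0:c1].mean(axis=(1, 2))
            coords[k] = (r, c)
            k += 1
    return NodeSeries(
        activity=activity,
        node_coords=coords,
        grid_shape=(grid_rows, grid_cols),
        encoding=encoding,
    )


def _lag_matrix(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Columns ``x(t - 1) .. x(t - max_lag)`` aligned with ``x(t)``,
    ``t = max_lag .. T-1``."""
    T = x.shape[-1]
    return np.stack([x[..., max_lag - ell : T - ell] for ell in range(1, max_lag + 1)], axis=-1)


def causal_links(
    ns: NodeSeries,
    max_lag: int = 25,
    threshold: float = 0.001,
    threshold_mode: str = "absolute",
    alpha: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Directed Granger-causality scores and thresholded adjacency.

    The score of ``i -> j`` is the largest magnitude, over lags
    ``1 .. max_lag``, of the partial correlation between ``activity_i(t -
    lag)`` and ``activity_j(t)`` conditioned on ``activity_j``'s own lags
    ``1 .. max_lag`` (and an intercept).  An edge is retained when its
    score exceeds ``threshold``.

    ``threshold_mode="significance"`` instead retains edges whose best lag
    is significant at level ``alpha`` under the t-distribution null for a
    partial correlation (the alternative reading of a percent cut-off),
    Bonferroni-corrected for the maximization over ``max_lag`` lags;
    ``threshold`` is then ignored.

    Pairs involving a constant (zero-variance) series score 0.  Returns
    ``(scores, adjacency)`` as ``n x n`` arrays with zero diagonals.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if threshold_mode not in ("absolute", "significance"):
        raise ValueError("threshold_mode must be 'absolute' or 'significance'")
    X = np.asarray(ns.activity, dtype=np.float64)
    n, T = X.shape
    if T <= 3 * max_lag:
        raise ValueError(
            f"series length {T} too short: need more than 3 * max_lag "
            f"= {3 * max_lag} steps"
        )
    T_eff = T - max_lag
    eps = 1e-12
    sd = X.std(axis=1)
    live = sd > eps

    y_now = X[:, max_lag:]  # (n, T_eff)
    lags = _lag_matrix(X, max_lag)  # (n, T_eff, max_lag)

    # Predictor columns x_i(t - lag), centered, shared across all targets.
    pred = lags.transpose(1, 0, 2).reshape(T_eff, n * max_lag)
    pred = pred - pred.mean(axis=0)

    scores = np.zeros((n, n), dtype=np.float64)
    df_resid = T_eff - max_lag - 2  # minus conditioning set, intercept, predictor
    for j in range(n):
        if not live[j]:
            continue
        Z = lags[j] - lags[j].mean(axis=0)  # own past, centered
        # pseudo-inverse projection is robust to rank-deficient pasts
        Zpinv = np.linalg.pinv(Z)
        yj = y_now[j] - y_now[j].mean()
        ry = yj - Z @ (Zpinv @ yj)
        ry_norm = np.linalg.norm(ry)
        if ry_norm <= eps:
            continue  # target fully explained by its own past
        rp = pred - Z @ (Zpinv @ pred)
        rp_norms = np.linalg.norm(rp, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pc = (rp.T @ ry) / (rp_norms * ry_norm)
        pc[rp_norms <= eps] = 0.0
        pc = np.abs(pc.reshape(n, max_lag))
        pc[~live, :] = 0.0
        scores[:, j] = pc.max(axis=1)
    np.fill_diagonal(scores, 0.0)
    scores = np.clip(scores, 0.0, 1.0)

    if threshold_mode == "absolute":
        adjacency = scores > threshold
    else:
        from scipy import stats

        # |r| significant at level alpha (two-sided) for df residual dof;
        # Bonferroni over the max_lag lags searched per pair
        tcrit = stats.t.ppf(1 - alpha / (2 * max_lag), df_resid)
        rcrit = tcrit / np.sqrt(tcrit**2 + df_resid)
        adjacency = scores > rcrit
    np.fill_diagonal(adjacency, False)
    return scores, adjacency


def cross_correlation(
    x: np.ndarray, y: np.ndarray, max_lag: int
) -> tuple[float, int]:
    """Signed Pearson cross-correlation of ``x`` leading ``y``.

    Evaluates ``corr(x(t - lag), y(t))`` for ``lag = 0 .. max_lag`` and
    returns ``(value, lag)`` at the lag maximizing the magnitude (ties to
    the smallest lag); the sign is preserved.
    """
    best_val, best_lag = 0.0, 0
    T = len(x)
    for ell in range(0, max_lag + 1):
        xs = x[: T - ell] if ell else x
        ys = y[ell:]
        xs = xs - xs.mean()
        ys = ys - ys.mean()
        denom = np.linalg.norm(xs) * np.linalg.norm(ys)
        if denom <= 1e-12:
            raise ValueError("zero-variance series in cross-correlation")
        r = float(xs @ ys / denom)
        if abs(r) > abs(best_val):
            best_val, best_lag = r, ell
    return best_val, best_lag


def edge_weights(
    ns: NodeSeries,
    adjacency: np.ndarray,
    max_lag: int = 25,
    scores: np.ndarray | None = None,
    threshold: float = 0.001,
) -> CausalNetwork:
    """Attach cross-correlation weights to the retained causal links.

    For each retained edge ``i -> j`` the weight is the cross-correlation
    of the two node series maximized in absolute value over lags
    ``0 .. max_lag`` (sign preserved).  A zero-variance series on a
    retained edge is an error: such pairs should have been excluded by
    :func:`causal_links`.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    if scores is None:
        scores = adjacency.astype(float)
    rows = []
    X = ns.activity
    for i, j in zip(*np.nonzero(adjacency)):
        w, lag = cross_correlation(X[i], X[j], max_lag)
        rows.append(
            {
                "src": int(i),
                "dst": int(j),
                "score": float(scores[i, j]),
                "weight": w,
                "lag": lag,
            }
        )
    edges = pd.DataFrame(rows, columns=list(CausalNetwork.EDGE_COLUMNS))
    edges = edges.astype(
        {"src": np.int64, "dst": np.int64, "lag": np.int64}, errors="ignore"
    )
    return CausalNetwork(
        node_coords=ns.node_coords.copy(),
        edges=edges,
        threshold=float(threshold),
        grid_shape=ns.grid_shape,
    )


def spatial_support(
    node_coords: np.ndarray,
    radius: float,
    lattice_L: int,
    spacing: float | None = None,
) -> np.ndarray:
    """Candidate-edge mask: node pairs within ``radius`` grid units.

    Distance is the Chebyshev distance of the lattice coordinates in
    units of the grid spacing, with the row coordinate wrapped (the
    lattice is periodic top-bottom).  Used as the support of the ERGM
    reference measure: spatially remote functional links are
    inadmissible.
    """
    coords = np.asarray(node_coords, dtype=float)
    if spacing is None:
        uniq = np.unique(coords[:, 1])
        spacing = float(np.diff(uniq).min()) if len(uniq) > 1 else 1.0
    d = np.abs(coords[:, None, :] - coords[None, :, :])
    d_row = np.minimum(d[..., 0], lattice_L - d[..., 0])
    cheb = np.maximum(d_row, d[..., 1]) / spacing
    mask = cheb <= radius + 1e-9
    np.fill_diagonal(mask, False)
    return mask


def build_network(
    series: StateSeries,
    grid_rows: int = 10,
    grid_cols: int = 10,
    neighborhood: int = 3,
    max_lag: int = 25,
    threshold: float = 0.001,
    encoding: str = "binary",
    threshold_mode: str = "absolute",
) -> CausalNetwork:
    """Convenience: coarse-grain a simulation and infer its causal network."""
    ns = coarse_grain(series, grid_rows, grid_cols, neighborhood, encoding)
    scores, adj = causal_links(
        ns, max_lag=max_lag, threshold=threshold, threshold_mode=threshold_mode
    )
    return edge_weights(ns, adj, max_lag=max_lag, scores=scores, threshold=threshold)
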