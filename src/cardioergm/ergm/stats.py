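"""Sufficient statistics, change statistics, and the reference measure.

All statistics are evaluated on a dense matrix ``M`` with zero diagonal:
the 0/1 adjacency in binary mode, or an edge-weight matrix in ``[0, 1]``
in weighted mode (signed correlation weights ``w`` are mapped by
``(w + 1) / 2``).  The binary formulas are the special case of the
weighted ones at weights in {0, 1}:

* ``edges``      = sum of entries,
* ``out2stars``  = sum over nodes of sum_{j<k} M_ij M_ik  (= choose(outdeg, 2)),
* ``in2stars``   = the transpose analogue,
* ``ctriads``    = trace(M^3) / 3, one count per directed 3-cycle,
* ``sender`` / ``receiver`` = covariate of the source / target summed
  (weighted) over edges.
"""

from __future__ import annotations

import numpy as np

from cardioergm.ergm.model import ERGMSpec, ReferenceMeasure

__all__ = [
    "adjacency_matrices",
    "motif_stats",
    "change_stats",
    "change_stat_matrix",
    "violation_count",
    "log_reference_measure",
    "reference_measure",
]


def adjacency_matrices(G) -> tuple[np.ndarray, np.ndarray | None]:
    """Normalize a graph-like input to ``(adjacency, weights or None)``.

    Accepts a :class:`~cardioergm.abstraction.CausalNetwork`, a networkx
    ``DiGraph`` (edge attribute ``weight`` if present), or a square
    ndarray (binary adjacency, or weights with adjacency = nonzero).
    Signed weights in ``[-1, 1]`` are rescaled to ``[0, 1]`` via
    ``(w + 1) / 2`` on present edges.
    """
    W = None
    if hasattr(G, "adjacency") and hasattr(G, "weight_matrix"):  # CausalNetwork
        A = np.asarray(G.adjacency(), dtype=np.int8)
        raw = np.asarray(G.weight_matrix(), dtype=float)
        W = np.where(A > 0, (raw + 1.0) / 2.0, 0.0)
    elif hasattr(G, "number_of_nodes"):  # networkx
        import networkx as nx

        nodes = sorted(G.nodes())
        A = np.asarray(
            nx.to_numpy_array(G, nodelist=nodes, weight=None), dtype=np.int8
        )
        raw = np.asarray(nx.to_numpy_array(G, nodelist=nodes, weight="weight"))
        if not np.array_equal(raw, A.astype(float)):
            W = np.where(A > 0, (raw + 1.0) / 2.0, 0.0)
    else:
        M = np.asarray(G)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if np.array_equal(M, M.astype(bool)):
            A = M.astype(np.int8)
        else:
            A = (M != 0).astype(np.int8)
            W = np.where(A > 0, (np.asarray(M, float) + 1.0) / 2.0, 0.0)
    if np.any(np.diagonal(A)):
        raise ValueError("graph must not contain self-loops")
    return A, W


def _stat_values(M: np.ndarray, spec: ERGMSpec) -> np.ndarray:
    row = M.sum(axis=1)
    col = M.sum(axis=0)
    vals = []
    for name in spec.statistics:
        if name == "edges":
            vals.append(M.sum())
        elif name == "out2stars":
            vals.append(((row**2 - (M**2).sum(axis=1)) / 2.0).sum())
        elif name == "in2stars":
            vals.append(((col**2 - (M**2).sum(axis=0)) / 2.0).sum())
        elif name == "ctriads":
            vals.append(np.trace(M @ M @ M) / 3.0)
    if spec.sender is not None:
        vals.append(float(row @ spec.sender))
    if spec.receiver is not None:
        vals.append(float(col @ spec.receiver))
    return np.asarray(vals, dtype=np.float64)


def motif_stats(G, spec: ERGMSpec) -> np.ndarray:
    """Sufficient-statistic vector ``x(G)`` in the order of ``spec.stat_names``.

    Binary mode counts motif instances; weighted mode sums, per motif
    instance, the product of its (rescaled) edge weights.
    """
    A, W = adjacency_matrices(G)
    spec.validate_for(A.shape[0])
    if spec.weighted:
        if W is None:
            W = A.astype(np.float64)
        if W.min() < 0 or W.max() > 1 + 1e-12:
            raise ValueError("weighted statistics require weights in [0, 1]")
        return _stat_values(W, spec)
    x = _stat_values(A.astype(np.float64), spec)
    return x


def change_stats(A: np.ndarray, i: int, j: int, spec: ERGMSpec) -> np.ndarray:
    """Change-statistic vector for edge ``(i, j)``: ``x(G + ij) - x(G - ij)``.

    Evaluated on the binary adjacency with the edge's own state ignored.
    """
    A = np.asarray(A)
    if i == j:
        raise ValueError("self-loops are not modelled")
    a_ij = A[i, j]
    vals = []
    for name in spec.statistics:
        if name == "edges":
            vals.append(1.0)
        elif name == "out2stars":
            vals.append(float(A[i].sum() - a_ij))
        elif name == "in2stars":
            vals.append(float(A[:, j].sum() - a_ij))
        elif name == "ctriads":
            # closes one 3-cycle per directed path j -> k -> i
            vals.append(float(A[j] @ A[:, i]))
    if spec.sender is not None:
        vals.append(float(spec.sender[i]))
    if spec.receiver is not None:
        vals.append(float(spec.receiver[j]))
    return np.asarray(vals, dtype=np.float64)


def change_stat_matrix(
    A: np.ndarray, spec: ERGMSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized change statistics for every ordered dyad.

    Returns ``(y, X, dyads)``: the edge indicators, the ``(n(n-1), k)``
    change-statistic design matrix (each row evaluated with that dyad's
    edge removed), and the ``(n(n-1), 2)`` dyad index array.  This is the
    design of the pseudo-likelihood logistic regression.
    """
    A = np.asarray(A, dtype=np.int64)
    n = A.shape[0]
    off = ~np.eye(n, dtype=bool)
    i_idx, j_idx = np.nonzero(off)
    y = A[i_idx, j_idx].astype(np.float64)
    cols = []
    out_deg = A.sum(axis=1)
    in_deg = A.sum(axis=0)
    AA = A @ A
    for name in spec.statistics:
        if name == "edges":
            cols.append(np.ones_like(y))
        elif name == "out2stars":
            cols.append((out_deg[i_idx] - A[i_idx, j_idx]).astype(np.float64))
        elif name == "in2stars":
            cols.append((in_deg[j_idx] - A[i_idx, j_idx]).astype(np.float64))
        elif name == "ctriads":
            cols.append(AA[j_idx, i_idx].astype(np.float64))
    if spec.sender is not None:
        cols.append(spec.sender[i_idx])
    if spec.receiver is not None:
        cols.append(spec.receiver[j_idx])
    X = np.column_stack(cols)
    return y, X, np.column_stack([i_idx, j_idx])


def violation_count(A: np.ndarray, ref: ReferenceMeasure) -> int:
    """Number of constraint violations of ``A`` under the reference config."""
    A = np.asarray(A)
    in_deg = A.sum(axis=0)
    out_deg = A.sum(axis=1)
    v = int((in_deg < ref.min_in).sum()) + int((out_deg < ref.min_out).sum())
    if ref.max_in is not None:
        v += int((in_deg > ref.max_in).sum())
    if ref.max_out is not None:
        v += int((out_deg > ref.max_out).sum())
    if ref.support is not None:
        v += int((A.astype(bool) & ~ref.support).sum())
    return v


def log_reference_measure(G, ref: ReferenceMeasure | None) -> float:
    """``log h(G)``: 0 for the uniform reference; ``-inf`` for hard
    violations; ``-penalty * violations`` in soft mode."""
    if ref is None:
        return 0.0
    A, _ = adjacency_matrices(G)
    v = violation_count(A, ref)
    if ref.mode == "hard":
        return 0.0 if v == 0 else -np.inf
    return -ref.penalty * v


def reference_measure(G, ref: ReferenceMeasure | None) -> float:
    """The reference measure ``h(G)`` itself (nonnegative real)."""
    return float(np.exp(log_reference_measure(G, ref)))
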