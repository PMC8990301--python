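"""Exact enumeration of small directed-graph ensembles.

For ``n <= 5`` nodes every simple directed graph (``2^{n(n-1)}`` of them)
can be enumerated, giving exact probabilities, the exact normalizing
constant, and the exact maximum-likelihood estimate.  These serve as the
oracle against which the Metropolis sampler and the Monte-Carlo MLE are
validated.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from cardioergm.ergm.model import ERGMSpec, ReferenceMeasure
from cardioergm.ergm.stats import adjacency_matrices

__all__ = [
    "MAX_EXACT_NODES",
    "enumerate_graphs",
    "exact_table",
    "exact_probabilities",
    "graph_index",
    "log_prob_exact",
    "exact_mle",
]

MAX_EXACT_NODES = 5


def _pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(n) if i != j]


def graph_index(A: np.ndarray) -> int:
    """Position of adjacency ``A`` in the enumeration order of
    :func:`exact_table` (bit ``p`` set iff the ``p``-th ordered dyad is
    an edge)."""
    A = np.asarray(A)
    n = A.shape[0]
    code = 0
    for p, (i, j) in enumerate(_pairs(n)):
        if A[i, j]:
            code |= 1 << p
    return code


def enumerate_graphs(n: int):
    """Yield every simple directed graph on ``n`` nodes as an adjacency
    matrix, in :func:`graph_index` order."""
    _check_n(n)
    pairs = _pairs(n)
    m = len(pairs)
    for code in range(1 << m):
        A = np.zeros((n, n), dtype=np.int8)
        for p, (i, j) in enumerate(pairs):
            if (code >> p) & 1:
                A[i, j] = 1
        yield A


def _check_n(n: int) -> None:
    if n > MAX_EXACT_NODES:
        raise ValueError(
            f"exact enumeration supports n <= {MAX_EXACT_NODES} "
            f"(2^(n(n-1)) graphs); use the MCMC sampler for n = {n}"
        )
    if n < 1:
        raise ValueError("need at least one node")


def exact_table(
    n: int, spec: ERGMSpec, ref: ReferenceMeasure | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sufficient statistics and ``log h`` for every graph on ``n`` nodes.

    Returns ``(stats, log_h)`` with ``stats`` of shape
    ``(2^{n(n-1)}, k)`` in :func:`graph_index` order.  Fully vectorized
    over graphs (bitwise enumeration), so ``n = 5`` (about one million
    graphs) remains fast.
    """
    _check_n(n)
    spec.validate_for(n)
    if spec.weighted:
        raise ValueError("exact enumeration is defined for binary ERGMs")
    pairs = _pairs(n)
    m = len(pairs)
    N = 1 << m
    codes = np.arange(N, dtype=np.int64)
    bits = ((codes[:, None] >> np.arange(m)) & 1).astype(np.int8)  # (N, m)

    src = np.array([p[0] for p in pairs])
    dst = np.array([p[1] for p in pairs])
    out_deg = np.zeros((N, n), dtype=np.int16)
    in_deg = np.zeros((N, n), dtype=np.int16)
    for i in range(n):
        out_deg[:, i] = bits[:, src == i].sum(axis=1)
        in_deg[:, i] = bits[:, dst == i].sum(axis=1)

    pair_index = {p: k for k, p in enumerate(pairs)}
    cols = []
    for name in spec.statistics:
        if name == "edges":
            cols.append(bits.sum(axis=1))
        elif name == "out2stars":
            cols.append((out_deg * (out_deg - 1) // 2).sum(axis=1))
        elif name == "in2stars":
            cols.append((in_deg * (in_deg - 1) // 2).sum(axis=1))
        elif name == "ctriads":
            ct = np.zeros(N, dtype=np.int16)
            for a, b, c in combinations(range(n), 3):
                for cyc in ((a, b), (b, c), (c, a)), ((a, c), (c, b), (b, a)):
                    e1, e2, e3 = (pair_index[p] for p in cyc)
                    ct += bits[:, e1] * bits[:, e2] * bits[:, e3]
            cols.append(ct)
    if spec.sender is not None:
        cols.append(out_deg @ spec.sender)
    if spec.receiver is not None:
        cols.append(in_deg @ spec.receiver)
    stats = np.column_stack(cols).astype(np.float64)

    log_h = np.zeros(N, dtype=np.float64)
    if ref is not None:
        viol = np.zeros(N, dtype=np.int32)
        viol += (in_deg < ref.min_in).sum(axis=1)
        viol += (out_deg < ref.min_out).sum(axis=1)
        if ref.max_in is not None:
            viol += (in_deg > ref.max_in).sum(axis=1)
        if ref.max_out is not None:
            viol += (out_deg > ref.max_out).sum(axis=1)
        if ref.support is not None:
            banned = [
                pair_index[(i, j)]
                for (i, j) in pairs
                if not ref.support[i, j]
            ]
            if banned:
                viol += bits[:, banned].astype(np.int32).sum(axis=1)
        if ref.mode == "hard":
            log_h = np.where(viol == 0, 0.0, -np.inf)
        else:
            log_h = -ref.penalty * viol.astype(np.float64)
    return stats, log_h


def exact_probabilities(
    theta: np.ndarray,
    spec: ERGMSpec,
    n: int,
    ref: ReferenceMeasure | None = None,
) -> np.ndarray:
    """Exact probability of every graph on ``n`` nodes under ``theta``."""
    stats, log_h = exact_table(n, spec, ref)
    logits = stats @ np.asarray(theta, dtype=np.float64) + log_h
    return np.exp(logits - logsumexp(logits))


def log_prob_exact(
    G,
    theta: np.ndarray,
    spec: ERGMSpec,
    ref: ReferenceMeasure | None = None,
) -> float:
    """Exact ``log P(G | theta)`` by full enumeration (``n <= 5``)."""
    A, _ = adjacency_matrices(G)
    n = A.shape[0]
    _check_n(n)
    stats, log_h = exact_table(n, spec, ref)
    theta = np.asarray(theta, dtype=np.float64)
    logits = stats @ theta + log_h
    log_z = logsumexp(logits)
    idx = graph_index(A)
    return float(logits[idx] - log_z)


def exact_mle(
    x_obs: np.ndarray,
    n: int,
    spec: ERGMSpec,
    ref: ReferenceMeasure | None = None,
    theta0: np.ndarray | None = None,
) -> np.ndarray:
    """Exact maximum-likelihood ``theta`` for observed statistics ``x_obs``.

    Minimizes ``log Z(theta) - theta . x_obs`` (convex) over the
    enumerated ensemble; the gradient is ``E_theta[x] - x_obs``.
    """
    stats, log_h = exact_table(n, spec, ref)
    x_obs = np.asarray(x_obs, dtype=np.float64)
    if theta0 is None:
        theta0 = np.zeros(len(x_obs))

    def neg_ll(theta):
        logits = stats @ theta + log_h
        lz = logsumexp(logits)
        w = np.exp(logits - lz)
        grad = w @ stats - x_obs
        return lz - theta @ x_obs, grad

    res = minimize(neg_ll, theta0, jac=True, method="L-BFGS-B")
    return res.x
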