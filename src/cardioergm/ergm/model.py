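"""Model specification types: sufficient statistics and reference measure."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["STATISTIC_NAMES", "ERGMSpec", "ReferenceMeasure"]

#: Motif statistics available for the sufficient-statistic vector.
STATISTIC_NAMES = ("edges", "in2stars", "out2stars", "ctriads")


@dataclass(frozen=True)
class ReferenceMeasure:
    """Reference measure ``h(G)``: structural constraints on admissible graphs.

    Degree bounds and an optional candidate-edge support mask (e.g. a
    spatial radius on node coordinates) encode geometric or physiological
    constraints.  ``mode="hard"`` sets ``h = 1`` when all constraints hold
    and 0 otherwise; ``mode="soft"`` sets ``h = exp(-penalty * v)`` where
    ``v`` counts violations.
    """

    min_in: int = 0
    max_in: int | None = None
    min_out: int = 0
    max_out: int | None = None
    support: np.ndarray | None = None  # (n, n) bool, True = admissible edge
    mode: str = "hard"
    penalty: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise ValueError(f"mode must be 'hard' or 'soft', got {self.mode!r}")
        if self.max_in is not None and self.min_in > self.max_in:
            raise ValueError("min_in must not exceed max_in")
        if self.max_out is not None and self.min_out > self.max_out:
            raise ValueError("min_out must not exceed max_out")
        if self.min_in < 0 or self.min_out < 0:
            raise ValueError("degree bounds must be non-negative")
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")

    @property
    def unconstrained(self) -> bool:
        return (
            self.min_in == 0
            and self.max_in is None
            and self.min_out == 0
            and self.max_out is None
            and self.support is None
        )


@dataclass(frozen=True)
class ERGMSpec:
    """Choice of sufficient statistics ``x(G)`` for an ERGM.

    Attributes
    ----------
    statistics : tuple of str
        Ordered subset of :data:`STATISTIC_NAMES`.  ``in2stars`` /
        ``out2stars`` count per node ``choose(degree, 2)``; ``ctriads``
        counts directed 3-cycles once each (a mutually complete triple
        carries two).
    sender, receiver : array, optional
        Node covariates; the corresponding statistics sum the covariate of
        the source (resp. target) over edges, capturing hub-like excess
        out-going / in-coming connectivity.
    weighted : bool
        When True, statistics are evaluated on an edge-weight matrix in
        ``[0, 1]`` (each motif instance contributes the product of its
        edge weights) instead of the binary adjacency.
    reference : ReferenceMeasure, optional
        Constraint configuration; ``None`` means the uniform reference
        ``h == 1``.
    """

    statistics: tuple[str, ...] = STATISTIC_NAMES
    sender: np.ndarray | None = None
    receiver: np.ndarray | None = None
    weighted: bool = False
    reference: ReferenceMeasure | None = None

    def __post_init__(self) -> None:
        stats = tuple(self.statistics)
        object.__setattr__(self, "statistics", stats)
        if not stats:
            raise ValueError("statistics list must be nonempty")
        if len(set(stats)) != len(stats):
            raise ValueError("statistics list must be duplicate-free")
        unknown = set(stats) - set(STATISTIC_NAMES)
        if unknown:
            raise ValueError(f"unknown statistics: {sorted(unknown)}")
        for name in ("sender", "receiver"):
            cov = getattr(self, name)
            if cov is not None:
                object.__setattr__(
                    self, name, np.asarray(cov, dtype=np.float64)
                )

    @property
    def stat_names(self) -> tuple[str, ...]:
        names = list(self.statistics)
        if self.sender is not None:
            names.append("sender")
        if self.receiver is not None:
            names.append("receiver")
        return tuple(names)

    @property
    def n_stats(self) -> int:
        return len(self.stat_names)

    def validate_for(self, n_nodes: int) -> None:
        for name in ("sender", "receiver"):
            cov = getattr(self, name)
            if cov is not None and len(cov) != n_nodes:
                raise ValueError(
                    f"{name} covariate length {len(cov)} != node count {n_nodes}"
                )


def hub_covariates(
    A: np.ndarray, percentile: float = 90.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sender/receiver hub indicators from the observed degrees.

    A node is a sender (receiver) hub when its out- (in-) degree lies at
    or above the given percentile of the degree distribution; the
    indicators are returned as 0/1 covariate vectors.
    """
    A = np.asarray(A)
    out_deg = A.sum(axis=1).astype(float)
    in_deg = A.sum(axis=0).astype(float)
    s_cut = np.percentile(out_deg, percentile)
    r_cut = np.percentile(in_deg, percentile)
    sender = (out_deg >= max(s_cut, 1e-12)).astype(float)
    receiver = (in_deg >= max(r_cut, 1e-12)).astype(float)
    return sender, receiver
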