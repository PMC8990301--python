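"""Excitable-lattice model of electrical conduction in 2D cardiac tissue.

The tissue is an ``L x L`` grid of cells arranged in horizontal fibers
(rows).  Neighboring cells within a fiber are always electrically coupled;
transverse couplings between adjacent fibers are present independently with
probability ``nu`` (quenched at construction).  At ``nu = 1`` the lattice
is fully coupled, at ``nu = 0`` the fibers are fully decoupled.

Each cell is a three-state excitable element: resting (excitable), excited
(fires for exactly one time step, stimulating its coupled neighbors), then
refractory for a per-cell quenched period ``tau`` drawn uniformly from
``tau_mean +/- tau_jitter``.  A small number of randomly placed
*dysfunctional* cells fail to excite, with probability ``epsilon`` per
stimulation event, which seeds wavebreak.  Pacemaker cells along the left
edge self-activate with period ``pacing_period`` and launch planar waves
traveling along the fibers.

At low transverse coupling a wavebreak can curl into self-sustaining
reentrant circuits no longer driven by the pacemaker — the model's
surrogate for fibrillation-like arrhythmia.  A time step is classified as
arrhythmic when the number of simultaneously excited cells exceeds
``arrhythmia_factor * L`` (a single planar wavefront excites exactly
``L`` cells, so paced activity never trips the threshold).

Boundary conditions are periodic top-bottom (a cylinder of fibers) and
open left-right.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LatticeConfig",
    "Lattice",
    "StateSeries",
    "RiskMetrics",
    "build_lattice",
    "initial_phase",
    "step",
    "simulate",
    "arrhythmia_metrics",
]

# Stream tags for per-role RNGs derived from the top-level seed, so the
# quenched lattice disorder is reusable across dynamical replicates.
_STREAM_LATTICE = 1
_STREAM_MISFIRE = 2


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class LatticeConfig:
    """Parameters of the excitable-lattice tissue model.

    Attributes
    ----------
    L : int
        Cells per side of the square lattice.
    nu : float
        Probability that a transverse (between-fiber) coupling is present.
    tau_mean, tau_jitter : int
        Refractory period is drawn uniformly from the integer range
        ``[tau_mean - tau_jitter, tau_mean + tau_jitter]`` per cell.
    n_dysfunctional : int
        Number of randomly placed dysfunctional cells.  The default, 2000,
        is a fraction 0.05 of the default 200 x 200 lattice — the defect
        density at which wavebreak-induced reentry emerges below
        ``nu ~ 0.14``.
    epsilon : float
        Probability that a dysfunctional cell fails to excite per
        stimulation event (default ``misfire_mode="failure"``), or fires
        ectopically per resting step (``misfire_mode="ectopic"``).
    pacing_period : int
        Self-activation period of the left-edge pacemaker column.
    horizon : int
        Number of simulated time steps.
    arrhythmia_factor : float
        Multiplier ``c``: a step is arrhythmic when the excited-cell count
        exceeds ``c * L``.
    seed : int
        Top-level seed; lattice disorder and misfire draws use independent
        streams derived from it.
    misfire_mode : str
        ``"failure"`` (excitation failure, default) or ``"ectopic"``
        (spontaneous firing of resting dysfunctional cells).
    """

    L: int = 200
    nu: float = 0.5
    tau_mean: int = 50
    tau_jitter: int = 5
    n_dysfunctional: int = 2000
    epsilon: float = 0.05
    pacing_period: int = 220
    horizon: int = 1000
    arrhythmia_factor: float = 1.1
    seed: int = 0
    misfire_mode: str = "failure"

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ConfigurationError(f"L must be >= 1, got {self.L}")
        if not 0.0 <= self.nu <= 1.0:
            raise ConfigurationError(f"nu must lie in [0, 1], got {self.nu}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigurationError(
                f"epsilon must lie in [0, 1], got {self.epsilon}"
            )
        if self.tau_jitter < 0 or self.tau_jitter >= self.tau_mean:
            raise ConfigurationError(
                f"tau_jitter must satisfy 0 <= tau_jitter < tau_mean, "
                f"got tau_jitter={self.tau_jitter}, tau_mean={self.tau_mean}"
            )
        if not 0 <= self.n_dysfunctional <= self.L**2:
            raise ConfigurationError(
                f"n_dysfunctional must lie in [0, L^2], got {self.n_dysfunctional}"
            )
        if self.horizon < 0:
            raise ConfigurationError(f"horizon must be >= 0, got {self.horizon}")
        if self.pacing_period < 1:
            raise ConfigurationError(
                f"pacing_period must be >= 1, got {self.pacing_period}"
            )
        if self.arrhythmia_factor <= 0:
            raise ConfigurationError("arrhythmia_factor must be positive")
        if self.misfire_mode not in ("failure", "ectopic"):
            raise ConfigurationError(
                f"misfire_mode must be 'failure' or 'ectopic', got "
                f"{self.misfire_mode!r}"
            )

    def with_(self, **kwargs) -> "LatticeConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class Lattice:
    """Quenched disorder of the tissue: couplings, defects, refractoriness.

    ``lateral_links[r, c]`` is True when rows ``r`` and ``(r+1) % L`` are
    coupled at column ``c`` (periodic top-bottom boundary).
    """

    lateral_links: np.ndarray  # (L, L) bool
    dysfunctional_mask: np.ndarray  # (L, L) bool
    tau_cell: np.ndarray  # (L, L) int
    config: LatticeConfig


@dataclass
class StateSeries:
    """Binary excitation history of every cell over time.

    ``excitation[t, r, c]`` is 1 iff cell ``(r, c)`` fired at step ``t``.
    ``phase`` optionally records the full refractory counter (needed only
    for the graded coarse-graining encoding).
    """

    excitation: np.ndarray  # (horizon, L, L) uint8
    excited_count: np.ndarray  # (horizon,) int
    config: LatticeConfig
    lattice: Lattice | None = None
    phase: np.ndarray | None = None  # (horizon, L, L) int16, optional

    @property
    def horizon(self) -> int:
        return self.excitation.shape[0]


@dataclass(frozen=True)
class RiskMetrics:
    """Arrhythmia summary of one simulated trajectory."""

    time_in_arrhythmia: float
    sustained_reentry: bool
    threshold: float
    window: int


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def build_lattice(config: LatticeConfig) -> Lattice:
    """Draw the quenched disorder of the tissue.

    Transverse couplings are i.i.d. Bernoulli(``nu``); dysfunctional cells
    are placed uniformly without replacement; per-cell refractory periods
    are uniform integers on ``[tau_mean - tau_jitter, tau_mean + tau_jitter]``.
    Deterministic given ``config.seed``.
    """
    L = config.L
    rng = _rng(config.seed, _STREAM_LATTICE)
    lateral = rng.random((L, L)) < config.nu
    flat = rng.choice(L * L, size=config.n_dysfunctional, replace=False)
    dys = np.zeros(L * L, dtype=bool)
    dys[flat] = True
    tau = rng.integers(
        config.tau_mean - config.tau_jitter,
        config.tau_mean + config.tau_jitter + 1,
        size=(L, L),
    )
    return Lattice(
        lateral_links=lateral,
        dysfunctional_mask=dys.reshape(L, L),
        tau_cell=tau.astype(np.int16),
        config=config,
    )


def initial_phase(lattice: Lattice) -> np.ndarray:
    """All-resting phase field (every counter at 0)."""
    return np.zeros((lattice.config.L, lattice.config.L), dtype=np.int16)


def _firing(lattice: Lattice, phase: np.ndarray) -> np.ndarray:
    return phase == lattice.tau_cell + 1


def step(
    lattice: Lattice,
    phase: np.ndarray,
    t: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Advance the lattice one time step (synchronous update).

    ``phase`` encodes each cell's state: 0 resting, ``tau_cell + 1`` firing
    this step, ``tau_cell .. 1`` refractory countdown.  Cells firing at
    ``t`` stimulate their coupled neighbors; a stimulated resting cell
    fires at ``t + 1`` unless it is dysfunctional, in which case each
    stimulation event independently fails with probability ``epsilon``.
    If ``t + 1`` is a pacing time, every resting left-edge cell fires.

    ``rng`` drives the misfire draws; pass the same generator across steps
    for a reproducible trajectory (``simulate`` does this).
    """
    cfg = lattice.config
    fire = _firing(lattice, phase)

    # Stimulation count per cell: longitudinal neighbors always coupled,
    # transverse neighbors only through present links (periodic rows).
    stim = np.zeros(fire.shape, dtype=np.int8)
    stim[:, 1:] += fire[:, :-1]
    stim[:, :-1] += fire[:, 1:]
    down = fire & lattice.lateral_links  # (r, c) fires -> stimulates (r+1, c)
    stim += np.roll(down, 1, axis=0)
    up = fire & np.roll(lattice.lateral_links, 1, axis=0)  # (r, c) -> (r-1, c)
    stim += np.roll(up, -1, axis=0)

    resting = phase == 0
    candidates = resting & (stim > 0)
    excite = candidates.copy()
    if cfg.misfire_mode == "failure":
        dys_cand = candidates & lattice.dysfunctional_mask
        if cfg.epsilon > 0 and dys_cand.any():
            if rng is None:
                rng = _rng(cfg.seed, _STREAM_MISFIRE)
            # each stimulation is an independent Bernoulli(1 - eps) attempt
            k = stim[dys_cand].astype(np.float64)
            p_fail_all = cfg.epsilon**k
            excite[dys_cand] = rng.random(k.shape) >= p_fail_all
    else:  # ectopic: stimulation always works; resting defects may self-fire
        dys_rest = resting & lattice.dysfunctional_mask & ~candidates
        if cfg.epsilon > 0 and dys_rest.any():
            if rng is None:
                rng = _rng(cfg.seed, _STREAM_MISFIRE)
            fires = rng.random(int(dys_rest.sum())) < cfg.epsilon
            ect = np.zeros_like(excite)
            ect[dys_rest] = fires
            excite |= ect

    new_phase = np.maximum(phase - 1, 0).astype(np.int16)
    new_phase[excite] = lattice.tau_cell[excite] + 1
    if (t + 1) % cfg.pacing_period == 0:
        pace = new_phase[:, 0] == 0
        new_phase[pace, 0] = lattice.tau_cell[pace, 0] + 1
    return new_phase


def simulate(config: LatticeConfig, record_phase: bool = False) -> StateSeries:
    """Run ``horizon`` steps from the all-resting state.

    The pacemaker fires at step 0 and every ``pacing_period`` steps
    thereafter.  Bitwise reproducible for a fixed seed.  Set
    ``record_phase`` to keep the full refractory-counter history (needed
    for the graded coarse-graining encoding).
    """
    lattice = build_lattice(config)
    L, H = config.L, config.horizon
    misfire_rng = _rng(config.seed, _STREAM_MISFIRE)

    phase = initial_phase(lattice)
    # initial pacing event at t = 0
    if H > 0:
        phase[:, 0] = lattice.tau_cell[:, 0] + 1

    excitation = np.zeros((H, L, L), dtype=np.uint8)
    counts = np.zeros(H, dtype=np.int64)
    phases = np.zeros((H, L, L), dtype=np.int16) if record_phase else None
    for t in range(H):
        fire = _firing(lattice, phase)
        excitation[t] = fire
        counts[t] = int(fire.sum())
        if record_phase:
            phases[t] = phase
        phase = step(lattice, phase, t, rng=misfire_rng)
    return StateSeries(
        excitation=excitation,
        excited_count=counts,
        config=config,
        lattice=lattice,
        phase=phases,
    )


def arrhythmia_metrics(
    series: StateSeries, window: int | None = None
) -> RiskMetrics:
    """Arrhythmic-risk summary of a trajectory.

    A step is arrhythmic when ``excited_count > arrhythmia_factor * L``
    (a single paced planar wavefront contributes exactly ``L`` excited
    cells, so only broken, multi-wavelet activity trips the threshold).
    ``time_in_arrhythmia`` is the fraction of arrhythmic steps.  The
    trajectory shows *sustained reentry* when every step of the final
    window (default: half a pacing period, a pacing-free stretch) is
    arrhythmic — activity self-perpetuates instead of dying out between
    beats.
    """
    if series.horizon == 0:
        raise ValueError("cannot compute metrics of an empty series")
    cfg = series.config
    threshold = cfg.arrhythmia_factor * cfg.L
    arrhythmic = series.excited_count > threshold
    if window is None:
        window = max(1, min(series.horizon, cfg.pacing_period // 2))
    sustained = bool(arrhythmic[-window:].all())
    return RiskMetrics(
        time_in_arrhythmia=float(arrhythmic.mean()),
        sustained_reentry=sustained,
        threshold=float(threshold),
        window=int(window),
    )
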