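"""Parameter estimation for directed ERGMs and the ERGM potential.

Two estimators are provided.  Maximum pseudo-likelihood (MPLE) fits a
logistic regression of each edge indicator on its change-statistic vector
``x(G + ij) - x(G - ij)``; it is exact for dyad-independent models (e.g.
the edges-only model, where it reduces to ``logit`` of the density) and a
standard fast approximation otherwise.  Monte-Carlo maximum likelihood
(MC-MLE) refines an initial estimate by simulated moment matching: at the
MLE the expected sufficient statistics under the model equal the observed
ones, so Newton steps use the sampled mean and covariance of ``x``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cardioergm.ergm.model import ERGMSpec, ReferenceMeasure
from cardioergm.ergm.stats import (
    adjacency_matrices,
    change_stat_matrix,
    motif_stats,
)
from cardioergm.ergm.sampler import sample_graphs

__all__ = ["FitResult", "fit_mple", "fit_mcmle", "potential"]

#: Bound applied to coefficients when the pseudo-likelihood separates.
SEPARATION_BOUND = 15.0


@dataclass
class FitResult:
    """Fitted ERGM parameters with diagnostics.

    ``potential`` is ``theta_hat . x(G_obs)``, the scalar network
    potential of the observed graph under its own fit.
    """

    theta: np.ndarray
    se: np.ndarray
    estimator: str
    stat_names: tuple[str, ...]
    x_obs: np.ndarray
    potential: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    @property
    def degenerate(self) -> bool:
        return bool(self.diagnostics.get("degenerate", False))

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "stat_names": list(self.stat_names),
            "theta": [float(v) for v in self.theta],
            "se": [float(v) for v in self.se],
            "x_obs": [float(v) for v in self.x_obs],
            "potential": float(self.potential),
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()
            },
        }


def potential(theta: np.ndarray, x: np.ndarray) -> float:
    """ERGM potential ``theta . x`` (the Boltzmann identification reads
    this as ``-beta H`` of the network)."""
    theta = np.asarray(theta, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if theta.shape != x.shape:
        raise ValueError(
            f"parameter and statistic vectors differ in length: "
            f"{theta.shape} vs {x.shape}"
        )
    return float(theta @ x)


def _bounded_logistic(y, X, bound=SEPARATION_BOUND):
    """Logistic MLE with box-bounded coefficients (separation fallback)."""
    from scipy.optimize import minimize
    from scipy.special import expit

    def nll(beta):
        eta = X @ beta
        # log(1 + e^eta) - y * eta, numerically stable
        val = np.logaddexp(0.0, eta) - y * eta
        grad = X.T @ (expit(eta) - y)
        return val.sum(), grad

    k = X.shape[1]
    res = minimize(
        nll,
        np.zeros(k),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-bound, bound)] * k,
    )
    return res.x


def fit_mple(
    G,
    spec: ERGMSpec,
    ref: ReferenceMeasure | None = None,
) -> FitResult:
    """Maximum pseudo-likelihood estimate of ``theta``.

    Fits ``logit P(edge ij | rest of G) = theta . delta_ij`` over all
    ordered dyads with statsmodels.  When the reference measure carries a
    support mask, dyads outside the support are excluded.  Perfect
    separation (e.g. an empty or complete graph) is flagged in the
    diagnostics and coefficients are reported at a bounded value.
    """
    A, _ = adjacency_matrices(G)
    spec.validate_for(A.shape[0])
    y, X, dyads = change_stat_matrix(A, spec)
    if ref is not None and ref.support is not None:
        keep = ref.support[dyads[:, 0], dyads[:, 1]]
        y, X = y[keep], X[keep]
    x_obs = motif_stats(A, spec)

    diagnostics: dict = {"n_dyads": int(len(y)), "density": float(y.mean())}
    separation = False
    theta = None
    se = np.full(X.shape[1], np.nan)
    if y.min() == y.max():
        separation = True  # empty or complete graph
    else:
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.Logit(y, X)
                fit = model.fit(disp=0, maxiter=200)
            theta = np.asarray(fit.params, dtype=np.float64)
            se = np.asarray(fit.bse, dtype=np.float64)
            if not fit.mle_retvals.get("converged", True):
                separation = True
            if np.any(np.abs(theta) > SEPARATION_BOUND):
                separation = True
        except Exception:
            separation = True
    if separation or theta is None:
        theta = _bounded_logistic(y, X)
        se = np.full(X.shape[1], np.nan)
        diagnostics["separation"] = True
    diagnostics.setdefault("separation", False)
    diagnostics["degenerate"] = bool(diagnostics["separation"])
    diagnostics["converged"] = not diagnostics["separation"]

    return FitResult(
        theta=theta,
        se=se,
        estimator="mple",
        stat_names=spec.stat_names,
        x_obs=x_obs,
        potential=potential(theta, x_obs),
        diagnostics=diagnostics,
    )


def _is_ascent_step(
    theta_t: np.ndarray,
    sampled_stats: np.ndarray,
    x_obs: np.ndarray,
    step_cap: float,
) -> np.ndarray:
    """One importance-sampling ascent round of the MC-MLE.

    With an ensemble drawn at ``theta_t``, the log-likelihood ratio
    ``l(theta) - l(theta_t)`` is estimated by
    ``(theta - theta_t) . x_obs - log mean_i exp((theta - theta_t) . x_i)``
    and maximized within a box trust region around ``theta_t`` (the
    importance estimate is only trustworthy near the sampling point)."""
    from scipy.optimize import minimize
    from scipy.special import logsumexp, softmax

    S = sampled_stats
    m = len(S)

    def neg_ratio(theta):
        d = theta - theta_t
        lse = logsumexp(S @ d)
        w = softmax(S @ d)
        val = lse - np.log(m) - d @ x_obs
        grad = w @ S - x_obs
        return val, grad

    bounds = [(t - step_cap, t + step_cap) for t in theta_t]
    res = minimize(
        neg_ratio, theta_t, jac=True, method="L-BFGS-B", bounds=bounds
    )
    return res.x


def fit_mcmle(
    G,
    spec: ERGMSpec,
    theta_init: np.ndarray | None = None,
    ref: ReferenceMeasure | None = None,
    n_samples: int = 1000,
    burn_in: int = 10_000,
    thin: int | None = None,
    max_iter: int = 20,
    tol: float = 0.05,
    step_cap: float = 0.5,
    seed: int = 0,
) -> FitResult:
    """Monte-Carlo maximum likelihood estimate of ``theta``.

    Starting from the MPLE (or ``theta_init``), repeat: sample an
    ensemble at the current ``theta`` (chain initialized at the observed
    graph), then take a damped Newton step
    ``theta += Cov(x)^-1 (x_obs - mean(x))``.  Converged when every
    statistic's simulated mean is within ``tol`` (relative) of its
    observed value — the exponential-family moment-matching condition at
    the MLE.  Non-convergence after ``max_iter`` rounds is reported in
    the diagnostics, not raised.
    """
    A, _ = adjacency_matrices(G)
    n = A.shape[0]
    spec.validate_for(n)
    x_obs = motif_stats(A, spec)
    if theta_init is None:
        mple = fit_mple(G, spec, ref)
        if mple.diagnostics.get("separation") or np.max(np.abs(mple.theta)) > 5.0:
            # MPLE (quasi-)separated: start from the density-matched
            # independent-edge model instead of a boundary estimate
            theta = np.zeros(spec.n_stats)
            if "edges" in spec.statistics:
                d = np.clip(mple.diagnostics["density"], 1e-6, 1 - 1e-6)
                theta[spec.statistics.index("edges")] = np.log(d / (1 - d))
        else:
            theta = mple.theta.copy()
    else:
        theta = np.asarray(theta_init, dtype=np.float64).copy()

    diagnostics: dict = {}
    converged = False
    gap = np.full_like(x_obs, np.inf)
    scale = np.maximum(np.abs(x_obs), 1.0)
    cov = np.eye(len(x_obs))
    acceptance = np.nan
    it = 0
    for it in range(1, max_iter + 1):
        sample = sample_graphs(
            theta,
            spec,
            n,
            n_samples=n_samples,
            burn_in=burn_in,
            thin=thin,
            seed=seed + it,
            init=A,
            ref=ref,
            keep_graphs=False,
        )
        mu = sample.stats.mean(axis=0)
        cov = np.cov(sample.stats.T, ddof=1)
        cov = np.atleast_2d(cov)
        acceptance = sample.acceptance_rate
        gap = (x_obs - mu) / scale
        if np.max(np.abs(gap)) <= tol:
            converged = True
            break
        theta = _is_ascent_step(theta, sample.stats, x_obs, step_cap)

    se = np.sqrt(np.clip(np.diag(np.linalg.pinv(cov)), 0.0, None))
    var_x = np.diag(cov)
    diagnostics.update(
        {
            "converged": converged,
            "iterations": it,
            "moment_gap": gap,
            "acceptance_rate": float(acceptance),
            "degenerate": bool(np.any(var_x < 1e-12)),
        }
    )
    return FitResult(
        theta=theta,
        se=se,
        estimator="mcmle",
        stat_names=spec.stat_names,
        x_obs=x_obs,
        potential=potential(theta, x_obs),
        diagnostics=diagnostics,
    )
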