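"""Monte-Carlo verification of the Bayesian view of response reconstruction.

The optimization-based reconstruction admits a hierarchical reading:
each anchor response t_k is conditionally Normal(t_n, tau_k^2) and each
latent variance tau_k^2 is Exponential with rate d_{r,n,k}^2 / 2.
Integrating the variance out gives the checkable results verified here:

* the marginal of t_k given (t_n, d) is Laplace(t_n, 1/d), and
* with a Normal(0, sigma^2) prior on t_n, its full conditional given
  the anchor responses and variances is Normal(u*, v*) with
  1/v* = 1/sigma^2 + sum 1/tau_k^2 and u* = v* sum(t_k / tau_k^2).

The ridge-prior sub-hierarchy and the process-level model are part of
the same statistical story but are point-estimated by the ridge fit
itself; no sampler is provided for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reconstruct import ReconstructionInput, optimization_reconstruct


@dataclass
class HierarchyParams:
    """Parameters of the reconstruction hierarchy for one sample."""

    t_n: float
    d: np.ndarray  # positive response-distance estimates d_{r,n,k}
    sigma2: float  # prior variance of t_n
    tau2: np.ndarray | None = None  # latent variances, when instantiated

    def __post_init__(self) -> None:
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if np.any(self.d <= 0):
            raise ValueError("distance estimates d must be > 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if self.tau2 is not None:
            self.tau2 = np.atleast_1d(np.asarray(self.tau2, dtype=float))
            if np.any(self.tau2 <= 0):
                raise ValueError("tau2 must be > 0")


def sample_t_marginal(
    t_n: float, d: float, n_draws: int, seed: int = 0
) -> np.ndarray:
    """Draws from the Normal-Exponential scale mixture for one anchor.

    tau^2 ~ Exponential(rate d^2/2), then t | tau^2 ~ Normal(t_n, tau^2).
    The marginal of t is Laplace(t_n, scale 1/d); these draws are used
    to verify that identity empirically.
    """
    if d <= 0:
        raise ValueError(f"d must be > 0, got {d}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    tau2 = rng.exponential(scale=2.0 / d**2, size=n_draws)
    return rng.normal(loc=t_n, scale=np.sqrt(tau2))


def laplace_ks_distance(samples: np.ndarray, t_n: float, d: float) -> float:
    """Kolmogorov-Smirnov distance to the Laplace(t_n, 1/d) CDF."""
    return float(stats.kstest(samples, stats.laplace(loc=t_n, scale=1.0 / d).cdf).statistic)


def posterior_t(
    t_vec: np.ndarray, tau2_vec: np.ndarray, sigma2: float
) -> tuple[float, float]:
    """Normal full conditional of t_n: point estimate u* and variance v*.

    Precisions add: 1/v* = 1/sigma2 + sum 1/tau_k^2, and
    u* = v* * sum(t_k / tau_k^2) (the prior mean is 0).
    """
    t_vec = np.atleast_1d(np.asarray(t_vec, dtype=float))
    tau2_vec = np.atleast_1d(np.asarray(tau2_vec, dtype=float))
    if t_vec.size != tau2_vec.size:
        raise ValueError("t_vec and tau2_vec must have equal length")
    if np.any(tau2_vec <= 0) or sigma2 <= 0:
        raise ValueError("variances must be > 0")
    v_star = 1.0 / (1.0 / sigma2 + np.sum(1.0 / tau2_vec))
    u_star = v_star * float(np.sum(t_vec / tau2_vec))
    return float(u_star), float(v_star)


def posterior_t_quadrature(
    t_vec: np.ndarray,
    tau2_vec: np.ndarray,
    sigma2: float,
    grid_points: int = 20001,
    half_width: float = 50.0,
) -> tuple[float, float]:
    """Grid-based oracle for the full conditional of t_n.

    Normalizes the product density prod_k N(t_k; t_n, tau_k^2) x
    N(t_n; 0, sigma2) on a fine grid and returns its mean and variance;
    independent of the closed form it cross-checks.
    """
    t_vec = np.atleast_1d(np.asarray(t_vec, dtype=float))
    tau2_vec = np.atleast_1d(np.asarray(tau2_vec, dtype=float))
    center = np.mean(t_vec)
    grid = np.linspace(center - half_width, center + half_width, grid_points)
    log_density = stats.norm(0.0, np.sqrt(sigma2)).logpdf(grid)
    for tk, tau2 in zip(t_vec, tau2_vec):
        log_density += stats.norm(grid, np.sqrt(tau2)).logpdf(tk)
    density = np.exp(log_density - log_density.max())
    density /= np.trapezoid(density, grid)
    mean = float(np.trapezoid(grid * density, grid))
    var = float(np.trapezoid((grid - mean) ** 2 * density, grid))
    return mean, var


def reconstruction_vs_posterior_demo(
    inp: ReconstructionInput, sigma2: float = 1e6, eps: float = 1e-6
) -> dict:
    """Side-by-side diagnostic: squared-loss minimizer vs posterior mean.

    Sets each tau_k^2 to its conditional mean 2/d_hat_k^2 (distances at
    or below zero are nudged to ``eps``) and reports the exact
    reconstruction minimizer next to the posterior point estimate u*.
    Purely descriptive; there is no pass/fail.
    """
    d = np.maximum(np.asarray(inp.d_hat, dtype=float), eps)
    tau2 = 2.0 / d**2
    u_star, v_star = posterior_t(inp.anchor_responses, tau2, sigma2)
    t_opt = optimization_reconstruct(inp, solver="exact")
    return {
        "optimization_minimizer": t_opt,
        "posterior_mean_u_star": u_star,
        "posterior_variance_v_star": v_star,
        "tau2": tau2,
    }


def verify_hierarchy(
    t_n_grid: tuple[float, ...] = (-2.0, 0.0, 5.0),
    d_grid: tuple[float, ...] = (0.5, 1.0, 2.0),
    n_draws: int = 100_000,
    ks_threshold: float = 0.01,
    posterior_tol: float = 1e-6,
    seed: int = 0,
) -> "pd.DataFrame":
    """Run the full verification table (used by the bayes-check command).

    For each (t_n, d) pair, checks the KS distance between the mixture
    samples and the Laplace marginal; then checks the closed-form
    (u*, v*) against the quadrature oracle on a seeded random case.
    """
    import pandas as pd

    rows = []
    rng = np.random.default_rng(seed)
    for i, t_n in enumerate(t_n_grid):
        for j, d in enumerate(d_grid):
            s = sample_t_marginal(t_n, d, n_draws, seed=seed + 17 * i + j)
            ks = laplace_ks_distance(s, t_n, d)
            rows.append(
                {
                    "check": f"laplace_marginal(t_n={t_n}, d={d})",
                    "statistic": ks,
                    "threshold": ks_threshold,
                    "passed": ks < ks_threshold,
                }
            )
    t_vec = rng.uniform(4, 8, size=6)
    tau2_vec = rng.uniform(0.2, 3.0, size=6)
    sigma2 = 10.0
    u_exact, v_exact = posterior_t(t_vec, tau2_vec, sigma2)
    u_quad, v_quad = posterior_t_quadrature(t_vec, tau2_vec, sigma2)
    err = max(abs(u_exact - u_quad), abs(v_exact - v_quad))
    rows.append(
        {
            "check": "posterior_u_v_vs_quadrature",
            "statistic": err,
            "threshold": posterior_tol,
            "passed": err < posterior_tol,
        }
    )
    return pd.DataFrame(rows)
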