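"""Turn estimated response distances into scalar response predictions.

Two routes are provided. RBF reconstruction is the weighted average of
anchor responses with Gaussian weights decaying in the estimated
distance; it can never leave the range of anchor responses. The
optimization route returns the response minimizing

    sum_k (max(0, d_hat_k) - |t - t_k|)^2

which uses every distance estimate (large ones included) and can
extrapolate beyond the anchor-response range. The piecewise-quadratic
structure of the objective admits an exact segment-wise solution, used
both as the default solver and as the reference for the Nelder-Mead
route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import minimize


class Solver(str, Enum):
    NELDER_MEAD = "nelder_mead"
    EXACT = "exact"


class ReconstructionMode(str, Enum):
    RBF = "rbf"
    OPTIMIZATION = "optimization"


@dataclass
class ReconstructionInput:
    """Estimated response distances d_hat paired with anchor responses t_k."""

    d_hat: np.ndarray
    anchor_responses: np.ndarray

    def __post_init__(self) -> None:
        self.d_hat = np.atleast_1d(np.asarray(self.d_hat, dtype=float))
        self.anchor_responses = np.atleast_1d(
            np.asarray(self.anchor_responses, dtype=float)
        )
        if self.d_hat.size != self.anchor_responses.size or self.d_hat.size < 1:
            raise ValueError("d_hat and anchor_responses must have equal length >= 1")
        if not np.all(np.isfinite(self.anchor_responses)):
            raise ValueError("anchor responses must be finite")


def reconstruction_objective(t: float, inp: ReconstructionInput) -> float:
    """Sum of squared mismatches between clipped estimates and |t - t_k|."""
    d = np.maximum(0.0, inp.d_hat)
    return float(np.sum((d - np.abs(t - inp.anchor_responses)) ** 2))


def rbf_reconstruct(inp: ReconstructionInput, gamma: float = 1.0) -> float:
    """Weighted-average reconstruction with Gaussian RBF weights.

    Weights u_k = exp(-gamma * max(0, d_hat_k)^2); the result is
    sum(u_k t_k) / sum(u_k), always inside [min t_k, max t_k]. If every
    weight underflows to zero the nearest anchor's response is returned
    with a warning.
    """
    d = np.maximum(0.0, inp.d_hat)
    u = np.exp(-gamma * d**2)
    total = u.sum()
    if total == 0.0:
        warnings.warn(
            "all RBF weights underflowed to zero; falling back to the "
            "nearest anchor's response",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(inp.anchor_responses[np.argmin(d)])
    return float(np.dot(u, inp.anchor_responses) / total)


def _exact_minimize(inp: ReconstructionInput) -> float:
    """Global minimizer of the piecewise-quadratic objective.

    On each interval between consecutive sorted anchor responses,
    |t - t_k| is linear with slope s_k = sign(t - t_k), so the objective
    is a convex quadratic with vertex t* = sum(s_k (d_k + s_k t_k)) / Kr.
    The global minimum is among the clamped vertices and breakpoints;
    ties resolve to the smallest t.
    """
    d = np.maximum(0.0, inp.d_hat)
    t_anchor = inp.anchor_responses
    K = t_anchor.size
    breaks = np.unique(t_anchor)
    # segment edges: (-inf, b1], [b1, b2], ..., [bm, inf)
    lo = np.concatenate([[-np.inf], breaks])
    hi = np.concatenate([breaks, [np.inf]])
    candidates: list[float] = list(breaks)
    for a, b in zip(lo, hi):
        mid = (
            a + 1.0 if np.isinf(b)
            else b - 1.0 if np.isinf(a)
            else 0.5 * (a + b)
        )
        s = np.where(mid >= t_anchor, 1.0, -1.0)
        vertex = float(np.sum(s * (d + s * t_anchor))) / K
        candidates.append(min(max(vertex, a), b))
    vals = np.array([reconstruction_objective(t, inp) for t in candidates])
    best = vals.min()
    # smallest t among (numerically) tied minima
    return float(min(t for t, v in zip(candidates, vals) if v <= best + 1e-12))


def optimization_reconstruct(
    inp: ReconstructionInput, solver: Solver | str = Solver.EXACT
) -> float:
    """Response minimizing the squared distance-mismatch objective.

    ``exact`` solves each piecewise-quadratic segment in closed form and
    is the reference; ``nelder_mead`` restarts the simplex method from
    each anchor response and the RBF estimate — the objective is
    piecewise quadratic but not convex, so a single start can stall in
    a local minimum (with degenerate multimodal inputs either global
    minimum may be returned).
    """
    solver = Solver(solver)
    if solver is Solver.EXACT:
        return _exact_minimize(inp)

    starts = sorted(set(inp.anchor_responses)) + [rbf_reconstruct(inp)]
    best_t, best_f = None, np.inf
    for x0 in starts:
        res = minimize(
            lambda t: reconstruction_objective(float(t[0]), inp),
            x0=np.array([x0]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 200},
        )
        f = float(res.fun)
        if f < best_f:
            best_t, best_f = float(res.x[0]), f
    return best_t


def reconstruct_batch(
    D_hat: np.ndarray,
    anchor_responses: np.ndarray,
    mode: ReconstructionMode | str = ReconstructionMode.OPTIMIZATION,
    gamma: float = 1.0,
    solver: Solver | str = Solver.EXACT,
) -> np.ndarray:
    """Reconstruct one response per row of an (N, Kr) distance-estimate matrix."""
    mode = ReconstructionMode(mode)
    out = np.empty(D_hat.shape[0])
    for i, row in enumerate(np.atleast_2d(D_hat)):
        inp = ReconstructionInput(row, anchor_responses)
        if mode is ReconstructionMode.RBF:
            out[i] = rbf_reconstruct(inp, gamma=gamma)
        else:
            out[i] = optimization_reconstruct(inp, solver=solver)
    return out
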