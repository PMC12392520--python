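"""Distance-space regression: the linear map from structure to response distances.

The driving model is Dr = Ds W + 1 beta + eps, fitted either by ordinary
least squares or by ridge regression with penalty lambda on the stacked
coefficient matrix W* = [beta^T, W^T]^T (the intercept row is penalized
too, matching the stated objective; an exemption flag is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.linalg

from .chem import DistanceMatrix, DistanceSpace


class ClipMode(str, Enum):
    RAW = "raw"
    ABS = "abs"
    NONNEG = "nonneg"


class SingularityError(np.linalg.LinAlgError):
    """OLS normal equations are rank-deficient; use lambda > 0."""


@dataclass
class DistanceModel:
    """Fitted weights of the distance regression.

    W maps Ks structure-anchor distances to Kr response-anchor
    distances; beta is the per-response-anchor intercept row;
    response_anchor_values holds t_k for reconstruction.
    """

    W: np.ndarray
    beta: np.ndarray
    lam: float
    structure_anchor_ids: list[str]
    response_anchor_ids: list[str]
    response_anchor_values: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float).reshape(-1)
        self.response_anchor_values = np.asarray(
            self.response_anchor_values, dtype=float
        )
        Ks, Kr = self.W.shape
        if Ks != len(self.structure_anchor_ids):
            raise ValueError("W rows != number of structure anchors")
        if Kr != len(self.response_anchor_ids) or Kr != self.beta.size:
            raise ValueError("W cols, beta and response anchors inconsistent")
        if self.response_anchor_values.size != Kr:
            raise ValueError("response anchor values inconsistent with Kr")
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.beta))):
            raise ValueError("non-finite model weights")

    @property
    def n_structure_anchors(self) -> int:
        return self.W.shape[0]

    @property
    def n_response_anchors(self) -> int:
        return self.W.shape[1]

    @property
    def W_star(self) -> np.ndarray:
        """Stacked coefficients [beta; W], shape (Ks + 1, Kr)."""
        return np.vstack([self.beta[None, :], self.W])


def fit_distance_regression(
    Ds: DistanceMatrix,
    Dr: DistanceMatrix,
    lam: float = 0.05,
    penalize_intercept: bool = True,
    response_anchor_values: np.ndarray | None = None,
    rank_deficient: str = "raise",
) -> DistanceModel:
    """Closed-form OLS/ridge fit of Dr ~ [1, Ds] W*.

    Solves (Ds*^T Ds* + lam I) W* = Ds*^T Dr via a symmetric
    positive-definite solve. With lam = 0 this is the plain
    least-squares solution and requires full-rank Ds*; a rank-deficient
    system raises :class:`SingularityError` advising lam > 0, unless
    ``rank_deficient="minnorm"`` requests the minimum-norm
    least-squares solution (the behavior of the unregularized model on
    the ill-conditioned distance matrices it is known to produce).
    """
    if Ds.row_ids != Dr.row_ids:
        raise ValueError("Ds and Dr must cover the same rows in the same order")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")

    X = np.hstack([np.ones((Ds.shape[0], 1)), Ds.values])  # Ds* = [1, Ds]
    G = X.T @ X
    b = X.T @ Dr.values

    if lam == 0:
        if np.linalg.matrix_rank(X) < X.shape[1]:
            if rank_deficient == "minnorm":
                W_star, *_ = np.linalg.lstsq(X, Dr.values, rcond=None)
            elif rank_deficient == "raise":
                raise SingularityError(
                    "Ds*^T Ds* is rank-deficient; OLS has no unique solution "
                    "(set lambda > 0 for a ridge fit)"
                )
            else:
                raise ValueError(f"unknown rank_deficient policy {rank_deficient!r}")
        else:
            W_star = scipy.linalg.solve(G, b, assume_a="pos")
    else:
        ridge = lam * np.eye(X.shape[1])
        if not penalize_intercept:
            ridge[0, 0] = 0.0
        W_star = scipy.linalg.solve(G + ridge, b, assume_a="pos")

    return DistanceModel(
        W=W_star[1:],
        beta=W_star[0],
        lam=float(lam),
        structure_anchor_ids=list(Ds.col_ids),
        response_anchor_ids=list(Dr.col_ids),
        response_anchor_values=(
            np.full(len(Dr.col_ids), np.nan)
            if response_anchor_values is None
            else response_anchor_values
        ),
    )


def predict_response_distances(
    model: DistanceModel,
    Ds_new: DistanceMatrix,
    clip: ClipMode | str = ClipMode.RAW,
) -> DistanceMatrix:
    """Predicted response distances D̂r = Ds* Ŵ* for new samples.

    ``clip`` post-processes the raw linear prediction: "abs" takes the
    elementwise absolute value (the interpretation convention), "nonneg"
    takes max(0, ·) (the reconstruction convention).
    """
    clip = ClipMode(clip)
    if list(Ds_new.col_ids) != list(model.structure_anchor_ids):
        raise ValueError(
            "structure distance columns do not match the model's anchor ids"
        )
    X = np.hstack([np.ones((Ds_new.shape[0], 1)), Ds_new.values])
    pred = X @ model.W_star
    if clip is ClipMode.ABS:
        pred = np.abs(pred)
    elif clip is ClipMode.NONNEG:
        pred = np.maximum(0.0, pred)
    return DistanceMatrix(
        pred, list(Ds_new.row_ids), list(model.response_anchor_ids),
        DistanceSpace.RESPONSE,
    )
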