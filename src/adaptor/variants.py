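"""Ensemble and stacking wrappers around TR-family models.

The ensemble draws per-member structure-anchor fractions from a clipped
Gaussian (mean 0.6, sd 0.3, clipped to [0.3, 0.9]) and averages member
predictions; stacking fits an unconstrained least-squares combination
(with intercept) of member predictions on a held-out validation split.
Both can also be applied across the intermediate models produced by
adaptive anchor selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .chem import FingerprintDataset
from .model import AdapToRModel, _spawn_seeds, fit_enhanced_tr
from .reconstruct import ReconstructionMode


class CombineMode(str, Enum):
    ENSEMBLE = "ensemble"
    STACK = "stack"


@dataclass
class EnsembleModel:
    """Mean-of-members predictor over independently fitted TR models."""

    members: list[AdapToRModel]
    fractions: list[float]
    seeds: list[int]

    def predict(self, data: FingerprintDataset | np.ndarray) -> np.ndarray:
        preds = np.vstack([m.predict(data) for m in self.members])
        return preds.mean(axis=0)


@dataclass
class StackModel:
    """Linear (OLS with intercept) combination of member predictions."""

    members: list[AdapToRModel]
    weights: np.ndarray  # length n_members
    intercept: float

    def predict(self, data: FingerprintDataset | np.ndarray) -> np.ndarray:
        preds = np.vstack([m.predict(data) for m in self.members])
        return self.intercept + self.weights @ preds


def ensemble_fit(
    train: FingerprintDataset,
    n_models: int = 15,
    frac_mean: float = 0.6,
    frac_sd: float = 0.3,
    frac_bounds: tuple[float, float] = (0.3, 0.9),
    lam: float = 0.05,
    Kr: int = 10,
    reconstruction: ReconstructionMode | str = ReconstructionMode.OPTIMIZATION,
    seed: int = 0,
) -> EnsembleModel:
    """Fit an ensemble of enhanced-TR models with random anchor fractions.

    Fractions are drawn from Normal(frac_mean, frac_sd) and clipped
    (not resampled) into ``frac_bounds``; each member is an enhanced TR
    (ridge + k-means response anchors) on its own random anchor set.
    """
    if n_models < 1:
        raise ValueError(f"n_models must be >= 1, got {n_models}")
    if len(train) == 0:
        raise ValueError("empty training set")
    seeds = _spawn_seeds(seed, n_models + 1)
    rng = np.random.default_rng(seeds[0])
    fractions = np.clip(
        rng.normal(frac_mean, frac_sd, size=n_models), *frac_bounds
    ).tolist()
    members = [
        fit_enhanced_tr(
            train,
            anchor_fraction=f,
            lam=lam,
            Kr=Kr,
            reconstruction=reconstruction,
            seed=s,
        )
        for f, s in zip(fractions, seeds[1:])
    ]
    return EnsembleModel(members=members, fractions=fractions, seeds=seeds[1:])


def stack_fit(
    train: FingerprintDataset,
    members: list,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> StackModel:
    """Estimate stacking weights on a held-out validation split.

    ``members`` are already-fitted models (ideally fitted without the
    validation samples); the combination is unconstrained ordinary least
    squares with an intercept.
    """
    if len(members) < 2:
        raise ValueError("stacking requires at least 2 members")
    rng = np.random.default_rng(seed)
    n = len(train)
    n_val = int(round(val_fraction * n))
    if n_val < len(members) + 1:
        raise ValueError(
            f"validation holdout of {n_val} cannot identify "
            f"{len(members)} weights + intercept"
        )
    pick = sorted(rng.choice(n, size=n_val, replace=False).tolist())
    val = train.subset([train.ids[i] for i in pick])
    preds = np.vstack([m.predict(val) for m in members])  # (M, n_val)
    X = np.hstack([np.ones((n_val, 1)), preds.T])
    coef, *_ = np.linalg.lstsq(X, val.responses, rcond=None)
    return StackModel(members=members, weights=coef[1:], intercept=float(coef[0]))


def adaptive_ensemble_predict(
    model: AdapToRModel,
    data: FingerprintDataset | np.ndarray,
    mode: CombineMode | str = CombineMode.ENSEMBLE,
    train: FingerprintDataset | None = None,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Combine predictions across the adaptive-selection step models.

    ``ensemble`` averages the P step models' predictions; ``stack``
    fits stacking weights on a validation split of ``train`` (required
    for that mode) and applies them.
    """
    mode = CombineMode(mode)
    if len(model.step_models) < 2:
        raise ValueError("model has no retained step history (need >= 2 step models)")
    preds = model.predict_per_step(data)
    if mode is CombineMode.ENSEMBLE:
        return preds.mean(axis=0)
    if train is None:
        raise ValueError("stack mode requires the training dataset")
    rng = np.random.default_rng(seed)
    n = len(train)
    n_val = int(round(val_fraction * n))
    if n_val < len(model.step_models) + 1:
        raise ValueError("validation holdout too small to estimate stacking weights")
    pick = sorted(rng.choice(n, size=n_val, replace=False).tolist())
    val = train.subset([train.ids[i] for i in pick])
    val_preds = model.predict_per_step(val)
    X = np.hstack([np.ones((n_val, 1)), val_preds.T])
    coef, *_ = np.linalg.lstsq(X, val.responses, rcond=None)
    return coef[0] + coef[1:] @ preds
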