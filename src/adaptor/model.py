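"""High-level TR / AdapToR predictors: fitting, prediction, serialization.

Vanilla topological regression (TR) randomly picks 60% of the training
samples as both structure and response anchors, fits the distance
regression by ordinary least squares, and reconstructs responses with
the RBF weighted average. AdapToR replaces each of those choices: ridge
fitting (lambda = 0.05), 10 k-means response anchors, adaptive growth of
the structure-anchor set over P = 4 steps (adding the Ka = 0.15*N
held-out samples with the highest absolute prediction error each step),
and optimization-based reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .anchors import (
    AnchorConfig,
    AnchorConfigError,
    AnchorSets,
    early_stop_check,
    rank_by_absolute_error,
    select_initial_structure_anchors,
    select_response_anchors,
)
from .chem import (
    DistanceMatrix,
    FingerprintDataset,
    FingerprintKind,
    response_distance_matrix,
    structure_distance_matrix,
)
from .reconstruct import ReconstructionMode, Solver, reconstruct_batch
from .regression import (
    ClipMode,
    DistanceModel,
    fit_distance_regression,
    predict_response_distances,
)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan a single seed out into named sub-seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass
class AdapToRModel:
    """A fitted distance-regression predictor with its anchor history.

    Wraps the final :class:`DistanceModel` together with everything
    needed to predict unseen molecules: the anchor fingerprints, the
    response-anchor values, the reconstruction mode, and (for adaptive
    fits) the per-step intermediate models.
    """

    model: DistanceModel
    anchor_sets: AnchorSets
    anchor_fingerprints: np.ndarray  # rows follow anchor_sets.final_ids
    fingerprint_kind: FingerprintKind
    reconstruction: ReconstructionMode = ReconstructionMode.OPTIMIZATION
    gamma: float = 1.0
    solver: Solver = Solver.EXACT
    step_models: list[DistanceModel] = field(default_factory=list)
    n_train: int = 0

    def __post_init__(self) -> None:
        self.fingerprint_kind = FingerprintKind(self.fingerprint_kind)
        self.reconstruction = ReconstructionMode(self.reconstruction)
        self.solver = Solver(self.solver)
        if list(self.model.structure_anchor_ids) != list(self.anchor_sets.final_ids):
            raise ValueError("final model anchors disagree with the anchor history")

    @property
    def n_steps(self) -> int:
        return max(len(self.step_models), 1)

    def _anchor_index(self) -> dict[str, int]:
        return {mid: i for i, mid in enumerate(self.anchor_sets.final_ids)}

    def predict_distances(
        self,
        fingerprints: np.ndarray,
        ids: list[str] | None = None,
        model: DistanceModel | None = None,
    ) -> DistanceMatrix:
        """Estimated response distances (clipped nonnegative) for new samples."""
        model = model or self.model
        ids = ids or [f"q{i}" for i in range(fingerprints.shape[0])]
        aidx = self._anchor_index()
        sel = [aidx[mid] for mid in model.structure_anchor_ids]
        all_fp = np.vstack([self.anchor_fingerprints, fingerprints])
        all_ids = self.anchor_sets.final_ids + list(ids)
        n_anchor = self.anchor_fingerprints.shape[0]
        Ds = structure_distance_matrix(
            all_fp,
            all_ids,
            anchor_index=sel,
            kind=self.fingerprint_kind,
            row_index=np.arange(n_anchor, n_anchor + fingerprints.shape[0]),
        )
        return predict_response_distances(model, Ds, clip=ClipMode.NONNEG)

    def predict(
        self,
        data: FingerprintDataset | np.ndarray,
        model: DistanceModel | None = None,
    ) -> np.ndarray:
        """Predict scalar responses for a dataset or raw fingerprint array."""
        if isinstance(data, FingerprintDataset):
            if data.kind != self.fingerprint_kind:
                raise ValueError(
                    f"dataset fingerprints are {data.kind.value}, model expects "
                    f"{self.fingerprint_kind.value}"
                )
            fingerprints, ids = data.fingerprints, data.ids
        else:
            fingerprints, ids = np.asarray(data), None
        D_hat = self.predict_distances(fingerprints, ids, model=model)
        used = model or self.model
        return reconstruct_batch(
            D_hat.values,
            used.response_anchor_values,
            mode=self.reconstruction,
            gamma=self.gamma,
            solver=self.solver,
        )

    def predict_per_step(self, data: FingerprintDataset | np.ndarray) -> np.ndarray:
        """(P, N) predictions from every step model (for ensembling/stacking)."""
        models = self.step_models or [self.model]
        return np.vstack([self.predict(data, model=m) for m in models])

    # -- serialization ------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the model as a single JSON archive (round-trip exact)."""
        models = self.step_models or [self.model]
        payload = {
            "format": "adaptor-model-v1",
            "fingerprint_kind": self.fingerprint_kind.value,
            "fingerprint_length": int(self.anchor_fingerprints.shape[1]),
            "reconstruction": self.reconstruction.value,
            "gamma": self.gamma,
            "solver": self.solver.value,
            "n_train": self.n_train,
            "anchor_sets": {
                "structure_sets": self.anchor_sets.structure_sets,
                "response_ids": self.anchor_sets.response_ids,
            },
            "anchor_fingerprints": self.anchor_fingerprints.tolist(),
            "step_models": [
                {
                    "W": m.W.tolist(),
                    "beta": m.beta.tolist(),
                    "lambda": m.lam,
                    "structure_anchor_ids": m.structure_anchor_ids,
                    "response_anchor_ids": m.response_anchor_ids,
                    "response_anchor_values": m.response_anchor_values.tolist(),
                }
                for m in models
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "AdapToRModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "adaptor-model-v1":
            raise ValueError(f"{path}: not an adaptor model archive")
        fp_dtype = (
            np.uint8
            if payload["fingerprint_kind"] == FingerprintKind.ECFP4.value
            else np.uint32
        )
        models = [
            DistanceModel(
                W=np.array(m["W"], dtype=float),
                beta=np.array(m["beta"], dtype=float),
                lam=m["lambda"],
                structure_anchor_ids=m["structure_anchor_ids"],
                response_anchor_ids=m["response_anchor_ids"],
                response_anchor_values=np.array(
                    m["response_anchor_values"], dtype=float
                ),
            )
            for m in payload["step_models"]
        ]
        return cls(
            model=models[-1],
            anchor_sets=AnchorSets(**payload["anchor_sets"]),
            anchor_fingerprints=np.array(payload["anchor_fingerprints"], dtype=fp_dtype),
            fingerprint_kind=payload["fingerprint_kind"],
            reconstruction=payload["reconstruction"],
            gamma=payload["gamma"],
            solver=payload["solver"],
            step_models=models,
            n_train=payload["n_train"],
        )


def _fit_step(
    data: FingerprintDataset,
    row_ids: list[str],
    structure_ids: list[str],
    response_ids: list[str],
    lam: float,
    rank_deficient: str = "raise",
) -> DistanceModel:
    """Fit one distance regression on the given rows/anchor columns."""
    idx = data.index_of
    rows = [idx[i] for i in row_ids]
    Ds = structure_distance_matrix(
        data.fingerprints,
        data.ids,
        anchor_index=[idx[i] for i in structure_ids],
        kind=data.kind,
        row_index=rows,
    )
    anchor_resp = data.responses[[idx[i] for i in response_ids]]
    Dr = response_distance_matrix(
        data.responses[rows], row_ids, anchor_resp, response_ids
    )
    return fit_distance_regression(
        Ds, Dr, lam=lam, response_anchor_values=anchor_resp,
        rank_deficient=rank_deficient,
    )


def fit_tr(
    data: FingerprintDataset,
    anchor_fraction: float = 0.6,
    lam: float = 0.0,
    reconstruction: ReconstructionMode | str = ReconstructionMode.RBF,
    gamma: float = 1.0,
    seed: int = 0,
) -> AdapToRModel:
    """Vanilla topological regression.

    round(anchor_fraction * N) randomly chosen training samples serve as
    both structure and response anchors; the regression rows are all
    training samples; OLS by default (falling back to the minimum-norm
    least-squares solution when the distance design is rank-deficient,
    the unregularized model's known failure mode); RBF reconstruction.
    """
    n = len(data)
    ka = int(round(anchor_fraction * n))
    anchor_ids = select_initial_structure_anchors(data.ids, ka, seed=seed)
    model = _fit_step(
        data, data.ids, anchor_ids, anchor_ids, lam=lam, rank_deficient="minnorm"
    )
    sets = AnchorSets(structure_sets=[anchor_ids], response_ids=anchor_ids)
    idx = data.index_of
    return AdapToRModel(
        model=model,
        anchor_sets=sets,
        anchor_fingerprints=data.fingerprints[[idx[i] for i in anchor_ids]],
        fingerprint_kind=data.kind,
        reconstruction=reconstruction,
        gamma=gamma,
        n_train=n,
    )


def fit_enhanced_tr(
    data: FingerprintDataset,
    anchor_fraction: float = 0.6,
    lam: float = 0.05,
    Kr: int = 10,
    reconstruction: ReconstructionMode | str = ReconstructionMode.OPTIMIZATION,
    gamma: float = 1.0,
    seed: int = 0,
) -> AdapToRModel:
    """TR with every enhancement except adaptive anchor selection.

    Ridge fit, k-means response anchors and the chosen reconstruction,
    with a single random structure-anchor set — the ensemble/stacking
    member model.
    """
    seeds = _spawn_seeds(seed, 2)
    n = len(data)
    ka = int(round(anchor_fraction * n))
    structure_ids = select_initial_structure_anchors(data.ids, ka, seed=seeds[0])
    response_ids = select_response_anchors(data.responses, data.ids, Kr, seed=seeds[1])
    model = _fit_step(data, data.ids, structure_ids, response_ids, lam=lam)
    sets = AnchorSets(structure_sets=[structure_ids], response_ids=response_ids)
    idx = data.index_of
    return AdapToRModel(
        model=model,
        anchor_sets=sets,
        anchor_fingerprints=data.fingerprints[[idx[i] for i in structure_ids]],
        fingerprint_kind=data.kind,
        reconstruction=reconstruction,
        gamma=gamma,
        n_train=n,
    )


def fit_adaptor(
    data: FingerprintDataset,
    cfg: AnchorConfig | None = None,
    lam: float = 0.05,
    reconstruction: ReconstructionMode | str = ReconstructionMode.OPTIMIZATION,
    gamma: float = 1.0,
    keep_history: bool = True,
) -> AdapToRModel:
    """Fit AdapToR with adaptive structure-anchor selection.

    For p = 1..P the step-p regression uses the current anchor set S_p
    as both its rows and structure-distance columns (response anchors
    are fixed k-means picks from the full training set); the training
    samples outside S_p are scored, and the Ka with the highest absolute
    prediction error join the anchors for step p+1. With early stopping
    enabled, a validation split is carved off first and the loop stops
    once validation NRMSE stalls.
    """
    cfg = cfg or AnchorConfig()
    reconstruction = ReconstructionMode(reconstruction)
    seeds = _spawn_seeds(cfg.seed, 4)  # split / anchors / kmeans / noise
    n_total = len(data)

    if cfg.early_stopping:
        if not (0 < cfg.val_fraction < 1):
            raise AnchorConfigError(
                "early stopping requires a validation split (0 < val_fraction < 1)"
            )
        rng = np.random.default_rng(seeds[0])
        n_val = max(1, int(round(cfg.val_fraction * n_total)))
        val_pick = set(rng.choice(n_total, size=n_val, replace=False).tolist())
        val_ids = [data.ids[i] for i in sorted(val_pick)]
        train_ids = [i for k, i in enumerate(data.ids) if k not in val_pick]
        val_data = data.subset(val_ids)
        train = data.subset(train_ids)
    else:
        val_data = None
        train = data

    n = len(train)
    cfg.validate_for(n)
    ka = cfg.ka_for(n)
    idx = train.index_of

    response_ids = select_response_anchors(
        train.responses, train.ids, cfg.Kr, seed=seeds[2]
    )
    S = select_initial_structure_anchors(train.ids, ka, seed=seeds[1])

    structure_sets: list[list[str]] = []
    step_models: list[DistanceModel] = []
    val_history: list[float] = []

    for p in range(1, cfg.P + 1):
        structure_sets.append(list(S))
        model = _fit_step(train, list(S), list(S), response_ids, lam=lam)
        step_models.append(model)

        partial = AdapToRModel(
            model=model,
            anchor_sets=AnchorSets(structure_sets=[list(S)], response_ids=response_ids),
            anchor_fingerprints=train.fingerprints[[idx[i] for i in S]],
            fingerprint_kind=train.kind,
            reconstruction=reconstruction,
            gamma=gamma,
            n_train=n,
        )

        if cfg.early_stopping and val_data is not None:
            resid = val_data.responses - partial.predict(val_data)
            denom = np.std(val_data.responses)
            val_history.append(float(np.sqrt(np.mean(resid**2)) / denom))
            if early_stop_check(val_history, cfg.min_delta, cfg.patience):
                break

        if p == cfg.P:
            break
        in_S = set(S)
        held_ids = [i for i in train.ids if i not in in_S]
        held = train.subset(held_ids)
        abs_err = np.abs(held.responses - partial.predict(held))
        S_star = rank_by_absolute_error(held_ids, abs_err, ka)
        S = sorted(set(S) | set(S_star))

    final = step_models[-1]
    sets = AnchorSets(structure_sets=structure_sets, response_ids=response_ids)
    return AdapToRModel(
        model=final,
        anchor_sets=sets,
        anchor_fingerprints=train.fingerprints[[idx[i] for i in sets.final_ids]],
        fingerprint_kind=train.kind,
        reconstruction=reconstruction,
        gamma=gamma,
        step_models=step_models if keep_history else [],
        n_train=n,
    )
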