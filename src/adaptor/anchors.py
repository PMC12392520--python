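"""Anchor selection: k-means response anchors and structure-anchor sets.

Response anchors are the handful of training molecules (default 10)
whose responses sit closest to k-means cluster centers in response
space, guaranteeing coverage of the response range. Structure anchors
are either a random fraction of the training set (vanilla usage) or
grown adaptively over P steps by adding, at each step, the Ka held-out
training samples with the highest absolute prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans


class AnchorConfigError(ValueError):
    """Infeasible anchor configuration for the given dataset size."""


@dataclass
class AnchorConfig:
    """Hyperparameters of anchor selection.

    Defaults follow the tuned values used throughout: 10 response
    anchors, Ka/N = 0.15 structure anchors added per step, P = 4 steps
    (so the final set holds 60% of training samples), early stopping off
    with min_delta 0.006 and patience 2 when enabled.
    """

    Kr: int = 10
    anchor_fraction: float = 0.15
    P: int = 4
    min_delta: float = 0.006
    patience: int = 2
    early_stopping: bool = False
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.anchor_fraction <= 1):
            raise AnchorConfigError(
                f"anchor_fraction must be in (0, 1], got {self.anchor_fraction}"
            )
        if self.P < 1:
            raise AnchorConfigError(f"P must be >= 1, got {self.P}")
        if self.Kr < 1:
            raise AnchorConfigError(f"Kr must be >= 1, got {self.Kr}")

    def ka_for(self, n: int) -> int:
        """Structure anchors added per step: round(anchor_fraction * N)."""
        ka = int(round(self.anchor_fraction * n))
        if ka < 1:
            raise AnchorConfigError(
                f"anchor_fraction {self.anchor_fraction} yields 0 anchors for N={n}"
            )
        return ka

    def validate_for(self, n: int) -> None:
        ka = self.ka_for(n)
        if self.P * ka > n:
            raise AnchorConfigError(
                f"P*Ka = {self.P * ka} exceeds N = {n}; reduce P or anchor_fraction"
            )
        if self.Kr > n:
            raise AnchorConfigError(f"Kr = {self.Kr} exceeds N = {n}")


@dataclass
class AnchorSets:
    """History of nested structure-anchor sets plus the response anchors.

    structure_sets[p-1] holds the ids used by the step-p model; sets are
    nested (S_1 ⊂ S_2 ⊂ ... ⊂ S_P) with |S_p| = p * Ka.
    """

    structure_sets: list[list[str]]
    response_ids: list[str]

    def __post_init__(self) -> None:
        prev: set[str] = set()
        for p, ids in enumerate(self.structure_sets, start=1):
            cur = set(ids)
            if len(cur) != len(ids):
                raise ValueError(f"duplicate ids in structure set {p}")
            if not prev <= cur:
                raise ValueError(f"structure set {p} does not contain set {p - 1}")
            prev = cur
        if len(set(self.response_ids)) != len(self.response_ids):
            raise ValueError("duplicate response anchor ids")

    @property
    def final_ids(self) -> list[str]:
        return self.structure_sets[-1]


def select_response_anchors(
    responses: np.ndarray,
    ids: Sequence[str],
    Kr: int,
    seed: int = 0,
) -> list[str]:
    """Pick Kr response anchors by k-means clustering in response space.

    Runs k-means (10 restarts, seeded) on the scalar responses and
    returns, per cluster, the member sample closest to the cluster
    center; ties go to the lower molecule id. The selected anchors are
    spread across the observed response range by construction.
    """
    responses = np.asarray(responses, dtype=float)
    n = responses.size
    if Kr > n:
        raise AnchorConfigError(f"Kr = {Kr} exceeds the number of samples ({n})")
    km = KMeans(n_clusters=Kr, n_init=10, random_state=seed)
    labels = km.fit_predict(responses.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()

    chosen: list[str] = []
    for c in range(Kr):
        members = np.flatnonzero(labels == c)
        # lexicographic: distance to center first, then molecule id for ties
        order = sorted(members, key=lambda i: (np.abs(responses[i] - centers[c]), ids[i]))
        chosen.append(ids[order[0]])
    # stable presentation order: by anchor response value
    chosen.sort(key=lambda mid: (responses[list(ids).index(mid)], mid))
    return chosen


def select_initial_structure_anchors(
    ids: Sequence[str], Ka: int, seed: int = 0
) -> list[str]:
    """Uniform random subset of Ka molecule ids, reproducible by seed."""
    if Ka > len(ids):
        raise AnchorConfigError(f"Ka = {Ka} exceeds the number of samples ({len(ids)})")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ids), size=Ka, replace=False)
    return [ids[i] for i in sorted(pick)]


def rank_by_absolute_error(
    ids: Sequence[str], abs_errors: np.ndarray, Ka: int
) -> list[str]:
    """Top-Ka ids by absolute prediction error; ties break on lower id."""
    order = sorted(range(len(ids)), key=lambda i: (-abs_errors[i], ids[i]))
    return [ids[i] for i in order[:Ka]]


def early_stop_check(
    history: Sequence[float], min_delta: float = 0.006, patience: int = 2
) -> bool:
    """True when the validation score stalled for `patience` steps.

    ``history`` is the per-step validation NRMSE (lower is better);
    stalling means the decrease from one step to the next fell below
    ``min_delta`` for ``patience`` consecutive transitions.
    """
    if len(history) == 0:
        raise ValueError("history must be nonempty")
    if len(history) <= patience:
        return False
    recent = list(history)[-(patience + 1):]
    improvements = [a - b for a, b in zip(recent[:-1], recent[1:])]
    return all(imp < min_delta for imp in improvements)
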