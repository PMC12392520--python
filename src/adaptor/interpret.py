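"""Weight-based interpretation of a fitted distance model.

Each column of the fitted W is the weight vector tied to one response
anchor: a positive (i, j) entry means a sample's structure distance to
structure anchor j pushes its estimated response distance to response
anchor i up. Critical structure anchors are found by flipping the sign
of columns belonging to low-response anchors (t_k below a threshold,
default 5 on the NLOGGI50 scale) and summing each row of the adjusted
weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import DistanceModel


@dataclass
class AnchorWeight:
    anchor_id: str
    weight: float


def top_anchors_for_response_anchor(
    model: DistanceModel, response_anchor_index: int, k: int = 5
) -> tuple[list[AnchorWeight], list[AnchorWeight]]:
    """Top-k positive and top-k negative structure-anchor weights.

    Returns (positive, negative): the k structure anchors with the
    largest positive weights in the chosen W column, and the k with the
    most negative; anchors with zero weight appear in neither list.
    """
    Kr = model.n_response_anchors
    if not (0 <= response_anchor_index < Kr):
        raise IndexError(
            f"response anchor index {response_anchor_index} out of range [0, {Kr})"
        )
    if k > model.n_structure_anchors:
        raise ValueError(f"k = {k} exceeds the number of structure anchors")
    col = model.W[:, response_anchor_index]
    ids = model.structure_anchor_ids
    if np.all(col == 0):
        warnings.warn(
            "all weights for this response anchor are zero", RuntimeWarning,
            stacklevel=2,
        )
        return [], []
    order = np.argsort(-col, kind="stable")
    positive = [
        AnchorWeight(ids[i], float(col[i])) for i in order[:k] if col[i] > 0
    ]
    negative = [
        AnchorWeight(ids[i], float(col[i])) for i in order[::-1][:k] if col[i] < 0
    ]
    return positive, negative


def adjust_weights(model: DistanceModel, low_response_threshold: float = 5.0) -> np.ndarray:
    """W with columns of low-response anchors (t_k < threshold) sign-flipped."""
    signs = np.where(model.response_anchor_values < low_response_threshold, -1.0, 1.0)
    return model.W * signs[None, :]


def adjusted_weight_sums(
    model: DistanceModel, low_response_threshold: float = 5.0
) -> pd.DataFrame:
    """Per-structure-anchor adjusted-weight sums, ranked by score.

    Columns of W tied to response anchors with t_k below the threshold
    are multiplied by -1, then rows are summed: a large positive score
    means closeness to that structure anchor is associated with high
    responses, a large negative score the opposite.
    """
    scores = adjust_weights(model, low_response_threshold).sum(axis=1)
    df = pd.DataFrame(
        {"anchor_id": model.structure_anchor_ids, "score": scores}
    )
    df["sign"] = np.sign(df["score"]).astype(int)
    df = df.reindex(df["score"].abs().sort_values(ascending=False).index)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def interpretation_report(
    model: DistanceModel,
    k: int = 5,
    low_response_threshold: float = 5.0,
    anchor_responses: dict[str, float] | None = None,
    anchor_smiles: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Bundle per-response-anchor top lists and the adjusted-sum ranking.

    Returns {"summary": adjusted-sum table, "response_anchor_<i>": top-k
    table per response anchor}; optional lookups attach each anchor's
    own response value and SMILES to the rows.
    """
    def enrich(df: pd.DataFrame) -> pd.DataFrame:
        if anchor_responses is not None:
            df["anchor_response"] = df["anchor_id"].map(anchor_responses)
        if anchor_smiles is not None:
            df["smiles"] = df["anchor_id"].map(anchor_smiles)
        return df

    out: dict[str, pd.DataFrame] = {
        "summary": enrich(adjusted_weight_sums(model, low_response_threshold))
    }
    for i, rid in enumerate(model.response_anchor_ids):
        pos, neg = top_anchors_for_response_anchor(model, i, k=k)
        rows = [
            {"anchor_id": a.anchor_id, "weight": a.weight, "direction": "positive"}
            for a in pos
        ] + [
            {"anchor_id": a.anchor_id, "weight": a.weight, "direction": "negative"}
            for a in neg
        ]
        out[f"response_anchor_{i}"] = enrich(
            pd.DataFrame(rows, columns=["anchor_id", "weight", "direction"])
        )
    return out
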