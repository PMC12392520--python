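"""Evaluation metrics and the drug-blind cross-validation harness.

The four metrics are the standard QSAR regression panel: NRMSE (RMSE
scaled by the standard deviation of the observed responses, so the
mean-predictor null model scores exactly 1), Spearman's rank
correlation, Pearson correlation, and bias — the slope of the best-fit
line of the residuals against the observed responses (0 for unbiased
predictions, 1 for the null model).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import FingerprintDataset


class MetricError(ValueError):
    """Metrics undefined (e.g. constant observed responses)."""


@dataclass
class MetricsReport:
    nrmse: float
    spearman_rho: float
    pcc: float
    bias: float
    n: int
    train_time_s: float = 0.0
    test_time_s: float = 0.0

    def to_dict(self) -> dict:
        return {
            "NRMSE": self.nrmse,
            "Spearman": self.spearman_rho,
            "PCC": self.pcc,
            "Bias": self.bias,
            "n": self.n,
            "train_time_s": self.train_time_s,
            "test_time_s": self.test_time_s,
        }


def _validate(y: np.ndarray, y_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or y.size < 2:
        raise MetricError("y and y_hat must be equal-length 1-D arrays, length >= 2")
    if np.ptp(y) == 0:
        raise MetricError("metrics undefined for constant observed responses")
    return y, y_hat


def nrmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """RMSE divided by the (population) standard deviation of y."""
    y, y_hat = _validate(y, y_hat)
    return float(np.sqrt(np.sum((y - y_hat) ** 2) / np.sum((y - np.mean(y)) ** 2)))


def spearman_rho(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Spearman rank correlation with mid-rank handling of ties."""
    y, y_hat = _validate(y, y_hat)
    if np.ptp(y_hat) == 0:
        return 0.0  # constant predictions carry no rank information
    ry = stats.rankdata(y)
    rh = stats.rankdata(y_hat)
    n = y.size
    has_ties = np.unique(ry).size < n or np.unique(rh).size < n
    if not has_ties:
        v = ry - rh
        return float(1 - 6 * np.sum(v**2) / (n * (n**2 - 1)))
    # with ties the rank-difference formula is invalid; use the
    # product-moment correlation of mid-ranks instead
    return float(stats.pearsonr(ry, rh).statistic)


def pcc(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation between observed and predicted responses."""
    y, y_hat = _validate(y, y_hat)
    if np.ptp(y_hat) == 0:
        return 0.0
    return float(stats.pearsonr(y, y_hat).statistic)


def bias(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Slope of the residuals (y - y_hat) regressed on y."""
    y, y_hat = _validate(y, y_hat)
    yc = y - np.mean(y)
    return float(np.sum(yc * (y - y_hat)) / np.sum(yc**2))


def bias_angle_check(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Bias via the centered-vector angle route.

    Geometrically the bias is the regression coefficient of the centered
    residual vector on the centered observed vector, i.e.
    ||r_c|| cos(angle(y_c, r_c)) / ||y_c||; must agree with the ratio
    formula to ~1e-10.
    """
    y, y_hat = _validate(y, y_hat)
    yc = y - np.mean(y)
    r = y - y_hat
    rc = r - np.mean(r)
    norm_r = np.linalg.norm(rc)
    if norm_r == 0:
        return 0.0
    cos_angle = float(np.dot(yc, rc) / (np.linalg.norm(yc) * norm_r))
    return float(norm_r * cos_angle / np.linalg.norm(yc))


def compute_metrics(
    y: np.ndarray,
    y_hat: np.ndarray,
    train_time_s: float = 0.0,
    test_time_s: float = 0.0,
) -> MetricsReport:
    """Full metric panel for one set of predictions."""
    y, y_hat = _validate(y, y_hat)
    return MetricsReport(
        nrmse=nrmse(y, y_hat),
        spearman_rho=spearman_rho(y, y_hat),
        pcc=pcc(y, y_hat),
        bias=bias(y, y_hat),
        n=int(y.size),
        train_time_s=train_time_s,
        test_time_s=test_time_s,
    )


class ModelSpec(Protocol):
    """fit/predict pair used by the cross-validation harness."""

    def fit(self, train: FingerprintDataset, seed: int) -> object: ...

    def predict(self, fitted: object, test: FingerprintDataset) -> np.ndarray: ...


@dataclass
class CallableSpec:
    """ModelSpec built from two plain callables."""

    fit_fn: Callable[[FingerprintDataset, int], object]
    name: str = "model"

    def fit(self, train: FingerprintDataset, seed: int) -> object:
        return self.fit_fn(train, seed)

    def predict(self, fitted: object, test: FingerprintDataset) -> np.ndarray:
        return fitted.predict(test)


class NullModelSpec:
    """Mean-of-training-responses predictor: the NRMSE = 1 reference."""

    name = "null"

    def fit(self, train: FingerprintDataset, seed: int) -> float:
        return float(np.mean(train.responses))

    def predict(self, fitted: float, test: FingerprintDataset) -> np.ndarray:
        return np.full(len(test), fitted)


def make_folds(ids: Sequence[str], folds: int, seed: int) -> list[list[str]]:
    """Disjoint drug-blind test folds by uniform shuffle (seeded)."""
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate molecule ids would leak drugs across folds")
    if len(ids) < folds:
        raise ValueError(f"cannot split {len(ids)} samples into {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(order, folds)]


def cross_validate(
    data: FingerprintDataset,
    spec: ModelSpec,
    folds: int = 5,
    seed: int = 0,
) -> list[MetricsReport]:
    """Drug-blind k-fold cross-validation of one model spec.

    Each molecule appears in exactly one test fold; per fold the model
    is fitted on the remaining samples and scored on the fold. Fold
    assignment is an independent uniform shuffle per dataset.
    """
    test_folds = make_folds(data.ids, folds, seed)
    reports: list[MetricsReport] = []
    for k, test_ids in enumerate(test_folds):
        test_set = set(test_ids)
        train_ids = [i for i in data.ids if i not in test_set]
        train = data.subset(train_ids)
        test = data.subset(test_ids)
        t0 = time.perf_counter()
        fitted = spec.fit(train, seed + k)
        t1 = time.perf_counter()
        y_hat = spec.predict(fitted, test)
        t2 = time.perf_counter()
        reports.append(
            compute_metrics(
                test.responses, y_hat, train_time_s=t1 - t0, test_time_s=t2 - t1
            )
        )
    return reports


def summarize_cv(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Mean and standard deviation of each metric across folds."""
    df = pd.DataFrame([r.to_dict() for r in reports])
    return df.agg(["mean", "std"])


def reports_to_frame(
    reports: Sequence[MetricsReport], dataset: str = "", model: str = ""
) -> pd.DataFrame:
    """One row per fold, Table-style columns, ready for CSV output."""
    rows = []
    for k, r in enumerate(reports):
        row = {"dataset": dataset, "model": model, "fold": k}
        row.update(r.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models_wilcoxon(scores_a: Sequence[float], scores_b: Sequence[float]):
    """Paired Wilcoxon signed-rank comparison of per-fold scores."""
    return stats.wilcoxon(scores_a, scores_b)
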