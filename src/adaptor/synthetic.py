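"""Synthetic fixtures: the four-anchor toy geometry and full QSAR datasets.

The toy example places four response anchors (responses 4, 5, 6, 8) and
one test sample (response 7) on the response line and perturbs the true
response distances with Gaussian noise (sd 0.5 by default), mirroring
the empirical distance-estimation error of fitted models.

The full generator emulates the regime the method assumes: responses
vary smoothly over a latent chemical space and structural similarity is
informative about response similarity. Molecules are latent 2-D points;
the response is a smooth multi-modal surface of the coordinates plus
noise, rescaled into the NLOGGI50-like range (4, 8); fingerprints are
random-hyperplane bit codes of the latent point, so Jaccard distance
grows with latent distance on average. Fingerprints are abstract bit
vectors, not derived from SMILES — the modeling stack only ever sees
fingerprints and distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import FingerprintDataset, FingerprintKind
from .reconstruct import ReconstructionInput


@dataclass
class ToyExample:
    """One noisy reconstruction instance with its ground truth."""

    input: ReconstructionInput
    true_response: float
    true_distances: np.ndarray
    noise: np.ndarray


def make_toy_example(
    anchor_responses: tuple[float, ...] = (4.0, 5.0, 6.0, 8.0),
    test_response: float = 7.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> ToyExample:
    """Toy reconstruction instance: true distances |t - t_k| plus noise."""
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    anchors = np.asarray(anchor_responses, dtype=float)
    true_d = np.abs(test_response - anchors)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=anchors.size) if noise_sd > 0 else np.zeros(
        anchors.size
    )
    d_hat = true_d + noise
    return ToyExample(
        input=ReconstructionInput(d_hat=d_hat, anchor_responses=anchors),
        true_response=float(test_response),
        true_distances=true_d,
        noise=noise,
    )


@dataclass
class SyntheticDataset:
    """Generated dataset plus the latent ground truth behind it."""

    data: FingerprintDataset
    latent: np.ndarray  # (N, 2) latent coordinates
    noiseless_responses: np.ndarray  # surface values before noise, same scale

    def write(self, csv_path: str | Path, fingerprints_path: str | Path) -> None:
        """Write the molecule table CSV and the fingerprint sidecar."""
        pd.DataFrame({"id": self.data.ids, "response": self.data.responses}).to_csv(
            csv_path, index=False
        )
        fp = pd.DataFrame(
            self.data.fingerprints,
            columns=[f"f{j}" for j in range(self.data.fingerprints.shape[1])],
        )
        fp.insert(0, "id", self.data.ids)
        fp.to_csv(fingerprints_path, index=False)


def read_fingerprint_dataset(
    csv_path: str | Path,
    fingerprints_path: str | Path,
    kind: FingerprintKind | str = FingerprintKind.ECFP4,
    name: str = "",
) -> FingerprintDataset:
    """Load an (id, response) CSV paired with a fingerprint sidecar."""
    df = pd.read_csv(csv_path)
    fp = pd.read_csv(fingerprints_path)
    if list(df["id"].astype(str)) != list(fp["id"].astype(str)):
        raise ValueError("molecule table and fingerprint sidecar ids disagree")
    values = fp.drop(columns=["id"]).to_numpy()
    return FingerprintDataset(
        ids=[str(i) for i in df["id"]],
        responses=df["response"].to_numpy(dtype=float),
        fingerprints=values,
        kind=kind,
        name=name or Path(csv_path).stem,
    )


def _response_surface(latent: np.ndarray) -> np.ndarray:
    """Smooth multi-modal surface on [0, 1]^2, range roughly [0, 1].

    A gentle diagonal gradient plus three Gaussian bumps: multi-modal
    enough that a single random anchor set underfits locally, smooth
    enough that structure distances predict response distances.
    """
    x, y = latent[:, 0], latent[:, 1]
    bumps = (
        0.9 * np.exp(-((x - 0.25) ** 2 + (y - 0.7) ** 2) / 0.02)
        + 0.7 * np.exp(-((x - 0.75) ** 2 + (y - 0.2) ** 2) / 0.03)
        + 0.5 * np.exp(-((x - 0.6) ** 2 + (y - 0.85) ** 2) / 0.015)
    )
    return 0.4 * (x + y) / 2 + 0.6 * bumps / 0.9


def make_synthetic_qsar(
    N: int,
    n_features: int = 512,
    response_range: tuple[float, float] = (4.0, 8.0),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a synthetic fingerprint/response dataset.

    Parameters
    ----------
    N
        Number of molecules (>= 20).
    n_features
        Fingerprint length; each bit is a random half-plane indicator
        of the latent coordinates, so Hamming/Jaccard distance between
        fingerprints grows with latent distance.
    response_range
        Responses are rescaled (after adding noise) to exactly span
        this interval, emulating the observed NLOGGI50 range.
    noise_sd
        Gaussian noise sd on the unit-scale surface before rescaling.
    """
    if N < 20:
        raise ValueError(f"N must be >= 20, got {N}")
    if n_features < 8:
        raise ValueError(f"n_features must be >= 8, got {n_features}")
    lo, hi = response_range
    if not (hi > lo):
        raise ValueError(f"degenerate response_range {response_range}")
    rng = np.random.default_rng(seed)

    latent = rng.uniform(0.0, 1.0, size=(N, 2))
    surface = _response_surface(latent)
    noisy = surface + rng.normal(0.0, noise_sd, size=N)

    def rescale(v: np.ndarray) -> np.ndarray:
        return lo + (v - noisy.min()) * (hi - lo) / (noisy.max() - noisy.min())

    responses = rescale(noisy)

    # random-hyperplane bit code of the latent point
    directions = rng.normal(size=(n_features, 2))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    projections = latent @ directions.T  # (N, n_features)
    offsets = rng.uniform(
        projections.min(axis=0), projections.max(axis=0)
    )
    bits = (projections > offsets[None, :]).astype(np.uint8)

    data = FingerprintDataset(
        ids=[f"mol{i:05d}" for i in range(N)],
        responses=responses,
        fingerprints=bits,
        kind=FingerprintKind.ECFP4,
        name=f"synthetic_seed{seed}",
    )
    return SyntheticDataset(
        data=data,
        latent=latent,
        noiseless_responses=rescale(surface),
    )
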