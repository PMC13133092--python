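"""Joint PCA embedding of the latent tensor.

All 2N latent vectors (N circuitries x 2 sides) are standardized
globally — column mean subtracted, column sample SD divided out — and
decomposed by a single PCA fitted on the pooled tensor.  The first
three principal components define the shared 3-D coordinate system in
which barycenter distances are measured; the full 18-component rotation
is retained so distances in complete score space are an isometry of the
standardized space.

Zero-variance columns are centered and assigned scale 1 so they pass
through as exact zeros, contributing no variance but never producing
NaNs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError, ShapeError


def standardize(
    tensor: np.ndarray, scale: bool = True, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Globally center and scale a (rows x d) tensor column-wise.

    Returns ``(standardized, means, scales)``.  Columns with zero
    variance keep scale 1 (they become exactly zero after centering).
    With ``scale=False`` only centering is applied (all scales 1).
    """
    X = np.asarray(tensor, dtype=float)
    if X.ndim != 2:
        raise ShapeError(f"expected a 2-D tensor, got ndim={X.ndim}")
    if X.shape[0] < 2:
        raise InsufficientDataError("standardization needs at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise DomainError("tensor contains non-finite entries")
    means = X.mean(axis=0)
    constant = np.ptp(X, axis=0) == 0  # exact: all entries identical
    if scale:
        sds = X.std(axis=0, ddof=ddof)
        scales = np.where(constant | (sds == 0), 1.0, sds)
    else:
        scales = np.ones(X.shape[1])
    Z = (X - means) / scales
    Z[:, constant] = 0.0  # centering residue on constant columns is noise
    return Z, means, scales


@dataclass
class EmbeddingModel:
    """Frozen coordinate system: column statistics plus PCA rotation.

    ``loadings`` columns are the principal axes ordered by decreasing
    eigenvalue, with a deterministic sign convention (largest-magnitude
    entry of each column is positive).
    """

    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (d x d), columns = components
    eigenvalues: np.ndarray
    n_components_default: int = 3

    @property
    def n_features(self) -> int:
        return self.means.shape[0]

    def project(self, vectors: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Project raw latent vectors into PC space.

        Applies ``(x - means) / scales`` then the loadings, returning the
        first ``n_components`` coordinates (default: the model default, 3).
        Accepts a single vector or a (k x d) matrix.
        """
        k = n_components if n_components is not None else self.n_components_default
        if not (1 <= k <= self.n_features):
            raise ShapeError(f"n_components must lie in [1, {self.n_features}]")
        V = np.atleast_2d(np.asarray(vectors, dtype=float))
        if V.shape[1] != self.n_features:
            raise ShapeError(
                f"expected vectors of dimension {self.n_features}, got {V.shape[1]}"
            )
        scores = ((V - self.means) / self.scales) @ self.loadings[:, :k]
        return scores[0] if np.asarray(vectors).ndim == 1 else scores

    def to_json(self, path) -> None:
        payload = {
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_components_default": self.n_components_default,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "EmbeddingModel":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            means=np.asarray(payload["means"], dtype=float),
            scales=np.asarray(payload["scales"], dtype=float),
            loadings=np.asarray(payload["loadings"], dtype=float),
            eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
            n_components_default=int(payload["n_components_default"]),
        )


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Pin PCA signs: make each column's largest-|entry| positive."""
    out = loadings.copy()
    idx = np.argmax(np.abs(out), axis=0)
    signs = np.sign(out[idx, np.arange(out.shape[1])])
    signs[signs == 0] = 1.0
    return out * signs


def fit_pca(
    standardized: np.ndarray,
    means: np.ndarray | None = None,
    scales: np.ndarray | None = None,
    n_components_default: int = 3,
) -> EmbeddingModel:
    """Fit the full PCA decomposition on an already-standardized tensor.

    All components are retained so the score space is a rotation of the
    standardized space.  ``means``/``scales`` record the standardization
    applied upstream (identity if omitted), so the resulting model
    projects raw-scale vectors.
    """
    X = np.asarray(standardized, dtype=float)
    if not np.all(np.isfinite(X)):
        raise DomainError("standardized tensor contains non-finite entries")
    n, d = X.shape
    # full-matrices SVD keeps all d principal axes even when n < d, so the
    # score space is always a complete rotation of the standardized space
    Xc = X - X.mean(axis=0)
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=True)
    loadings = _fix_signs(Vt.T)
    eigenvalues = np.zeros(d)
    k = min(n, d)
    eigenvalues[:k] = svals[:k] ** 2 / max(n - 1, 1)
    return EmbeddingModel(
        means=np.zeros(d) if means is None else np.asarray(means, dtype=float),
        scales=np.ones(d) if scales is None else np.asarray(scales, dtype=float),
        loadings=loadings,
        eigenvalues=eigenvalues,
        n_components_default=n_components_default,
    )


def fit_embedding(
    tensor: np.ndarray,
    scale: bool = True,
    ddof: int = 1,
    n_components_default: int = 3,
) -> EmbeddingModel:
    """Convenience wrapper: standardize then fit the joint PCA."""
    Z, means, scales = standardize(tensor, scale=scale, ddof=ddof)
    return fit_pca(Z, means=means, scales=scales, n_components_default=n_components_default)
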