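"""PCA with an explicit reuse contract.

The decomposition is fitted on the averaged, scatter-corrected pure-sample
spectra only; mixture spectra are *projected* with the identical, frozen
transformation (same center, same loadings). That keeps the mixture scores
comparable with the pure-sample scores and makes the "mixtures fall on the
line between the pure groups" reading legitimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["PCAModel", "pca_fit", "pca_project"]


@dataclass(frozen=True)
class PCAModel:
    """Frozen principal-component transformation.

    center : mean spectrum of the fit set;
    loadings : (k, p) orthonormal component directions, variance-ordered;
    explained_variance_ratio : fraction of total variance per component
    (sums to 1 when all components are kept).
    """

    center: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def pca_fit(spectra: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Centered, unscaled, SVD-based PCA.

    Keeps all min(n - 1, p) components by default. The sign of each
    component is fixed so its largest-magnitude loading element is
    positive, making outputs reproducible across SVD implementations.
    """
    x = np.asarray(spectra, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("PCA needs a 2-D matrix with at least 2 rows")
    center = x.mean(axis=0)
    xc = x - center
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(x.shape[0] - 1, x.shape[1])
    if n_components is not None:
        k = min(k, n_components)
    s, vt = s[:k], vt[:k]
    # deterministic sign: largest-|loading| element of each component > 0
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    var = s**2
    total = float((xc**2).sum())
    ratios = var / total if total > 0 else np.zeros(k)
    return PCAModel(center=center, loadings=vt,
                    explained_variance_ratio=ratios)


def pca_project(model: PCAModel, spectra: np.ndarray) -> np.ndarray:
    """Project spectra into the frozen PCA space: (x - center) @ loadings.T.

    Projecting the fit set reproduces the fit scores; projecting the
    model's own center gives all-zero scores.
    """
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if x.shape[1] != model.center.size:
        raise ValidationError(
            f"spectra have {x.shape[1]} channels, model expects "
            f"{model.center.size}")
    scores = (x - model.center) @ model.loadings.T
    return scores[0] if np.asarray(spectra).ndim == 1 else scores
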