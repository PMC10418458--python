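"""Spectral preprocessing: replicate averaging, MSC, SNV, detrend, derivative.

The pipeline order is fixed: technical replicates are averaged per
sample/mixture first, then one scatter-correction variant is applied,
then the data go to PCA or regression. Variants:

``msc``
    Multiplicative scatter correction. Each spectrum x is regressed on a
    reference spectrum r by least squares, x ~ a + b*r, and corrected as
    (x - a) / b. This inverts exactly the simulator's replicate-level
    distortion y = b*x + a.
``snv``
    Standard normal variate: per-spectrum standardization to mean 0, unit
    SD (n-1 denominator).
``detrend_snv``
    SNV followed by removal of a 2nd-degree polynomial baseline in
    wavenumber.
``msc_d1``
    MSC followed by a smoothed first derivative (moving average of length
    101, then finite differences over the signed 4 cm^-1 channel step).

The MSC reference contract matters for validity: for exploratory plots the
reference is the mean of all pure-sample spectra; inside cross-validation
it is computed from the training samples only and the *same* reference is
applied to the test spectra, so no test-set information leaks into
preprocessing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, ValidationError
from .grid import WavenumberGrid
from .io import Dataset

__all__ = [
    "average_replicates",
    "msc_reference",
    "msc_correct",
    "snv",
    "detrend_snv",
    "smoothed_first_derivative",
    "apply_preprocessing",
    "PREPROCESSING_VARIANTS",
]

PREPROCESSING_VARIANTS = ("msc", "snv", "detrend_snv", "msc_d1")

_B_TOL = 1e-12


def average_replicates(dataset: Dataset) -> Dataset:
    """Collapse technical replicates to one per-channel mean spectrum per
    sample; the replicate count is recorded in an ``n_replicates`` column
    and the sample id becomes the measurement id."""
    meta = dataset.meta
    order = meta["sample_id"].drop_duplicates().tolist()
    groups = meta.groupby("sample_id", sort=False).indices
    rows, values = [], []
    for sid in order:
        idx = groups[sid]
        values.append(dataset.X[idx].mean(axis=0))
        first = meta.iloc[idx[0]]
        rows.append({
            "measurement_id": sid,
            "sample_id": sid,
            "role": first["role"],
            "shell_fraction": first["shell_fraction"],
            "nutmeg_id": first["nutmeg_id"],
            "shell_id": first["shell_id"],
            "replicate": 0,
            "n_replicates": len(idx),
        })
    return Dataset(grid=dataset.grid, X=np.asarray(values),
                   meta=pd.DataFrame(rows))


def msc_reference(dataset: Dataset, scope: str = "all_pure",
                  train_ids: list[str] | None = None) -> np.ndarray:
    """Reference spectrum for MSC.

    scope="all_pure": channel-wise mean over all pure nutmeg and shell
    measurements (the exploratory-analysis convention). scope="train_only":
    mean over the given training sample ids; the caller must apply this
    same reference to both training and test spectra.
    """
    if scope == "all_pure":
        mask = dataset.meta["role"].isin(["nutmeg", "shell"]).to_numpy()
    elif scope == "train_only":
        if train_ids is None:
            raise ValidationError("train_only scope requires train_ids")
        mask = dataset.meta["sample_id"].isin(train_ids).to_numpy()
    else:
        raise ValidationError(f"unknown MSC reference scope {scope!r}")
    if not mask.any():
        raise ValidationError(f"MSC reference scope {scope!r} selects nothing")
    return dataset.X[mask].mean(axis=0)


def msc_correct(spectra: np.ndarray, reference: np.ndarray,
                return_coef: bool = False):
    """Multiplicative scatter correction against a reference spectrum.

    Fits each spectrum as ``x ~ a + b * reference`` by ordinary least
    squares over all channels and returns ``(x - a) / b``. Accepts a single
    spectrum or a matrix (rows = spectra).

    Raises DegenerateFitError if the reference has zero variance or a
    fitted |b| is below tolerance.
    """
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    r = np.asarray(reference, dtype=float)
    r_centered = r - r.mean()
    denom = float(r_centered @ r_centered)
    if denom <= _B_TOL:
        raise DegenerateFitError("MSC reference spectrum has zero variance")
    b = (x - x.mean(axis=1, keepdims=True)) @ r_centered / denom
    a = x.mean(axis=1) - b * r.mean()
    if np.any(np.abs(b) < _B_TOL):
        raise DegenerateFitError("MSC multiplicative coefficient ~ 0")
    corrected = (x - a[:, None]) / b[:, None]
    if np.asarray(spectra).ndim == 1:
        corrected, a, b = corrected[0], float(a[0]), float(b[0])
    if return_coef:
        return corrected, a, b
    return corrected


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd, sd with the
    n-1 denominator. Raises on a constant spectrum."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    sd = x.std(axis=1, ddof=1)
    if np.any(sd <= 0):
        raise DegenerateFitError("SNV undefined for a constant spectrum")
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return out[0] if np.asarray(spectra).ndim == 1 else out


def detrend_snv(spectra: np.ndarray, grid: WavenumberGrid) -> np.ndarray:
    """SNV followed by subtraction of the least-squares 2nd-degree
    polynomial in wavenumber."""
    x = np.atleast_2d(snv(spectra))
    # orthonormal polynomial basis in wavenumber for a stable projection
    nu = (grid.values - grid.values.mean()) / grid.values.std()
    basis = np.vander(nu, 3, increasing=True)
    q, _ = np.linalg.qr(basis)
    out = x - (x @ q) @ q.T
    return out[0] if np.asarray(spectra).ndim == 1 else out


def smoothed_first_derivative(spectra: np.ndarray, grid: WavenumberGrid,
                              window: int = 101) -> np.ndarray:
    """Moving-average smoothing then first derivative w.r.t. wavenumber.

    The moving average is centered with a truncated (shrinking) window at
    the edges. The derivative uses central differences over the signed
    channel step (-step for a descending grid) with one-sided differences
    at the two ends. Window must be odd and no longer than the grid.
    """
    if window % 2 == 0:
        raise ValidationError(f"smoothing window must be odd, got {window}")
    if window > len(grid):
        raise ValidationError(
            f"smoothing window {window} exceeds grid length {len(grid)}")
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    half = window // 2
    n = x.shape[1]
    csum = np.cumsum(np.pad(x, ((0, 0), (1, 0))), axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    smooth = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    step = -grid.step  # descending axis
    deriv = np.empty_like(smooth)
    deriv[:, 1:-1] = (smooth[:, 2:] - smooth[:, :-2]) / (2 * step)
    deriv[:, 0] = (smooth[:, 1] - smooth[:, 0]) / step
    deriv[:, -1] = (smooth[:, -1] - smooth[:, -2]) / step
    return deriv[0] if np.asarray(spectra).ndim == 1 else deriv


def apply_preprocessing(spectra: np.ndarray, variant: str,
                        grid: WavenumberGrid,
                        reference: np.ndarray | None = None) -> np.ndarray:
    """Dispatch one preprocessing variant; MSC variants need a reference."""
    if variant not in PREPROCESSING_VARIANTS:
        raise ValidationError(
            f"unknown preprocessing variant {variant!r}; "
            f"choose from {PREPROCESSING_VARIANTS}")
    if variant in ("msc", "msc_d1"):
        if reference is None:
            raise ValidationError(f"variant {variant!r} requires a reference")
        corrected = msc_correct(spectra, reference)
        if variant == "msc":
            return corrected
        return smoothed_first_derivative(corrected, grid, window=101)
    if variant == "snv":
        return snv(spectra)
    return detrend_snv(spectra, grid)
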