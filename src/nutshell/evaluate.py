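"""Evaluation statistics for shell-content predictions.

Covers range-restricted R2 and RMSEP, the blank-prediction distribution
(pure nutmeg samples are the "blanks" of this assay — they contain no
shell, so their predicted shell content characterizes the method's noise
floor), Gaussian tail probabilities for exceeding a reporting threshold,
the 3-sigma/9-sigma detection and quantitation limits, and the true-vs-
predicted flow (Sankey) binning.

All percentages are on the 0-100 scale of shell mass percent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError

__all__ = [
    "BlankStats",
    "NormalTail",
    "DetectionLimits",
    "r_squared",
    "rmsep",
    "blank_stats",
    "normal_tail",
    "detection_limits",
    "flow_table",
]


@dataclass(frozen=True)
class BlankStats:
    """Distribution of predicted shell % over blank (pure nutmeg) samples."""

    mean: float
    sd: float
    max: float
    n: int


@dataclass(frozen=True)
class NormalTail:
    """P(prediction > threshold) for a zero-mean Gaussian blank model.

    z = threshold / sigma; area = Phi(z); upper_p = 1 - Phi(z).
    """

    sigma: float
    threshold: float
    z: float
    area: float
    upper_p: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DetectionLimits:
    """LOD = 3*sigma, LOQ = 9*sigma of the blank distribution, in %."""

    sigma: float
    lod: float
    loq: float


def _range_filter(y_true: np.ndarray, y_pred: np.ndarray,
                  value_range: tuple[float, float] | None):
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError("true and predicted arrays differ in length")
    if value_range is not None:
        lo, hi = value_range
        mask = (y_true >= lo) & (y_true <= hi)
        y_true, y_pred = y_true[mask], y_pred[mask]
    if y_true.size < 2:
        raise ValidationError("need >= 2 pairs inside the evaluation range")
    return y_true, y_pred


def r_squared(y_true, y_pred, value_range: tuple[float, float] | None = None,
              kind: str = "ss") -> float:
    """Coefficient of determination over pairs whose TRUE value is in range.

    kind="ss" (default): 1 - SS_res/SS_tot of predicted vs. true.
    kind="pearson": squared Pearson correlation, for comparison.
    """
    y_true, y_pred = _range_filter(y_true, y_pred, value_range)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot <= 0:
        raise ValidationError("true values have zero variance in range")
    if kind == "ss":
        ss_res = float(np.sum((y_true - y_pred) ** 2))
        return 1.0 - ss_res / ss_tot
    if kind == "pearson":
        return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    raise ValidationError(f"unknown R^2 kind {kind!r}")


def rmsep(y_true, y_pred,
          value_range: tuple[float, float] | None = None) -> float:
    """Root mean squared error of prediction over the in-range pairs, %."""
    y_true, y_pred = _range_filter(y_true, y_pred, value_range)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def blank_stats(predictions) -> BlankStats:
    """Mean, sample SD (n-1) and maximum of blank predictions.

    ``predictions`` are predicted shell percentages of pure nutmeg samples
    only — either all single CV predictions (pooled) or the per-sample
    ensemble means, depending on which distribution is being summarized.
    """
    p = np.asarray(predictions, dtype=float)
    if p.size < 2:
        raise ValidationError("need >= 2 blank predictions")
    return BlankStats(mean=float(p.mean()), sd=float(p.std(ddof=1)),
                      max=float(p.max()), n=int(p.size))


def normal_tail(sigma: float, threshold: float) -> NormalTail:
    """Tail probability that a blank exceeds ``threshold`` percent.

    The blank distribution is modeled as N(0, sigma^2) — centered at zero,
    the known true shell content of a blank, not at the empirical blank
    mean.
    """
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    z = threshold / sigma
    area = float(norm.cdf(z))
    return NormalTail(sigma=sigma, threshold=threshold, z=z, area=area,
                      upper_p=1.0 - area)


def detection_limits(sigma: float) -> DetectionLimits:
    """Blank-based limits: LOD = 3*sigma, LOQ = 9*sigma (both in %)."""
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    return DetectionLimits(sigma=sigma, lod=3.0 * sigma, loq=9.0 * sigma)


def flow_table(y_true, y_pred) -> pd.DataFrame:
    """True-level -> predicted-level flow counts for the Sankey view.

    The true bin is the exact design level ("pure" for 0%, else the
    integer percent). The predicted bin is "pure" below 0.5%, otherwise
    the nearest integer level 1-10 (bin edges at k +/- 0.5); predictions
    beyond the 0-10% range are clamped to the boundary bin and counted in
    an ``out_of_range`` column. Total inflow equals total outflow equals
    the sample count.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError("true and predicted arrays differ in length")

    def true_bin(v: float) -> str:
        return "pure" if v == 0 else f"{v:g}"

    def pred_bin(v: float) -> tuple[str, bool]:
        if v < 0.5:
            return "pure", v < -0.5
        level = int(round(v))
        if level > 10:
            return "10", True
        return str(level), False

    rows = {}
    for t, p in zip(y_true, y_pred):
        tb = true_bin(t)
        pb, clamped = pred_bin(p)
        key = (tb, pb)
        if key not in rows:
            rows[key] = {"true_bin": tb, "predicted_bin": pb, "count": 0,
                         "out_of_range": 0}
        rows[key]["count"] += 1
        rows[key]["out_of_range"] += int(clamped)
    out = pd.DataFrame(sorted(rows.values(),
                              key=lambda r: (r["true_bin"], r["predicted_bin"])))
    return out.reset_index(drop=True)
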