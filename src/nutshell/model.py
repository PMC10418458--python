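"""Constituent-aware repeated 2-fold cross-validation with SVR/PLS.

The estimand is the shell mass percentage of a sample. Because every
mixture is built from one specific nutmeg sample and one specific shell
sample, a naive random split would leak constituent identity between
training and test. The split therefore operates on *pure samples*: half of
the nutmeg samples and half of the shell samples form the training half, a
mixture joins the training set only if BOTH of its constituents are in the
training half, the test set is built symmetrically from the complementary
half, and mixtures with split constituents sit out that repeat entirely.
Folds 1 and 2 of a repeat swap the halves, so every pure sample is tested
exactly once per repeat while each eligible mixture is tested in about
half the repeats (both constituents land in the same half with probability
~1/2). Repeating 100 times and averaging the per-sample predictions gives
the ensemble estimate.

Only mixtures with up to 10% shell content enter the CV; higher levels are
trivially separable and excluded from the regression problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVR

from .errors import DegenerateFitError, ValidationError
from .io import Dataset
from .preprocess import apply_preprocessing, msc_reference

__all__ = [
    "CVSplit",
    "make_split",
    "check_split_leakage",
    "fit_predict",
    "repeat_cv",
    "ensemble_average",
    "MAX_ELIGIBLE_FRACTION",
]

#: Mixtures above this shell fraction are excluded from the CV regression.
MAX_ELIGIBLE_FRACTION = 0.10

_F_TOL = 1e-9


@dataclass(frozen=True)
class CVSplit:
    """One fold of one repeat: disjoint train/test sample-id sets."""

    repeat: int
    fold: int  # 1 or 2
    train_samples: tuple[str, ...]
    test_samples: tuple[str, ...]


def _eligible(samples: pd.DataFrame) -> pd.DataFrame:
    mixtures = samples["role"] == "mixture"
    too_high = samples["shell_fraction"] > MAX_ELIGIBLE_FRACTION + _F_TOL
    return samples[~(mixtures & too_high)]


def _half_sizes(n: int, rng: np.random.Generator) -> int:
    """Size of the first half; for odd n the larger half is randomized."""
    k = n // 2
    if n % 2 == 1 and rng.integers(2) == 1:
        k += 1
    return k


def make_split(samples: pd.DataFrame, seed: int | np.random.Generator = 0,
               repeat: int = 0) -> tuple[CVSplit, CVSplit]:
    """Draw one repeat's pair of complementary constituent-aware folds.

    ``samples`` is a sample registry (sample_id, role, shell_fraction,
    nutmeg_id, shell_id). Returns folds 1 and 2; fold 2 swaps the halves
    of fold 1 exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    samples = _eligible(samples)
    nutmeg_ids = samples.loc[samples["role"] == "nutmeg", "sample_id"].tolist()
    shell_ids = samples.loc[samples["role"] == "shell", "sample_id"].tolist()
    if not nutmeg_ids or not shell_ids:
        raise ValidationError("sample registry must contain both pure roles")

    nut_perm = rng.permutation(nutmeg_ids)
    shell_perm = rng.permutation(shell_ids)
    half_a_pure = set(nut_perm[: _half_sizes(len(nut_perm), rng)]) | set(
        shell_perm[: _half_sizes(len(shell_perm), rng)])
    half_b_pure = (set(nutmeg_ids) | set(shell_ids)) - half_a_pure

    half_a = list(half_a_pure)
    half_b = list(half_b_pure)
    for row in samples[samples["role"] == "mixture"].itertuples(index=False):
        in_a = row.nutmeg_id in half_a_pure and row.shell_id in half_a_pure
        in_b = row.nutmeg_id in half_b_pure and row.shell_id in half_b_pure
        if in_a:
            half_a.append(row.sample_id)
        elif in_b:
            half_b.append(row.sample_id)
        # split constituents: the mixture sits out this repeat

    fold1 = CVSplit(repeat=repeat, fold=1, train_samples=tuple(half_a),
                    test_samples=tuple(half_b))
    fold2 = CVSplit(repeat=repeat, fold=2, train_samples=tuple(half_b),
                    test_samples=tuple(half_a))
    return fold1, fold2


def check_split_leakage(split: CVSplit, samples: pd.DataFrame) -> None:
    """Audit: no test mixture may share a constituent with the train half.

    Raises ValidationError on the first violation. Run on every fold of
    every repeat.
    """
    table = samples.set_index("sample_id")
    train = set(split.train_samples)
    test = set(split.test_samples)
    if train & test:
        raise ValidationError(
            f"repeat {split.repeat} fold {split.fold}: train/test overlap "
            f"{sorted(train & test)}")
    train_pure = {s for s in train if table.loc[s, "role"] != "mixture"}
    train_constituents = set(train_pure)
    for s in train:
        if table.loc[s, "role"] == "mixture":
            train_constituents |= {table.loc[s, "nutmeg_id"],
                                   table.loc[s, "shell_id"]}
    for s in test:
        row = table.loc[s]
        if row["role"] == "mixture":
            shared = {row["nutmeg_id"], row["shell_id"]} & train_constituents
            if shared:
                raise ValidationError(
                    f"repeat {split.repeat} fold {split.fold}: test mixture "
                    f"{s} shares constituent(s) {sorted(shared)} with the "
                    f"training set")
        elif s in train_constituents and row["role"] != "mixture":
            # pure test sample listed as a train constituent
            raise ValidationError(
                f"repeat {split.repeat} fold {split.fold}: pure test sample "
                f"{s} appears in the training set")


def _standardize(train: np.ndarray, test: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mean) / sd, (test - mean) / sd


def fit_predict(
    dataset: Dataset,
    split: CVSplit,
    model: str = "svm_linear",
    variant: str = "msc",
    pls_components: int = 10,
    include_shell_targets: bool = True,
) -> pd.DataFrame:
    """Fit one fold's model on the training half and predict the test half.

    ``dataset`` is the replicate-averaged dataset. For MSC variants the
    reference spectrum is the mean of the training spectra only and is
    applied unchanged to the test spectra. Features are standardized with
    training-set statistics. The regression target is shell content in
    percent; predictions are recorded untouched (no clipping or rounding),
    so blank predictions may legitimately go negative.

    ``include_shell_targets=False`` drops the pure-shell (100%) rows from
    the regression training set while leaving them available as mixture
    constituents.
    """
    meta = dataset.meta
    train_mask = meta["sample_id"].isin(split.train_samples).to_numpy()
    test_mask = meta["sample_id"].isin(split.test_samples).to_numpy()
    if not include_shell_targets:
        train_mask &= (meta["role"] != "shell").to_numpy()
    roles = set(meta.loc[train_mask, "role"])
    if "nutmeg" not in roles or train_mask.sum() < 2:
        raise DegenerateFitError(
            "training set needs >= 2 samples including pure nutmeg")

    reference = None
    if variant in ("msc", "msc_d1"):
        train_ids = meta.loc[train_mask, "sample_id"].tolist()
        reference = msc_reference(dataset, scope="train_only",
                                  train_ids=train_ids)
    processed = apply_preprocessing(dataset.X, variant, dataset.grid,
                                    reference=reference)
    x_train, x_test = _standardize(processed[train_mask],
                                   processed[test_mask])
    if not np.any(x_train.std(axis=0) > 0):
        raise DegenerateFitError("training matrix has zero variance")
    y_train = meta.loc[train_mask, "shell_fraction"].to_numpy() * 100.0

    if model == "svm_linear":
        reg = SVR(kernel="linear", C=1.0, epsilon=0.1)
    elif model == "pls":
        k = min(pls_components, x_train.shape[0] - 1, x_train.shape[1])
        reg = PLSRegression(n_components=k, scale=False)
    else:
        raise ValidationError(f"unknown model {model!r}")
    reg.fit(x_train, y_train)
    y_pred = np.asarray(reg.predict(x_test)).ravel()

    return pd.DataFrame({
        "sample_id": meta.loc[test_mask, "sample_id"].to_numpy(),
        "repeat": split.repeat,
        "fold": split.fold,
        "predicted_percent": y_pred,
    })


def repeat_cv(
    dataset: Dataset,
    n_repeats: int = 100,
    model: str = "svm_linear",
    seed: int = 0,
    variant: str = "msc",
    pls_components: int = 10,
    include_shell_targets: bool = True,
) -> pd.DataFrame:
    """Run the repeated constituent-aware 2-fold CV.

    Each repeat draws a fresh random half-split from a per-repeat seed
    derived deterministically from the master seed, audits both folds with
    the leakage guard, and accumulates test-set predictions. Every pure
    sample accrues exactly ``n_repeats`` predictions; each eligible mixture
    accrues Binomial(n_repeats, 1/2) of them.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    samples = _eligible(dataset.sample_table())
    children = np.random.SeedSequence(seed).spawn(n_repeats)
    records: list[pd.DataFrame] = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        fold1, fold2 = make_split(samples, rng, repeat=r)
        for split in (fold1, fold2):
            check_split_leakage(split, samples)
            records.append(fit_predict(
                dataset, split, model=model, variant=variant,
                pls_components=pls_components,
                include_shell_targets=include_shell_targets))
    return pd.concat(records, ignore_index=True)


def ensemble_average(records: pd.DataFrame) -> pd.DataFrame:
    """Per-sample arithmetic mean of all CV predictions.

    Returns columns sample_id, predicted_percent (the ensemble estimate)
    and n_predictions.
    """
    if len(records) == 0:
        raise ValidationError("no prediction records to average")
    grouped = records.groupby("sample_id", sort=False)["predicted_percent"]
    out = grouped.agg(predicted_percent="mean", n_predictions="size")
    return out.reset_index()
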