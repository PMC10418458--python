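"""Constituent-aware CV: splits, leakage guard, SVR fits, ensembling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nutshell import (CVSplit, Dataset, ValidationError, check_split_leakage,
                      ensemble_average, fit_predict, make_split, repeat_cv,
                      run_experiment)
from nutshell.model import MAX_ELIGIBLE_FRACTION


def _registry(n_nutmeg, n_shell, mixtures):
    """mixtures: list of (mixture_id, nutmeg_id, shell_id, f)"""
    rows = [{"sample_id": f"N{i}", "role": "nutmeg", "shell_fraction": 0.0,
             "nutmeg_id": f"N{i}", "shell_id": ""} for i in range(n_nutmeg)]
    rows += [{"sample_id": f"S{i}", "role": "shell", "shell_fraction": 1.0,
              "nutmeg_id": "", "shell_id": f"S{i}"} for i in range(n_shell)]
    rows += [{"sample_id": mid, "role": "mixture", "shell_fraction": f,
              "nutmeg_id": nid, "shell_id": sid}
             for mid, nid, sid, f in mixtures]
    return pd.DataFrame(rows)


class TestMakeSplit:
    def test_study_sizes_split_into_18_and_5(self):
        reg = _registry(36, 10, [])
        fold1, fold2 = make_split(reg, seed=0)
        for fold in (fold1, fold2):
            nut = [s for s in fold.train_samples if s.startswith("N")]
            shell = [s for s in fold.train_samples if s.startswith("S")]
            assert len(nut) == 18
            assert len(shell) == 5
        assert set(fold1.train_samples) == set(fold2.test_samples)
        assert set(fold1.test_samples) == set(fold2.train_samples)

    def test_all_small_splits_keep_mixtures_with_their_halves(self):
        # brute-force oracle: recompute fold membership of every mixture
        # from the pure-sample halves, over many random splits
        mixtures = [(f"M{i}", f"N{a}", f"S{b}", 0.05)
                    for i, (a, b) in enumerate(
                        itertools.product(range(2), range(2)))]
        reg = _registry(2, 2, mixtures)
        table = reg.set_index("sample_id")
        for seed in range(50):
            for fold in make_split(reg, seed=seed):
                check_split_leakage(fold, reg)
                train_pure = {s for s in fold.train_samples
                              if table.loc[s, "role"] != "mixture"}
                for mid, nid, sid, _ in mixtures:
                    both_train = nid in train_pure and sid in train_pure
                    assert (mid in fold.train_samples) == both_train

    def test_fold_symmetry_over_pure_samples(self):
        reg = _registry(7, 3, [])  # odd counts: floor/ceil halves
        fold1, fold2 = make_split(reg, seed=1)
        pure = set(reg["sample_id"])
        assert set(fold1.train_samples) | set(fold1.test_samples) == pure
        assert set(fold1.train_samples).isdisjoint(fold1.test_samples)
        assert set(fold2.train_samples) == set(fold1.test_samples)

    def test_high_fraction_mixtures_excluded(self):
        reg = _registry(2, 2, [("M0", "N0", "S0", 0.3),
                               ("M1", "N0", "S0", 0.10)])
        fold1, fold2 = make_split(reg, seed=0)
        members = set(fold1.train_samples + fold1.test_samples
                      + fold2.train_samples + fold2.test_samples)
        assert "M0" not in members  # 30% > eligibility cutoff
        assert MAX_ELIGIBLE_FRACTION == 0.10

    def test_quarter_of_mixtures_per_fold_train_set(self):
        rng = np.random.default_rng(0)
        mixtures = [(f"M{i}", f"N{rng.integers(12)}", f"S{rng.integers(6)}",
                     0.05) for i in range(120)]
        reg = _registry(12, 6, mixtures)
        fractions = []
        for seed in range(60):
            fold1, _ = make_split(reg, seed=seed)
            n_train_mix = sum(s.startswith("M") for s in fold1.train_samples)
            fractions.append(n_train_mix / len(mixtures))
        assert np.mean(fractions) == pytest.approx(0.25, abs=0.03)

    def test_registry_without_both_roles_rejected(self):
        with pytest.raises(ValidationError):
            make_split(_registry(3, 0, []), seed=0)

    def test_leakage_guard_flags_contaminated_split(self):
        reg = _registry(2, 2, [("M0", "N0", "S0", 0.05)])
        bad = CVSplit(repeat=0, fold=1, train_samples=("N0", "S0", "N1", "S1"),
                      test_samples=("M0",))
        with pytest.raises(ValidationError, match="M0"):
            check_split_leakage(bad, reg)


def _linear_dataset(small_grid, samples):
    """Dataset whose spectra are exactly linear in shell percent."""
    from conftest import make_linear_spectra

    fractions = [f for _, _, f in samples]
    x, _, _ = make_linear_spectra(small_grid, fractions)
    meta = pd.DataFrame([
        {"measurement_id": sid, "sample_id": sid, "role": role,
         "shell_fraction": f,
         "nutmeg_id": "N1" if role != "shell" else "",
         "shell_id": "S1" if role != "nutmeg" else "",
         "replicate": 0, "n_replicates": 1}
        for sid, role, f in samples])
    return Dataset(grid=small_grid, X=x, meta=meta)


class TestFitPredict:
    def test_collinear_training_points_interpolate(self, small_grid):
        # spectra vary along one direction; SVR with its 0.1%-insensitive
        # tube must interpolate a held-out midpoint to within the tube
        ds = _linear_dataset(small_grid, [
            ("N1", "nutmeg", 0.0), ("MA", "mixture", 0.05),
            ("MB", "mixture", 0.10), ("MC", "mixture", 0.025)])
        split = CVSplit(repeat=0, fold=1,
                        train_samples=("N1", "MA", "MB"),
                        test_samples=("MC",))
        rec = fit_predict(ds, split, model="svm_linear",
                          include_shell_targets=False)
        assert rec.loc[0, "predicted_percent"] == pytest.approx(2.5, abs=0.3)

    def test_train_equals_test_is_near_perfect(self, small_grid):
        samples = ([("N1", "nutmeg", 0.0)]
                   + [(f"M{i}", "mixture", 0.01 * i) for i in range(1, 10)])
        ds = _linear_dataset(small_grid, samples)
        ids = tuple(s for s, _, _ in samples)
        split = CVSplit(repeat=0, fold=1, train_samples=ids,
                        test_samples=ids)
        rec = fit_predict(ds, split, include_shell_targets=False)
        truth = {s: f * 100 for s, _, f in samples}
        for _, row in rec.iterrows():
            assert row["predicted_percent"] == pytest.approx(
                truth[row["sample_id"]], abs=0.25)

    def test_unknown_model_rejected(self, small_grid):
        ds = _linear_dataset(small_grid, [("N1", "nutmeg", 0.0),
                                          ("MA", "mixture", 0.05)])
        split = CVSplit(repeat=0, fold=1, train_samples=("N1", "MA"),
                        test_samples=("N1",))
        with pytest.raises(ValidationError, match="model"):
            fit_predict(ds, split, model="forest")


@pytest.fixture(scope="module")
def small_run(tiny_config):
    return run_experiment(tiny_config, seed=3)


class TestRepeatCV:
    def test_every_pure_sample_predicted_once_per_repeat(self, small_run):
        records = small_run["records"]
        meta = small_run["averaged"].sample_table()
        pure = meta.loc[meta["role"] != "mixture", "sample_id"]
        counts = records.groupby("sample_id").size()
        for sid in pure:
            assert counts[sid] == tiny_n_repeats(small_run)

    def test_predictions_not_clipped(self, small_run):
        # blanks scatter around zero, so some predictions must go negative
        records = small_run["records"]
        meta = small_run["averaged"].sample_table()
        blanks = meta.loc[meta["role"] == "nutmeg", "sample_id"]
        blank_preds = records[records["sample_id"].isin(blanks)]
        assert (blank_preds["predicted_percent"] < 0).any()

    def test_single_repeat_gives_single_records(self, tiny_config):
        import copy

        cfg = copy.deepcopy(tiny_config)
        cfg["n_repeats"] = 1
        art = run_experiment(cfg, seed=0)
        meta = art["averaged"].sample_table()
        pure = meta.loc[meta["role"] != "mixture", "sample_id"]
        counts = art["records"].groupby("sample_id").size()
        assert all(counts[sid] == 1 for sid in pure)

    def test_master_seed_determinism(self, tiny_config, small_run):
        again = run_experiment(tiny_config, seed=3)
        pd.testing.assert_frame_equal(small_run["records"], again["records"])


def tiny_n_repeats(artifacts):
    return artifacts["report"]["n_repeats"]


class TestEnsemble:
    def test_mean_of_two_records(self):
        records = pd.DataFrame({"sample_id": ["a", "a"], "repeat": [0, 1],
                                "fold": [1, 1],
                                "predicted_percent": [2.0, 4.0]})
        out = ensemble_average(records)
        assert out.loc[0, "predicted_percent"] == 3.0
        assert out.loc[0, "n_predictions"] == 2

    def test_ensemble_rmse_not_worse_than_pooled(self, tiny_config):
        # variance-of-means: averaging per-sample predictions cannot
        # increase squared error (Jensen)
        art = run_experiment(tiny_config, seed=1)
        truth = art["averaged"].sample_table().set_index(
            "sample_id")["shell_fraction"] * 100
        rec = art["records"]
        pooled = np.sqrt(np.mean(
            (rec["predicted_percent"] - truth[rec["sample_id"]].values) ** 2))
        ens = art["ensemble"]
        ens_rmse = np.sqrt(np.mean(
            (ens["predicted_percent"] - truth[ens["sample_id"]].values) ** 2))
        assert ens_rmse <= pooled + 1e-12

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            ensemble_average(pd.DataFrame(columns=["sample_id", "repeat",
                                                   "fold",
                                                   "predicted_percent"]))


class TestParameterRecovery:
    def test_noise_free_ensemble_recovers_fractions(self, tiny_config):
        import copy

        cfg = copy.deepcopy(tiny_config)
        for role in ("nutmeg", "shell"):
            cfg["endmembers"][role]["population_sd"] = 0.0
        cfg["scatter"].update(sigma_b=0.0, sigma_a=0.0, sigma_eps=0.0)
        cfg["n_repeats"] = 4
        art = run_experiment(cfg, seed=0)
        assert art["report"]["metrics"]["ensemble"]["r2"] > 0.999
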