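"""End-to-end orchestration: simulate -> preprocess -> PCA -> CV -> report.

One master seed drives everything; per-stage seeds are derived from it by
fixed offsets (design = seed, spectra = seed + 1, cross-validation =
seed + 2, each reduced mod 2^31) so stages can be reproduced in isolation.
All randomness flows through seeded generators; no global RNG state is
touched.
"""

from __future__ import annotations

import logging

import numpy as np

from .configload import (default_config, endmember_from_config,
                         grid_from_config, scatter_from_config)
from .errors import PipelineError
from .evaluate import (blank_stats, detection_limits, flow_table, normal_tail,
                       r_squared, rmsep)
from .model import ensemble_average, repeat_cv
from .pca import pca_fit
from .preprocess import (apply_preprocessing, average_replicates,
                         msc_reference)
from .synth import generate_design, simulate_dataset, validate_design

__all__ = ["stage_seed", "simulate_stage", "run_experiment"]

logger = logging.getLogger("nutshell")

_MOD = 2**31


def stage_seed(master: int, stage: str) -> int:
    offsets = {"design": 0, "spectra": 1, "cv": 2}
    if stage not in offsets:
        raise PipelineError(f"unknown pipeline stage {stage!r}")
    return (int(master) + offsets[stage]) % _MOD


def simulate_stage(config: dict, seed: int | None = None):
    """Generate the mixture design and the simulated dataset."""
    master = config["seed"] if seed is None else seed
    d = config["design"]
    design = generate_design(
        n_nutmeg=int(d["n_nutmeg"]), n_shell=int(d["n_shell"]),
        forced_levels=tuple(float(v) for v in d["forced_levels"]),
        per_level_counts={float(k): int(v)
                          for k, v in d["per_level_counts"].items()},
        min_per_nutmeg=int(d["min_per_nutmeg"]),
        min_per_shell=int(d["min_per_shell"]),
        count_range=tuple(d.get("count_range", (15, 23))),
        seed=stage_seed(master, "design"))
    validate_design(design)
    dataset = simulate_dataset(
        design,
        nutmeg_model=endmember_from_config(config, "nutmeg"),
        shell_model=endmember_from_config(config, "shell"),
        scatter=scatter_from_config(config),
        grid=grid_from_config(config),
        seed=stage_seed(master, "spectra"))
    logger.info("simulated %d measurements (%d mixtures)",
                len(dataset), design.n_mixtures)
    return design, dataset


def _evaluate(records, ensemble, sample_truth, config: dict) -> dict:
    ev = config["evaluation"]
    single_range = tuple(float(v) for v in ev["single_range"])
    ensemble_range = tuple(float(v) for v in ev["ensemble_range"])

    rec = records.merge(sample_truth, on="sample_id")
    rec["true_percent"] = rec["shell_fraction"] * 100.0
    ens = ensemble.merge(sample_truth, on="sample_id")
    ens["true_percent"] = ens["shell_fraction"] * 100.0

    single_blanks = rec.loc[rec["role"] == "nutmeg", "predicted_percent"]
    ens_blanks = ens.loc[ens["role"] == "nutmeg", "predicted_percent"]
    bs_single = blank_stats(single_blanks)
    bs_ens = blank_stats(ens_blanks)
    limits = detection_limits(bs_ens.sd)

    tails = []
    for t in ev.get("tail_thresholds", []):
        for label, bs in (("single", bs_single), ("ensemble", bs_ens)):
            nt = normal_tail(bs.sd, float(t))
            tails.append({"predictions": label, **nt.as_dict()})

    in_range = ens[(ens["true_percent"] >= ensemble_range[0])
                   & (ens["true_percent"] <= ensemble_range[1])]
    flow = flow_table(in_range["true_percent"].to_numpy(),
                      in_range["predicted_percent"].to_numpy())

    mixtures = ens["role"] == "mixture"
    report = {
        "metrics": {
            "single": {
                "range": list(single_range),
                "r2": r_squared(rec["true_percent"], rec["predicted_percent"],
                                single_range),
                "rmsep": rmsep(rec["true_percent"], rec["predicted_percent"],
                               single_range),
            },
            "ensemble": {
                "range": list(ensemble_range),
                "r2": r_squared(ens["true_percent"], ens["predicted_percent"],
                                ensemble_range),
                "rmsep": rmsep(ens["true_percent"], ens["predicted_percent"],
                               ensemble_range),
            },
        },
        "blanks": {
            "single": vars(bs_single).copy(),
            "ensemble": vars(bs_ens).copy(),
        },
        "detection_limits": {"sigma": limits.sigma, "lod": limits.lod,
                             "loq": limits.loq},
        "normal_tails": tails,
        "cv": {
            "n_records": int(len(records)),
            "n_pure_nutmeg": int((ens["role"] == "nutmeg").sum()),
            "records_per_pure_nutmeg": {
                "min": int(ens.loc[ens["role"] == "nutmeg",
                                   "n_predictions"].min()),
                "max": int(ens.loc[ens["role"] == "nutmeg",
                                   "n_predictions"].max()),
            },
            "mean_records_per_mixture": float(
                ens.loc[mixtures, "n_predictions"].mean()),
        },
        "flow_table": flow.to_dict(orient="records"),
    }
    return report


def run_experiment(config: dict | None = None, seed: int | None = None) -> dict:
    """Run the full pipeline and return all artifacts.

    Returns a dict with keys design, dataset, averaged, pca (model fitted
    on MSC-corrected pure samples), records, ensemble and report. The
    report is JSON-serializable and byte-identical across runs with the
    same config and seed.
    """
    config = default_config() if config is None else config
    master = config["seed"] if seed is None else seed

    design, dataset = simulate_stage(config, master)
    averaged = average_replicates(dataset)

    # exploratory PCA: averaged, MSC-corrected pure samples, reference =
    # mean of all pure-sample spectra
    pure_mask = averaged.meta["role"].isin(["nutmeg", "shell"]).to_numpy()
    reference = msc_reference(averaged, scope="all_pure")
    pure_corrected = apply_preprocessing(
        averaged.X[pure_mask], "msc", averaged.grid, reference=reference)
    pca_model = pca_fit(pure_corrected)

    records = repeat_cv(
        averaged,
        n_repeats=int(config["n_repeats"]),
        model=config["model"],
        seed=stage_seed(master, "cv"),
        variant=config["preprocessing"],
        pls_components=int(config.get("pls_components", 10)),
        include_shell_targets=bool(config.get("include_shell_targets", True)))
    ensemble = ensemble_average(records)

    sample_truth = averaged.sample_table()[
        ["sample_id", "role", "shell_fraction"]]
    report = _evaluate(records, ensemble, sample_truth, config)
    report["seed"] = int(master)
    report["design"] = {
        "n_nutmeg": len(design.nutmeg_ids),
        "n_shell": len(design.shell_ids),
        "n_mixtures": design.n_mixtures,
        "n_eligible_mixtures": int(sum(m.f <= 0.10 + 1e-9
                                       for m in design.mixtures)),
    }
    report["pca"] = {
        "pc1_percent": float(pca_model.explained_variance_ratio[0] * 100.0),
        "pc2_percent": float(pca_model.explained_variance_ratio[1] * 100.0),
    }
    report["model"] = config["model"]
    report["preprocessing"] = config["preprocessing"]
    report["n_repeats"] = int(config["n_repeats"])

    return {
        "design": design,
        "dataset": dataset,
        "averaged": averaged,
        "pca": pca_model,
        "records": records,
        "ensemble": ensemble,
        "report": report,
    }
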