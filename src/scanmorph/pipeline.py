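"""End-to-end measurement-error analysis over a landmark dataset.

``run_full_analysis`` executes the full sequence: read or simulate data,
superimpose with sliding semilandmarks, decompose object symmetry, partition
variance (asymmetry ANOVA, symmetric-component ANOVA, sex + device ANOVA),
ordinate (PCA), quantify digitization error (per-device repeatability over
landmark subsets, per-cell Procrustes variance with a device permutation
test), and classify by sex with a cross-validated between-group PCA.  Every
table is written as CSV into the output directory together with a log that
records the configuration and seed, so a run is a pure function of its
inputs and config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .anova import procrustes_anova, symmetry_anova
from .classify import average_replicates, loocv_classify, pca
from .datatypes import BilateralMap, LandmarkDataset, SlidingDefinition, validate
from .error_metrics import (
    LANDMARK_SUBSETS,
    compare_group_variance,
    procrustes_variance_by_group,
    repeatability,
)
from .simulate import SyntheticParams, simulate_dataset
from .sliding import slide_gpa
from .symmetry import decompose

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run; ``seed`` governs every source
    of randomness (permutations and, for synthetic input, simulation)."""

    landmarks_path: str | None = None
    dialect: str = "csv_long"
    factors_path: str | None = None
    sliders_path: str | None = None
    patches_path: str | None = None
    bilateral_path: str | None = None
    synthetic: SyntheticParams | None = None
    sliding_enabled: bool = True
    sliding_cycles: int = 3
    symmetry_axis: str = "x"
    n_perm: int = 999
    seed: int = 0
    landmark_subsets: tuple[str, ...] = ("all", "fixed+curves", "fixed_only")
    classify_by: str = "sex"
    output_dir: str = "scanmorph_results"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def load_inputs(config: RunConfig):
    """Dataset plus topology side-tables from files or the simulator."""
    if config.synthetic is not None:
        params = dataclasses.replace(config.synthetic, seed=config.seed)
        dataset, truth = simulate_dataset(params)
        return dataset, truth.sliders, truth.bilateral, truth
    if config.landmarks_path is None:
        raise ValueError("either landmarks_path or synthetic must be set")
    factors = (lio.read_factors(config.factors_path)
               if config.factors_path else None)
    dataset = lio.read_landmarks(config.landmarks_path, config.dialect,
                                 factors=factors)
    sliders = None
    if config.sliders_path:
        sliders = lio.read_sliders(config.sliders_path, dataset.n_points,
                                   patch_path=config.patches_path)
    bilateral = None
    if config.bilateral_path:
        bilateral = lio.read_bilateral(config.bilateral_path,
                                       dataset.n_points)
    return dataset, sliders, bilateral, None


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline and write all result tables.

    Returns a result bundle: the fitted objects and output DataFrames,
    keyed by stage name.  Any stage failure is re-raised annotated with the
    stage it occurred in.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": _config_dict(config)}
    stage = "setup"
    try:
        stage = "input"
        dataset, sliders, bilateral, truth = load_inputs(config)
        problems = validate(dataset, sliders, bilateral)
        if problems:
            raise ValueError("; ".join(problems))
        results["dataset"] = dataset
        if truth is not None:
            results["truth"] = truth

        stage = "superimposition"
        fit = slide_gpa(
            dataset,
            sliders if config.sliding_enabled else None,
            n_cycles=config.sliding_cycles,
        )
        results["gpa"] = fit

        stage = "symmetry decomposition"
        if bilateral is None:
            raise ValueError("a bilateral map is required for the "
                             "symmetry stages")
        decomp = decompose(fit.aligned, bilateral, axis=config.symmetry_axis)
        results["symmetry"] = decomp
        n = dataset.n_specimens
        sym_coords = _sym_tangent(decomp, n)

        stage = "asymmetry ANOVA"
        t1 = symmetry_anova(decomp, dataset.factors,
                            n_perm=config.n_perm, seed=config.seed)
        results["asymmetry_anova"] = t1
        t1.to_csv(out / "anova_asymmetry.csv")

        stage = "symmetric-component ANOVA"
        t2 = procrustes_anova(
            sym_coords, dataset.factors,
            ["individual", "individual:device"],
            n_perm=config.n_perm, seed=config.seed + 1,
        )
        results["symmetric_anova"] = t2
        t2.to_csv(out / "anova_symmetric.csv")

        stage = "PCA"
        pca_res = pca(sym_coords)
        results["pca"] = pca_res
        scores = pd.DataFrame(
            pca_res.scores,
            index=dataset.specimen_ids,
            columns=[f"PC{k + 1}" for k in range(pca_res.scores.shape[1])],
        )
        scores.to_csv(out / "pca_scores.csv")
        results["pca_variance_pct"] = pca_res.variance_explained

        stage = "repeatability"
        rep_rows = []
        for dev in dict.fromkeys(dataset.factors["device"]):
            for subset in config.landmark_subsets:
                if subset not in LANDMARK_SUBSETS:
                    raise ValueError(f"unknown landmark subset {subset!r}")
                rep = repeatability(
                    dataset, device=dev, landmark_subset=subset,
                    bilateral=bilateral, sliders=sliders,
                    n_cycles=config.sliding_cycles,
                )
                rep_rows.append({
                    "device": dev, "subset": subset, "R": rep.r_value,
                    "MS_among": rep.ms_among, "MS_within": rep.ms_within,
                    "replicates": rep.replicates_per_group,
                })
        t3 = pd.DataFrame(rep_rows)
        results["repeatability"] = t3
        t3.to_csv(out / "repeatability.csv", index=False)

        stage = "Procrustes variance"
        disparity = procrustes_variance_by_group(sym_coords, dataset.factors)
        p_dev = compare_group_variance(disparity, n_perm=config.n_perm,
                                       seed=config.seed + 2)
        results["disparity"] = disparity
        dv = disparity.cell_variances.copy()
        dv.to_csv(out / "procrustes_variance_cells.csv", index=False)
        pd.DataFrame([
            {"device": k, "mean_procrustes_variance": v,
             "permutation_p": p_dev}
            for k, v in disparity.group_variances.items()
        ]).to_csv(out / "procrustes_variance_devices.csv", index=False)

        stage = "sex + device ANOVA"
        has_sex = dataset.factors[config.classify_by].notna().to_numpy()
        t4 = None
        if has_sex.sum() >= 4:
            t4 = procrustes_anova(
                sym_coords[has_sex],
                dataset.factors.loc[has_sex].reset_index(drop=True),
                ["device", config.classify_by],
                n_perm=config.n_perm, seed=config.seed + 3,
            )
            t4.to_csv(out / "anova_sex_device.csv")
        results["sex_device_anova"] = t4

        stage = "classification"
        cls_rows, bg_scores = [], []
        if t4 is not None:
            sub_factors = dataset.factors.loc[has_sex].reset_index(drop=True)
            avg, avg_factors = average_replicates(
                sym_coords[has_sex], sub_factors)
            for dev in dict.fromkeys(avg_factors["device"]):
                m = (avg_factors["device"] == dev).to_numpy()
                groups = avg_factors.loc[m, config.classify_by].to_numpy()
                if min((groups == g).sum()
                       for g in dict.fromkeys(groups)) < 2:
                    continue
                report = loocv_classify(avg[m], groups)
                cls_rows.append({
                    "device": dev,
                    "accuracy_pct": report.accuracy_pct,
                    "kappa": report.kappa,
                    "confusion": report.confusion.to_dict(),
                })
            pd.DataFrame([
                {k: v for k, v in row.items() if k != "confusion"}
                for row in cls_rows
            ]).to_csv(out / "classification.csv", index=False)
        results["classification"] = cls_rows

        stage = "bgPCA scores"
        if t4 is not None:
            from .classify import bgpca

            groups_all = avg_factors[config.classify_by].to_numpy()
            bg = bgpca(avg, groups_all)
            bg_scores = pd.DataFrame(
                bg.scores,
                columns=[f"bgPC{k + 1}"
                         for k in range(bg.scores.shape[1])],
            )
            bg_scores.insert(0, "group", groups_all)
            bg_scores.insert(0, "device", avg_factors["device"].to_numpy())
            bg_scores.to_csv(out / "bgpca_scores.csv", index=False)
        results["bgpca_scores"] = bg_scores
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    cfg_json = json.dumps(results["config"], sort_keys=True)
    logrec = {
        "seed": config.seed,
        "n_perm": config.n_perm,
        "config": results["config"],
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_specimens": int(dataset.n_specimens),
        "n_points": int(dataset.n_points),
    }
    (out / "run_log.json").write_text(json.dumps(logrec, indent=2))
    return results


def _sym_tangent(decomp, n: int) -> np.ndarray:
    """Tangent-space shape variables of the symmetric component."""
    flat = decomp.symmetric.reshape(n, -1)
    c = decomp.consensus.reshape(-1)
    c_hat = c / np.linalg.norm(c)
    dev = flat - c
    return dev - np.outer(dev @ c_hat, c_hat)
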