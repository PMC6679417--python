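"""Simulation-based verification of the inference stages.

Three studies, all driven by the synthetic-data generator at the emulated
study scale (8 males per group, 40 cells per male, two activation
temperatures) unless stated otherwise:

* **Type-I error** — each comparison stage refitted on replicates of its
  matching null generator; the rejection rate at alpha = 0.05 should sit
  within binomial noise of 0.05.
* **Parameter recovery** — a known warm-group shift in L_F/A_H is injected
  and the stage's 95% confidence interval is checked for coverage of the true
  (large-sample) group difference.
* **Scenario pattern** — under the warm-acclimation scenario preset the
  L_F/A_H group test should reject more often than the absolute-size tests,
  and the within-warm post-hoc activation drag contrast more often than the
  within-cold one.

Replicate seeds are spawned deterministically from the base seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import EffectConfig, StudyDesign
from .hydrodynamics import ViscosityTable, WATER_VISCOSITY, drag_table, mean_drag_per_male
from .inference import (DeformityModel, MorphologyModel, SpeedModel, DragModel,
                        compare_morphology)
from .morphometry import derive_cells, summarize_per_male
from .synthetic import generate_dataset, _temp_tag

__all__ = ["type1_error", "recovery_coverage", "scenario_rejection_rates",
           "INFERENCE_STAGES"]

INFERENCE_STAGES = ("deformity", "morphology", "speed", "drag")


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _stage_pvalue(stage: str, ds, table: ViscosityTable) -> float:
    """Fit one stage on a generated dataset, return the null-term p-value."""
    if stage == "deformity":
        res = DeformityModel.from_males_frame(ds.males_frame()).fit()
        return float(res.pvalues.iloc[1])
    cells = derive_cells(ds.cells_frame())
    if stage == "morphology":
        res = compare_morphology("ratio_LF_AH_per_um", cells)
        return float(res.pvalues.iloc[1])
    males = ds.males_frame()
    if stage == "speed":
        t0 = ds.design.activation_temps[0]
        per_male = summarize_per_male(cells).merge(
            males[["male_id", f"vap_um_per_s_at_{_temp_tag(t0)}"]], on="male_id")
        res = SpeedModel(per_male, "ratio_LF_AH_per_um",
                         f"vap_um_per_s_at_{_temp_tag(t0)}", t0).fit()
        return float(res.pvalues.iloc[1])
    if stage == "drag":
        drag = drag_table(males, cells, table, ds.design.activation_temps)
        res = DragModel(mean_drag_per_male(drag)).fit()
        # acclimation main effect: null under the no-group-effect generator
        return float(res.pvalues.iloc[1])
    raise ValueError(f"unknown stage {stage!r}")


def type1_error(stage: str, n_reps: int = 1000, seed: int = 0,
                alpha: float = 0.05,
                design: StudyDesign | None = None,
                table: ViscosityTable = WATER_VISCOSITY) -> float:
    """Rejection rate of one stage's null term under the null generator."""
    design = design or StudyDesign()
    effects = EffectConfig.null()
    seeds = _spawn_seeds(seed, n_reps)
    rej = 0
    for s in seeds:
        ds = generate_dataset(design, effects, int(s))
        if _stage_pvalue(stage, ds, table) < alpha:
            rej += 1
    return rej / n_reps


def true_ratio_shift(pct: float = 0.20, n_cells: int = 200_000,
                     seed: int = 987_654) -> float:
    """Large-sample true warm-cold difference in mean L_F/A_H (µm⁻¹).

    Monte-Carlo expectation under the shifted generator: one male per group
    with male-level effects silenced (the estimand is the marginal group
    difference in population mean) and ``n_cells`` cells.
    """
    effects = EffectConfig.ratio_shift(pct).with_updates(
        male_sd_log=0.0, male_sd_dim_log=0.0)
    design = StudyDesign(n_males_per_group=1, n_cells_per_male=n_cells)
    ds = generate_dataset(design, effects, seed)
    cells = derive_cells(ds.cells_frame())
    means = cells.groupby("group")["ratio_LF_AH_per_um"].mean()
    return float(means["warm"] - means["cold"])


def recovery_coverage(n_reps: int = 500, seed: int = 0, pct: float = 0.20,
                      alpha: float = 0.05,
                      design: StudyDesign | None = None) -> float:
    """CI coverage of the injected L_F/A_H group effect at study scale."""
    design = design or StudyDesign()
    effects = EffectConfig.ratio_shift(pct)
    truth = true_ratio_shift(pct)
    seeds = _spawn_seeds(seed, n_reps)
    covered = 0
    for s in seeds:
        ds = generate_dataset(design, effects, int(s))
        cells = derive_cells(ds.cells_frame())
        res = compare_morphology("ratio_LF_AH_per_um", cells)
        lo, hi = res.conf_int(alpha).iloc[1]
        if lo <= truth <= hi:
            covered += 1
    return covered / n_reps


def scenario_rejection_rates(n_reps: int = 500, seed: int = 0,
                             alpha: float = 0.05,
                             design: StudyDesign | None = None,
                             table: ViscosityTable = WATER_VISCOSITY) -> dict:
    """Rejection rates under the warm-acclimation scenario preset.

    Returns rates for the group test of each morphology measure and for the
    two post-hoc within-acclimation activation drag contrasts.
    """
    design = design or StudyDesign()
    effects = EffectConfig.warm_acclimation_scenario()
    seeds = _spawn_seeds(seed, n_reps)
    measures = ("A_H_um2", "L_F_um", "L_T_um", "ratio_LF_AH_per_um")
    rej = {m: 0 for m in measures}
    rej["drag_contrast_cold"] = 0
    rej["drag_contrast_warm"] = 0
    for s in seeds:
        ds = generate_dataset(design, effects, int(s))
        cells = derive_cells(ds.cells_frame())
        for m in measures:
            if float(compare_morphology(m, cells).pvalues.iloc[1]) < alpha:
                rej[m] += 1
        drag = drag_table(ds.males_frame(), cells, table, ds.design.activation_temps)
        res = DragModel(mean_drag_per_male(drag)).fit()
        for _, row in res.contrasts.iterrows():
            if row["pvalue"] < alpha:
                rej[f"drag_contrast_{row['within']}"] += 1
    return {k: v / n_reps for k, v in rej.items()}
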