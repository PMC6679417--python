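"""End-to-end orchestration: simulate → analyze → report.

``simulate`` writes the study dataset (cells, males, deformity-scan fields)
to CSV; ``analyze`` runs morphometry → hydrodynamics → deformity → inference
in order and writes every intermediate table plus per-model result CSVs;
``report`` renders a deterministic plain-text summary whose sections mirror
the four result tables of the emulated study (deformity proportions, sperm
morphology comparisons, morphology effects on swimming speed, drag model with
post-hoc contrasts).

All outputs carry metadata headers (version, seed, config hash) and runs are
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from .deformity import count_with_stopping_rule, tabulate_proportions, FieldScan
from .design import DEFORMITY_CATEGORIES
from .hydrodynamics import ViscosityTable, WATER_VISCOSITY, drag_table, mean_drag_per_male
from .inference import (DeformityModel, InferenceResults, MORPHOLOGY_MEASURES,
                        SpeedModel, compare_morphology, drag_model)
from .io import PipelineConfig, read_csv, write_csv
from .morphometry import derive_cells, summarize_per_male
from .synthetic import generate_dataset, _temp_tag

__all__ = ["simulate", "analyze", "report"]

log = logging.getLogger("troutsperm")


def _timer(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2fs", stage, time.perf_counter() - self.t0)
    return _T()


def simulate(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a dataset and write ``cells.csv``, ``males.csv``, ``fields.csv``."""
    outdir = Path(outdir)
    h = config.hash()
    with _timer("simulate"):
        ds = generate_dataset(config.design, config.effects, config.seed)
        paths = {
            "cells": write_csv(ds.cells_frame(), outdir / "cells.csv",
                               seed=config.seed, cfg_hash=h),
            "males": write_csv(ds.males_frame(), outdir / "males.csv",
                               seed=config.seed, cfg_hash=h),
            "fields": write_csv(ds.fields_frame(), outdir / "fields.csv",
                                seed=config.seed, cfg_hash=h),
        }
    return paths


def _results_frame(res: InferenceResults) -> pd.DataFrame:
    out = res.terms.reset_index(names="term")
    out.insert(0, "model", res.model_name)
    out.insert(1, "response", res.response)
    out["transform"] = res.transform
    out["converged"] = res.converged
    out["flags"] = "; ".join(res.flags) or "-"
    return out


def analyze(cells_path: str | Path, males_path: str | Path,
            fields_path: str | Path, config: PipelineConfig,
            outdir: str | Path) -> dict[str, object]:
    """Run every analysis stage on a dataset and write all outputs.

    Returns the fitted results keyed by stage; raises on schema violations,
    naming the offending file and column.
    """
    outdir = Path(outdir)
    h = config.hash()
    meta = dict(seed=config.seed, cfg_hash=h)

    cells = read_csv(cells_path)
    males = read_csv(males_path)
    fields = read_csv(fields_path)
    for name, df, req in (
            ("cells.csv", cells, {"male_id", "group", "cell_id",
                                  "L_H_um", "W_H_um", "L_F_um", "category"}),
            ("males.csv", males, {"male_id", "group"}),
            ("fields.csv", fields, {"male_id", "field_idx", *DEFORMITY_CATEGORIES})):
        missing = req - set(df.columns)
        if missing:
            raise ValueError(f"{name}: missing columns {sorted(missing)}")
        if df.empty:
            raise ValueError(f"{name}: no data rows")

    table = (ViscosityTable.from_csv(config.viscosity_table)
             if config.viscosity_table else WATER_VISCOSITY)
    temps = config.design.activation_temps
    results: dict[str, object] = {}

    with _timer("morphometry"):
        derived = derive_cells(cells[cells["category"] == "normal"])
        per_male = summarize_per_male(derived)
        write_csv(derived, outdir / "cells_derived.csv", extra=meta)
        write_csv(per_male, outdir / "per_male_morphology.csv", extra=meta)

    with _timer("hydrodynamics"):
        drag = drag_table(males, derived, table, temps, config.viscosity_mode)
        drag_pm = mean_drag_per_male(drag)
        write_csv(drag, outdir / "drag.csv", extra=meta)
        write_csv(drag_pm, outdir / "drag_per_male.csv", extra=meta)

    with _timer("deformity"):
        counts, groups = {}, {}
        for male_id, sub in fields.sort_values("field_idx").groupby("male_id"):
            scan = FieldScan(fields=tuple(
                {c: int(r[c]) for c in DEFORMITY_CATEGORIES}
                for _, r in sub.iterrows()))
            counts[male_id] = count_with_stopping_rule(
                scan, config.design.target_scan_count)
        groups = dict(zip(males["male_id"], males["group"]))
        prop_table = tabulate_proportions(counts, groups)
        write_csv(prop_table, outdir / "deformity_counts.csv", extra=meta)
        counts_df = pd.DataFrame({
            "male_id": list(counts),
            "group": [groups[m] for m in counts],
            "n_deformed": [c.n_deformed for c in counts.values()],
            "n_total": [c.total_counted for c in counts.values()],
        })
        results["deformity"] = DeformityModel(counts_df).fit()

    with _timer("inference"):
        morph = {}
        for measure in MORPHOLOGY_MEASURES:
            morph[measure] = compare_morphology(measure, derived)
        results["morphology"] = morph

        speed = {}
        pm = per_male.merge(males[["male_id"] + [
            f"vap_um_per_s_at_{_temp_tag(t)}" for t in temps]], on="male_id")
        for t in temps:
            vap_col = f"vap_um_per_s_at_{_temp_tag(t)}"
            speed[(t, "ratio_LF_LH")] = SpeedModel(
                pm, "ratio_LF_LH", vap_col, t).fit()
            # L_F/A_H differs between groups, so acclimation enters its model
            speed[(t, "ratio_LF_AH_per_um")] = SpeedModel(
                pm, "ratio_LF_AH_per_um", vap_col, t,
                include_acclimation=True).fit()
        results["speed"] = speed

        results["drag"] = drag_model(drag_pm, df_method=config.df_method)

        frames = [_results_frame(results["deformity"])]
        frames += [_results_frame(r) for r in morph.values()]
        frames += [_results_frame(r) for r in speed.values()]
        frames.append(_results_frame(results["drag"]))
        write_csv(pd.concat(frames, ignore_index=True),
                  outdir / "model_results.csv", extra=meta)
        write_csv(results["drag"].contrasts, outdir / "drag_contrasts.csv",
                  extra=meta)
    return results


def report(results_dir: str | Path, config: PipelineConfig | None = None) -> str:
    """Render the plain-text study report from a populated results directory."""
    results_dir = Path(results_dir)

    def _load(name: str) -> pd.DataFrame | None:
        p = results_dir / name
        return read_csv(p) if p.exists() else None

    fmt = lambda v: f"{v:.6g}"
    lines: list[str] = ["Thermal acclimation sperm analysis report",
                       "=" * 41, ""]

    lines.append("1. Deformed spermatozoa (per-group category proportions)")
    lines.append("-" * 57)
    t = _load("deformity_counts.csv")
    if t is None:
        lines.append("  [stage missing: deformity_counts.csv not found]")
    else:
        sub = t[t["level"] == "group_mean"].drop(columns=["male_id", "level"])
        lines.append(sub.to_string(index=False, float_format=fmt))
    lines.append("")

    res = _load("model_results.csv")
    lines.append("2. Sperm morphology comparisons (warm vs cold acclimation)")
    lines.append("-" * 58)
    if res is None:
        lines.append("  [stage missing: model_results.csv not found]")
    else:
        morph = res[res["model"].str.startswith(("Deformity", "Morphology"))]
        lines.append(morph.to_string(index=False, float_format=fmt))
    lines.append("")

    lines.append("3. Sperm morphology effects on swimming speed")
    lines.append("-" * 45)
    if res is None:
        lines.append("  [stage missing: model_results.csv not found]")
    else:
        speed = res[res["model"].str.startswith("Speed")]
        lines.append(speed.to_string(index=False, float_format=fmt))
    lines.append("")

    lines.append("4. Factors affecting drag force D (pN)")
    lines.append("-" * 38)
    if res is None:
        lines.append("  [stage missing: model_results.csv not found]")
    else:
        dragr = res[res["model"].str.startswith("Drag")]
        lines.append(dragr.to_string(index=False, float_format=fmt))
    contrasts = _load("drag_contrasts.csv")
    lines.append("")
    lines.append("Post-hoc least-squares-means activation contrasts:")
    if contrasts is None:
        lines.append("  [stage missing: drag_contrasts.csv not found]")
    else:
        lines.append(contrasts.to_string(index=False, float_format=fmt))
    lines.append("")
    return "\n".join(lines)
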