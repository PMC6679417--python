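"""Seeded synthetic study generator.

Emulates the hierarchical structure of the acclimation experiment so every
downstream stage (morphometry, drag, deformity counting, inference) can be
exercised and calibrated without external data: no raw data accompany studies
of this kind, so the generator *is* the test bed.

Generative model
----------------
Per male *m* in group *g* (cold/warm):

* shared size factor ``b_m ~ N(0, male_sd_log²)`` on the log scale, plus small
  per-dimension male effects ``d ~ N(0, male_sd_dim_log²)``;
* per normal cell: ``L_H = median_LH · k_g · exp(b_m + d_LH + ε)`` with
  cell-level ``ε ~ N(0, cv²)``; the head width is generated as a lognormal
  *fraction* of ``L_H`` (fraction < 1 enforced by redrawing), which guarantees
  the prolate precondition ``W_H < L_H`` for every cell; flagellum length is
  lognormal with the same shared male factor;
* a deformity scan: fields of view with shifted-Poisson cell numbers, each
  cell's category multinomial over {normal, kink, coil, short, tailless};
* one V_AP per activation temperature, lognormal around the configured median
  with male-level and residual (per-temperature) dispersion.

Identical ``(design, effects, seed)`` give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DEFORMITY_CATEGORIES, EffectConfig, StudyDesign, ValidationError
from .deformity import FieldScan

__all__ = [
    "SpermCellRecord", "MaleSample", "SyntheticDataset",
    "generate_dataset", "generate_field_scan",
]


@dataclass(frozen=True)
class SpermCellRecord:
    """One measured spermatozoon (lengths in µm)."""

    male_id: str
    cell_id: str
    L_H: float          # head length, flagellum insertion to apex
    W_H: float          # head width, centre-perpendicular to L_H
    L_F: float          # flagellum length
    category: str = "normal"

    def __post_init__(self) -> None:
        if self.category not in DEFORMITY_CATEGORIES:
            raise ValidationError(f"category: unknown category {self.category!r}")
        if self.L_H <= 0 or self.W_H <= 0 or self.L_F < 0:
            raise ValidationError("dimensions: L_H, W_H must be > 0 and L_F >= 0")


@dataclass(frozen=True)
class MaleSample:
    """A male's metadata, measured cells, deformity scan and swimming speeds."""

    male_id: str
    group: str                       # "cold" | "warm"
    acclimation_temp: float          # °C
    cells: tuple[SpermCellRecord, ...]
    field_scan: FieldScan
    vap_um_s: Mapping[float, float]  # activation temp °C -> V_AP (µm s⁻¹)


@dataclass(frozen=True)
class SyntheticDataset:
    males: tuple[MaleSample, ...]
    design: StudyDesign
    effects: EffectConfig
    seed: int

    @property
    def n_cells(self) -> int:
        return sum(len(m.cells) for m in self.males)

    def cells_frame(self) -> pd.DataFrame:
        """Long table of measured normal cells (one row per cell)."""
        rows = [
            (m.male_id, m.group, c.cell_id, c.L_H, c.W_H, c.L_F, c.category)
            for m in self.males for c in m.cells
        ]
        return pd.DataFrame(
            rows, columns=["male_id", "group", "cell_id",
                           "L_H_um", "W_H_um", "L_F_um", "category"]
        )

    def males_frame(self) -> pd.DataFrame:
        """Per-male table: group, V_AP per activation temperature, scan totals."""
        from .deformity import count_with_stopping_rule

        rows = []
        for m in self.males:
            row: dict = {"male_id": m.male_id, "group": m.group,
                         "acclimation_temp_C": m.acclimation_temp}
            for t in self.design.activation_temps:
                row[f"vap_um_per_s_at_{_temp_tag(t)}"] = m.vap_um_s[t]
            counts = count_with_stopping_rule(m.field_scan, self.design.target_scan_count)
            for cat in DEFORMITY_CATEGORIES:
                row[f"scanned_{cat}"] = counts.totals[cat]
            row["scanned_total"] = counts.total_counted
            row["scan_excluded_aggregates"] = m.field_scan.excluded_aggregates
            rows.append(row)
        return pd.DataFrame(rows)

    def fields_frame(self) -> pd.DataFrame:
        """Per-field-of-view deformity scan counts."""
        rows = []
        for m in self.males:
            for i, f in enumerate(m.field_scan.fields):
                rows.append({"male_id": m.male_id, "field_idx": i,
                             **{c: f[c] for c in DEFORMITY_CATEGORIES}})
        return pd.DataFrame(rows)


def _temp_tag(t: float) -> str:
    return f"{t:g}C".replace(".", "p")


def generate_field_scan(design: StudyDesign,
                        deformity_probs: Mapping[str, float],
                        seed_or_rng) -> FieldScan:
    """Simulate a grid scan: fields of view with per-category cell counts.

    Emits fields until the cumulative discernible-cell count reaches
    ``design.target_scan_count`` (the stopping rule itself is applied later by
    :func:`troutsperm.deformity.count_with_stopping_rule`), so the scan always
    contains enough cells.
    """
    probs = dict(deformity_probs)
    bad = [c for c, p in probs.items() if not 0 <= p <= 1]
    if bad or sum(probs.values()) > 1:
        raise ValidationError("deformity_probs: probabilities must be in [0,1] and sum to <= 1")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    cats = list(DEFORMITY_CATEGORIES)
    p = np.array([1.0 - sum(probs.values())] +
                 [probs.get(c, 0.0) for c in cats[1:]])
    fields: list[dict] = []
    excluded = 0
    total = 0
    while total < design.target_scan_count:
        n_cells = 1 + rng.poisson(design.field_mean_cells - 1)  # >= 1 cell per field
        counts = rng.multinomial(n_cells, p)
        fields.append(dict(zip(cats, (int(x) for x in counts))))
        excluded += int(rng.poisson(0.5))  # indiscernible clumps, never counted
        total += n_cells
    return FieldScan(fields=tuple(fields), excluded_aggregates=excluded)


def _draw_male(rng: np.random.Generator, male_id: str, group: str,
               acclimation_temp: float, design: StudyDesign,
               effects: EffectConfig) -> MaleSample:
    e = effects
    warm = group == "warm"
    head_mult = e.warm_head_multiplier if warm else 1.0
    flag_mult = e.warm_flagellum_multiplier if warm else 1.0

    b = rng.normal(0.0, e.male_sd_log)
    d_lh, d_f, d_lf = rng.normal(0.0, e.male_sd_dim_log, size=3)

    n = design.n_cells_per_male
    L_H = e.head_length_median_um * head_mult * np.exp(
        b + d_lh + rng.normal(0.0, e.cv_head_length, size=n))
    frac = e.head_width_fraction * np.exp(d_f + rng.normal(0.0, e.cv_width_fraction, size=n))
    # prolate guarantee: redraw the rare fraction >= 1 (probability ~1e-11 at defaults)
    while np.any(frac >= 1.0):
        k = frac >= 1.0
        frac[k] = e.head_width_fraction * np.exp(d_f + rng.normal(0.0, e.cv_width_fraction, size=int(k.sum())))
    W_H = frac * L_H
    L_F = e.flagellum_median_um * flag_mult * np.exp(
        b + d_lf + rng.normal(0.0, e.cv_flagellum, size=n))

    cells = tuple(
        SpermCellRecord(male_id=male_id, cell_id=f"{male_id}-{i + 1:03d}",
                        L_H=float(L_H[i]), W_H=float(W_H[i]), L_F=float(L_F[i]))
        for i in range(n)
    )

    scan = generate_field_scan(design, e.deformity_probs, rng)

    v_male = rng.normal(0.0, e.vap_male_cv)
    vap: dict[float, float] = {}
    group_temp_mult = e.vap_warm_temp_multiplier if warm else e.vap_cold_temp_multiplier
    for t in design.activation_temps:
        if t not in e.vap_median_um_s:
            raise ValidationError(f"vap_median_um_s: no speed configured for {t} °C")
        mu = e.vap_median_um_s[t] * (e.vap_warm_multiplier if warm else 1.0)
        mu *= group_temp_mult.get(t, 1.0)
        vap[float(t)] = float(mu * np.exp(v_male + rng.normal(0.0, e.vap_resid_cv)))

    return MaleSample(male_id=male_id, group=group, acclimation_temp=acclimation_temp,
                      cells=cells, field_scan=scan, vap_um_s=vap)


def generate_dataset(design: StudyDesign | None = None,
                     effects: EffectConfig | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Generate one complete study dataset; deterministic given the seed."""
    design = design or StudyDesign()
    effects = effects or EffectConfig()
    rng = np.random.default_rng(seed)
    cold_t, warm_t = design.acclimation_temps
    males: list[MaleSample] = []
    for group, temp, prefix in (("cold", cold_t, "C"), ("warm", warm_t, "W")):
        for j in range(design.n_males_per_group):
            males.append(_draw_male(rng, f"{prefix}{j + 1}", group, temp, design, effects))
    return SyntheticDataset(males=tuple(males), design=design,
                            effects=effects, seed=int(seed))
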