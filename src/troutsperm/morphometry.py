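"""Per-cell derived morphometrics.

The sperm head is modelled as a prolate spheroid with equatorial radius
``r_e = W_H / 2`` and polar radius ``r_p = L_H / 2`` (polar > equatorial).
From the two measured head dimensions and the flagellum length the module
derives, per cell:

* ellipticity ``e = sqrt(1 - r_e²/r_p²)`` — the eccentricity of the meridional
  ellipse, 0 for a sphere and -> 1 as the head elongates;
* head surface area ``A_H = 2π r_e² + 2π r_e r_p · arcsin(e)/e`` (µm²), the
  closed-form prolate-spheroid area, continuous at the sphere limit where it
  reduces to ``4π r²``;
* total length ``L_T = L_H + L_F`` (µm);
* the two ratio predictors of swimming performance, ``L_F/L_H``
  (dimensionless) and ``L_F/A_H`` (µm⁻¹).

Deformed cells are excluded from all morphometric derivations; cells whose
width exceeds their length violate the prolate assumption and are rejected
rather than silently axis-swapped (a strict-validation helper lists them).
The mid-piece is not modelled: it is indistinguishable from the head under
light microscopy in most fishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SpermCellRecord

__all__ = ["DerivedMorphometry", "ellipticity", "head_surface_area",
           "derive_cell", "derive_cells", "summarize_per_male",
           "prolate_violations", "DeformedCellError", "ProlateViolationError"]

_SPHERE_EPS = 1e-9  # below this ellipticity, use the exact sphere formula

#: Derived columns appended by :func:`derive_cells`.
DERIVED_COLUMNS = ("L_T_um", "e", "A_H_um2", "ratio_LF_LH", "ratio_LF_AH_per_um")


class ProlateViolationError(ValueError):
    """Head wider than long (or non-positive) violates the prolate assumption."""


class DeformedCellError(ValueError):
    """Morphometric derivations are only defined for normal cells."""


@dataclass(frozen=True)
class DerivedMorphometry:
    male_id: str
    cell_id: str
    r_e: float            # equatorial radius, µm
    r_p: float            # polar radius, µm
    e: float              # ellipticity, dimensionless
    A_H: float            # head surface area, µm²
    L_T: float            # total length, µm
    ratio_LF_LH: float    # dimensionless
    ratio_LF_AH: float    # µm⁻¹


def ellipticity(r_e, r_p):
    """Eccentricity of the meridional ellipse of a prolate spheroid.

    ``e = sqrt(r_p² - r_e²) / r_p`` (focal distance over polar radius); 0 iff
    the spheroid is a sphere.  Accepts scalars or arrays.  Requires
    ``0 < r_e <= r_p``.
    """
    r_e = np.asarray(r_e, dtype=float)
    r_p = np.asarray(r_p, dtype=float)
    if np.any(r_e <= 0) or np.any(r_p <= 0):
        raise ProlateViolationError("radii must be positive")
    if np.any(r_e > r_p):
        raise ProlateViolationError(
            "head wider than long violates the prolate assumption (r_e > r_p)")
    e = np.sqrt(np.clip(1.0 - (r_e / r_p) ** 2, 0.0, None))
    return e if e.ndim else float(e)


def head_surface_area(L_H, W_H):
    """Prolate-spheroid head surface area in µm² from head length and width.

    ``A = 2π r_e² + 2π r_e r_p · arcsin(e)/e`` with ``r_e = W_H/2``,
    ``r_p = L_H/2``.  At the sphere limit (``e < 1e-9``) the exact value
    ``4π r²`` is returned, avoiding the 0/0 in ``arcsin(e)/e``.
    """
    L_H = np.asarray(L_H, dtype=float)
    W_H = np.asarray(W_H, dtype=float)
    if np.any(L_H <= 0) or np.any(W_H <= 0):
        raise ProlateViolationError("head dimensions must be positive")
    if np.any(W_H > L_H):
        raise ProlateViolationError(
            "head wider than long violates the prolate assumption (W_H > L_H)")
    r_e = 0.5 * W_H
    r_p = 0.5 * L_H
    e = ellipticity(r_e, r_p)
    e = np.asarray(e, dtype=float)
    # arcsin(e)/e -> 1 as e -> 0; substitute exactly at the sphere limit
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(e < _SPHERE_EPS, 1.0, np.arcsin(e) / np.where(e == 0, 1.0, e))
    A = 2.0 * np.pi * r_e**2 + 2.0 * np.pi * r_e * r_p * factor
    return A if A.ndim else float(A)


def derive_cell(cell: SpermCellRecord) -> DerivedMorphometry:
    """All derived quantities for one normal cell."""
    if cell.category != "normal":
        raise DeformedCellError(
            f"cell {cell.cell_id} has category {cell.category!r}; "
            "deformed cells are excluded from measurements")
    A_H = head_surface_area(cell.L_H, cell.W_H)
    return DerivedMorphometry(
        male_id=cell.male_id, cell_id=cell.cell_id,
        r_e=0.5 * cell.W_H, r_p=0.5 * cell.L_H,
        e=ellipticity(0.5 * cell.W_H, 0.5 * cell.L_H),
        A_H=A_H, L_T=cell.L_H + cell.L_F,
        ratio_LF_LH=cell.L_F / cell.L_H,
        ratio_LF_AH=cell.L_F / A_H,
    )


def prolate_violations(cells: pd.DataFrame) -> pd.DataFrame:
    """Rows of ``cells`` whose width exceeds their length (strict validation)."""
    return cells.loc[cells["W_H_um"] > cells["L_H_um"]]


def derive_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`derive_cell` over a ``cells.csv``-schema table.

    Expects columns ``male_id, group, cell_id, L_H_um, W_H_um, L_F_um``
    and (optionally) ``category``; only normal cells may be present.
    Returns a copy with the derived columns appended.
    """
    required = {"male_id", "cell_id", "L_H_um", "W_H_um", "L_F_um"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table missing columns: {sorted(missing)}")
    if "category" in cells.columns and (cells["category"] != "normal").any():
        bad = cells.loc[cells["category"] != "normal", "category"].unique()
        raise DeformedCellError(
            f"deformed cells present (categories {sorted(bad)}); "
            "exclude them before deriving morphometrics")
    viol = prolate_violations(cells)
    if len(viol):
        raise ProlateViolationError(
            f"{len(viol)} cell(s) have W_H > L_H "
            f"(first offender: {viol.iloc[0]['cell_id']})")
    out = cells.copy()
    A_H = head_surface_area(out["L_H_um"].to_numpy(), out["W_H_um"].to_numpy())
    out["L_T_um"] = out["L_H_um"] + out["L_F_um"]
    out["e"] = ellipticity(0.5 * out["W_H_um"].to_numpy(), 0.5 * out["L_H_um"].to_numpy())
    out["A_H_um2"] = A_H
    out["ratio_LF_LH"] = out["L_F_um"] / out["L_H_um"]
    out["ratio_LF_AH_per_um"] = out["L_F_um"] / A_H
    return out


def summarize_per_male(derived: pd.DataFrame) -> pd.DataFrame:
    """Per-male arithmetic means of every measured and derived quantity.

    Speed was only recorded as a per-sample average, so morphology enters the
    speed models as the matching per-male mean over the measured cells.
    Reports ``n_cells`` used per male.
    """
    if derived.empty:
        raise ValueError("no derived cells to summarise")
    value_cols = [c for c in ("L_H_um", "W_H_um", "L_F_um", *DERIVED_COLUMNS)
                  if c in derived.columns]
    keys = ["male_id"] + (["group"] if "group" in derived.columns else [])
    g = derived.groupby(keys, sort=True)
    out = g[value_cols].mean().reset_index()
    out["n_cells"] = g.size().to_numpy()
    return out
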