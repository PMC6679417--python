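"""Theoretical Stokes drag on sperm heads at each activation temperature.

Sperm swim at low Reynolds number, where viscous forces dominate and the drag
on a small sphere follows Stokes' law ``D = 6π µ a U`` with dynamic viscosity
``µ`` (Pa·s), head radius ``a`` (m) and flow speed relative to the head ``U``
(m s⁻¹).  Here ``a`` is half the measured head *width* (the equatorial
half-width, not an equivalent-sphere radius) and ``U`` is the male's average
path velocity (V_AP) at the relevant activation temperature — speeds were
recorded per sample, not per cell, so each male's V_AP applies to all of its
cells.  Drag is reported in piconewtons (pN).

Viscosity is looked up in a temperature table.  The default lookup mode
(``"bracket_mean"``) averages the two tabulated values bracketing the target
temperature — e.g. with a 5 °C-step table, 8 °C uses the mean of the 5 and
10 °C entries and 13 °C the mean of the 10 and 15 °C entries — matching the
protocol this pipeline reproduces; plain linear interpolation is available
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ViscosityTable", "WATER_VISCOSITY", "viscosity_at", "stokes_drag",
           "drag_table", "mean_drag_per_male"]

UM_TO_M = 1e-6
N_TO_PN = 1e12


@dataclass(frozen=True)
class ViscosityTable:
    """Dynamic viscosity of the activation medium vs temperature.

    ``entries`` maps temperature (°C) to µ (Pa·s); viscosity must decrease
    strictly with temperature, as it does for liquid water.
    """

    entries: Mapping[float, float]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("viscosity table needs at least two entries")
        temps = self.temps
        mus = np.array([self.entries[t] for t in temps])
        if np.any(mus <= 0):
            raise ValueError("viscosities must be strictly positive")
        if np.any(np.diff(mus) >= 0):
            raise ValueError("viscosity must decrease strictly with temperature")

    @property
    def temps(self) -> tuple[float, ...]:
        return tuple(sorted(float(t) for t in self.entries))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ViscosityTable":
        df = pd.read_csv(path, comment="#")
        if not {"temp_C", "mu_Pa_s"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns temp_C, mu_Pa_s")
        return cls(entries={float(t): float(m)
                            for t, m in zip(df["temp_C"], df["mu_Pa_s"])})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temp_C": self.temps,
                             "mu_Pa_s": [self.entries[t] for t in self.temps]})


#: Dynamic viscosity of pure water at 5 °C steps (standard reference values,
#: CRC-handbook style, in Pa·s).  Shipped as a convenient default; the table
#: is a configurable input and all unit tests use explicit toy tables.
WATER_VISCOSITY = ViscosityTable(entries={
    0.0: 1.792e-3,
    5.0: 1.519e-3,
    10.0: 1.307e-3,
    15.0: 1.138e-3,
    20.0: 1.002e-3,
    25.0: 0.890e-3,
})


def viscosity_at(temp: float, table: ViscosityTable = WATER_VISCOSITY,
                 mode: str = "bracket_mean") -> float:
    """Viscosity (Pa·s) at ``temp`` °C under the chosen lookup rule.

    ``"bracket_mean"``: arithmetic mean of the two table entries bracketing
    ``temp`` (an exact table hit returns that entry unchanged).
    ``"linear"``: linear interpolation between the bracketing entries.
    """
    temps = table.temps
    if not temps[0] <= temp <= temps[-1]:
        raise ValueError(f"temperature {temp} °C outside table range "
                         f"[{temps[0]}, {temps[-1]}]")
    if temp in table.entries:
        return float(table.entries[float(temp)])
    i = int(np.searchsorted(temps, temp)) - 1
    t0, t1 = temps[i], temps[i + 1]
    mu0, mu1 = table.entries[t0], table.entries[t1]
    if mode == "bracket_mean":
        return 0.5 * (mu0 + mu1)
    if mode == "linear":
        return float(mu0 + (mu1 - mu0) * (temp - t0) / (t1 - t0))
    raise ValueError(f"unknown viscosity mode {mode!r}")


def stokes_drag(mu, a, U):
    """Stokes' law: ``D = 6π µ a U`` in newtons (SI inputs).

    Linear in each argument; zero exactly when ``U`` is zero.  Accepts scalars
    or arrays; negative inputs are rejected.
    """
    mu = np.asarray(mu, dtype=float)
    a = np.asarray(a, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(mu <= 0) or np.any(a <= 0):
        raise ValueError("viscosity and head radius must be positive")
    if np.any(U < 0):
        raise ValueError("speed must be non-negative")
    D = 6.0 * np.pi * mu * a * U
    return D if D.ndim else float(D)


def drag_table(males: pd.DataFrame, derived_cells: pd.DataFrame,
               table: ViscosityTable = WATER_VISCOSITY,
               activation_temps: Sequence[float] = (8.0, 13.0),
               mode: str = "bracket_mean") -> pd.DataFrame:
    """One drag record per (measured cell, activation temperature).

    With 40 cells per male and two activation temperatures this yields 80
    theoretical drag values per male.  Each record stores the inputs used —
    head radius ``a = 0.5 × W_H`` (m), the male-level ``U = V_AP`` (m s⁻¹) and
    ``µ`` — alongside ``D`` in pN, so per-cell speeds could be substituted
    later without a schema change.
    """
    from .synthetic import _temp_tag

    recs = []
    for t in activation_temps:
        col = f"vap_um_per_s_at_{_temp_tag(t)}"
        if col not in males.columns:
            raise ValueError(f"males table lacks V_AP at {t} °C (column {col})")
        if males[col].isna().any():
            bad = males.loc[males[col].isna(), "male_id"].iloc[0]
            raise ValueError(f"male {bad} is missing V_AP at {t} °C")
        mu = viscosity_at(t, table, mode)
        sub = derived_cells.merge(males[["male_id", col]], on="male_id",
                                  how="left", validate="many_to_one")
        if sub[col].isna().any():
            bad = sub.loc[sub[col].isna(), "male_id"].iloc[0]
            raise ValueError(f"male {bad} has cells but no V_AP at {t} °C")
        a_m = 0.5 * sub["W_H_um"].to_numpy() * UM_TO_M
        U_m = sub[col].to_numpy() * UM_TO_M
        frame = pd.DataFrame({
            "male_id": sub["male_id"],
            "cell_id": sub["cell_id"],
            "activation_temp_C": float(t),
            "a_m": a_m,
            "U_m_per_s": U_m,
            "mu_Pa_s": mu,
            "D_pN": stokes_drag(mu, a_m, U_m) * N_TO_PN,
        })
        if "group" in sub.columns:
            frame.insert(1, "group", sub["group"])
        recs.append(frame)
    out = pd.concat(recs, ignore_index=True)
    return out.sort_values(["male_id", "activation_temp_C", "cell_id"],
                           kind="stable", ignore_index=True)


def mean_drag_per_male(records: pd.DataFrame) -> pd.DataFrame:
    """Mean drag (pN) per male per activation temperature, one row each."""
    if records.empty:
        raise ValueError("no drag records to average")
    keys = ["male_id"] + (["group"] if "group" in records.columns else [])
    g = records.groupby(keys + ["activation_temp_C"], sort=True)
    out = g["D_pN"].agg(mean_D_pN="mean", n_cells="size").reset_index()
    return out
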