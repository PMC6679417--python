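"""Study design and generative-effect configuration.

The default :class:`StudyDesign` mirrors a split-tank thermal acclimation
experiment on brown trout (*Salmo trutta*): two acclimation groups (cold 8 °C,
warm 13 °C), 8 males per group, 40 measured normal spermatozoa per male, sperm
activated and speed-tracked at both 8 °C and 13 °C, and a ~100-cell scan per
male for deformity counts.

:class:`EffectConfig` encodes the generative assumptions of the synthetic-data
module: lognormal cell dimensions with a shared per-male size factor on the log
scale, multiplicative warm-group effects, multinomial deformity categories and
male-level average path velocities (V_AP).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

__all__ = ["StudyDesign", "EffectConfig", "ValidationError", "DEFORMITY_CATEGORIES"]

#: The five scoring categories used when scanning a semen sample.
DEFORMITY_CATEGORIES = ("normal", "kink", "coil", "short", "tailless")


class ValidationError(ValueError):
    """A configuration field violates its invariant; the message names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class StudyDesign:
    """Hierarchical layout of the emulated experiment.

    Parameters
    ----------
    n_males_per_group
        Males per acclimation group (default 8).
    n_cells_per_male
        Normal cells measured per male (default 40).
    acclimation_temps
        Acclimation temperatures in °C, cold listed first (default (8, 13)).
    activation_temps
        Water temperatures at which sperm are activated (default (8, 13)).
    target_scan_count
        Nominal number of cells to count per deformity scan (default 100);
        the final field of view is always counted in full, so realised totals
        can overshoot.
    field_mean_cells
        Mean of the (shifted-Poisson) number of discernible cells per field of
        view in the deformity scan.
    """

    n_males_per_group: int = 8
    n_cells_per_male: int = 40
    acclimation_temps: tuple[float, float] = (8.0, 13.0)
    activation_temps: tuple[float, ...] = (8.0, 13.0)
    target_scan_count: int = 100
    field_mean_cells: float = 25.0

    def __post_init__(self) -> None:
        _require(self.n_males_per_group >= 1, "n_males_per_group", "must be >= 1")
        _require(self.n_cells_per_male >= 1, "n_cells_per_male", "must be >= 1")
        _require(len(self.acclimation_temps) == 2, "acclimation_temps",
                 "exactly two acclimation groups (cold, warm) are supported")
        _require(self.acclimation_temps[0] < self.acclimation_temps[1],
                 "acclimation_temps", "cold group must be listed before warm group")
        _require(len(self.activation_temps) >= 1, "activation_temps", "must be non-empty")
        _require(self.target_scan_count >= 1, "target_scan_count", "must be >= 1")
        _require(self.field_mean_cells > 0, "field_mean_cells", "must be > 0")

    @property
    def n_males(self) -> int:
        return 2 * self.n_males_per_group

    @property
    def groups(self) -> tuple[str, str]:
        return ("cold", "warm")


@dataclass(frozen=True)
class EffectConfig:
    """Generative parameters for the synthetic study.

    Lengths are µm and speeds µm s⁻¹.  All dispersion parameters are standard
    deviations on the natural-log scale (≈ coefficients of variation for small
    values).  Baseline location parameters are medians of the corresponding
    lognormal distributions.

    The warm-group multipliers express acclimation effects: a
    ``warm_head_multiplier`` of 1.0 is the null; values below 1 shrink both
    head dimensions of warm-acclimated males, which raises their flagellum
    length to head surface area ratio by roughly the inverse square.
    """

    # baseline cell geometry
    head_length_median_um: float = 3.2
    head_width_fraction: float = 0.65     # W_H generated as fraction of L_H (< 1)
    flagellum_median_um: float = 32.0
    cv_head_length: float = 0.08          # per-cell log-scale SD
    cv_width_fraction: float = 0.06
    cv_flagellum: float = 0.05
    # male-level heterogeneity
    male_sd_log: float = 0.06             # shared size factor across all dimensions
    male_sd_dim_log: float = 0.02         # per-dimension male effects
    # acclimation (group) effects, applied to the warm group
    warm_head_multiplier: float = 1.0
    warm_flagellum_multiplier: float = 1.0
    # deformity mixture (per scanned cell); remainder is "normal"
    deformity_probs: Mapping[str, float] = field(
        default_factory=lambda: {"kink": 0.12, "coil": 0.08, "short": 0.04, "tailless": 0.06}
    )
    # swimming speed (average path velocity, per male x activation temperature)
    vap_median_um_s: Mapping[float, float] = field(
        default_factory=lambda: {8.0: 95.0, 13.0: 95.0}
    )
    vap_male_cv: float = 0.15             # between-male, log scale
    vap_resid_cv: float = 0.11            # within-male, per activation temperature
    vap_warm_multiplier: float = 1.0      # group effect on V_AP at every temperature
    # group-specific activation response: temp -> extra multiplier
    vap_cold_temp_multiplier: Mapping[float, float] = field(default_factory=dict)
    vap_warm_temp_multiplier: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("head_length_median_um", "flagellum_median_um"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(0 < self.head_width_fraction < 1, "head_width_fraction",
                 "must lie in (0, 1): heads are prolate (width < length)")
        for name in ("cv_head_length", "cv_width_fraction", "cv_flagellum",
                     "male_sd_log", "male_sd_dim_log", "vap_male_cv", "vap_resid_cv"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        for name in ("warm_head_multiplier", "warm_flagellum_multiplier",
                     "vap_warm_multiplier"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        unknown = set(self.deformity_probs) - set(DEFORMITY_CATEGORIES[1:])
        _require(not unknown, "deformity_probs", f"unknown categories: {sorted(unknown)}")
        for cat, p in self.deformity_probs.items():
            _require(0.0 <= p <= 1.0, "deformity_probs", f"{cat} outside [0, 1]")
        _require(sum(self.deformity_probs.values()) < 1.0, "deformity_probs",
                 "must sum to < 1 so normal cells remain")
        for t, v in self.vap_median_um_s.items():
            _require(v > 0, "vap_median_um_s", f"speed at {t} °C must be > 0")
        for name in ("vap_cold_temp_multiplier", "vap_warm_temp_multiplier"):
            for t, m in getattr(self, name).items():
                _require(m > 0, name, f"multiplier at {t} °C must be > 0")

    # ------------------------------------------------------------------ presets
    @classmethod
    def null(cls) -> "EffectConfig":
        """No group effect anywhere: the calibration (type-I error) condition."""
        return cls()

    @classmethod
    def ratio_shift(cls, pct: float = 0.20) -> "EffectConfig":
        """Warm-group L_F/A_H raised by ``pct`` via head shrinkage.

        A head multiplier of (1+pct)^-1/2 scales A_H by 1/(1+pct) and hence the
        flagellum-to-head-area ratio by (1+pct), leaving flagella untouched.
        """
        _require(pct > -1, "pct", "must be > -1")
        return cls(warm_head_multiplier=(1.0 + pct) ** -0.5)

    @classmethod
    def warm_acclimation_scenario(cls) -> "EffectConfig":
        """Qualitative thermal-acclimation scenario.

        Warm-acclimated males grow ~5% smaller sperm heads with unchanged
        flagella, raising L_F/A_H by ~11% while leaving absolute lengths
        nearly unchanged.  Group V_AP medians are equal at 8 °C; cold-group
        sperm respond to the warmer activation water with a +5.6% V_AP
        increase that warm-group sperm fail to produce (a smaller power unit
        accompanies the smaller head).  See docs/methods.md for the derivation
        of these magnitudes.
        """
        return cls(warm_head_multiplier=0.95,
                   vap_cold_temp_multiplier={13.0: 1.056})

    def with_updates(self, **kwargs) -> "EffectConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["deformity_probs"] = dict(self.deformity_probs)
        d["vap_median_um_s"] = {float(k): v for k, v in self.vap_median_um_s.items()}
        d["vap_cold_temp_multiplier"] = {float(k): v for k, v in self.vap_cold_temp_multiplier.items()}
        d["vap_warm_temp_multiplier"] = {float(k): v for k, v in self.vap_warm_temp_multiplier.items()}
        return d
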