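"""Statistical comparisons of the acclimation study, as Model/Results objects.

Each comparison in the analysis is a model class built from a data table whose
``fit()`` returns a results object with a uniform term table (estimate,
standard error, test statistic, degrees of freedom, p-value), diagnostic
flags and a ``summary()``:

* :class:`DeformityModel` — binomial GLM (logit link) of deformed count /
  total scanned count per male on acclimation group.
* :class:`MorphologyModel` — mixed model of a per-cell measure on acclimation
  group with a per-male random intercept.  Absolute sizes (A_H, L_F, L_T) are
  right-skewed and modelled on the log scale (a linear mixed model on the log
  response, i.e. a lognormal error family); the two ratio predictors are
  modelled on the identity scale.
* :class:`SpeedModel` — per-male linear regression of V_AP at one activation
  temperature on a morphology ratio (optionally plus acclimation group);
  identity response at 8 °C, log response at 13 °C where speeds are skewed.
* :class:`DragModel` — linear mixed model of per-male mean drag with
  acclimation group, activation temperature and their interaction as fixed
  effects and male (nested within acclimation) as a random intercept, plus
  least-squares-means style post-hoc activation contrasts within each
  acclimation level (Satterthwaite df; no multiplicity adjustment).

Significance is conventionally judged at alpha = 0.05 throughout; no
multiple-testing correction is applied anywhere in the pipeline.
Functional wrappers (:func:`compare_deformity`, :func:`compare_morphology`,
:func:`speed_vs_morphology`, :func:`drag_model`, :func:`lsmeans_contrasts`)
expose each stage as a single call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lmm import ContrastResult, RandomInterceptLM, RandomInterceptLMResults

__all__ = [
    "InferenceResults", "DeformityModel", "MorphologyModel", "SpeedModel",
    "DragModel", "DragResults", "compare_deformity", "compare_morphology",
    "speed_vs_morphology", "drag_model", "lsmeans_contrasts",
    "LOG_SCALE_MEASURES", "MORPHOLOGY_MEASURES",
]

#: Measures modelled on the log scale (lognormal error family).
LOG_SCALE_MEASURES = ("A_H_um2", "L_F_um", "L_T_um")
#: All per-cell measures the morphology stage compares between groups.
MORPHOLOGY_MEASURES = ("A_H_um2", "L_F_um", "L_T_um",
                       "ratio_LF_LH", "ratio_LF_AH_per_um")

_TERM_COLS = ["estimate", "se", "statistic", "df", "pvalue"]


class DesignError(ValueError):
    """The input table cannot support the requested comparison."""


@dataclass
class InferenceResults:
    """Uniform result contract for one fitted comparison."""

    model_name: str
    response: str
    transform: str                   # "identity" | "log" | "logit"
    terms: pd.DataFrame              # index: term; columns: _TERM_COLS
    n_obs: int
    n_groups: int | None = None
    converged: bool = True
    flags: tuple[str, ...] = ()
    contrasts: pd.DataFrame | None = None

    @property
    def pvalues(self) -> pd.Series:
        return self.terms["pvalue"]

    @property
    def params(self) -> pd.Series:
        return self.terms["estimate"]

    @property
    def bse(self) -> pd.Series:
        return self.terms["se"]

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = self.terms["df"].map(
            lambda d: stats.norm.ppf(1 - alpha / 2) if not np.isfinite(d)
            else stats.t.ppf(1 - alpha / 2, d))
        return pd.DataFrame({
            "lower": self.terms["estimate"] - q * self.terms["se"],
            "upper": self.terms["estimate"] + q * self.terms["se"],
        })

    def summary(self) -> str:
        head = [f"{self.model_name}: {self.transform}({self.response})"
                if self.transform != "identity" else
                f"{self.model_name}: {self.response}",
                f"  n_obs: {self.n_obs}"
                + (f"   n_males: {self.n_groups}" if self.n_groups else "")
                + f"   converged: {self.converged}"]
        if self.flags:
            head.append("  flags: " + ", ".join(self.flags))
        body = self.terms.to_string(float_format=lambda v: f"{v:.6g}")
        parts = head + ["", body]
        if self.contrasts is not None:
            parts += ["", "Post-hoc contrasts:",
                      self.contrasts.to_string(index=False,
                                               float_format=lambda v: f"{v:.6g}")]
        return "\n".join(parts)


def _group_indicator(groups: pd.Series) -> np.ndarray:
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise DesignError(f"expected two acclimation groups, found {levels}")
    if levels != ["cold", "warm"]:
        # accept any two labels; reference = lexicographically first
        pass
    return (groups == levels[-1]).to_numpy(float), levels


# ------------------------------------------------------------------ deformity
class DeformityModel:
    """Binomial GLM of per-male deformed/total counts on acclimation group."""

    def __init__(self, counts: pd.DataFrame):
        req = {"male_id", "group", "n_deformed", "n_total"}
        if not req <= set(counts.columns):
            raise DesignError(f"counts table needs columns {sorted(req)}")
        if (counts["n_total"] <= 0).any():
            raise DesignError("all totals must be > 0")
        if counts.groupby("group")["male_id"].nunique().min() < 2:
            raise DesignError("need >= 2 males per group")
        self.counts = counts.reset_index(drop=True)

    @classmethod
    def from_males_frame(cls, males: pd.DataFrame) -> "DeformityModel":
        """Build from a ``males.csv``-schema table with scanned_* columns."""
        from .design import DEFORMITY_CATEGORIES
        deformed = sum(males[f"scanned_{c}"] for c in DEFORMITY_CATEGORIES[1:])
        return cls(pd.DataFrame({
            "male_id": males["male_id"], "group": males["group"],
            "n_deformed": deformed, "n_total": males["scanned_total"],
        }))

    def fit(self) -> InferenceResults:
        warm, levels = _group_indicator(self.counts["group"])
        X = np.column_stack([np.ones(len(self.counts)), warm])
        endog = self.counts[["n_deformed"]].copy()
        endog["n_ok"] = self.counts["n_total"] - self.counts["n_deformed"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog.to_numpy(), X,
                         family=sm.families.Binomial()).fit()
        flags: list[str] = []
        if np.any(np.abs(res.params) > 15) or np.any(res.bse > 1e3):
            flags.append("possible complete separation")
        terms = pd.DataFrame({
            "estimate": res.params, "se": res.bse, "statistic": res.tvalues,
            "df": np.inf, "pvalue": res.pvalues,
        }, index=["intercept", f"group[{levels[-1]}]"])[_TERM_COLS]
        return InferenceResults(
            model_name="Deformity binomial GLM", response="n_deformed/n_total",
            transform="logit", terms=terms, n_obs=len(self.counts),
            n_groups=self.counts["male_id"].nunique(),
            converged=bool(res.converged), flags=tuple(flags))


# ----------------------------------------------------------------- morphology
class MorphologyModel:
    """Mixed model of one per-cell measure on acclimation group.

    Random intercept per male; log response for absolute sizes, identity for
    the ratio predictors (override with ``transform``).
    """

    def __init__(self, cells: pd.DataFrame, measure: str,
                 transform: str | None = None):
        req = {"male_id", "group", measure}
        if not req <= set(cells.columns):
            raise DesignError(f"cells table needs columns {sorted(req)}")
        per_group = cells.groupby("group")["male_id"].nunique()
        if len(per_group) < 2 or per_group.min() < 2:
            raise DesignError("need >= 2 males per acclimation group")
        if cells.groupby("male_id").size().min() < 2:
            raise DesignError("need >= 2 cells per male")
        self.cells = cells.reset_index(drop=True)
        self.measure = measure
        self.transform = transform or (
            "log" if measure in LOG_SCALE_MEASURES else "identity")
        if self.transform == "log" and (self.cells[measure] <= 0).any():
            raise DesignError(f"{measure}: non-positive values under log transform")

    def fit(self) -> InferenceResults:
        warm, levels = _group_indicator(self.cells["group"])
        y = self.cells[self.measure].to_numpy(float)
        if self.transform == "log":
            y = np.log(y)
        X = np.column_stack([np.ones(len(y)), warm])
        lm = RandomInterceptLM(y, X, self.cells["male_id"].to_numpy(),
                               ["intercept", f"group[{levels[-1]}]"])
        res = lm.fit()
        flags = []
        if res.degenerate:
            flags.append("degenerate fit: zero residual variance")
        if res.boundary:
            flags.append("boundary fit: zero male-level variance")
        terms = res.term_tests().rename(columns={"tvalue": "statistic"})[_TERM_COLS]
        return InferenceResults(
            model_name=f"Morphology LMM ({self.measure})", response=self.measure,
            transform=self.transform, terms=terms, n_obs=res.n_obs,
            n_groups=res.n_groups, converged=res.converged, flags=tuple(flags))


# ---------------------------------------------------------------------- speed
class SpeedModel:
    """Per-male regression of V_AP at one activation temperature on morphology.

    ``ratio`` names the per-male mean morphology column; ``include_acclimation``
    adds the group term (used for L_F/A_H, which differs between groups).
    Response transform defaults by activation temperature: identity at 8 °C,
    log at 13 °C.
    """

    def __init__(self, per_male: pd.DataFrame, ratio: str, vap_col: str,
                 activation_temp: float, include_acclimation: bool = False,
                 transform: str | None = None):
        req = {"male_id", ratio, vap_col} | ({"group"} if include_acclimation else set())
        if not req <= set(per_male.columns):
            raise DesignError(f"per-male table needs columns {sorted(req)}")
        n_params = 2 + int(include_acclimation)
        if len(per_male) < 3 * n_params:
            raise DesignError(f"need >= {3 * n_params} males for {n_params} parameters")
        self.per_male = per_male.reset_index(drop=True)
        self.ratio = ratio
        self.vap_col = vap_col
        self.activation_temp = float(activation_temp)
        self.include_acclimation = include_acclimation
        self.transform = transform or ("log" if activation_temp >= 13.0 else "identity")

    def fit(self) -> InferenceResults:
        d = self.per_male
        y = d[self.vap_col].to_numpy(float)
        if self.transform == "log":
            if (y <= 0).any():
                raise DesignError("non-positive V_AP under log transform")
            y = np.log(y)
        cols = [np.ones(len(d)), d[self.ratio].to_numpy(float)]
        names = ["intercept", self.ratio]
        if self.include_acclimation:
            warm, levels = _group_indicator(d["group"])
            cols.append(warm)
            names.append(f"group[{levels[-1]}]")
        X = np.column_stack(cols)
        flags = []
        if np.linalg.matrix_rank(X) < X.shape[1] or np.ptp(X[:, 1]) == 0:
            flags.append("degenerate fit: constant or collinear predictor")
            terms = pd.DataFrame(np.nan, index=names, columns=_TERM_COLS)
            return InferenceResults(
                model_name=f"Speed model (V_AP at {self.activation_temp:g} °C)",
                response=self.vap_col, transform=self.transform, terms=terms,
                n_obs=len(d), converged=False, flags=tuple(flags))
        res = sm.OLS(y, X).fit()
        terms = pd.DataFrame({
            "estimate": res.params, "se": res.bse, "statistic": res.tvalues,
            "df": float(res.df_resid), "pvalue": res.pvalues,
        }, index=names)[_TERM_COLS]
        return InferenceResults(
            model_name=f"Speed model (V_AP at {self.activation_temp:g} °C)",
            response=self.vap_col, transform=self.transform, terms=terms,
            n_obs=len(d), converged=True, flags=tuple(flags))


# ----------------------------------------------------------------------- drag
@dataclass
class DragResults(InferenceResults):
    """Drag-model results; retains the underlying mixed-model fit so the
    least-squares-means contrasts can be recomputed with other options."""

    lmm_results: RandomInterceptLMResults | None = None
    activation_levels: tuple[float, float] = (8.0, 13.0)
    df_method: str = "satterthwaite"


class DragModel:
    """LMM of per-male mean drag: acclimation × activation, male random intercept.

    Requires the full factorial design: every male must contribute a mean drag
    at each activation temperature.  ``df_method`` is ``"satterthwaite"``
    (default) or ``"residual"`` (n - p).
    """

    def __init__(self, per_male_drag: pd.DataFrame, df_method: str = "satterthwaite"):
        req = {"male_id", "group", "activation_temp_C", "mean_D_pN"}
        if not req <= set(per_male_drag.columns):
            raise DesignError(f"drag table needs columns {sorted(req)}")
        d = per_male_drag.reset_index(drop=True)
        temps = sorted(d["activation_temp_C"].unique())
        if len(temps) != 2:
            raise DesignError(f"expected two activation temperatures, found {temps}")
        cell_counts = d.groupby(["male_id", "activation_temp_C"]).size()
        if (cell_counts != 1).any():
            raise DesignError("need exactly one mean drag per male per temperature")
        per_male = d.groupby("male_id")["activation_temp_C"].nunique()
        if (per_male != 2).any():
            missing = per_male[per_male != 2].index[0]
            raise DesignError(f"male {missing} lacks drag at both activation temperatures")
        if df_method not in ("satterthwaite", "residual"):
            raise DesignError(f"unknown df method {df_method!r}")
        self.data = d
        self.temps = tuple(float(t) for t in temps)
        self.df_method = df_method

    def fit(self) -> DragResults:
        d = self.data
        warm, levels = _group_indicator(d["group"])
        act = (d["activation_temp_C"] == self.temps[1]).to_numpy(float)
        X = np.column_stack([np.ones(len(d)), warm, act, warm * act])
        names = ["intercept", f"acclimation[{levels[-1]}]",
                 f"activation[{self.temps[1]:g}C]",
                 f"acclimation[{levels[-1]}]:activation[{self.temps[1]:g}C]"]
        lm = RandomInterceptLM(d["mean_D_pN"].to_numpy(float), X,
                               d["male_id"].to_numpy(), names)
        res = lm.fit()
        flags = []
        if res.degenerate:
            flags.append("degenerate fit: zero residual variance")
        if res.boundary:
            flags.append("boundary fit: zero male-level variance")
        terms = res.term_tests().rename(columns={"tvalue": "statistic"})[_TERM_COLS]
        if self.df_method == "residual":
            terms["df"] = float(res.df_resid)
            terms["pvalue"] = 2 * stats.t.sf(np.abs(terms["statistic"]), terms["df"])
        out = DragResults(
            model_name="Drag LMM", response="mean_D_pN", transform="identity",
            terms=terms, n_obs=res.n_obs, n_groups=res.n_groups,
            converged=res.converged, flags=tuple(flags), lmm_results=res,
            activation_levels=self.temps, df_method=self.df_method)
        out.contrasts = lsmeans_contrasts(out)
        return out


def lsmeans_contrasts(result: DragResults, within: str = "acclimation") -> pd.DataFrame:
    """Pairwise activation-temperature contrasts within each acclimation level.

    Least-squares-means differences (high activation temperature minus low)
    computed from the fitted fixed effects: within the reference (cold) group
    the contrast is the activation coefficient; within the warm group it adds
    the interaction.  t and p use Satterthwaite df (or residual df when the
    model was fitted with ``df_method="residual"``); no multiplicity
    adjustment is applied.
    """
    if within != "acclimation":
        raise DesignError(f"factor {within!r} not in the drag model; "
                          "contrasts are within acclimation levels")
    res = result.lmm_results
    if res is None:
        raise DesignError("result does not carry a fitted mixed model")
    lo, hi = result.activation_levels
    rows = []
    for label, L in (("cold", [0.0, 0.0, 1.0, 0.0]),
                     ("warm", [0.0, 0.0, 1.0, 1.0])):
        c = res.t_test(L)
        if result.df_method == "residual":
            df = float(res.df_resid)
            p = 2 * float(stats.t.sf(abs(c.tvalue), df))
            c = ContrastResult(c.estimate, c.se, c.tvalue, df, p)
        rows.append({"within": label,
                     "contrast": f"{hi:g}C - {lo:g}C",
                     "estimate": c.estimate, "se": c.se,
                     "tvalue": c.tvalue, "df": c.df, "pvalue": c.pvalue})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- wrappers
def compare_deformity(counts: pd.DataFrame) -> InferenceResults:
    """Fit the deformity-proportion comparison (see :class:`DeformityModel`)."""
    return DeformityModel(counts).fit()


def compare_morphology(measure: str, cells: pd.DataFrame,
                       transform: str | None = None) -> InferenceResults:
    """Fit the group comparison for one morphometric measure."""
    return MorphologyModel(cells, measure, transform=transform).fit()


def speed_vs_morphology(per_male: pd.DataFrame, ratio: str, vap_col: str,
                        activation_temp: float,
                        include_acclimation: bool = False,
                        transform: str | None = None) -> InferenceResults:
    """Fit the per-male speed-on-morphology regression."""
    return SpeedModel(per_male, ratio, vap_col, activation_temp,
                      include_acclimation, transform).fit()


def drag_model(per_male_drag: pd.DataFrame,
               df_method: str = "satterthwaite") -> DragResults:
    """Fit the acclimation × activation drag mixed model with post-hoc contrasts."""
    return DragModel(per_male_drag, df_method=df_method).fit()
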