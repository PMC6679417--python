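"""Random-intercept linear mixed model with Satterthwaite inference.

A small, exact engine for the one mixed-model structure this pipeline needs:

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, s2_b),  e_ij ~ N(0, s2_e)

fitted by REML with the variance ratio lambda = s2_b / s2_e profiled out, and
per-term / per-contrast t tests with Satterthwaite-approximated denominator
degrees of freedom (the lmerTest convention).  For the balanced 16-male,
two-activation-temperature drag design this yields df = 14 for within-male
contrasts, the compatibility anchor for the post-hoc analysis.

Everything reduces to per-group sufficient statistics (X'X, X'y, 1'X, 1'y,
y'y, n_i), so a fit costs microseconds and thousands of simulation replicates
are cheap; the fit is deterministic (bounded scalar minimisation, fixed
bracket).  Estimates and standard errors agree with statsmodels MixedLM and
with lme4/lmerTest, which serve as independent oracles in the test suite.

Satterthwaite df: for a contrast L, var(L'beta_hat) = L' C(theta) L with
C(theta) = (X' V(theta)^-1 X)^-1 and theta = (s2_b, s2_e).  Then

    df = 2 * (L'CL)^2 / (g' A g)

where g is the gradient of L'C(theta)L in theta (finite differences) and A is
the asymptotic covariance of theta_hat, the inverse of the negative Hessian of
the REML log-likelihood (finite differences).  Boundary fits (s2_b -> 0) fall
back to the residual df of the fixed-effects model and are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["RandomInterceptLM", "RandomInterceptLMResults", "ContrastResult"]

_LOG2PI = math.log(2.0 * math.pi)


class ContrastResult(NamedTuple):
    estimate: float
    se: float
    tvalue: float
    df: float
    pvalue: float


@dataclass
class _SuffStats:
    """Per-group sufficient statistics for the random-intercept likelihood."""

    n: int                 # total observations
    p: int                 # fixed-effect parameters
    XtX: np.ndarray        # sum_i X_i' X_i               (p, p)
    Xty: np.ndarray        # sum_i X_i' y_i               (p,)
    yty: float             # y'y
    sx: np.ndarray         # per-group 1' X_i             (G, p)
    sy: np.ndarray         # per-group 1' y_i             (G,)
    ni: np.ndarray         # per-group sizes              (G,)


def _build_stats(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> _SuffStats:
    codes, _ = pd.factorize(groups, sort=False)
    G = codes.max() + 1
    p = X.shape[1]
    sx = np.zeros((G, p))
    np.add.at(sx, codes, X)
    sy = np.bincount(codes, weights=y, minlength=G)
    ni = np.bincount(codes, minlength=G)
    return _SuffStats(n=len(y), p=p, XtX=X.T @ X, Xty=X.T @ y,
                      yty=float(y @ y), sx=sx, sy=sy, ni=ni.astype(float))


def _gls_pieces(s: _SuffStats, c: np.ndarray):
    """A = X'W^-1X, r = X'W^-1y, q = y'W^-1y with W = I + lam*J per group,
    all scaled by s2_e = 1 (caller supplies c_i = weight of the rank-one
    downdate for the chosen covariance)."""
    A = s.XtX - (s.sx * c[:, None]).T @ s.sx
    r = s.Xty - s.sx.T @ (c * s.sy)
    q = s.yty - float(c @ s.sy**2)
    return A, r, q


def _profiled_neg_reml(log_lam: float, s: _SuffStats) -> float:
    lam = math.exp(log_lam)
    c = lam / (1.0 + lam * s.ni)
    A, r, q = _gls_pieces(s, c)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return 1e300
    beta = np.linalg.solve(A, r)
    rss = q - float(beta @ r)
    if rss <= 0:
        return 1e300  # perfectly fitting: residual variance collapses
    dfe = s.n - s.p
    s2e = rss / dfe
    logdetV = float(np.sum(np.log1p(lam * s.ni)))  # + n*log(s2e) handled below
    # profiled REML deviance (constants dropped)
    return 0.5 * (dfe * math.log(s2e) + logdetV + logdetA + dfe)


def _reml_loglike(theta: np.ndarray, s: _SuffStats) -> float:
    """Full REML log-likelihood at theta = (s2_b, s2_e), beta profiled out."""
    s2b, s2e = theta
    if s2e <= 0 or s2b < 0:
        return -np.inf
    c = (s2b / (s2e + s.ni * s2b)) / s2e          # weight on rank-one downdate / s2e
    A = (s.XtX - (s.sx * (c * s2e)[:, None]).T @ s.sx) / s2e
    r = (s.Xty - s.sx.T @ ((c * s2e) * s.sy)) / s2e
    q = (s.yty - float((c * s2e) @ s.sy**2)) / s2e
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(A, r)
    rss = q - float(beta @ r)
    logdetV = (s.n - len(s.ni)) * math.log(s2e) + float(
        np.sum(np.log(s2e + s.ni * s2b)))
    return -0.5 * (logdetV + logdetA + rss + (s.n - s.p) * _LOG2PI)


def _cov_beta(theta: Sequence[float], s: _SuffStats) -> np.ndarray:
    """C(theta) = (X' V^-1 X)^-1."""
    s2b, s2e = theta
    w = s2b / (s2e + s.ni * s2b)
    A = (s.XtX - (s.sx * w[:, None]).T @ s.sx) / s2e
    return np.linalg.inv(A)


class RandomInterceptLM:
    """Linear mixed model with a single random intercept per group.

    Parameters
    ----------
    endog : array-like
        Response vector.
    exog : array-like (n, p)
        Fixed-effects design matrix (include the constant explicitly).
    groups : array-like
        Grouping labels (one random intercept per distinct label).
    exog_names : sequence of str, optional
        Names for the fixed-effect columns.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        self.groups = np.asarray(groups)
        if not (len(self.endog) == len(self.exog) == len(self.groups)):
            raise ValueError("endog, exog and groups must have equal length")
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("fixed-effects design matrix is rank deficient")
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(self.exog.shape[1])]
        self._stats = _build_stats(self.endog, self.exog, self.groups)

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, groups: str
                     ) -> "RandomInterceptLM":
        """Build from a patsy formula; ``groups`` names the grouping column."""
        import patsy

        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        return cls(y.to_numpy().ravel(), X.to_numpy(), data[groups].to_numpy(),
                   exog_names=list(X.columns))

    def fit(self) -> "RandomInterceptLMResults":
        s = self._stats
        res = optimize.minimize_scalar(
            _profiled_neg_reml, bounds=(-20.0, 12.0), args=(s,),
            method="bounded", options={"xatol": 1e-10})
        lam = float(np.exp(res.x))
        boundary = res.x <= -19.0 or _profiled_neg_reml(-30.0, s) <= res.fun + 1e-12
        if boundary:
            lam = 0.0
        c = lam / (1.0 + lam * s.ni)
        A, r, q = _gls_pieces(s, c)
        beta = np.linalg.solve(A, r)
        rss = q - float(beta @ r)
        dfe = s.n - s.p
        s2e = rss / dfe if rss > 0 else 0.0
        s2b = lam * s2e
        # residual variance vanishing, absolutely or relative to the group
        # variance (lambda at its upper bound), makes the fit degenerate
        degenerate = (s2e <= max(1e-30, 1e-14 * abs(s.yty) / max(s.n, 1))
                      or res.x >= 11.5)
        cov = np.linalg.inv(A) * s2e if s2e > 0 else np.linalg.inv(A) * 0.0
        return RandomInterceptLMResults(
            model=self, fe_params=beta, cov_fe=cov,
            sigma2_group=s2b, sigma2_resid=s2e,
            converged=bool(res.success), boundary=bool(boundary),
            degenerate=bool(degenerate),
            loglike=_reml_loglike(np.array([s2b, max(s2e, 1e-300)]), s),
        )


@dataclass
class RandomInterceptLMResults:
    """REML fit of a :class:`RandomInterceptLM`.

    Carries the fixed-effect estimates and covariance, the two variance
    components, convergence/boundary flags, and Satterthwaite-based t tests.
    """

    model: RandomInterceptLM
    fe_params: np.ndarray
    cov_fe: np.ndarray
    sigma2_group: float
    sigma2_resid: float
    converged: bool
    boundary: bool
    degenerate: bool
    loglike: float

    # ------------------------------------------------------------- accessors
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fe_params, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_fe)), index=self.model.exog_names)

    @property
    def n_obs(self) -> int:
        return self.model._stats.n

    @property
    def n_groups(self) -> int:
        return len(self.model._stats.ni)

    @property
    def df_resid(self) -> int:
        return self.model._stats.n - self.model._stats.p

    # ---------------------------------------------------------- satterthwaite
    def satterthwaite_df(self, L) -> float:
        """Denominator df for the contrast ``L'beta`` (lmerTest convention)."""
        L = np.asarray(L, dtype=float)
        s = self.model._stats
        theta = np.array([self.sigma2_group, self.sigma2_resid])
        if self.degenerate:
            return float(max(self.df_resid, 1))
        if self.boundary or theta[0] < 1e-12 * theta[1]:
            # no usable group variance: inference collapses to the fixed model
            return float(max(self.df_resid, 1))

        def varL(th):
            return float(L @ _cov_beta(th, s) @ L)

        h = np.maximum(1e-6 * theta, 1e-12)
        g = np.empty(2)
        for j in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h[j]
            tm[j] = max(tm[j] - h[j], 1e-300)
            g[j] = (varL(tp) - varL(tm)) / (tp[j] - tm[j])

        H = np.empty((2, 2))
        hh = np.maximum(1e-4 * theta, 1e-10)
        for j in range(2):
            for k in range(j, 2):
                tpp = theta.copy(); tpp[j] += hh[j]; tpp[k] += hh[k]
                tpm = theta.copy(); tpm[j] += hh[j]; tpm[k] -= hh[k]
                tmp = theta.copy(); tmp[j] -= hh[j]; tmp[k] += hh[k]
                tmm = theta.copy(); tmm[j] -= hh[j]; tmm[k] -= hh[k]
                H[j, k] = H[k, j] = (
                    _reml_loglike(tpp, s) - _reml_loglike(tpm, s)
                    - _reml_loglike(tmp, s) + _reml_loglike(tmm, s)
                ) / (4.0 * hh[j] * hh[k])
        try:
            Acov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return float(max(self.df_resid, 1))
        denom = float(g @ Acov @ g)
        if denom <= 0 or not np.isfinite(denom):
            return float(max(self.df_resid, 1))
        df = 2.0 * varL(theta) ** 2 / denom
        return float(np.clip(df, 1.0, self.df_resid))

    def t_test(self, L) -> ContrastResult:
        """t test of ``L'beta = 0`` with Satterthwaite df."""
        L = np.asarray(L, dtype=float)
        est = float(L @ self.fe_params)
        var = float(L @ self.cov_fe @ L)
        if var <= 0:
            return ContrastResult(est, 0.0, np.nan, np.nan, np.nan)
        se = math.sqrt(var)
        df = self.satterthwaite_df(L)
        t = est / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
        return ContrastResult(est, se, t, df, p)

    def term_tests(self) -> pd.DataFrame:
        """Per-coefficient t tests (estimate, se, t, Satterthwaite df, p)."""
        p = len(self.fe_params)
        rows = []
        for j in range(p):
            L = np.zeros(p)
            L[j] = 1.0
            rows.append(self.t_test(L))
        return pd.DataFrame(rows, index=self.model.exog_names,
                            columns=["estimate", "se", "tvalue", "df", "pvalue"])

    def conf_int(self, L, alpha: float = 0.05) -> tuple[float, float]:
        r = self.t_test(L)
        q = float(stats.t.ppf(1.0 - alpha / 2.0, r.df))
        return (r.estimate - q * r.se, r.estimate + q * r.se)

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model (REML)",
            f"  n_obs: {self.n_obs}   n_groups: {self.n_groups}",
            f"  sigma2_group: {self.sigma2_group:.6g}   "
            f"sigma2_resid: {self.sigma2_resid:.6g}",
            f"  converged: {self.converged}   boundary: {self.boundary}"
            + ("   DEGENERATE (zero residual variance)" if self.degenerate else ""),
            "",
            self.term_tests().to_string(float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)
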