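"""Power-law fits for predator-prey biomass scaling.

All relations are fitted on double-logarithmic scales, where the power law
``y = c * x^k`` becomes the line ``log10 y = log10 c + k * log10 x``; OLS
(type-1 regression) is used throughout.

Within webs the records are hierarchical (predators nested in webs), so the
mean exponent ``k_bar`` and normalisation ``c_bar`` are estimated by a
linear mixed-effects model that treats per-web slope and intercept as
random: ``k_i = k_bar + eps_k_i``, ``c_i = c_bar + eps_c_i``.  Model
selection is top-down in two stages: (1) with the full fixed structure,
choose the random structure (correlated slope+intercept / uncorrelated /
intercept only) by REML AIC; (2) under that structure, likelihood-ratio
tests under full ML decide whether the slope differs among ecosystem types;
the selected model is refitted by REML for reporting.

Across webs each community contributes one point, so an ANCOVA (OLS with an
ecosystem factor) estimates per-ecosystem exponents and an F-test compares
the common-slope null against separate slopes.

Trait-augmented fits add predator-prey body-mass ratio and omnivory (each
interacted with ecosystem type) to the within-web model; their F-tests use
Satterthwaite's approximation for the denominator degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger("trophoscale")

_ALPHA = 0.05
_EXACT_RTOL = 1e-10  # pooled-OLS residual SD below this => noise-free data


class ModelFitError(RuntimeError):
    """Optimizer failed to converge; carries the fit diagnostics."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient (e.g. an ecosystem with no spread)."""


class SpeciesFitError(ValueError):
    """A per-species fit was requested with too few webs."""


@dataclass
class ScalingFit:
    """Fitted power-law parameters and diagnostics.

    ``k_bar``/``c_bar`` are the mean exponent and (log10) normalisation;
    ``k_by_ecosystem`` maps ecosystem type to its slope and 95% CI;
    ``eps_k``/``eps_c`` are per-web random deviations (empty for plain OLS
    fits); ``model_comparison`` records the selection tests that were run.
    """

    method: str
    k_bar: float
    c_bar: float
    ci_k: tuple[float, float]
    k_by_ecosystem: dict[str, dict[str, float]] = field(default_factory=dict)
    eps_k: dict[str, float] = field(default_factory=dict)
    eps_c: dict[str, float] = field(default_factory=dict)
    sigma_k: float = 0.0
    sigma_c: float = 0.0
    rho: float = float("nan")
    sigma_res: float = 0.0
    r2_marginal: float = float("nan")
    r2_conditional: float = float("nan")
    model_comparison: list[dict] = field(default_factory=list)
    fixed_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    trait_tests: list[dict] = field(default_factory=list)
    random_structure: str = ""
    n_records: int = 0
    n_webs: int = 0

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {k: clean(v) for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

_Y = "log10_predator_biomass"
_X = "log10_prey_biomass"
_ECO = "ecosystem_type"


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _check_within(table: pd.DataFrame) -> pd.DataFrame:
    need = {_Y, _X, "web_id", _ECO}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"within-web table missing columns: {sorted(missing)}")
    return table


def _pooled_resid_sd(table: pd.DataFrame) -> float:
    x = table[_X].to_numpy()
    y = table[_Y].to_numpy()
    k, c = _ols_line(x, y)
    return float(np.std(y - (c + k * x)))


def _slope_contrast(
    exog_names: Sequence[str], eco: str, ref: bool, x_col: str = _X
) -> np.ndarray:
    """Contrast vector extracting the absolute slope for one ecosystem from a
    treatment-coded ``x * C(ecosystem)`` parameterisation."""
    L = np.zeros(len(exog_names))
    for j, name in enumerate(exog_names):
        if name == x_col:
            L[j] = 1.0
        elif not ref and name.startswith(f"{x_col}:") and f"[T.{eco}]" in name:
            L[j] = 1.0
    return L


# ---------------------------------------------------------------------------
# direct LMM likelihood (for Satterthwaite degrees of freedom)
# ---------------------------------------------------------------------------


class _LMMProfile:
    """REML machinery for a random-intercept(+slope) LMM, parameterised by
    the raw variance components.

    Used to approximate the sampling variance of the variance components
    (observed information) and hence Satterthwaite denominator degrees of
    freedom for fixed-effect contrasts; the point estimates themselves come
    from the main fitting route.
    """

    def __init__(self, y, X, groups, z_slope: np.ndarray | None, structure: str):
        order = np.argsort(groups, kind="stable")
        self.y = np.asarray(y, float)[order]
        self.X = np.asarray(X, float)[order]
        g = np.asarray(groups)[order]
        zs = None if z_slope is None else np.asarray(z_slope, float)[order]
        self.structure = structure
        self.blocks = []
        for lab in pd.unique(g):
            idx = np.flatnonzero(g == lab)
            if structure == "intercept":
                Z = np.ones((len(idx), 1))
            else:
                Z = np.column_stack([np.ones(len(idx)), zs[idx]])
            self.blocks.append((idx, Z))
        self.p = self.X.shape[1]

    def n_theta(self) -> int:
        return {"correlated": 4, "uncorrelated": 3, "intercept": 2}[self.structure]

    def _cov_re(self, theta: np.ndarray) -> np.ndarray:
        if self.structure == "correlated":
            s11, s21, s22 = theta[0], theta[1], theta[2]
            return np.array([[s11, s21], [s21, s22]])
        if self.structure == "uncorrelated":
            return np.diag([theta[0], theta[1]])
        return np.array([[theta[0]]])

    def pack(self, cov_re: np.ndarray, scale: float) -> np.ndarray:
        if self.structure == "correlated":
            return np.array([cov_re[0, 0], cov_re[1, 0], cov_re[1, 1], scale])
        if self.structure == "uncorrelated":
            return np.array([cov_re[0, 0], cov_re[1, 1], scale])
        return np.array([cov_re[0, 0], scale])

    def _vinvs(self, theta):
        cov = self._cov_re(theta)
        s2 = theta[-1]
        out = []
        for idx, Z in self.blocks:
            V = s2 * np.eye(len(idx)) + Z @ cov @ Z.T
            out.append((idx, np.linalg.inv(V), V))
        return out

    def fixed_cov(self, theta: np.ndarray) -> np.ndarray:
        """Var(beta_hat) = (sum_i X_i' V_i^-1 X_i)^-1 at given components."""
        M = np.zeros((self.p, self.p))
        for idx, Vinv, _ in self._vinvs(theta):
            Xi = self.X[idx]
            M += Xi.T @ Vinv @ Xi
        return np.linalg.inv(M)

    def reml_loglike(self, theta: np.ndarray) -> float:
        M = np.zeros((self.p, self.p))
        Xty = np.zeros(self.p)
        logdet = 0.0
        for idx, Vinv, V in self._vinvs(theta):
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return -np.inf
            logdet += ld
            Xi = self.X[idx]
            M += Xi.T @ Vinv @ Xi
            Xty += Xi.T @ Vinv @ self.y[idx]
        signM, ldM = np.linalg.slogdet(M)
        if signM <= 0:
            return -np.inf
        beta = np.linalg.solve(M, Xty)
        quad = 0.0
        for idx, Vinv, _ in self._vinvs(theta):
            r = self.y[idx] - self.X[idx] @ beta
            quad += r @ Vinv @ r
        return -0.5 * (logdet + ldM + quad)

    def theta_vcov(self, theta: np.ndarray) -> np.ndarray | None:
        """Inverse observed information of the REML log-likelihood, by
        central finite differences; None if not positive definite."""
        q = len(theta)
        h = 1e-4 * (np.abs(theta) + 1e-3)
        H = np.zeros((q, q))
        f0 = self.reml_loglike(theta)
        if not np.isfinite(f0):
            return None
        for i in range(q):
            for j in range(i, q):
                ei = np.zeros(q)
                ej = np.zeros(q)
                ei[i] = h[i]
                ej[j] = h[j]
                fpp = self.reml_loglike(theta + ei + ej)
                fpm = self.reml_loglike(theta + ei - ej)
                fmp = self.reml_loglike(theta - ei + ej)
                fmm = self.reml_loglike(theta - ei - ej)
                if not all(np.isfinite([fpp, fpm, fmp, fmm])):
                    return None
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        info = -H
        try:
            evals = np.linalg.eigvalsh(info)
            if np.min(evals) <= 0:
                return None
            return np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return None

    def satterthwaite_df(self, theta: np.ndarray, L: np.ndarray) -> float | None:
        """1-df Satterthwaite denominator df for the contrast L'beta."""
        A = self.theta_vcov(theta)
        if A is None:
            return None

        def fvar(t):
            return float(L @ self.fixed_cov(t) @ L)

        f0 = fvar(theta)
        h = 1e-4 * (np.abs(theta) + 1e-3)
        g = np.zeros(len(theta))
        for i in range(len(theta)):
            e = np.zeros(len(theta))
            e[i] = h[i]
            g[i] = (fvar(theta + e) - fvar(theta - e)) / (2 * h[i])
        denom = float(g @ A @ g)
        if denom <= 0:
            return None
        return 2 * f0**2 / denom


def _satterthwaite_ftest(
    profile: _LMMProfile,
    theta: np.ndarray,
    beta: np.ndarray,
    L: np.ndarray,
) -> dict | None:
    """Multi-df F test of L beta = 0 with Satterthwaite denominator df,
    combining per-eigenvector 1-df approximations."""
    L = np.atleast_2d(L)
    q = L.shape[0]
    C = L @ profile.fixed_cov(theta) @ L.T
    try:
        evals, evecs = np.linalg.eigh(C)
    except np.linalg.LinAlgError:
        return None
    if np.min(evals) <= 0:
        return None
    tsq = []
    dfs = []
    for j in range(q):
        lj = evecs[:, j] @ L
        df_j = profile.satterthwaite_df(theta, lj)
        if df_j is None:
            return None
        est = float(lj @ beta)
        tsq.append(est**2 / evals[j])
        dfs.append(max(df_j, 2.0 + 1e-8))
    fstat = float(np.sum(tsq) / q)
    E = float(np.sum([d / (d - 2) for d in dfs]))
    ddf = 2 * E / (E - q) if E > q else float(np.mean(dfs))
    p = float(scipy.stats.f.sf(fstat, q, ddf))
    return {"F": fstat, "df_num": q, "df_den": float(ddf), "p": p}


# ---------------------------------------------------------------------------
# within-web LME
# ---------------------------------------------------------------------------

_STRUCTURES = ("correlated", "uncorrelated", "intercept")


def _fit_mixed(formula, data, structure, reml):
    re_formula = "1" if structure == "intercept" else f"~{_X}"
    model = smf.mixedlm(formula, data, groups=data["web_id"], re_formula=re_formula)
    free = None
    if structure == "uncorrelated":
        k_fe = model.exog.shape[1]
        free = MixedLMParams.from_components(
            fe_params=np.ones(k_fe), cov_re=np.eye(2)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(
                reml=reml, free=free, method=["lbfgs", "bfgs", "cg", "powell"]
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise ModelFitError(f"mixed-model fit failed: {exc}") from exc
    if not res.converged:
        raise ModelFitError(
            f"mixed-model fit did not converge (structure={structure}, "
            f"reml={reml})"
        )
    return res


def _n_var_params(structure: str) -> int:
    return {"correlated": 4, "uncorrelated": 3, "intercept": 2}[structure]


def _reml_aic(res, structure: str) -> float:
    # REML AIC over the variance parameters (fixed structure held constant)
    return float(-2 * res.llf + 2 * (_n_var_params(structure) + res.k_fe))


def _is_singular(res, structure: str) -> bool:
    cov = np.atleast_2d(np.asarray(res.cov_re))
    tr = np.trace(cov)
    if tr <= 0:
        return True
    return bool(np.min(np.linalg.eigvalsh(cov)) < 1e-8 * tr)


def _select_random_structure(formula, data) -> tuple[str, object, list[dict]]:
    comparison = []
    fits = {}
    for structure in _STRUCTURES:
        try:
            res = _fit_mixed(formula, data, structure, reml=True)
        except ModelFitError as exc:
            logger.warning("random structure %s: %s", structure, exc)
            comparison.append(
                {"stage": "random_structure", "structure": structure,
                 "aic": float("nan"), "singular": True}
            )
            continue
        singular = _is_singular(res, structure)
        if singular:
            logger.warning(
                "random structure %s produced a singular random-effects "
                "covariance; falling back to a simpler structure",
                structure,
            )
        comparison.append(
            {
                "stage": "random_structure",
                "structure": structure,
                "aic": _reml_aic(res, structure),
                "singular": bool(singular),
            }
        )
        if not singular:
            fits[structure] = res
    if not fits:
        # all structures degenerate; try intercept-only unconditionally, and
        # if even that fails there is no usable between-web variance: the
        # model collapses to plain OLS
        try:
            res = _fit_mixed(formula, data, "intercept", reml=True)
            return "intercept", res, comparison
        except ModelFitError:
            logger.warning(
                "no random-effects structure is estimable; collapsing to OLS"
            )
            comparison.append(
                {"stage": "random_structure", "structure": "none",
                 "note": "no estimable between-web variance"}
            )
            return "none", None, comparison
    best = min(fits, key=lambda s: _reml_aic(fits[s], s))
    return best, fits[best], comparison


def _simpler_structures(structure: str) -> list[str]:
    order = list(_STRUCTURES)
    return order[order.index(structure):] if structure in order else []


def _n_fe(res) -> int:
    return len(res.fe_params) if hasattr(res, "fe_params") else len(res.params)


def _ml_pair_with_fallback(formulas: Sequence[str], data, structure):
    """Fit all formulas by ML under one common random structure (LRTs need a
    shared structure), preferring the selected structure and walking through
    the alternatives; in the zero-between-web-variance limit the comparison
    degenerates to OLS likelihoods."""
    candidates = [structure] + [s for s in _STRUCTURES if s != structure]
    for s in candidates:
        try:
            return [_fit_mixed(f, data, s, reml=False) for f in formulas], s
        except ModelFitError as exc:
            logger.warning("ML fits under structure %s failed (%s)", s, exc)
    logger.warning(
        "no random structure supports the ML comparison; using OLS likelihoods"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [smf.ols(f, data=data).fit() for f in formulas], structure


def _reml_with_fallback(formula, data, structure):
    for s in _simpler_structures(structure):
        try:
            return _fit_mixed(formula, data, s, reml=True), s
        except ModelFitError as exc:
            logger.warning("REML refit under structure %s failed (%s)", s, exc)
    raise ModelFitError(f"REML refit failed for {formula!r}")


def _exact_fit(table: pd.DataFrame, method: str) -> ScalingFit:
    """Degenerate noise-free case: all records on one exact line."""
    x = table[_X].to_numpy()
    y = table[_Y].to_numpy()
    k, c = _ols_line(x, y)
    ecos = sorted(table[_ECO].unique())
    fit = ScalingFit(
        method=method,
        k_bar=k,
        c_bar=c,
        ci_k=(k, k),
        k_by_ecosystem={e: {"k": k, "ci_low": k, "ci_high": k} for e in ecos},
        sigma_res=0.0,
        r2_marginal=1.0,
        r2_conditional=1.0,
        random_structure="degenerate (noise-free)",
        n_records=len(table),
        n_webs=table["web_id"].nunique(),
    )
    for wid in table["web_id"].unique():
        fit.eps_k[str(wid)] = 0.0
        fit.eps_c[str(wid)] = 0.0
    logger.info("records are exactly collinear; returning noise-free fit")
    return fit


def _nakagawa_r2(res, data, structure) -> tuple[float, float]:
    fe = np.asarray(res.fe_params)
    X = res.model.exog
    var_f = float(np.var(X @ fe))
    cov = np.atleast_2d(np.asarray(res.cov_re))
    if structure == "intercept":
        Z = np.ones((len(data), 1))
    else:
        Z = np.column_stack([np.ones(len(data)), data[_X].to_numpy()])
    var_re = float(np.mean(np.einsum("ij,jk,ik->i", Z, cov, Z)))
    var_res = float(res.scale)
    tot = var_f + var_re + var_res
    return var_f / tot, (var_f + var_re) / tot


def _populate_random_effects(fit: ScalingFit, res, structure: str) -> None:
    cov = np.atleast_2d(np.asarray(res.cov_re))
    fit.sigma_c = float(np.sqrt(max(cov[0, 0], 0.0)))
    if structure != "intercept":
        fit.sigma_k = float(np.sqrt(max(cov[1, 1], 0.0)))
        if fit.sigma_k > 0 and fit.sigma_c > 0 and structure == "correlated":
            fit.rho = float(cov[0, 1] / (fit.sigma_k * fit.sigma_c))
    fit.sigma_res = float(np.sqrt(res.scale))
    try:
        random_effects = res.random_effects
    except (ValueError, np.linalg.LinAlgError):
        logger.warning(
            "random-effects covariance is singular; per-web deviations not "
            "predicted"
        )
        return
    for wid, re_vals in random_effects.items():
        vals = np.asarray(re_vals)
        fit.eps_c[str(wid)] = float(vals[0])
        fit.eps_k[str(wid)] = float(vals[1]) if len(vals) > 1 else 0.0


def _eco_slopes_from_interaction(res, ecos: Sequence[str]) -> dict[str, dict[str, float]]:
    names = list(res.model.exog_names)
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(names), : len(names)]
    out = {}
    ref = ecos[0]
    for eco in ecos:
        L = _slope_contrast(names, eco, ref=eco == ref)
        k = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        z = scipy.stats.norm.ppf(0.975)
        out[eco] = {"k": k, "ci_low": k - z * se, "ci_high": k + z * se}
    return out


def _single_web_ols(table: pd.DataFrame) -> ScalingFit:
    x = table[_X].to_numpy()
    y = table[_Y].to_numpy()
    res = scipy.stats.linregress(x, y)
    k = float(res.slope)
    dof = max(len(table) - 2, 1)
    tcrit = scipy.stats.t.ppf(0.975, df=dof)
    return ScalingFit(
        method="lme_within",
        k_bar=k,
        c_bar=float(res.intercept),
        ci_k=(k - tcrit * res.stderr, k + tcrit * res.stderr),
        sigma_res=float(
            np.sqrt(np.sum((y - (res.intercept + k * x)) ** 2) / dof)
        ),
        r2_marginal=float(res.rvalue**2),
        r2_conditional=float(res.rvalue**2),
        random_structure="none (single web)",
        n_records=len(table),
        n_webs=1,
    )


def fit_within_lme(
    within_table: pd.DataFrame, alpha: float = _ALPHA
) -> ScalingFit:
    """Hierarchical power-law fit of predator biomass on available prey
    biomass, with webs as the grouping level.

    Runs the two-stage top-down selection described in the module docstring
    and reports the mean exponent ``k_bar`` with a 95% Wald confidence
    interval from the REML refit of the selected model, plus per-ecosystem
    slopes from the full interaction model.
    """
    table = _check_within(within_table).copy()
    n_webs = table["web_id"].nunique()
    if n_webs < 2:
        # degenerate design: no between-web level, collapse to plain OLS
        logger.warning(
            "single web: random effects suppressed, fitting plain OLS"
        )
        return _single_web_ols(table)
    if _pooled_resid_sd(table) < _EXACT_RTOL:
        return _exact_fit(table, method="lme_within")

    ecos = sorted(table[_ECO].unique())
    multi_eco = len(ecos) > 1
    full_formula = (
        f"{_Y} ~ {_X} * C({_ECO})" if multi_eco else f"{_Y} ~ {_X}"
    )

    # stage 1: random structure by REML AIC under the full fixed structure
    structure, stage1_res, comparison = _select_random_structure(
        full_formula, table
    )
    if structure == "none":
        fit = _ancova(table, y_col=_Y, x_col=_X, method="lme_within")
        fit.model_comparison = comparison + fit.model_comparison
        fit.random_structure = "none (degenerate random effects)"
        fit.n_webs = n_webs
        return fit

    # stage 2: fixed-effects selection by ML likelihood-ratio tests
    final_formula = full_formula
    if multi_eco:
        add_formula = f"{_Y} ~ {_X} + C({_ECO})"
        (ml_full, ml_add), structure = _ml_pair_with_fallback(
            [full_formula, add_formula], table, structure
        )
        lr = 2 * (ml_full.llf - ml_add.llf)
        df = _n_fe(ml_full) - _n_fe(ml_add)
        p = float(scipy.stats.chi2.sf(lr, df))
        comparison.append(
            {
                "stage": "fixed_effects",
                "test": "ecosystem x slope interaction (LRT, ML)",
                "chi2": float(lr),
                "df": int(df),
                "p": p,
            }
        )
        if p >= alpha:
            final_formula = add_formula
            # also test the ecosystem main effect on the intercept
            (ml_add, ml_x), structure = _ml_pair_with_fallback(
                [add_formula, f"{_Y} ~ {_X}"], table, structure
            )
            lr2 = 2 * (ml_add.llf - ml_x.llf)
            df2 = _n_fe(ml_add) - _n_fe(ml_x)
            p2 = float(scipy.stats.chi2.sf(lr2, df2))
            comparison.append(
                {
                    "stage": "fixed_effects",
                    "test": "ecosystem main effect (LRT, ML)",
                    "chi2": float(lr2),
                    "df": int(df2),
                    "p": p2,
                }
            )
            if p2 >= alpha:
                final_formula = f"{_Y} ~ {_X}"
    else:
        logger.info("single ecosystem type: interaction test skipped")
        comparison.append(
            {
                "stage": "fixed_effects",
                "test": "ecosystem x slope interaction",
                "skipped": "single ecosystem type",
            }
        )

    # REML refit of the selected model for reporting
    res, structure = _reml_with_fallback(final_formula, table, structure)
    names = list(res.model.exog_names)
    beta = np.asarray(res.fe_params)
    ix = names.index(_X)
    k_bar = float(beta[ix])
    bse = np.asarray(res.bse_fe)
    se = float(bse[ix])
    z = scipy.stats.norm.ppf(0.975)
    fit = ScalingFit(
        method="lme_within",
        k_bar=k_bar,
        c_bar=float(beta[names.index("Intercept")]),
        ci_k=(k_bar - z * se, k_bar + z * se),
        model_comparison=comparison,
        random_structure=structure,
        n_records=len(table),
        n_webs=n_webs,
    )
    if multi_eco:
        # per-ecosystem slopes from the full interaction model (REML)
        try:
            res_int = (
                stage1_res
                if final_formula == full_formula and stage1_res is not None
                else _reml_with_fallback(full_formula, table, structure)[0]
            )
            fit.k_by_ecosystem = _eco_slopes_from_interaction(res_int, ecos)
        except ModelFitError as exc:
            logger.warning("per-ecosystem slopes unavailable: %s", exc)
    else:
        fit.k_by_ecosystem = {
            ecos[0]: {"k": k_bar, "ci_low": fit.ci_k[0], "ci_high": fit.ci_k[1]}
        }
    _populate_random_effects(fit, res, structure)
    fit.r2_marginal, fit.r2_conditional = _nakagawa_r2(res, table, structure)
    fit.fixed_effects = {
        name: {"estimate": float(beta[j]), "se": float(bse[j])}
        for j, name in enumerate(names)
    }
    return fit


# ---------------------------------------------------------------------------
# trait-augmented LME
# ---------------------------------------------------------------------------


def _screen_predictors(
    table: pd.DataFrame, candidates: Sequence[str], r_max: float = 0.7
) -> tuple[list[str], list[dict]]:
    """Drop constant predictors, then later members of any pair with
    |pairwise r| > r_max (the biomass covariate is always kept)."""
    kept: list[str] = []
    notes: list[dict] = []
    for c in candidates:
        if table[c].nunique() <= 1 or float(np.std(table[c])) == 0.0:
            logger.warning("predictor %s is constant; dropped", c)
            notes.append({"predictor": c, "dropped": "constant"})
            continue
        collinear = None
        for prev in [_X] + kept:
            r = float(np.corrcoef(table[prev], table[c])[0, 1])
            if abs(r) > r_max:
                collinear = (prev, r)
                break
        if collinear:
            logger.warning(
                "predictor %s dropped: |r|=%.2f with %s exceeds %.1f",
                c, abs(collinear[1]), collinear[0], r_max,
            )
            notes.append(
                {"predictor": c, "dropped": "collinear",
                 "with": collinear[0], "r": collinear[1]}
            )
            continue
        kept.append(c)
    return kept, notes


def fit_trait_lme(
    within_table: pd.DataFrame, alpha: float = _ALPHA
) -> tuple[ScalingFit, pd.DataFrame]:
    """Within-web LME augmented with predator traits (PPmR and omnivory,
    each interacted with ecosystem type).

    Returns the fit plus a table of partial residuals for the trait panels.
    Term significance uses F tests with Satterthwaite-approximated
    denominator degrees of freedom, falling back to likelihood-ratio
    chi-square tests when the information matrix is degenerate.
    """
    table = _check_within(within_table).copy()
    table = table.dropna(subset=["ppmr_log10", "omnivory"]).reset_index(drop=True)
    if table["web_id"].nunique() < 2:
        raise ValueError("trait LME requires records from >= 2 webs")
    if _pooled_resid_sd(table) < _EXACT_RTOL:
        fit = _exact_fit(table, method="lme_traits")
        return fit, pd.DataFrame()

    traits, screen_notes = _screen_predictors(table, ["ppmr_log10", "omnivory"])
    ecos = sorted(table[_ECO].unique())
    multi_eco = len(ecos) > 1
    terms = [f"{_X}"]
    if multi_eco:
        terms.append(f"C({_ECO})")
        terms += [f"{t} * C({_ECO})" for t in traits]
    else:
        terms += list(traits)
    formula = f"{_Y} ~ " + " + ".join(terms)

    structure, _, comparison = _select_random_structure(formula, table)
    use_ols = structure == "none"
    if use_ols:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.ols(formula, data=table).fit()
        beta = np.asarray(res.params)
        bse = np.asarray(res.bse)
    else:
        res, structure = _reml_with_fallback(formula, table, structure)
        beta = np.asarray(res.fe_params)
        bse = np.asarray(res.bse_fe)
    names = list(res.model.exog_names)
    ix = names.index(_X)
    z = scipy.stats.norm.ppf(0.975)
    k_bar = float(beta[ix])
    fit = ScalingFit(
        method="lme_traits",
        k_bar=k_bar,
        c_bar=float(beta[names.index("Intercept")]),
        ci_k=(k_bar - z * float(bse[ix]), k_bar + z * float(bse[ix])),
        model_comparison=comparison + [
            {"stage": "screening", **n} for n in screen_notes
        ],
        random_structure="none (degenerate random effects)" if use_ols else structure,
        n_records=len(table),
        n_webs=table["web_id"].nunique(),
    )
    if use_ols:
        fit.sigma_res = float(np.sqrt(res.mse_resid))
        fit.r2_marginal = fit.r2_conditional = float(res.rsquared)
    else:
        _populate_random_effects(fit, res, structure)
        fit.r2_marginal, fit.r2_conditional = _nakagawa_r2(res, table, structure)
    fit.fixed_effects = {
        name: {"estimate": float(beta[j]), "se": float(bse[j])}
        for j, name in enumerate(names)
    }

    # F tests per trait term (main + its ecosystem interaction); under the
    # mixed model the denominator df use Satterthwaite's approximation
    if not use_ols:
        profile = _LMMProfile(
            y=table[_Y].to_numpy(),
            X=res.model.exog,
            groups=table["web_id"].to_numpy(),
            z_slope=table[_X].to_numpy(),
            structure=structure,
        )
        theta = profile.pack(
            np.atleast_2d(np.asarray(res.cov_re)), float(res.scale)
        )
    for trait in traits:
        for label, pred in (
            (f"{trait}", lambda n, t=trait: n == t),
            (
                f"{trait} x ecosystem",
                lambda n, t=trait: n.startswith(f"{t}:") or n.endswith(f":{t}"),
            ),
        ):
            rows = [j for j, n in enumerate(names) if pred(n)]
            if not rows:
                continue
            L = np.zeros((len(rows), len(names)))
            for r, j in enumerate(rows):
                L[r, j] = 1.0
            if use_ols:
                ftest = res.f_test(L)
                test = {
                    "F": float(ftest.fvalue),
                    "df_num": int(ftest.df_num),
                    "df_den": float(ftest.df_denom),
                    "p": float(ftest.pvalue),
                    "method": "ols",
                }
            else:
                test = _satterthwaite_ftest(profile, theta, beta, L)
                if test is None:
                    test = _lrt_fallback(formula, table, structure, names, rows)
            test["term"] = label
            fit.trait_tests.append(test)

    partial = _partial_residuals(res.model.exog, beta, table, names, traits)
    return fit, partial


def _lrt_fallback(formula, table, structure, names, rows) -> dict:
    """LR chi-square when Satterthwaite df cannot be computed."""
    logger.warning(
        "Satterthwaite approximation unavailable; using likelihood-ratio test"
    )
    keep = [j for j in range(len(names)) if j not in rows]
    df = len(rows)
    for s in [structure] + [x for x in _STRUCTURES if x != structure]:
        try:
            full = _fit_mixed(formula, table, s, reml=False)
            exog = full.model.exog[:, keep]
            model = sm.MixedLM(
                table[_Y].to_numpy(),
                exog,
                groups=table["web_id"].to_numpy(),
                exog_re=full.model.exog_re,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                red = model.fit(reml=False, method=["lbfgs", "bfgs", "powell"])
            lr = 2 * (full.llf - red.llf)
            break
        except (ModelFitError, np.linalg.LinAlgError, ValueError):
            continue
    else:
        # zero between-web variance limit: OLS likelihoods
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full_ols = smf.ols(formula, data=table).fit()
            red_ols = sm.OLS(
                table[_Y].to_numpy(), full_ols.model.exog[:, keep]
            ).fit()
        lr = 2 * (full_ols.llf - red_ols.llf)
    return {
        "method": "lrt_fallback",
        "chi2": float(lr),
        "df": int(df),
        "p": float(scipy.stats.chi2.sf(lr, df)),
    }


def _partial_residuals(X, beta, table, names, traits) -> pd.DataFrame:
    resid = table[_Y].to_numpy() - X @ beta
    out = table[["web_id", _ECO, "predator_id"] + list(traits)].copy()
    for trait in traits:
        cols = [
            j
            for j, n in enumerate(names)
            if n == trait or n.startswith(f"{trait}:") or n.endswith(f":{trait}")
        ]
        contrib = X[:, cols] @ beta[cols] if cols else 0.0
        out[f"partial_resid_{trait}"] = resid + contrib
    return out


# ---------------------------------------------------------------------------
# per-web OLS
# ---------------------------------------------------------------------------


def fit_per_web_ols(
    within_table: pd.DataFrame, min_records: int = 2
) -> pd.DataFrame:
    """Per-web OLS slope and intercept of log10 predator biomass on log10
    available prey biomass; webs with too few records or no x-variance are
    skipped with a log entry."""
    table = _check_within(within_table)
    rows = []
    for web_id, grp in table.groupby("web_id", sort=False):
        x = grp[_X].to_numpy()
        y = grp[_Y].to_numpy()
        if len(grp) < min_records:
            logger.info("web %s: %d record(s) < %d, skipped", web_id, len(grp), min_records)
            continue
        if np.ptp(x) == 0:
            logger.info("web %s: zero variance in prey biomass, skipped", web_id)
            continue
        k, c = _ols_line(x, y)
        pred = c + k * x
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        rows.append(
            {
                "web_id": str(web_id),
                "ecosystem_type": grp[_ECO].iloc[0],
                "k_i": k,
                "c_i": c,
                "n": len(grp),
                "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["web_id", "ecosystem_type", "k_i", "c_i", "n", "r2"]
    )


# ---------------------------------------------------------------------------
# across-web ANCOVA
# ---------------------------------------------------------------------------


def _ancova(
    table: pd.DataFrame, y_col: str, x_col: str, method: str
) -> ScalingFit:
    table = table.copy()
    ecos = sorted(table[_ECO].unique())
    multi_eco = len(ecos) > 1
    if multi_eco:
        full_formula = f"{y_col} ~ {x_col} * C({_ECO})"
        null_formula = f"{y_col} ~ {x_col} + C({_ECO})"
    else:
        full_formula = null_formula = f"{y_col} ~ {x_col}"
    full = smf.ols(full_formula, data=table).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise RankDeficiencyError(
            f"ANCOVA design is rank deficient for {full_formula!r}"
        )
    comparison = []
    if multi_eco:
        null = smf.ols(null_formula, data=table).fit()
        if full.ssr < 1e-12:
            # both models interpolate (noise-free data): no interaction signal
            fstat, pval = 0.0, 1.0
            df_num = float(full.df_model - null.df_model)
            df_den = float(full.df_resid)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tab = anova_lm(null, full)
            fstat = float(tab["F"].iloc[1])
            pval = float(tab["Pr(>F)"].iloc[1])
            df_num = float(tab["df_diff"].iloc[1])
            df_den = float(tab["df_resid"].iloc[1])
        comparison.append(
            {
                "stage": "fixed_effects",
                "test": "ecosystem x slope interaction (F)",
                "F": fstat,
                "df_num": df_num,
                "df_den": df_den,
                "p": pval,
            }
        )
    else:
        logger.info("single ecosystem type: ANCOVA interaction test skipped")
        comparison.append(
            {
                "stage": "fixed_effects",
                "test": "ecosystem x slope interaction",
                "skipped": "single ecosystem type",
            }
        )
        null = full

    names = list(full.model.exog_names)
    beta = np.asarray(full.params)
    covb = np.asarray(full.cov_params())
    tcrit = scipy.stats.t.ppf(0.975, df=full.df_resid)
    k_by_eco = {}
    ref = ecos[0]
    for eco in ecos:
        L = _slope_contrast(names, eco, ref=eco == ref, x_col=x_col)
        k = float(L @ beta)
        se = float(np.sqrt(L @ covb @ L))
        k_by_eco[eco] = {
            "k": k,
            "ci_low": k - tcrit * se,
            "ci_high": k + tcrit * se,
            "p_slope_zero": float(
                2 * scipy.stats.t.sf(abs(k / se), df=full.df_resid)
            )
            if se > 0
            else (1.0 if k == 0 else 0.0),
        }
    k_bar = float(np.mean([v["k"] for v in k_by_eco.values()]))

    # common-slope estimate and CI from the null (common-slope) model
    nnames = list(null.model.exog_names)
    jx = nnames.index(x_col)
    ks = float(null.params.iloc[jx])
    ses = float(null.bse.iloc[jx])
    tnull = scipy.stats.t.ppf(0.975, df=null.df_resid)
    comparison.append(
        {
            "stage": "common_slope",
            "k": ks,
            "ci_low": ks - tnull * ses,
            "ci_high": ks + tnull * ses,
            "p_slope_zero": float(null.pvalues.iloc[jx]),
        }
    )

    ctss = float(full.centered_tss)
    r2 = 1.0 - full.ssr / ctss if ctss > 1e-12 else (
        1.0 if full.ssr < 1e-12 else 0.0
    )
    fit = ScalingFit(
        method=method,
        k_bar=k_bar,
        c_bar=float(null.params.iloc[nnames.index("Intercept")]),
        ci_k=(ks - tnull * ses, ks + tnull * ses),
        k_by_ecosystem=k_by_eco,
        sigma_res=float(np.sqrt(null.mse_resid)),
        r2_marginal=r2,
        r2_conditional=r2,
        model_comparison=comparison,
        n_records=len(table),
        n_webs=len(table),
    )
    return fit


def fit_across_ancova(across_table: pd.DataFrame) -> ScalingFit:
    """Across-web power-law fit: one point per web, OLS of log10 total
    predator biomass on log10 total prey biomass with an ecosystem factor.

    ``k_bar`` is the mean of the per-ecosystem slopes; ``ci_k`` comes from
    the common-slope model.  The F-test compares a single-power-law null to
    separate power laws per ecosystem type.
    """
    return _ancova(
        across_table,
        y_col="log10_total_predator_biomass",
        x_col="log10_total_prey_biomass",
        method="ancova_across",
    )


def fit_prey_mass_model(
    across_table: pd.DataFrame, outlier_ids: Sequence[str] = ()
) -> ScalingFit:
    """Diagnostic regression of log10 mean prey body mass on log10 total
    prey biomass (same ANCOVA machinery), after removing annotated outlier
    webs.  A slope near zero indicates prey-biomass gradients are driven by
    density rather than prey size."""
    table = across_table[~across_table["web_id"].isin(set(outlier_ids))]
    if len(table) < len(across_table):
        logger.info(
            "prey-mass model: removed %d outlier web(s)",
            len(across_table) - len(table),
        )
    return _ancova(
        table,
        y_col="log10_mean_prey_mass",
        x_col="log10_total_prey_biomass",
        method="ancova_prey_mass",
    )


# ---------------------------------------------------------------------------
# per-species across-web fit
# ---------------------------------------------------------------------------


def fit_species_across_webs(
    within_table: pd.DataFrame, species_name: str, min_webs: int = 5
) -> ScalingFit:
    """OLS power-law fit for one predator species across the webs where it
    occurs: its biomass against its available prey biomass, one point per
    web."""
    table = _check_within(within_table)
    rows = table[table["taxon_name"] == species_name]
    n_webs = rows["web_id"].nunique()
    if n_webs < min_webs:
        raise SpeciesFitError(
            f"species {species_name!r} occurs as predator in {n_webs} web(s); "
            f"need >= {min_webs}"
        )
    x = rows[_X].to_numpy()
    y = rows[_Y].to_numpy()
    res = scipy.stats.linregress(x, y)
    tcrit = scipy.stats.t.ppf(0.975, df=len(rows) - 2)
    k = float(res.slope)
    return ScalingFit(
        method="ols_species",
        k_bar=k,
        c_bar=float(res.intercept),
        ci_k=(k - tcrit * res.stderr, k + tcrit * res.stderr),
        sigma_res=float(
            np.sqrt(
                np.sum((y - (res.intercept + k * x)) ** 2) / max(len(rows) - 2, 1)
            )
        ),
        r2_marginal=float(res.rvalue**2),
        r2_conditional=float(res.rvalue**2),
        n_records=len(rows),
        n_webs=n_webs,
    )


# ---------------------------------------------------------------------------
# derived identities
# ---------------------------------------------------------------------------


def doubling_increase_percent(k: float) -> float:
    """Predicted % increase in predator biomass when prey biomass doubles:
    (2^k - 1) * 100."""
    return float((2.0**k - 1.0) * 100.0)


def fold_increase(k: float, x_fold: float) -> float:
    """Fold change in predator biomass for an ``x_fold``-fold change in prey
    biomass under exponent ``k``: ``x_fold ** k``."""
    return float(x_fold**k)
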