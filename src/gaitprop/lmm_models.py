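"""Linear mixed models for gait-speed effects on propulsion.

Four model families, all fitted by REML with participant as the grouping
factor:

* **Symmetry model (stroke)** — response: propulsion peak or impulse
  symmetry (fraction scale); fixed effects: gait speed (m/s, uncentered),
  symmetry at comfortable walking speed (CWS), and their interaction;
  random: intercept + speed slope per participant.  The symmetry-at-CWS
  main effect is estimated for correct adjustment but not meaningful on
  its own and is marked not-reported.
* **Symmetry model (controls)** — reduced: fixed speed; random intercept
  + speed slope.
* **Per-leg model (stroke)** — response: absolute peak or impulse per
  leg; fixed: speed, leg (non-paretic = reference, paretic = 1), and
  speed x leg; random: intercept, speed, leg, and speed x leg per
  participant (independent components).  The negative printed paretic
  effects fix the reference coding.
* **Post-hoc per-leg / control propulsion models** — fixed speed; random
  intercept + slope; used per leg when the speed x leg interaction is
  significant at alpha = 0.05, and for the control reference cohort.

Degrees of freedom use a Satterthwaite approximation computed from the
numerical curvature of the REML log-likelihood (Kenward-Roger is not
available in this stack; see docs/methods.md).  Fixed-effect estimates and
SEs do not depend on the df method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import GaitPropError, ParameterError

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class LmmSpec:
    """Declarative description of one mixed-model fit."""

    response: str
    fixed_terms: List[str]
    random_terms: List[str]
    diagonal_re: bool = False
    reml: bool = True
    df_method: str = "satterthwaite"  # "satterthwaite" | "between_within"


@dataclass
class LmmFit:
    """Fixed-effect table, random-effect SDs and fit status for one model."""

    spec: LmmSpec
    params: pd.DataFrame  # index: term; columns: estimate, se, t, df, p
    random_sd: Dict[str, float]
    resid_sd: float
    converged: bool
    singular: bool
    n_obs: int
    n_groups: int
    not_reported: List[str] = field(default_factory=list)
    # raw materials for diagnostics
    residuals: Optional[np.ndarray] = None
    fitted: Optional[np.ndarray] = None

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "fixed_effects": {
                t: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for t, row in self.params.iterrows()
            },
            "random_sd": {k: float(v) for k, v in self.random_sd.items()},
            "residual_sd": float(self.resid_sd),
            "converged": bool(self.converged),
            "singular": bool(self.singular),
            "n_obs": int(self.n_obs),
            "n_participants": int(self.n_groups),
            "df_method": self.spec.df_method,
            "not_reported": list(self.not_reported),
        }


@dataclass
class DiagnosticsBundle:
    """Raw material for the three standard residual plots."""

    residuals: np.ndarray
    fitted: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    shapiro_w: float
    shapiro_p: float


# ---------------------------------------------------------------------------
# Satterthwaite degrees of freedom
# ---------------------------------------------------------------------------

def _group_blocks(model):
    """Split endog/exog/exog_re by group label, preserving order."""
    labels = np.asarray(model.groups)
    X = np.asarray(model.exog, dtype=float)
    Z = np.asarray(model.exog_re, dtype=float)
    y = np.asarray(model.endog, dtype=float)
    blocks = []
    for g in pd.unique(labels):
        m = labels == g
        blocks.append((y[m], X[m], Z[m]))
    return blocks


def _beta_cov(blocks, psi, sigma2):
    """(X' V^-1 X)^-1 for V_i = Z_i Psi Z_i' + sigma2 I."""
    p = blocks[0][1].shape[1]
    xtvx = np.zeros((p, p))
    for _, X, Z in blocks:
        V = Z @ psi @ Z.T + sigma2 * np.eye(Z.shape[0])
        xtvx += X.T @ np.linalg.solve(V, X)
    return np.linalg.inv(xtvx)


def _reml_loglik(blocks, psi, sigma2):
    p = blocks[0][1].shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet = 0.0
    for y, X, Z in blocks:
        V = Z @ psi @ Z.T + sigma2 * np.eye(Z.shape[0])
        sign, ld = np.linalg.slogdet(V)
        if sign <= 0:
            return -np.inf
        logdet += ld
        Vi_X = np.linalg.solve(V, X)
        xtvx += X.T @ Vi_X
        xtvy += Vi_X.T @ y
    beta = np.linalg.solve(xtvx, xtvy)
    quad = 0.0
    for y, X, Z in blocks:
        V = Z @ psi @ Z.T + sigma2 * np.eye(Z.shape[0])
        r = y - X @ beta
        quad += r @ np.linalg.solve(V, r)
    sign, ld_x = np.linalg.slogdet(xtvx)
    return -0.5 * (logdet + ld_x + quad)


def _pack(psi, sigma, diagonal):
    if diagonal:
        theta = list(np.sqrt(np.clip(np.diag(psi), 0.0, None)))
    else:
        L = np.linalg.cholesky(psi + 1e-12 * np.eye(psi.shape[0]))
        theta = [L[i, j] for i in range(psi.shape[0]) for j in range(i + 1)]
    return np.array(theta + [sigma])


def _unpack(theta, q, diagonal):
    if diagonal:
        psi = np.diag(np.asarray(theta[:q]) ** 2)
    else:
        L = np.zeros((q, q))
        k = 0
        for i in range(q):
            for j in range(i + 1):
                L[i, j] = theta[k]
                k += 1
        psi = L @ L.T
    sigma = theta[-1]
    return psi, sigma ** 2


def satterthwaite_df(model, psi, sigma2, diagonal: bool) -> np.ndarray:
    """Per-coefficient Satterthwaite df from numerical REML curvature.

    df_c = 2 (c' Vb c)^2 / Var(c' Vb(theta_hat) c), with Var via the delta
    method: the gradient of Vb_cc w.r.t. the variance parameters and the
    inverse observed REML information, both by central finite differences.
    Returns NaN per coefficient on numerical failure (caller falls back).
    """
    blocks = _group_blocks(model)
    q = psi.shape[0]
    theta0 = _pack(psi, np.sqrt(sigma2), diagonal)
    dim = theta0.size
    h = 1e-4 * np.maximum(np.abs(theta0), 1e-3)

    def ll(th):
        ps, s2 = _unpack(th, q, diagonal)
        if s2 <= 0:
            return -np.inf
        return _reml_loglik(blocks, ps, s2)

    # observed information (negative Hessian) by central differences
    H = np.zeros((dim, dim))
    for i in range(dim):
        for j in range(i + 1):
            ei = np.zeros(dim); ei[i] = h[i]
            ej = np.zeros(dim); ej[j] = h[j]
            f = (ll(theta0 + ei + ej) - ll(theta0 + ei - ej)
                 - ll(theta0 - ei + ej) + ll(theta0 - ei - ej)) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = f
    if not np.all(np.isfinite(H)):
        return np.full(model.exog.shape[1], np.nan)
    try:
        var_theta = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.full(model.exog.shape[1], np.nan)

    p = model.exog.shape[1]
    vb0 = _beta_cov(blocks, *_unpack(theta0, q, diagonal))
    dfs = np.empty(p)
    # gradient of each Vb_cc w.r.t. theta
    grads = np.zeros((p, dim))
    for i in range(dim):
        e = np.zeros(dim); e[i] = h[i]
        vb_plus = _beta_cov(blocks, *_unpack(theta0 + e, q, diagonal))
        vb_minus = _beta_cov(blocks, *_unpack(theta0 - e, q, diagonal))
        grads[:, i] = (np.diag(vb_plus) - np.diag(vb_minus)) / (2 * h[i])
    for c in range(p):
        g = grads[c]
        denom = g @ var_theta @ g
        dfs[c] = 2 * vb0[c, c] ** 2 / denom if denom > 0 else np.nan
    return dfs


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_mixed(data: pd.DataFrame, formula: str, re_formula: str, spec: LmmSpec,
               groups_col: str = "pid") -> LmmFit:
    if data[groups_col].nunique() < 2:
        raise GaitPropError("mixed model needs at least 2 participants")
    model = smf.mixedlm(formula, data, groups=data[groups_col], re_formula=re_formula)
    k_fe = model.exog.shape[1]
    k_re = model.exog_re.shape[1]
    free = None
    if spec.diagonal_re:
        free = MixedLMParams.from_components(fe_params=np.ones(k_fe), cov_re=np.eye(k_re))
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(reml=spec.reml, free=free, method="lbfgs", maxiter=1000)
        except (np.linalg.LinAlgError, ValueError):
            res = None
        if res is None or not np.all(np.isfinite(res.fe_params)):
            res = model.fit(reml=spec.reml, free=free, method="powell", maxiter=2000)
        converged = bool(getattr(res, "converged", True))

    psi = np.asarray(res.cov_re, dtype=float)
    if spec.diagonal_re:
        psi = np.diag(np.diag(psi))
    sigma2 = float(res.scale)
    ev = np.linalg.eigvalsh(psi)
    singular = bool(ev.min() < 1e-10 * max(ev.max(), 1e-12))
    if singular:
        logger.warning("random-effect covariance is singular for %s", spec.response)

    terms = list(res.fe_params.index)
    est = res.fe_params.to_numpy()
    se = res.bse_fe.to_numpy()
    tval = est / se

    n_groups = data[groups_col].nunique()
    dfs = np.full(len(terms), np.nan)
    if spec.df_method == "satterthwaite":
        try:
            dfs = satterthwaite_df(model, psi, sigma2, spec.diagonal_re)
        except Exception:  # numerical failure -> fallback below
            dfs = np.full(len(terms), np.nan)
    fallback = float(max(n_groups - k_fe, 1))
    dfs = np.where(np.isfinite(dfs) & (dfs >= 1.0), dfs, fallback)
    dfs = np.minimum(dfs, model.exog.shape[0] - k_fe)
    pvals = 2 * stats.t.sf(np.abs(tval), dfs)

    re_names = list(model.data.exog_re_names) if hasattr(model.data, "exog_re_names") else \
        [f"re{i}" for i in range(k_re)]
    random_sd = {name: float(np.sqrt(max(psi[i, i], 0.0)))
                 for i, name in enumerate(re_names)}

    fitted = np.asarray(res.fittedvalues, dtype=float)
    resid = np.asarray(model.endog, dtype=float) - fitted
    params = pd.DataFrame(
        {"estimate": est, "se": se, "t": tval, "df": dfs, "p": pvals}, index=terms)
    return LmmFit(spec=spec, params=params, random_sd=random_sd,
                  resid_sd=float(np.sqrt(sigma2)), converged=converged,
                  singular=singular, n_obs=model.exog.shape[0],
                  n_groups=n_groups, residuals=resid, fitted=fitted)


def _condition_level(table: pd.DataFrame, group: str) -> pd.DataFrame:
    df = table[table["group"] == group]
    return df.drop_duplicates(subset=["participant_id", "condition_id"])


def fit_symmetry_model(table: pd.DataFrame, metric: str, group: str,
                       df_method: str = "satterthwaite") -> LmmFit:
    """Gait-speed effect on propulsion symmetry (fraction scale).

    Stroke: ``symmetry ~ speed + symmetry_at_cws + speed:symmetry_at_cws``
    with random intercept + speed slope.  Controls: ``symmetry ~ speed``
    with the same random structure.  Participants lacking a usable CWS
    condition are dropped from the stroke fit.
    """
    if metric not in ("peak", "impulse"):
        raise ParameterError(f"unknown metric {metric!r}")
    df = _condition_level(table, group)
    work = pd.DataFrame({
        "pid": df["participant_id"],
        "speed": df["speed"].astype(float),
        "sym": df[f"{metric}_symmetry"].astype(float),
        "s0": df[f"{metric}_symmetry_at_cws"].astype(float),
    })
    work = work.dropna(subset=["sym"])
    if group == "stroke":
        work = work.dropna(subset=["s0"])
        spec = LmmSpec(response=f"{metric}_symmetry",
                       fixed_terms=["speed", "s0", "speed:s0"],
                       random_terms=["intercept", "speed"], df_method=df_method)
        fit = _fit_mixed(work, "sym ~ speed + s0 + speed:s0", "~speed", spec)
        fit.not_reported = ["s0"]
    else:
        spec = LmmSpec(response=f"{metric}_symmetry", fixed_terms=["speed"],
                       random_terms=["intercept", "speed"], df_method=df_method)
        fit = _fit_mixed(work, "sym ~ speed", "~speed", spec)
    return fit


def _leg_frame(table: pd.DataFrame, metric: str, group: str) -> pd.DataFrame:
    df = table[table["group"] == group]
    work = pd.DataFrame({
        "pid": df["participant_id"],
        "speed": df["speed"].astype(float),
        "value": df[metric].astype(float),
        "leg": df["leg"],
    }).dropna(subset=["value"])
    return work


def fit_leg_model(table: pd.DataFrame, metric: str,
                  df_method: str = "satterthwaite") -> LmmFit:
    """Speed x leg model on absolute per-leg propulsion (stroke cohort).

    Leg is an indicator (non-paretic = 0, paretic = 1); random intercept,
    speed, leg and speed x leg per participant as independent components.
    """
    work = _leg_frame(table, metric, "stroke")
    present = set(work["leg"])
    if not {"paretic", "non_paretic"} <= present:
        raise GaitPropError(f"per-leg model needs both legs, found {sorted(present)}")
    work = work.assign(leg_p=(work["leg"] == "paretic").astype(float))
    spec = LmmSpec(response=metric,
                   fixed_terms=["speed", "leg_p", "speed:leg_p"],
                   random_terms=["intercept", "speed", "leg_p", "speed:leg_p"],
                   diagonal_re=True, df_method=df_method)
    return _fit_mixed(work, "value ~ speed + leg_p + speed:leg_p",
                      "~speed + leg_p + speed:leg_p", spec)


def fit_per_leg_posthoc(table: pd.DataFrame, metric: str, leg: str,
                        df_method: str = "satterthwaite") -> LmmFit:
    """Single-leg speed model (stroke), used when the speed x leg
    interaction is significant: fixed speed, random intercept + slope."""
    work = _leg_frame(table, metric, "stroke")
    work = work[work["leg"] == leg]
    if work["pid"].nunique() < 2:
        raise GaitPropError(f"post-hoc model for leg {leg!r} needs >= 2 participants")
    spec = LmmSpec(response=f"{metric}[{leg}]", fixed_terms=["speed"],
                   random_terms=["intercept", "speed"], df_method=df_method)
    return _fit_mixed(work, "value ~ speed", "~speed", spec)


def fit_control_propulsion_model(table: pd.DataFrame, metric: str,
                                 df_method: str = "satterthwaite") -> LmmFit:
    """Control-cohort speed model on absolute propulsion, both legs pooled:
    fixed speed, random intercept + slope per participant."""
    work = _leg_frame(table, metric, "control")
    if work.empty:
        raise GaitPropError("no control rows")
    spec = LmmSpec(response=f"{metric}[control]", fixed_terms=["speed"],
                   random_terms=["intercept", "speed"], df_method=df_method)
    return _fit_mixed(work, "value ~ speed", "~speed", spec)


def posthoc_required(leg_fit: LmmFit, alpha: float = ALPHA) -> bool:
    """Decision rule: per-leg post-hoc models are fitted when the
    speed x leg interaction is significant."""
    return leg_fit.pvalue("speed:leg_p") < alpha


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def compute_diagnostics(fit: LmmFit) -> DiagnosticsBundle:
    """Residual summaries behind the Q-Q plot, residual histogram and
    residual-vs-fitted plot, plus a Shapiro-Wilk normality statistic."""
    if fit.residuals is None or fit.fitted is None:
        raise GaitPropError("fit carries no residual information")
    r = np.asarray(fit.residuals, dtype=float)
    std = r.std(ddof=1)
    z = np.sort(r / std) if std > 0 else np.sort(r)
    n = z.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    w, p = stats.shapiro(r)
    return DiagnosticsBundle(residuals=r, fitted=np.asarray(fit.fitted, dtype=float),
                             qq_theoretical=theo, qq_sample=z,
                             shapiro_w=float(w), shapiro_p=float(p))


def render_diagnostics(bundle: DiagnosticsBundle, path) -> None:
    """Write the three standard diagnostic panels as one PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    axes[0].plot(bundle.qq_theoretical, bundle.qq_sample, "o", ms=3)
    lim = [bundle.qq_theoretical.min(), bundle.qq_theoretical.max()]
    axes[0].plot(lim, lim, "k--", lw=1)
    axes[0].set_title("Normal Q-Q")
    axes[0].set_xlabel("theoretical quantiles")
    axes[0].set_ylabel("standardized residuals")
    axes[1].hist(bundle.residuals, bins=20)
    axes[1].set_title("Residuals")
    axes[2].plot(bundle.fitted, bundle.residuals, "o", ms=3)
    axes[2].axhline(0.0, color="k", lw=1)
    axes[2].set_title("Residuals vs fitted")
    axes[2].set_xlabel("fitted")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
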