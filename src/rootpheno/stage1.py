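"""Stage-1 mixed models: plot aggregation, REML, BLUPs and de-regression.

Plot-level traits are the mean and the standard deviation (uniformity) of
the per-root measurements in each plot.  Four model variants are fitted by
REML::

    y = X m + Z_clone c + Z_range r + e          (models 1, 2)
    y = X m + Z_clone c + Z_loc:range r + e      (models 3, 4)

with c ~ N(0, I sigma2_c), r ~ N(0, I sigma2_r).  Models 1 and 3 include
the plot CMD severity score as a fixed covariate alongside NOHAV (number of
harvested plants); models 2 and 4 fit NOHAV only.

From the fit we extract clone BLUPs (estimated genetic values, EGV), their
prediction-error variances, reliabilities r2 = 1 - PEV/sigma2_c, and
de-regressed EGVs (EGV / r2) for use as genomic-prediction responses, plus
broad-sense heritability H2 = sigma2_c / (sigma2_c + sigma2_e) and the
genotypic / phenotypic coefficients of variation.

The REML engine profiles out the residual variance and optimises the two
variance ratios by Nelder-Mead on the log scale; boundary estimates
(sigma2 -> 0) are reached smoothly as the log-ratio goes very negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

__all__ = [
    "TRAITS",
    "VarianceComponents",
    "aggregate_plots",
    "reml_fit",
    "fit_stage1",
    "deregress",
    "variability_stats",
    "gcv",
    "pcv",
]

TRAITS = ["area", "perimeter", "feret", "circularity", "roundness", "solidity",
          "aspect_ratio"]

_RATIO_FLOOR = 1e-8  # variance ratios below this are treated as boundary zeros


@dataclass
class VarianceComponents:
    trait: str
    sigma2_clone: float
    sigma2_range: float
    sigma2_resid: float
    fixed_effects: dict[str, float]
    grand_mean: float
    loglik: float
    n_obs: int
    model: int
    converged: bool = True

    @property
    def h2(self) -> float:
        denom = self.sigma2_clone + self.sigma2_resid
        return self.sigma2_clone / denom if denom > 0 else 0.0


def aggregate_plots(
    root_table: pd.DataFrame,
    design_table: pd.DataFrame,
    traits: list[str] | None = None,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-plot trait means and standard deviations, joined to the design.

    For each trait ``t`` the output carries ``t_mean`` and ``t_sd`` (sample
    SD over the plot's imaged roots; missing when fewer than two roots).
    With ``log_transform`` the natural log is applied to the plot-level
    values; non-positive values are dropped with a logged count.  Raw-scale
    grand means per trait are stored in ``result.attrs['grand_means']`` for
    the coefficient-of-variation statistics.
    """
    traits = traits or [t for t in TRAITS if t in root_table.columns]
    missing_plots = set(root_table["plot_id"]) - set(design_table["plot_id"])
    if missing_plots:
        raise ValueError(
            f"{len(missing_plots)} plots in the root table are absent from the design"
        )
    grouped = root_table.groupby("plot_id")
    agg = grouped[traits].agg(["mean", "std", "count"])
    out = pd.DataFrame(index=agg.index)
    grand_means = {}
    for t in traits:
        out[f"{t}_mean"] = agg[(t, "mean")]
        sd = agg[(t, "std")].copy()
        sd[agg[(t, "count")] < 2] = np.nan
        out[f"{t}_sd"] = sd
        grand_means[t] = float(root_table[t].mean())
    out["n_roots"] = agg[(traits[0], "count")].astype(int)
    out = out.reset_index().merge(design_table, on="plot_id", how="left")

    if log_transform:
        value_cols = [c for t in traits for c in (f"{t}_mean", f"{t}_sd")]
        n_bad = 0
        for c in value_cols:
            bad = out[c] <= 0
            n_bad += int(bad.sum())
            out.loc[bad, c] = np.nan
            out[c] = np.log(out[c])
        if n_bad:
            logger.warning("log transform: %d non-positive plot values dropped", n_bad)
    out.attrs["grand_means"] = grand_means
    out.attrs["log_transformed"] = log_transform
    return out


def _incidence(labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    levels, codes = np.unique(labels.to_numpy(), return_inverse=True)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), codes] = 1.0
    return Z, levels


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[np.ndarray, float, np.ndarray, float, bool]:
    """REML for y = X b + sum_i Z_i u_i + e with u_i ~ N(0, I sigma2_i).

    Profiles the residual variance and optimises the log variance ratios
    gamma_i = sigma2_i / sigma2_e.  Returns (sigma2 per random term,
    sigma2_e, GLS fixed effects, restricted log-likelihood, converged).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    k = len(Z_list)
    Z = np.hstack(Z_list)
    q_sizes = [Zi.shape[1] for Zi in Z_list]
    block = np.repeat(np.arange(k), q_sizes)
    # Woodbury: work in the q-dimensional random-effect space.
    # H = I + Z Gamma Z'  =>  H^-1 = I - Z (Gamma^-1 + Z'Z)^-1 Z'
    #                         log|H| = sum_i q_i log gamma_i + log|Gamma^-1 + Z'Z|
    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def _solve(lg: np.ndarray):
        gamma = np.exp(lg)
        M = ZtZ + np.diag(1.0 / gamma[block])
        cf = cho_factor(M, lower=True)
        logdetH = float(np.dot(q_sizes, lg)) + 2.0 * np.log(np.diag(cf[0])).sum()
        MiZtX = cho_solve(cf, ZtX)
        MiZty = cho_solve(cf, Zty)
        XtHiX = XtX - ZtX.T @ MiZtX
        XtHiy = Xty - ZtX.T @ MiZty
        ytHiy = yty - float(Zty @ MiZty)
        return logdetH, XtHiX, XtHiy, ytHiy

    def negll(log_gamma: np.ndarray) -> float:
        lg = np.clip(log_gamma, -30.0, 15.0)
        try:
            logdetH, XtHiX, XtHiy, ytHiy = _solve(lg)
        except np.linalg.LinAlgError:
            return 1e10
        sign, logdetXtHiX = np.linalg.slogdet(XtHiX)
        if sign <= 0:
            return 1e10
        beta = np.linalg.solve(XtHiX, XtHiy)
        yPy = ytHiy - float(XtHiy @ beta)
        if yPy <= 0:
            return 1e10
        s2e = yPy / (n - p)
        return 0.5 * (logdetH + logdetXtHiX + (n - p) * (np.log(s2e) + 1.0))

    starts = [np.zeros(k), np.full(k, -3.0)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            negll, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": tol, "maxiter": max_iter * (k + 1)},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML optimisation failed to produce a finite likelihood")
    lg = np.clip(best.x, -30.0, 15.0)
    _, XtHiX, XtHiy, ytHiy = _solve(lg)
    beta = np.linalg.solve(XtHiX, XtHiy)
    s2e = (ytHiy - float(XtHiy @ beta)) / (n - p)
    gamma = np.exp(lg)
    gamma[gamma < _RATIO_FLOOR] = 0.0
    sigma2 = gamma * s2e
    return sigma2, s2e, beta, -best.fun, bool(best.success)


def _blups_and_pev(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    sigma2: np.ndarray,
    s2e: float,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Solve the mixed-model equations; (BLUP, PEV) per random term.

    Terms with a boundary variance (sigma2 = 0) get zero BLUPs and
    PEV = sigma2 (zero), i.e. no information.
    """
    active = [i for i, s in enumerate(sigma2) if s > 0]
    out: list[tuple[np.ndarray, np.ndarray]] = [
        (np.zeros(Z.shape[1]), np.zeros(Z.shape[1])) for Z in Z_list
    ]
    if not active:
        return out
    Z = np.hstack([Z_list[i] for i in active])
    lam = np.concatenate(
        [np.full(Z_list[i].shape[1], s2e / sigma2[i]) for i in active]
    )
    p = X.shape[1]
    M = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + np.diag(lam)]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    Minv = np.linalg.inv(M)
    sol = Minv @ rhs
    u = sol[p:]
    pev_all = s2e * np.diag(Minv)[p:]
    ofs = 0
    for i in active:
        q = Z_list[i].shape[1]
        out[i] = (u[ofs:ofs + q], pev_all[ofs:ofs + q])
        ofs += q
    return out


def fit_stage1(
    table: pd.DataFrame,
    trait: str,
    model: int = 1,
    value_col: str | None = None,
) -> tuple[VarianceComponents, pd.DataFrame]:
    """Fit one stage-1 model for one trait column.

    ``value_col`` defaults to ``trait`` itself if present, else
    ``{trait}_mean``.  Returns the variance components and a clone table
    with columns ``clone_id, egv, pev, reliability``.
    """
    if model not in (1, 2, 3, 4):
        raise ValueError(f"model must be 1-4, got {model}")
    col = value_col or (trait if trait in table.columns else f"{trait}_mean")
    if col not in table.columns:
        raise KeyError(f"trait column {col!r} not found")
    df = table.dropna(subset=[col]).reset_index(drop=True)
    y = df[col].to_numpy(float)
    if np.std(y) == 0:
        raise ValueError(f"trait column {col!r} is degenerate (constant)")
    if df["clone_id"].nunique() < 2:
        raise ValueError("need at least two clones")

    covariates = ["NOHAV", "CMD"] if model in (1, 3) else ["NOHAV"]
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for c in covariates:
        if c not in df.columns or df[c].nunique() < 2:
            warnings.warn(f"fixed covariate {c} constant or absent: dropped")
            continue
        cols.append(df[c].to_numpy(float))
        names.append(c)
    X = np.column_stack(cols)

    if model in (3, 4) and "location" in df.columns:
        group = df["location"].astype(str) + ":" + df["range"].astype(str)
    else:
        group = df["range"].astype(str)
    Zc, clones = _incidence(df["clone_id"])
    Zr, _ = _incidence(group)

    sigma2, s2e, beta, ll, conv = reml_fit(y, X, [Zc, Zr])
    if not conv:
        logger.warning("REML for %s (model %d) hit the iteration cap", trait, model)
    (c_blup, c_pev), _ = _blups_and_pev(y, X, [Zc, Zr], sigma2, s2e)

    s2c = float(sigma2[0])
    rel = 1.0 - c_pev / s2c if s2c > 0 else np.zeros_like(c_pev)
    rel = np.clip(rel, 0.0, 1.0 - 1e-12)
    est = pd.DataFrame(
        {"clone_id": clones, "egv": c_blup, "pev": c_pev, "reliability": rel}
    )
    vc = VarianceComponents(
        trait=trait,
        sigma2_clone=s2c,
        sigma2_range=float(sigma2[1]),
        sigma2_resid=s2e,
        fixed_effects=dict(zip(names, beta)),
        grand_mean=float(np.mean(y)),
        loglik=ll,
        n_obs=len(df),
        model=model,
    )
    return vc, est


def deregress(
    estimates: pd.DataFrame, min_reliability: float = 0.1
) -> pd.DataFrame:
    """De-regressed EGVs: EGV / reliability; low-reliability clones set missing."""
    out = estimates.copy()
    r2 = out["reliability"].to_numpy(float)
    bad = r2 <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} clones with non-positive reliability excluded")
    with np.errstate(divide="ignore", invalid="ignore"):
        dr = np.where(r2 > 0, out["egv"].to_numpy(float) / r2, np.nan)
    dr[r2 < min_reliability] = np.nan
    out["deregressed_egv"] = dr
    return out


def gcv(var_g: float, mu: float) -> float:
    """Genotypic coefficient of variation, percent: 100*sqrt(var_g)/mu."""
    if mu <= 0:
        raise ValueError("grand mean must be positive")
    return 100.0 * np.sqrt(var_g) / mu


def pcv(var_p: float, mu: float) -> float:
    """Phenotypic coefficient of variation, percent: 100*sqrt(var_p)/mu."""
    if mu <= 0:
        raise ValueError("grand mean must be positive")
    return 100.0 * np.sqrt(var_p) / mu


def variability_stats(
    vc: VarianceComponents,
    mu: float | None = None,
    include_range_in_pcv: bool = False,
) -> tuple[float, float, float]:
    """(H2, GCV%, PCV%) from fitted components.

    ``mu`` is the grand mean on the original measurement scale (pass it
    explicitly when the model was fitted on log values).  Phenotypic
    variance defaults to sigma2_clone + sigma2_resid, optionally adding the
    range variance.
    """
    mu = vc.grand_mean if mu is None else mu
    var_p = vc.sigma2_clone + vc.sigma2_resid
    if include_range_in_pcv:
        var_p += vc.sigma2_range
    return vc.h2, gcv(vc.sigma2_clone, mu), pcv(var_p, mu)
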