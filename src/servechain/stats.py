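"""Statistical analysis: paired t-tests on per-player means and Gaussian GEE.

Two analyses mirror standard practice for repeated serves nested in players:

* **First vs second serve.** Each player's 24 first and 24 second serves are
  averaged; the per-player mean pairs are compared with a two-tailed paired
  samples t-test (df = n_players - 1).

* **Kinematics vs performance.** Each outcome (ball speed, accuracy points)
  is regressed on one kinematic predictor at a time with generalized
  estimating equations: identity link, Gaussian variance, and an
  *exchangeable* working correlation (any two serves of the same player
  share correlation alpha). Coefficients solve the GEE fixed point

      sum_i X_i' R(alpha)^{-1} (y_i - X_i beta) = 0,

  alternating with moment estimation of the scale phi (Pearson residuals,
  N - p denominator) and of alpha (within-cluster residual cross-products
  over sum_i n_i(n_i - 1)/2 - p). Uncertainty uses the robust sandwich
  covariance B^{-1} M B^{-1}, valid even when the working correlation is
  misspecified; inference on the slope is a 1-df Wald chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TTestResult",
    "GeeFit",
    "GeeConvergenceError",
    "per_player_means",
    "paired_t",
    "fit_gee",
    "wald_ci",
    "descriptives",
    "regression_table",
    "KINEMATIC_QUANTITIES",
    "OUTCOME_QUANTITIES",
]

logger = logging.getLogger(__name__)

Z975 = float(sps.norm.ppf(0.975))

KINEMATIC_QUANTITIES = ("peak_pelvis", "peak_trunk", "peak_upper_arm",
                        "dt_pelvis_trunk", "dt_trunk_upper_arm")
OUTCOME_QUANTITIES = ("ball_speed_kph", "accuracy_points")


@dataclass(frozen=True)
class PairedSample:
    """Per-player means of one quantity over first and over second serves."""

    quantity: str
    player_ids: np.ndarray
    first: np.ndarray
    second: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.first) == len(self.second) == len(self.player_ids)):
            raise ValueError("paired sample arrays must have equal length")
        if len(self.first) < 2:
            raise ValueError("paired t-test needs at least 2 complete pairs")

    @property
    def n(self) -> int:
        return len(self.first)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    sd_diff: float


@dataclass(frozen=True)
class GeeFit:
    """Exchangeable-GEE fit of ``outcome = b0 + b1 * predictor``."""

    b0: float
    b1: float
    se_b1: float
    ci_low: float
    ci_high: float
    wald_chi2: float
    p: float
    alpha: float  # working exchangeable correlation estimate
    scale: float  # dispersion phi (outcome-units squared)
    n_obs: int
    n_clusters: int
    iterations: int
    converged: bool
    cov: np.ndarray | None = None  # robust 2x2 covariance of (b0, b1)


class GeeConvergenceError(RuntimeError):
    def __init__(self, message: str, last_fit: GeeFit):
        super().__init__(message)
        self.last_fit = last_fit


def per_player_means(df: pd.DataFrame, quantity: str) -> PairedSample:
    """Average one quantity per player per serve type and pair the results.

    ``df`` needs ``player_id``, ``serve_type`` and the quantity column; rows
    with a missing value (e.g. unregistered ball speed) are ignored. Players
    lacking either serve type entirely are excluded with a warning.
    """
    if quantity not in df.columns:
        raise ValueError(f"column {quantity!r} not found")
    sub = df.dropna(subset=[quantity])
    means = sub.groupby(["player_id", "serve_type"])[quantity].mean().unstack("serve_type")
    for st in ("first", "second"):
        if st not in means.columns:
            means[st] = np.nan
    incomplete = means.index[means[["first", "second"]].isna().any(axis=1)]
    if len(incomplete):
        logger.warning("excluding player(s) %s from %s: missing a serve type",
                       list(incomplete), quantity)
        means = means.drop(index=incomplete)
    return PairedSample(quantity, means.index.to_numpy(),
                        means["first"].to_numpy(float), means["second"].to_numpy(float))


def paired_t(sample: PairedSample) -> TTestResult:
    """Two-tailed paired samples t-test on per-player means.

    t = mean(d) / (SD(d)/sqrt(n)) with d = first - second, df = n - 1.
    """
    d = sample.first - sample.second
    n = sample.n
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValueError("all paired differences are equal; the t-test is degenerate")
    mean = float(np.mean(d))
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return TTestResult(t=float(t), df=n - 1, p=p, mean_diff=mean, sd_diff=sd)


# ---------------------------------------------------------------------------
# Exchangeable Gaussian GEE


def _exch_solve(z: np.ndarray, alpha: float) -> np.ndarray:
    """R(alpha)^{-1} z for the exchangeable correlation matrix (closed form)."""
    k = z.shape[0]
    c = alpha / ((1.0 - alpha) * (1.0 + alpha * (k - 1)))
    if z.ndim == 1:
        return z / (1.0 - alpha) - c * z.sum()
    return z / (1.0 - alpha) - c * z.sum(axis=0)


def fit_gee(y: np.ndarray, x: np.ndarray, cluster: np.ndarray,
            tol: float = 1e-8, maxiter: int = 500,
            bias_corrected: bool = False) -> GeeFit:
    """Fit ``y = b0 + b1 x`` by GEE with exchangeable working correlation.

    ``cluster`` labels group repeated observations (serves within a player).
    With singleton clusters the working correlation is irrelevant and the
    coefficients equal ordinary least squares.

    ``bias_corrected`` applies the Mancl-DeRouen small-sample correction to
    the sandwich covariance (each cluster's residuals are inflated by
    (I - H_i)^{-1}, countering the downward bias of the plain sandwich when
    there are few clusters); the default is the plain sandwich.
    """
    y = np.asarray(y, float).ravel()
    x = np.asarray(x, float).ravel()
    cluster = np.asarray(cluster).ravel()
    if not (len(y) == len(x) == len(cluster)):
        raise ValueError("y, x and cluster must have equal length")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    _, inverse = np.unique(cluster, return_inverse=True)
    groups = [np.flatnonzero(inverse == g) for g in range(inverse.max() + 1)]
    if len(groups) < 2:
        raise ValueError("GEE needs at least 2 clusters")

    X = np.column_stack([np.ones_like(x), x])
    n_obs, p = X.shape
    sizes = np.array([len(g) for g in groups])
    n_pairs = float(np.sum(sizes * (sizes - 1)) / 2.0)
    alpha_floor = -1.0 / (sizes.max() - 1) + 1e-8 if sizes.max() > 1 else 0.0

    beta = np.linalg.lstsq(X, y, rcond=None)[0]  # OLS start
    alpha, phi = 0.0, 1.0
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        # moment estimates of phi and alpha at the current coefficients
        r = y - X @ beta
        phi = float(r @ r) / (n_obs - p)
        if n_pairs > p:
            cross = sum(float(r[g].sum() ** 2 - r[g] @ r[g]) / 2.0 for g in groups)
            alpha = float(np.clip(cross / phi / (n_pairs - p),
                                  alpha_floor, 1.0 - 1e-8))
        else:
            alpha = 0.0
        # coefficient update under the working correlation R(alpha)
        B = np.zeros((p, p))
        u = np.zeros(p)
        for g in groups:
            Xi, yi = X[g], y[g]
            Ri_X = _exch_solve(Xi, alpha)
            B += Xi.T @ Ri_X
            u += Ri_X.T @ yi
        try:
            beta_new = np.linalg.solve(B, u)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular working system at iteration {it} (alpha={alpha:.4f})") from exc
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    # Refresh the moment estimates at the final coefficients, then form the
    # robust sandwich covariance there.
    r = y - X @ beta
    phi = float(r @ r) / (n_obs - p)
    if n_pairs > p:
        cross = sum(float(r[g].sum() ** 2 - r[g] @ r[g]) / 2.0 for g in groups)
        alpha = float(np.clip(cross / phi / (n_pairs - p), alpha_floor, 1.0 - 1e-8))
    B = np.zeros((p, p))
    for g in groups:
        Xi = X[g]
        B += Xi.T @ _exch_solve(Xi, alpha)
    Binv = np.linalg.inv(B)
    M = np.zeros((p, p))
    for g in groups:
        Xi = X[g]
        Ri_X = _exch_solve(Xi, alpha)
        ri = r[g]
        if bias_corrected:
            # Mancl-DeRouen: inflate residuals by (I - H_i)^{-1},
            # H_i = X_i B^{-1} X_i' R_i^{-1}
            Hi = Xi @ Binv @ Ri_X.T
            ri = np.linalg.solve(np.eye(len(g)) - Hi, ri)
        gi = Ri_X.T @ ri
        M += np.outer(gi, gi)
    cov = Binv @ M @ Binv
    se = float(np.sqrt(cov[1, 1]))
    wald = (beta[1] / se) ** 2 if se > 0 else np.inf
    fit = GeeFit(
        b0=float(beta[0]), b1=float(beta[1]), se_b1=se,
        ci_low=float(beta[1] - Z975 * se), ci_high=float(beta[1] + Z975 * se),
        wald_chi2=float(wald), p=float(sps.chi2.sf(wald, 1)),
        alpha=float(alpha), scale=phi, n_obs=n_obs, n_clusters=len(groups),
        iterations=it, converged=converged, cov=cov)
    if not converged:
        raise GeeConvergenceError(
            f"GEE did not converge in {maxiter} iterations (last max|dbeta| >= {tol})", fit)
    return fit


def wald_ci(fit: GeeFit, level: float = 0.95) -> tuple[tuple[float, float], float]:
    """Wald confidence interval for the slope and its chi-square(1) p-value."""
    if not fit.converged:
        raise ValueError("refusing inference on a non-converged fit")
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    ci = (fit.b1 - z * fit.se_b1, fit.b1 + z * fit.se_b1)
    p = float(sps.chi2.sf((fit.b1 / fit.se_b1) ** 2, 1)) if fit.se_b1 > 0 else 0.0
    return ci, p


# ---------------------------------------------------------------------------
# Descriptive tables and the regression report


def descriptives(df: pd.DataFrame,
                 quantities: tuple[str, ...] = OUTCOME_QUANTITIES + KINEMATIC_QUANTITIES
                 ) -> pd.DataFrame:
    """Group-level summary: mean and between-player SD per quantity per serve type.

    The SD is the SD of per-player means (between-player spread). Also
    reports ``pct_in`` — each player's percentage of serves that bounced in
    the correct box (accuracy > 0) — when accuracy is available. With a
    single player the SD is undefined and reported as 0 with ``sd_defined``
    False.
    """
    if df.empty:
        raise ValueError("empty dataset")
    work = df.copy()
    if "accuracy_points" in work.columns:
        work["pct_in"] = (work["accuracy_points"] > 0) * 100.0
        quantities = tuple(quantities) + ("pct_in",)
    rows = []
    for st, sub in work.groupby("serve_type"):
        for q in quantities:
            if q not in sub.columns:
                continue
            pm = sub.dropna(subset=[q]).groupby("player_id")[q].mean()
            sd_defined = len(pm) > 1
            rows.append({"serve_type": st, "quantity": q,
                         "mean": float(pm.mean()),
                         "sd_between": float(pm.std(ddof=1)) if sd_defined else 0.0,
                         "n_players": int(len(pm)), "sd_defined": sd_defined})
    return pd.DataFrame(rows)


def regression_table(df: pd.DataFrame,
                     outcomes: tuple[str, ...] = OUTCOME_QUANTITIES,
                     predictors: tuple[str, ...] = KINEMATIC_QUANTITIES,
                     bias_corrected: bool = False) -> pd.DataFrame:
    """One exchangeable-GEE fit per (outcome, predictor, serve type).

    Separate fits per serve type and one predictor at a time, reported as
    b0, b1, the 95% Wald CI and p — the layout of a published coefficient
    table. Rows with missing outcome values are dropped per fit.
    """
    rows = []
    for outcome in outcomes:
        for predictor in predictors:
            for st, sub in df.groupby("serve_type"):
                data = sub.dropna(subset=[outcome, predictor])
                fit = fit_gee(data[outcome].to_numpy(float),
                              data[predictor].to_numpy(float),
                              data["player_id"].to_numpy(),
                              bias_corrected=bias_corrected)
                rows.append({"outcome": outcome, "predictor": predictor,
                             "serve_type": st, "n": fit.n_obs,
                             "b0": fit.b0, "b1": fit.b1,
                             "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                             "p": fit.p, "alpha": fit.alpha})
    return pd.DataFrame(rows)
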