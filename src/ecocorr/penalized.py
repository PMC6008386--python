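"""Penalized-regression ensemble and the top-5 selection-frequency statistic.

Ridge, LASSO and elastic-net regressions of one outcome on all standardized
predictors at once, with the penalty level chosen by cross-validation or by
bootstrap out-of-bag error, under an "optimal" (minimum prediction error)
or "parsimonious" (one-standard-error) rule.  The cross product

    {ridge, lasso, enet} x {cross_validation, bootstrap} x {optimal, parsimonious}

yields the 12-model battery; per model, the 5 predictors with the largest
absolute standardized coefficients are recorded, and per-variable
appearance counts (out of the 6 optimal models and out of all 12) summarize
which variables the ensemble keeps selecting.

All objectives use the 1/(2n) scaling

    ||y - X b||^2 / (2n) + lambda * (alpha * ||b||_1 + (1-alpha) * ||b||^2 / 2)

so ridge is alpha=0, LASSO is alpha=1, and every lambda in this module is
defined on that scale.  The elastic-net solver is cyclic coordinate descent
with soft-thresholding on precomputed Gram/covariance products; ridge paths
use the closed-form solve via one eigendecomposition of the Gram matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .panel import PanelError

log = logging.getLogger(__name__)

METHODS = ("ridge", "lasso", "enet")
TREATMENTS = ("cross_validation", "bootstrap")
RULES = ("optimal", "parsimonious")

#: relative |beta| threshold under which a ridge coefficient is not counted
#: as a "selected" predictor (ridge never produces exact zeros)
RIDGE_SELECT_RTOL = 1e-3


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Scaler:
    """Column means/SDs recorded by :func:`standardize` (population SDs)."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float

    def transform(self, X: np.ndarray, y: np.ndarray | None = None):
        Xs = (X - self.x_mean) / self.x_sd
        if y is None:
            return Xs
        return Xs, (np.asarray(y, float) - self.y_mean) / self.y_sd

    def back_transform(self, Xs: np.ndarray) -> np.ndarray:
        return Xs * self.x_sd + self.x_mean


@dataclass(frozen=True)
class PenalizedFit:
    method: str
    lam: float
    alpha: float           # mixing: 0 = ridge, 1 = lasso
    beta: np.ndarray       # standardized coefficients
    intercept: float
    objective: float

    def n_selected(self) -> int:
        """Count of selected predictors.

        Exact nonzeros for lasso/enet; for ridge (never exactly zero),
        coefficients above ``RIDGE_SELECT_RTOL`` of the largest magnitude.
        """
        b = np.abs(self.beta)
        if self.method == "ridge":
            top = b.max(initial=0.0)
            return int(np.sum(b > RIDGE_SELECT_RTOL * top)) if top > 0 else 0
        return int(np.sum(b != 0))


@dataclass
class ModelSelection:
    treatment: str                      # cross_validation | bootstrap
    lambdas: np.ndarray                 # descending grid
    mean_error: np.ndarray              # mean squared prediction error per lambda
    se_error: np.ndarray                # its standard error per lambda
    lambda_optimal: float
    lambda_parsimonious: float
    mean_beta: np.ndarray | None = None  # bootstrap: mean beta per lambda (L x p)

    def chosen_lambda(self, rule: str) -> float:
        if rule == "optimal":
            return self.lambda_optimal
        if rule == "parsimonious":
            return self.lambda_parsimonious
        raise PanelError(f"unknown rule {rule!r}")


@dataclass(frozen=True)
class ModelRecord:
    """One of the 12 battery members."""

    method: str
    treatment: str
    rule: str
    selection: ModelSelection
    fit: PenalizedFit

    @property
    def label(self) -> str:
        return f"{self.method}/{self.treatment}/{self.rule}"


@dataclass
class BatteryConfig:
    n_lambda: int = 100
    lambda_min_ratio: float | None = None  # see lambda_grid
    alpha: float = 0.5       # elastic-net mixing
    k_folds: int = 10
    n_boot: int = 500
    tol: float = 1e-8
    max_iter: int = 100_000
    select_then_average: bool = False


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(X, y, names: Sequence[str] | None = None):
    """Standardize predictor columns and the outcome to mean 0, SD 1.

    Population (1/n) SDs, so diag(X'X/n) = 1 for the solver.  Errors on a
    constant column, naming it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise PanelError("X must be 2-D with one row per element of y")
    if np.isnan(X).any() or np.isnan(y).any():
        raise PanelError("missing values not allowed; drop incomplete rows first")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        bad = ([names[i] for i in const] if names is not None
               else const.tolist())
        raise PanelError(f"constant predictor column(s): {bad}")
    y_sd = y.std()
    if y_sd == 0:
        raise PanelError("outcome is constant")
    scaler = Scaler(mu, sd, float(y.mean()), float(y_sd))
    Xs, ys = scaler.transform(X, y)
    return Xs, ys, scaler


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def _objective(X, y, beta, lam, alpha):
    n = len(y)
    resid = y - X @ beta
    pen = alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * (beta @ beta)
    return float(resid @ resid / (2 * n) + lam * pen)


@njit(cache=True)
def _cd_sweeps(G, c, l1, l2, beta, tol, max_iter):
    """Cyclic coordinate descent on the Gram form; returns sweeps used (-1
    if not converged).  G = X'X/n, c = X'y/n, l1 = lam*alpha,
    l2 = lam*(1-alpha).  beta is updated in place."""
    p = G.shape[0]
    for sweep in range(max_iter):
        dmax = 0.0
        for j in range(p):
            bj = beta[j]
            gj = 0.0
            for k in range(p):
                gj += G[j, k] * beta[k]
            rho = c[j] - gj + G[j, j] * bj
            az = abs(rho) - l1
            if az <= 0.0:
                bnew = 0.0
            else:
                bnew = az / (G[j, j] + l2)
                if rho < 0.0:
                    bnew = -bnew
            d = abs(bnew - bj)
            if d > dmax:
                dmax = d
            beta[j] = bnew
        if dmax < tol:
            return sweep + 1
    return -1


def enet_fit(X, y, lam: float, alpha: float, beta0=None,
             tol: float = 1e-8, max_iter: int = 100_000) -> PenalizedFit:
    """Elastic-net fit by cyclic coordinate descent with soft-thresholding.

    Expects standardized inputs (see :func:`standardize`); convergence when
    the largest coefficient change in a full sweep drops below ``tol``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if lam < 0 or not (0.0 <= alpha <= 1.0):
        raise PanelError(f"need lam >= 0 and alpha in [0,1], got {lam}, {alpha}")
    n, p = X.shape
    G = X.T @ X / n
    c = X.T @ y / n
    beta = (np.zeros(p) if beta0 is None else np.array(beta0, float))
    sweeps = _cd_sweeps(G, c, lam * alpha, lam * (1 - alpha), beta,
                        tol, max_iter)
    if sweeps < 0:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps "
            f"(lam={lam:.4g}, alpha={alpha}, p={p}, n={n}, "
            f"max|beta|={np.abs(beta).max():.4g})")
    method = "lasso" if alpha == 1.0 else ("ridge" if alpha == 0.0 else "enet")
    return PenalizedFit(method, float(lam), float(alpha), beta, 0.0,
                        _objective(X, y, beta, lam, alpha))


def lasso_fit(X, y, lam: float, **kw) -> PenalizedFit:
    """LASSO = elastic net at alpha = 1."""
    return enet_fit(X, y, lam, alpha=1.0, **kw)


def ridge_fit(X, y, lam: float) -> PenalizedFit:
    """Ridge fit by the closed-form linear solve (X'X/n + lam I) b = X'y/n."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if lam < 0:
        raise PanelError(f"need lam >= 0, got {lam}")
    n, p = X.shape
    G = X.T @ X / n
    beta = np.linalg.solve(G + lam * np.eye(p), X.T @ y / n)
    return PenalizedFit("ridge", float(lam), 0.0, beta, 0.0,
                        _objective(X, y, beta, lam, 0.0))


def lambda_grid(X, y, alpha: float, n_lambda: int = 100,
                min_ratio: float | None = None) -> np.ndarray:
    """Descending log-spaced grid from lambda_max to min_ratio*lambda_max.

    lambda_max = max|X'y|/n / alpha is the smallest penalty zeroing every
    coefficient (KKT); for ridge (alpha=0) the top of the grid uses the
    alpha=0.001 convention so it stays finite, while the floor stays on
    the alpha=1 scale (min_ratio * max|X'y|/n) — otherwise the whole ridge
    grid sits in heavily-shrunk territory and penalty selection pins to
    the grid boundary.  The default floor ratio is 1e-4, raised to 1e-2
    when predictors outnumber rows (where near-zero penalties leave the
    l1 problem without a unique solution and coordinate descent crawls).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if min_ratio is None:
        min_ratio = 1e-4 if X.shape[0] > X.shape[1] else 1e-2
    base = np.abs(X.T @ y).max() / len(y)
    if base <= 0:
        base = 1.0
    lam_max = base / max(alpha, 1e-3)
    lam_min = base * min_ratio
    return np.logspace(np.log10(lam_max), np.log10(lam_min), n_lambda)


def fit_path(X, y, method: str, lambdas: np.ndarray, alpha: float = 0.5,
             tol: float = 1e-8, max_iter: int = 100_000) -> np.ndarray:
    """Coefficient path over a descending lambda grid (warm-started).

    Returns an (n_lambda, p) array of standardized coefficients.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    lambdas = np.asarray(lambdas, float)
    if np.any(np.diff(lambdas) > 0):
        raise PanelError("lambda grid must be descending for warm starts")
    betas = np.empty((len(lambdas), p))
    if method == "ridge":
        G = X.T @ X / n
        c = X.T @ y / n
        evals, evecs = np.linalg.eigh(G)
        ct = evecs.T @ c
        for i, lam in enumerate(lambdas):
            betas[i] = evecs @ (ct / (evals + lam))
        return betas
    a = 1.0 if method == "lasso" else alpha
    if method not in ("lasso", "enet"):
        raise PanelError(f"unknown method {method!r}")
    G = X.T @ X / n
    c = X.T @ y / n
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        sweeps = _cd_sweeps(G, c, lam * a, lam * (1 - a), beta, tol, max_iter)
        if sweeps < 0:
            # near-degenerate designs (e.g. bootstrap resamples with p >= n)
            # leave a flat solution valley at small lam where coefficient
            # changes crawl; a relaxed tolerance is ample for ranking
            log.warning("path fit at lam=%.4g (alpha=%g): relaxing tol to "
                        "%.0e", lam, a, tol * 100)
            sweeps = _cd_sweeps(G, c, lam * a, lam * (1 - a), beta,
                                tol * 100, max_iter)
            if sweeps < 0:
                raise ConvergenceError(
                    f"path fit did not converge at lam={lam:.4g} (alpha={a})")
        betas[i] = beta
    return betas


# ---------------------------------------------------------------------------
# penalty selection: cross-validation and bootstrap
# ---------------------------------------------------------------------------

def _one_se_rules(lambdas, mean_error, se_error):
    i_opt = int(np.nanargmin(mean_error))
    thresh = mean_error[i_opt] + se_error[i_opt]
    ok = np.flatnonzero(mean_error <= thresh)
    # grid is descending, so the smallest index is the largest lambda
    i_par = int(ok.min()) if ok.size else i_opt
    return float(lambdas[i_opt]), float(lambdas[i_par])


def cross_validate(X, y, method: str, lambdas=None, k_folds: int = 10,
                   seed: int = 0, alpha: float = 0.5,
                   tol: float = 1e-8, max_iter: int = 100_000) -> ModelSelection:
    """K-fold cross-validated prediction error over the lambda grid.

    Each training fold is standardized on its own statistics; the held-out
    fold is transformed with the training scaler before prediction, so no
    information leaks.  Optimal = argmin mean error; parsimonious = the
    largest lambda within one standard error of the minimum.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if k_folds > n:
        raise PanelError(f"k_folds={k_folds} exceeds n={n}")
    if lambdas is None:
        Xs, ys, _ = standardize(X, y)
        lambdas = lambda_grid(Xs, ys, 1.0 if method == "lasso" else alpha)
    lambdas = np.asarray(lambdas, float)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, k_folds)
    if min(len(f) for f in folds) < 2:
        raise PanelError("every fold needs >= 2 observations")
    errs = np.empty((k_folds, len(lambdas)))
    for f, test in enumerate(folds):
        train = np.setdiff1d(idx, test)
        Xs, ys, scaler = standardize(X[train], y[train])
        betas = fit_path(Xs, ys, method, lambdas, alpha, tol, max_iter)
        Xt, yt = scaler.transform(X[test], y[test])
        pred = betas @ Xt.T                      # (L, n_test)
        errs[f] = np.mean((yt[None, :] - pred) ** 2, axis=1)
    mean_error = errs.mean(axis=0)
    se_error = errs.std(axis=0, ddof=1) / np.sqrt(k_folds)
    lam_opt, lam_par = _one_se_rules(lambdas, mean_error, se_error)
    return ModelSelection("cross_validation", lambdas, mean_error, se_error,
                          lam_opt, lam_par)


def bootstrap_treatment(X, y, method: str, lambdas=None, B: int = 500,
                        seed: int = 0, alpha: float = 0.5,
                        tol: float = 1e-8, max_iter: int = 100_000,
                        select_then_average: bool = False,
                        max_redraws: int = 100):
    """Bootstrap-averaged coefficient paths with out-of-bag penalty selection.

    For each of ``B`` row resamples (with replacement) the full coefficient
    path is fitted and the mean squared prediction error is measured on the
    out-of-bag rows; per lambda, coefficient vectors are averaged over
    resamples, and the selection rules are applied to the mean out-of-bag
    error curve.  Resamples that leave a predictor constant are redrawn
    (logged).

    Returns ``(ModelSelection, mean_beta)`` where ``mean_beta`` is the
    (n_lambda, p) bootstrap-mean coefficient path (also stored on the
    selection).  With ``select_then_average`` the returned per-rule betas
    average each resample's coefficients at that resample's own best
    out-of-bag lambda instead.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if B < 1:
        raise PanelError("B must be >= 1")
    if lambdas is None:
        Xs, ys, _ = standardize(X, y)
        lambdas = lambda_grid(Xs, ys, 1.0 if method == "lasso" else alpha)
    lambdas = np.asarray(lambdas, float)
    L = len(lambdas)
    rng = np.random.default_rng(seed)
    beta_sum = np.zeros((L, p))
    errs = np.full((B, L), np.nan)
    per_rep_best = np.empty((B, p))
    redraws = 0
    for b in range(B):
        for _ in range(max_redraws):
            rows = rng.integers(0, n, size=n)
            Xb = X[rows]
            if np.all(Xb.std(axis=0) > 0) and y[rows].std() > 0:
                break
            redraws += 1
        else:
            raise PanelError("could not draw a resample without a constant "
                             f"column in {max_redraws} tries")
        Xs, ys, scaler = standardize(Xb, y[rows])
        betas = fit_path(Xs, ys, method, lambdas, alpha, tol, max_iter)
        beta_sum += betas
        oob = np.setdiff1d(np.arange(n), rows)
        if oob.size:
            Xo, yo = scaler.transform(X[oob], y[oob])
            errs[b] = np.mean((yo[None, :] - betas @ Xo.T) ** 2, axis=1)
            per_rep_best[b] = betas[int(np.nanargmin(errs[b]))]
        else:
            per_rep_best[b] = betas[-1]
    if redraws:
        log.info("bootstrap: redrew %d resample(s) with a constant column", redraws)
    mean_beta = beta_sum / B
    n_eff = np.sum(~np.isnan(errs), axis=0)
    mean_error = np.nanmean(errs, axis=0)
    se_error = np.nanstd(errs, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    lam_opt, lam_par = _one_se_rules(lambdas, mean_error, se_error)
    sel = ModelSelection("bootstrap", lambdas, mean_error, se_error,
                         lam_opt, lam_par, mean_beta=mean_beta)
    if select_then_average:
        sel.mean_beta = None  # per-rule beta is rep-wise; path average unused
        sel.beta_select_then_average = per_rep_best.mean(axis=0)
    return sel, mean_beta


# ---------------------------------------------------------------------------
# the 12-model battery and selection frequencies
# ---------------------------------------------------------------------------

def twelve_model_battery(X, y, config: BatteryConfig | None = None,
                         seed: int = 0) -> list[ModelRecord]:
    """Fit the full {ridge, lasso, enet} x {CV, bootstrap} x {optimal,
    parsimonious} cross product: exactly 12 labeled models, 6 optimal.

    ``X``/``y`` are raw (unstandardized) arrays; every fit standardizes
    internally, so the returned betas are comparable standardized
    coefficients.  Deterministic under a fixed seed.
    """
    cfg = config or BatteryConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    Xs, ys, _ = standardize(X, y)
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(METHODS))
    records: list[ModelRecord] = []
    for mi, method in enumerate(METHODS):
        a = {"ridge": 0.0, "lasso": 1.0, "enet": cfg.alpha}[method]
        lambdas = lambda_grid(Xs, ys, max(a, 1e-3), cfg.n_lambda,
                              cfg.lambda_min_ratio)
        cv = cross_validate(X, y, method, lambdas, cfg.k_folds,
                            seed=int(seeds[2 * mi] % 2**31), alpha=cfg.alpha,
                            tol=cfg.tol, max_iter=cfg.max_iter)
        boot, mean_beta = bootstrap_treatment(
            X, y, method, lambdas, cfg.n_boot,
            seed=int(seeds[2 * mi + 1] % 2**31), alpha=cfg.alpha,
            tol=cfg.tol, max_iter=cfg.max_iter,
            select_then_average=cfg.select_then_average)
        full_path = fit_path(Xs, ys, method, lambdas, cfg.alpha,
                             cfg.tol, cfg.max_iter)
        for treatment, sel in (("cross_validation", cv), ("bootstrap", boot)):
            for rule in RULES:
                lam = sel.chosen_lambda(rule)
                i_lam = int(np.argmin(np.abs(lambdas - lam)))
                if treatment == "cross_validation":
                    beta = full_path[i_lam]
                elif cfg.select_then_average:
                    beta = sel.beta_select_then_average
                else:
                    beta = mean_beta[i_lam]
                fit = PenalizedFit(method, lam, a, np.array(beta), 0.0,
                                   _objective(Xs, ys, beta, lam, a))
                records.append(ModelRecord(method, treatment, rule, sel, fit))
    assert len(records) == 12
    return records


def top5_frequency(records: list[ModelRecord],
                   var_names: Sequence[str], top_k: int = 5) -> pd.DataFrame:
    """Per-variable counts of top-5 |beta| appearances across the battery.

    Per model, coefficients are ranked by absolute value (ties broken
    lexicographically by variable name, logged) and the top 5 with nonzero
    beta are taken.  ``count_optimal`` counts appearances in the 6 optimal
    models, ``count_total`` in all 12; ``sign`` is positive/negative when
    the counted betas agree, else mixed.
    """
    var_names = list(var_names)
    counts_opt = {v: 0 for v in var_names}
    counts_tot = {v: 0 for v in var_names}
    signs: dict[str, set] = {v: set() for v in var_names}
    for rec in records:
        b = rec.fit.beta
        if len(b) != len(var_names):
            raise PanelError("beta length does not match var_names")
        absb = np.abs(b)
        nz = np.flatnonzero(absb > 0)
        if nz.size == 0:
            continue
        # sort by descending |beta|, ties by ascending name
        order = sorted(nz, key=lambda j: (-absb[j], var_names[j]))
        ties = len({round(absb[j], 15) for j in nz}) < nz.size
        if ties:
            log.warning("tied |beta| in model %s broken by variable name",
                        rec.label)
        for j in order[:top_k]:
            v = var_names[j]
            counts_tot[v] += 1
            if rec.rule == "optimal":
                counts_opt[v] += 1
            signs[v].add(1 if b[j] > 0 else -1)
    def sign_label(v):
        s = signs[v]
        if not s:
            return ""
        if s == {1}:
            return "positive"
        if s == {-1}:
            return "negative"
        return "mixed"
    out = pd.DataFrame({
        "variable": var_names,
        "count_optimal": [counts_opt[v] for v in var_names],
        "count_total": [counts_tot[v] for v in var_names],
        "sign": [sign_label(v) for v in var_names],
    })
    return out.sort_values(["count_total", "count_optimal", "variable"],
                           ascending=[False, False, True], ignore_index=True)
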