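"""Correlation screening: Pearson/Spearman with p-values, matrices with
sex-matched covariate pairing, and confounder-adjusted OLS associations.

Missing data are handled pairwise-complete for correlations and listwise
for adjusted associations; every result records the number of countries
actually used, so per-cell sample sizes stay auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .panel import CountryPanel, PanelError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    method: str  # "pearson" | "spearman"
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class AdjustedAssociation:
    outcome: str
    exposure: str
    confounders: tuple[str, ...]
    exposure_coefficient: float  # standardized units
    exposure_p: float
    n: int


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PanelError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def pearson_with_p(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Sample Pearson r with a two-sided p from the t transform.

    p is computed from ``t = r * sqrt(n-2) / sqrt(1-r^2)`` on ``n-2``
    degrees of freedom.  Pairs with a missing value in either vector are
    dropped.  A constant vector yields a missing result with a warning.
    """
    xv, yv = _pairwise_complete(x, y)
    n = len(xv)
    if n < 3:
        raise PanelError(f"need >= 3 complete pairs, got {n}")
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        log.warning("constant vector in correlation (%s, %s)", var_x, var_y)
        return CorrelationResult(var_x, var_y, "pearson", np.nan, np.nan, n)
    r = float(((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(var_x, var_y, "pearson", r, p, n)


def spearman_with_p(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Spearman rank correlation: Pearson on average ranks (ties averaged)."""
    xv, yv = _pairwise_complete(x, y)
    if len(xv) < 3:
        raise PanelError(f"need >= 3 complete pairs, got {len(xv)}")
    rx = stats.rankdata(xv, method="average")
    ry = stats.rankdata(yv, method="average")
    res = pearson_with_p(rx, ry, var_x, var_y)
    return CorrelationResult(var_x, var_y, "spearman", res.r, res.p, res.n)


_SEXED = ("male", "female")


def _sex_compatible(panel: CountryPanel, exposure: str, outcome: str) -> bool:
    se = panel.meta[exposure].sex
    so = panel.meta[outcome].sex
    if se not in _SEXED or so not in _SEXED:
        return True
    return se == so


def correlation_matrix(panel: CountryPanel, exposures: list[str],
                       outcomes: list[str], method: str = "pearson",
                       sex_matching: bool = True):
    """Exposures x outcomes tables of r, p and n.

    Pairwise-complete countries per cell.  With ``sex_matching`` on,
    sex-specific exposures (e.g. smoking prevalence in men) are paired
    only with same-sex outcomes; mismatched cells are left blank (NaN),
    reproducing the blank cells of sex-stratified summary tables.
    """
    if not exposures or not outcomes:
        raise PanelError("exposure and outcome lists must be nonempty")
    fun = {"pearson": pearson_with_p, "spearman": spearman_with_p}.get(method)
    if fun is None:
        raise PanelError(f"unknown method {method!r}")
    r = pd.DataFrame(np.nan, index=exposures, columns=outcomes)
    p = r.copy()
    n = pd.DataFrame(0, index=exposures, columns=outcomes, dtype=int)
    for e in exposures:
        xe = panel.column(e)
        for o in outcomes:
            if sex_matching and not _sex_compatible(panel, e, o):
                continue
            res = fun(xe.to_numpy(), panel.column(o).to_numpy(), e, o)
            r.loc[e, o] = res.r
            p.loc[e, o] = res.p
            n.loc[e, o] = res.n
    return r, p, n


def adjusted_association(panel: CountryPanel, outcome: str, exposure: str,
                         confounders: list[str]) -> AdjustedAssociation:
    """OLS of outcome on exposure + confounders, all standardized.

    Listwise-complete countries; reports the exposure's standardized
    coefficient and its two-sided p.  A rank-deficient design is an error
    naming the collinear set.
    """
    cols = [outcome, exposure, *confounders]
    if len(set(cols)) != len(cols):
        raise PanelError(f"design is rank-deficient: duplicated variables in {cols}")
    data = panel.values[cols].dropna()
    n = len(data)
    n_pred = 1 + len(confounders)
    if n <= n_pred + 1:
        raise PanelError(f"need more than {n_pred + 1} complete countries, got {n}")
    z = (data - data.mean()) / data.std(ddof=1)
    if z.isna().any().any():
        const = [c for c in cols if data[c].std(ddof=1) == 0]
        raise PanelError(f"constant variables in design: {const}")
    X = z[[exposure, *confounders]].to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        names = [exposure, *confounders]
        collinear = sorted({names[i] for i, j in zip(*iu)
                            if abs(corr[i, j]) > 1 - 1e-10}
                           | {names[j] for i, j in zip(*iu)
                              if abs(corr[i, j]) > 1 - 1e-10})
        raise PanelError(f"design is rank-deficient; collinear set: {collinear}")
    fit = sm.OLS(z[outcome].to_numpy(), sm.add_constant(X)).fit()
    return AdjustedAssociation(outcome, exposure, tuple(confounders),
                               float(fit.params[1]), float(fit.pvalues[1]), n)


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Flatten correlation results into a tidy DataFrame."""
    return pd.DataFrame([r.__dict__ for r in results])
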