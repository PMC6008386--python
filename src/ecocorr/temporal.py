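"""Temporal lag-correlation profiles and the trend-line parallelism test.

Cancer incidence is referenced to a fixed detection year; per-year
cross-country correlations between that fixed outcome and the food supply
of each single year trace how the association strengthens or decays with
lag, and the year of maximum correlation gives the peak lag.  Whether two
exposures' correlation-vs-year trend lines run parallel (a sign of
long-term collinearity) is tested with the standard two-line
slope-homogeneity t-test: t = (b1 - b2) / sqrt(se1^2 + se2^2) on
n1 + n2 - 4 degrees of freedom — a HIGH p-value means parallel lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correlate import pearson_with_p
from .panel import CountryPanel, PanelError

log = logging.getLogger(__name__)

DETECTION_YEAR = 2012


@dataclass
class TemporalProfile:
    outcome: str
    exposure: str
    years: np.ndarray       # strictly increasing
    r_series: np.ndarray    # per-year Pearson r
    n_series: np.ndarray    # per-year country counts
    peak_year: int
    peak_r: float
    detection_year: int = DETECTION_YEAR

    @property
    def peak_lag(self) -> int:
        """Years between the peak-correlation year and outcome detection."""
        return self.detection_year - self.peak_year


@dataclass(frozen=True)
class SlopeTestResult:
    slope_a: float
    slope_b: float
    se_a: float
    se_b: float
    t_statistic: float
    p_parallel: float  # two-sided; high p = parallel trend lines

    def parallel(self, level: float = 0.05) -> bool:
        return self.p_parallel > level


def yearly_profile(series: pd.DataFrame, panel: CountryPanel, outcome: str,
                   exposure: str, years=None, countries=None,
                   peak: str = "signed") -> TemporalProfile:
    """Correlate a fixed outcome with single-year supplies of one item.

    Per year, the Pearson r between the outcome column and that year's
    per-country supply of ``exposure`` (>= 3 countries with both values).
    ``peak`` chooses the peak-year convention: ``signed`` (maximum r,
    the default — profiles are framed for positive correlates) or ``abs``
    (maximum |r|).  Years with no usable data are dropped with a warning.
    """
    if peak not in ("signed", "abs"):
        raise PanelError(f"unknown peak convention {peak!r}")
    out_col = panel.column(outcome)
    sub = series[series["item"] == exposure]
    if countries is not None:
        countries = [str(c).strip() for c in countries]
        sub = sub[sub["country"].isin(countries)]
        out_col = out_col[out_col.index.isin(countries)]
    if years is not None:
        sub = sub[sub["year"].isin(list(years))]
    if sub.empty:
        raise PanelError(f"no series rows for exposure {exposure!r}")
    yrs, rs, ns = [], [], []
    for year, grp in sub.groupby("year", sort=True):
        merged = pd.DataFrame({
            "x": grp.set_index("country")["supply_g"],
            "y": out_col,
        }).dropna()
        if len(merged) < 3:
            log.warning("year %d dropped: only %d usable countries",
                        year, len(merged))
            continue
        res = pearson_with_p(merged["x"].to_numpy(), merged["y"].to_numpy(),
                             exposure, outcome)
        if np.isnan(res.r):
            log.warning("year %d dropped: constant vector", year)
            continue
        yrs.append(int(year))
        rs.append(res.r)
        ns.append(res.n)
    if not yrs:
        raise PanelError(f"no usable years for ({exposure!r}, {outcome!r})")
    yrs = np.array(yrs)
    rs = np.array(rs)
    i = int(np.argmax(rs)) if peak == "signed" else int(np.argmax(np.abs(rs)))
    return TemporalProfile(outcome, exposure, yrs, rs, np.array(ns),
                           int(yrs[i]), float(rs[i]))


def slope_parallelism_test(profile_a: TemporalProfile,
                           profile_b: TemporalProfile) -> SlopeTestResult:
    """Test whether two r-vs-year trend lines have equal slopes.

    Straight lines are fitted to each profile by least squares; the slope
    difference is referred to a t distribution with n_a + n_b - 4 degrees
    of freedom.  Symmetric in argument order.
    """
    res = []
    for pr in (profile_a, profile_b):
        if len(pr.years) < 3:
            raise PanelError(f"profile ({pr.exposure}, {pr.outcome}) needs "
                             ">= 3 points")
        if np.ptp(pr.years) == 0:
            raise PanelError("degenerate profile: all points in one year")
        res.append(stats.linregress(pr.years, pr.r_series))
    (fa, fb) = res
    se = np.sqrt(fa.stderr ** 2 + fb.stderr ** 2)
    diff = fa.slope - fb.slope
    df = len(profile_a.years) + len(profile_b.years) - 4
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), df=df))
    return SlopeTestResult(float(fa.slope), float(fb.slope),
                           float(fa.stderr), float(fb.stderr), float(t), p)


def profile_battery(series: pd.DataFrame, panel: CountryPanel,
                    outcomes: list[str], exposures: list[str],
                    years=None, countries=None, peak: str = "signed"):
    """All (outcome, exposure) profiles plus, per outcome, the symmetric
    exposures x exposures parallelism p-value matrix (diagonal = 1)."""
    if not outcomes or not exposures:
        raise PanelError("outcome and exposure lists must be nonempty")
    profiles: dict[tuple[str, str], TemporalProfile] = {}
    for o in outcomes:
        for e in exposures:
            profiles[(o, e)] = yearly_profile(series, panel, o, e,
                                              years, countries, peak)
    matrices: dict[str, pd.DataFrame] = {}
    for o in outcomes:
        m = pd.DataFrame(1.0, index=exposures, columns=exposures)
        for i, e1 in enumerate(exposures):
            for e2 in exposures[i + 1:]:
                p = slope_parallelism_test(profiles[(o, e1)],
                                           profiles[(o, e2)]).p_parallel
                m.loc[e1, e2] = m.loc[e2, e1] = p
        matrices[o] = m
    return profiles, matrices


def profiles_to_frame(profiles: dict) -> pd.DataFrame:
    """Flatten a profile collection into a tidy per-year DataFrame."""
    rows = []
    for (o, e), pr in profiles.items():
        for year, r, n in zip(pr.years, pr.r_series, pr.n_series):
            rows.append({"outcome": o, "exposure": e, "year": int(year),
                         "r": float(r), "n": int(n),
                         "peak_year": pr.peak_year, "peak_lag": pr.peak_lag})
    return pd.DataFrame(rows)
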