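"""Derived dietary variables from item-level supply, protein, fat and energy.

Food balance sheets report, per item, the per-capita daily supply (g), the
protein and fat it contributes (g), and its energy (kcal).  Carbohydrate
(plus alcohol) energy is not reported and is recovered as the residual
after subtracting protein energy at ``4.1 kcal/g`` and fat energy at
``9 kcal/g``.  All composites here (energy shares, the dairy/wheat protein
index, signed sum composites, outcome shares) build on that residual
identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import CountryPanel, PanelError, VariableMeta

log = logging.getLogger(__name__)

KCAL_PER_G_PROTEIN = 4.1
KCAL_PER_G_FAT = 9.0


@dataclass(frozen=True)
class EnergyPartition:
    """Split of total dietary energy into protein / fat / residual shares."""

    total_kcal: float
    protein_g: float
    fat_g: float

    @property
    def protein_kcal(self) -> float:
        return KCAL_PER_G_PROTEIN * self.protein_g

    @property
    def fat_kcal(self) -> float:
        return KCAL_PER_G_FAT * self.fat_g

    @property
    def carb_alcohol_kcal(self) -> float:
        """Residual energy attributed to carbohydrates and alcohol."""
        return self.total_kcal - self.protein_kcal - self.fat_kcal

    @property
    def shares(self) -> tuple[float, float, float]:
        """(protein, fat, carbohydrate+alcohol) percentages of total."""
        t = self.total_kcal
        if t <= 0:
            raise PanelError(f"total energy must be positive, got {t}")
        return (100.0 * self.protein_kcal / t,
                100.0 * self.fat_kcal / t,
                100.0 * self.carb_alcohol_kcal / t)


def carb_alcohol_energy_share(total_kcal, protein_g, fat_g):
    """Percent of total energy from carbohydrates and alcohol (% CA energy).

    Residual share ``100 * (E - 4.1 P - 9 F) / E``.  Accepts scalars or
    aligned arrays.  A negative result signals inconsistent inputs and is
    returned as-is with a warning, never clamped.
    """
    total_kcal = np.asarray(total_kcal, dtype=float)
    if np.any(total_kcal <= 0):
        raise PanelError("total_kcal must be positive")
    protein_g = np.asarray(protein_g, dtype=float)
    fat_g = np.asarray(fat_g, dtype=float)
    share = 100.0 * (total_kcal - KCAL_PER_G_PROTEIN * protein_g
                     - KCAL_PER_G_FAT * fat_g) / total_kcal
    if np.any(share < 0):
        log.warning("negative carbohydrate+alcohol energy residual: protein "
                    "and fat energy exceed total energy for some rows")
    return share.item() if share.ndim == 0 else share


def subset_energy_share(item_energy_kcal, item_protein_g, item_fat_g,
                        total_kcal) -> float:
    """Carbohydrate energy of the named items as percent of total energy.

    Used for e.g. % energy from potato and cereal carbohydrates: per item,
    the carbohydrate fraction is the item's energy minus its protein and
    fat energy; these residuals are summed and divided by total energy.
    Arguments are sequences over the chosen items (empty -> 0).
    """
    total_kcal = float(total_kcal)
    if total_kcal <= 0:
        raise PanelError("total_kcal must be positive")
    e = np.asarray(item_energy_kcal, dtype=float)
    p = np.asarray(item_protein_g, dtype=float)
    f = np.asarray(item_fat_g, dtype=float)
    if e.size == 0:
        return 0.0
    if np.isnan(e).any() or np.isnan(p).any() or np.isnan(f).any():
        raise PanelError("subset_energy_share: item missing a required component")
    resid = e - KCAL_PER_G_PROTEIN * p - KCAL_PER_G_FAT * f
    return float(100.0 * resid.sum() / total_kcal)


def plant_energy_share(plant_energy_kcal, total_kcal) -> float:
    """Percent of total energy supplied by the named plant items."""
    total_kcal = float(total_kcal)
    if total_kcal <= 0:
        raise PanelError("total_kcal must be positive")
    e = np.asarray(plant_energy_kcal, dtype=float)
    if np.isnan(e).any():
        raise PanelError("plant_energy_share: missing item energy")
    return float(100.0 * e.sum() / total_kcal)


def protein_index(dairy_protein_g, wheat_protein_g):
    """Ratio of dairy to wheat protein supply (dietary protein quality proxy).

    A nonpositive denominator yields a missing value with a warning rather
    than an error, so one degenerate country does not abort a screen.
    Accepts scalars or aligned arrays.
    """
    num = np.asarray(dairy_protein_g, dtype=float)
    den = np.asarray(wheat_protein_g, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if np.any(~(den > 0)):
        log.warning("protein_index: nonpositive wheat protein -> missing value")
    return out.item() if out.ndim == 0 else out


def sum_composite(panel: CountryPanel, operands: Sequence[str],
                  name: str | None = None) -> pd.Series:
    """Row-wise signed sum of panel columns.

    ``operands`` are variable names, optionally prefixed ``+``/``-``
    (e.g. ``["animal_fat", "animal_protein", "-milk_fat"]``).  A missing
    operand value propagates missing for that country.
    """
    if not operands:
        raise PanelError("sum_composite needs at least one operand")
    total = None
    for op in operands:
        sign = 1.0
        col = op
        if op.startswith(("+", "-")):
            sign = -1.0 if op[0] == "-" else 1.0
            col = op[1:]
        term = sign * panel.column(col)
        total = term if total is None else total + term
    total.name = name or "+".join(operands)
    return total


def add_derived(panel: CountryPanel, name: str, values: pd.Series,
                units: str = "dimensionless") -> CountryPanel:
    """Attach a derived variable to the panel with ``derived`` metadata."""
    return panel.with_column(
        name, values, VariableMeta(name, "derived", "na", units))


def long_term_mean(series: pd.DataFrame,
                   year_range: tuple[int, int] = (1993, 2011),
                   value: str = "supply_g") -> pd.DataFrame:
    """Mean of a yearly component over the given inclusive year range.

    Returns one row per (country, item) with the mean and the count of
    contributing years.  Requires at least one in-range year per pair.
    """
    lo, hi = year_range
    sub = series[(series["year"] >= lo) & (series["year"] <= hi)]
    sub = sub.dropna(subset=[value])
    if sub.empty:
        raise PanelError(f"no observations in years [{lo}, {hi}]")
    grp = sub.groupby(["country", "item"], sort=True)[value]
    out = grp.agg(mean="mean", n_years="count").reset_index()
    return out


def outcome_share(panel: CountryPanel, subset_outcomes: Sequence[str],
                  all_outcomes: Sequence[str], sex: str,
                  weighting: str = "sum") -> float:
    """Percent of the summed incidence burden carried by a subset of cancers.

    Rates are aggregated over countries by summing (default) or averaging
    the country age-standardized rates; the share is
    ``100 * aggregate(subset) / aggregate(all)``.  All outcomes must carry
    the requested sex.
    """
    for name in list(subset_outcomes) + list(all_outcomes):
        m = panel.meta.get(name)
        if m is None:
            raise PanelError(f"unknown outcome {name!r}")
        if m.sex != sex:
            raise PanelError(f"outcome {name!r} has sex {m.sex!r}, wanted {sex!r}")
    if not set(subset_outcomes) <= set(all_outcomes):
        raise PanelError("subset_outcomes must be contained in all_outcomes")
    if weighting not in ("sum", "mean"):
        raise PanelError(f"unknown weighting {weighting!r}")
    # per-country total burden first, then aggregate across countries
    sub_burden = np.nansum(panel.values[list(subset_outcomes)].to_numpy(), axis=1)
    all_burden = np.nansum(panel.values[list(all_outcomes)].to_numpy(), axis=1)
    agg = np.sum if weighting == "sum" else np.mean
    num = agg(sub_burden)
    den = agg(all_burden)
    if den <= 0:
        raise PanelError("total outcome burden is not positive")
    return float(100.0 * num / den)
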