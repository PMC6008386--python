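"""Country-level panel data model and delimited-text I/O.

The central container is :class:`CountryPanel`: a rectangular
countries x variables table of per-capita food supply (g/day), derived
dietary indicators, lifestyle covariates, and sex-specific age-standardized
cancer incidence rates (per 100,000), with per-variable metadata.

Yearly per-item supply series (long layout: one row per
country/item/year with supply, protein, fat and energy components) are
kept as plain :class:`pandas.DataFrame` objects validated by
:func:`validate_series`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CATEGORIES = ("food", "derived", "covariate", "outcome")
SEXES = ("male", "female", "both", "na")

#: columns of a long-layout yearly supply series file
SERIES_COLUMNS = ("country", "item", "year", "supply_g", "protein_g",
                  "fat_g", "energy_kcal")

YEAR_MIN, YEAR_MAX = 1961, 2011


class PanelError(ValueError):
    """Raised when a panel or series violates its invariants."""


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one panel column.

    Parameters
    ----------
    name
        Unique variable identifier.
    category
        One of ``food``, ``derived``, ``covariate``, ``outcome``.
    sex
        ``male``/``female`` for sex-specific series, ``both`` or ``na``
        otherwise. Outcome variables must be sex-specific.
    units
        Non-empty unit string, e.g. ``"g/day"``, ``"per-100000"``.
    source_sheet
        Optional provenance label.
    """

    name: str
    category: str = "food"
    sex: str = "na"
    units: str = "g/day"
    source_sheet: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise PanelError(f"unknown category {self.category!r} for {self.name!r}")
        if self.sex not in SEXES:
            raise PanelError(f"unknown sex {self.sex!r} for {self.name!r}")
        if self.category == "outcome" and self.sex not in ("male", "female"):
            raise PanelError(
                f"outcome variable {self.name!r} must be sex-specific, got {self.sex!r}")
        if not self.units:
            raise PanelError(f"units must be nonempty for {self.name!r}")


def _default_meta(name: str) -> VariableMeta:
    # convention: outcome columns end in _male/_female
    if name.endswith("_male"):
        return VariableMeta(name, "outcome", "male", "per-100000")
    if name.endswith("_female"):
        return VariableMeta(name, "outcome", "female", "per-100000")
    return VariableMeta(name, "food", "na", "g/day")


@dataclass
class CountryPanel:
    """Countries x variables table with variable metadata.

    ``values`` is indexed by country, one column per variable; missing
    cells are NaN and never silently zero-filled.
    """

    values: pd.DataFrame
    meta: dict[str, VariableMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str).str.strip()
        self.values.index.name = "country"
        for name in self.values.columns:
            if name not in self.meta:
                self.meta[name] = _default_meta(name)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def countries(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def column(self, name: str) -> pd.Series:
        if name not in self.values.columns:
            raise PanelError(f"unknown variable {name!r}")
        return self.values[name]

    def variables_of(self, category: str | None = None,
                     sex: str | None = None) -> list[str]:
        """Variable names filtered by category and/or sex."""
        out = []
        for name in self.values.columns:
            m = self.meta[name]
            if category is not None and m.category != category:
                continue
            if sex is not None and m.sex != sex:
                continue
            out.append(name)
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].tolist()
            raise PanelError(f"duplicate country identifiers: {dup}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].tolist()
            raise PanelError(f"duplicate variable names: {dup}")
        extra = set(self.meta) - set(cols)
        if extra:
            raise PanelError(f"metadata for unknown variables: {sorted(extra)}")
        # supply and prevalence values must be nonnegative where present
        for name in cols:
            if self.meta[name].category in ("food", "covariate", "outcome"):
                col = self.values[name]
                bad = col[col < 0]
                if len(bad):
                    raise PanelError(
                        f"negative values in {name!r} for countries "
                        f"{bad.index.tolist()}")
        if len(idx) and len(idx) < 3:
            log.warning("panel has only %d countries; most analyses need >= 3",
                        len(idx))

    # -- operations --------------------------------------------------------
    def exclude_countries(self, names: Sequence[str],
                          allow_empty: bool = False) -> "CountryPanel":
        """Return a copy of the panel without the named countries.

        Mirrors the study-design step of dropping countries whose outcome
        statistics are wholly estimated rather than measured.
        """
        names = [str(n).strip() for n in names]
        unknown = set(names) - set(self.values.index)
        if unknown:
            raise PanelError(f"unknown countries: {sorted(unknown)}")
        keep = self.values.index.difference(names, sort=False)
        if len(keep) == 0 and not allow_empty:
            raise PanelError("excluding all countries (pass allow_empty=True "
                             "to permit an empty panel)")
        return CountryPanel(self.values.loc[keep].copy(), dict(self.meta))

    def with_column(self, name: str, data: pd.Series,
                    meta: VariableMeta | None = None) -> "CountryPanel":
        """Return a copy with an added (or replaced) variable column."""
        values = self.values.copy()
        values[name] = data.reindex(values.index)
        new_meta = dict(self.meta)
        new_meta[name] = meta if meta is not None else _default_meta(name)
        if new_meta[name].name != name:
            new_meta[name] = replace(new_meta[name], name=name)
        return CountryPanel(values, new_meta)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountryPanel):
            return NotImplemented
        same_vals = (self.values.shape == other.values.shape
                     and list(self.values.index) == list(other.values.index)
                     and list(self.values.columns) == list(other.values.columns)
                     and np.array_equal(self.values.to_numpy(),
                                        other.values.to_numpy(), equal_nan=True))
        return same_vals and self.meta == other.meta


# ---------------------------------------------------------------------------
# panel I/O
# ---------------------------------------------------------------------------

def _read_csv(path, sep):
    return pd.read_csv(path, sep=sep, comment="#", dtype=str,
                       keep_default_na=False, encoding="utf-8")


def _to_float(cell: str, where: str) -> float:
    cell = cell.strip()
    if cell in ("", "NA"):
        return np.nan
    try:
        return float(cell)
    except ValueError:
        raise PanelError(f"non-numeric value {cell!r} at {where}") from None


def read_panel(path, layout: str = "wide", sep: str = ",",
               meta: Mapping[str, VariableMeta] | None = None) -> CountryPanel:
    """Read a country panel from a delimited text file.

    ``wide`` layout: first column ``country``, one column per variable.
    ``long`` layout: columns ``country,variable,value``.  Empty cells and
    the literal ``NA`` are read as missing.  Duplicate (country, variable)
    pairs and non-numeric cells are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise PanelError(f"no such file: {path}")
    raw = _read_csv(path, sep)
    if layout == "wide":
        if raw.shape[1] < 1 or raw.columns[0].strip().lower() != "country":
            raise PanelError("wide layout requires first column 'country'")
        raw = raw.rename(columns={raw.columns[0]: "country"})
        countries = raw["country"].astype(str).str.strip()
        data = {}
        for col in raw.columns[1:]:
            data[col.strip()] = [
                _to_float(v, f"row {i + 2}, column {col!r}")
                for i, v in enumerate(raw[col])
            ]
        values = pd.DataFrame(data, index=countries)
        if values.index.has_duplicates:
            raise PanelError(
                f"duplicate countries: {values.index[values.index.duplicated()].tolist()}")
    elif layout == "long":
        need = {"country", "variable", "value"}
        raw.columns = [c.strip() for c in raw.columns]
        if not need.issubset(raw.columns):
            raise PanelError(f"long layout requires columns {sorted(need)}")
        raw["country"] = raw["country"].str.strip()
        raw["variable"] = raw["variable"].str.strip()
        dup = raw.duplicated(subset=["country", "variable"])
        if dup.any():
            pairs = raw.loc[dup, ["country", "variable"]].values.tolist()
            raise PanelError(f"duplicate (country, variable) pairs: {pairs}")
        raw["value"] = [
            _to_float(v, f"row {i + 2}") for i, v in enumerate(raw["value"])
        ]
        values = raw.pivot(index="country", columns="variable", values="value")
        values = values.loc[raw["country"].unique(), raw["variable"].unique()]
    else:
        raise PanelError(f"unknown layout {layout!r}")
    return CountryPanel(values, dict(meta) if meta else {})


def write_panel(panel: CountryPanel, path, layout: str = "wide",
                sep: str = ",", header_lines: Iterable[str] = ()) -> None:
    """Write a panel so that :func:`read_panel` round-trips it exactly.

    Missing cells are written as empty fields.  ``header_lines`` are
    prepended as ``#`` comments (provenance).
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        if layout == "wide":
            df = panel.values.reset_index()
            df.to_csv(fh, sep=sep, index=False, na_rep="", float_format="%.17g")
        elif layout == "long":
            long = panel.values.stack(future_stack=True).rename("value").reset_index()
            long.columns = ["country", "variable", "value"]
            long.to_csv(fh, sep=sep, index=False, na_rep="", float_format="%.17g")
        else:
            raise PanelError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# yearly supply series
# ---------------------------------------------------------------------------

def validate_series(series: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-layout yearly supply table and return it typed.

    Requires columns ``country,item,year,supply_g,protein_g,fat_g,
    energy_kcal`` (component columns may hold missing values), years in
    [1961, 2011], nonnegative quantities, and unique (country, item, year).
    """
    missing = set(SERIES_COLUMNS) - set(series.columns)
    if missing:
        raise PanelError(f"series missing columns: {sorted(missing)}")
    out = series.loc[:, list(SERIES_COLUMNS)].copy()
    out["country"] = out["country"].astype(str).str.strip()
    out["item"] = out["item"].astype(str).str.strip()
    out["year"] = out["year"].astype(int)
    bad_year = out[(out["year"] < YEAR_MIN) | (out["year"] > YEAR_MAX)]
    if len(bad_year):
        raise PanelError(
            f"years outside [{YEAR_MIN}, {YEAR_MAX}]: "
            f"{sorted(bad_year['year'].unique().tolist())}")
    for col in SERIES_COLUMNS[3:]:
        out[col] = out[col].astype(float)
        if (out[col] < 0).any():
            raise PanelError(f"negative values in series column {col!r}")
    if out.duplicated(subset=["country", "item", "year"]).any():
        raise PanelError("duplicate (country, item, year) rows in series")
    return out


def read_series(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a long-layout yearly supply series CSV."""
    path = Path(path)
    if not path.exists():
        raise PanelError(f"no such file: {path}")
    raw = pd.read_csv(path, sep=sep, comment="#", encoding="utf-8",
                      na_values=["", "NA"], keep_default_na=False)
    return validate_series(raw)


def write_series(series: pd.DataFrame, path, sep: str = ",",
                 header_lines: Iterable[str] = ()) -> None:
    series = validate_series(series)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        series.to_csv(fh, sep=sep, index=False, na_rep="", float_format="%.17g")
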