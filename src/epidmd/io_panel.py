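"""Reading, validation, filtering and reshaping of county-by-year rate panels.

The central object is :class:`IncidencePanel`: an ``n_counties x n_years``
dense matrix of age-adjusted incidence rates (cases per 100,000), with rows
keyed by 5-digit FIPS county codes and columns by consecutive calendar years.
Long CSV extracts (one row per county-year) are parsed into
:class:`IncidenceRecord` lists, assembled into a possibly-incomplete panel,
and reduced to a complete-case panel by dropping every county with any
missing year — registries suppress small counts, so missingness is a
per-county, not per-cell, phenomenon in practice.

Missing-value conventions follow registry-export style: empty cells and the
sentinels ``NA``, ``^`` and ``*`` all denote suppressed/unavailable rates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyPanelError,
    PanelIntegrityError,
    RowParseError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "IncidenceRecord",
    "IncidencePanel",
    "MISSING_SENTINELS",
    "read_long_csv",
    "assemble_panel",
    "filter_complete",
    "write_wide_csv",
    "read_wide_csv",
]

#: Cell contents treated as "rate missing" when parsing long CSVs.
MISSING_SENTINELS = frozenset({"", "NA", "^", "*"})

_FIPS_RE = re.compile(r"^[0-9]{5}$")


@dataclass(frozen=True)
class IncidenceRecord:
    """One county-year observation; ``rate`` is None when suppressed/missing."""

    fips: str
    year: int
    rate: float | None

    def __post_init__(self):
        if not _FIPS_RE.match(self.fips):
            raise ValidationError(f"invalid FIPS code {self.fips!r}")
        if self.rate is not None and self.rate < 0:
            raise ValidationError(
                f"negative rate {self.rate} for ({self.fips}, {self.year})"
            )


@dataclass
class IncidencePanel:
    """Dense counties x years rate matrix.

    ``values[i, j]`` is the rate for ``counties[i]`` in ``years[j]``; missing
    entries are NaN. ``years`` are strictly consecutive. The county order
    fixed here is the canonical row order for every downstream matrix.
    """

    counties: list[str]
    years: list[int]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.counties), len(self.years)
        if self.values.shape != (n, m):
            raise ValidationError(
                f"values shape {self.values.shape} != ({n}, {m})"
            )
        if any(b - a != 1 for a, b in zip(self.years, self.years[1:])):
            raise ValidationError(f"years not consecutive: {self.years}")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValidationError("panel contains negative rates")

    @property
    def n_counties(self) -> int:
        return len(self.counties)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(year)
        except ValueError:
            raise ValidationError(f"year {year} not in panel {self.years[0]}-{self.years[-1]}") from None

    def column(self, year: int) -> np.ndarray:
        """Rates of all counties for one year, in canonical county order."""
        return self.values[:, self.year_index(year)].copy()

    def restrict_years(self, first: int, last: int) -> "IncidencePanel":
        """Sub-panel covering ``first..last`` inclusive."""
        if first > last:
            raise ValidationError(f"empty year range [{first}, {last}]")
        i, j = self.year_index(first), self.year_index(last)
        return IncidencePanel(
            counties=list(self.counties),
            years=list(range(first, last + 1)),
            values=self.values[:, i : j + 1].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame indexed by fips with one column per year."""
        return pd.DataFrame(
            self.values, index=pd.Index(self.counties, name="fips"),
            columns=self.years,
        )


def _parse_rate(cell: str, line: int) -> float | None:
    cell = cell.strip()
    if cell in MISSING_SENTINELS:
        return None
    try:
        rate = float(cell)
    except ValueError:
        raise RowParseError(f"unparseable rate {cell!r}", line) from None
    if rate < 0:
        raise RowParseError(f"negative rate {rate}", line)
    return rate


def read_long_csv(
    path,
    schema: dict[str, str] | None = None,
) -> list[IncidenceRecord]:
    """Parse a long-format CSV (one row per county-year) into records.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Mapping from the canonical field names ``fips``, ``year``, ``rate``
        to the column names used in the file. Defaults to identity.
    """
    schema = schema or {"fips": "fips", "year": "year", "rate": "rate"}
    for key in ("fips", "year", "rate"):
        if key not in schema:
            raise SchemaError(f"schema lacks a mapping for {key!r}")

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for key, col in schema.items():
        if col not in df.columns:
            raise SchemaError(f"column {col!r} (mapped from {key!r}) not in header")

    records: list[IncidenceRecord] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        fips = str(getattr(row, schema["fips"])).strip().zfill(5)
        raw_year = str(getattr(row, schema["year"])).strip()
        try:
            year = int(raw_year)
        except ValueError:
            raise RowParseError(f"unparseable year {raw_year!r}", line) from None
        rate = _parse_rate(str(getattr(row, schema["rate"])), line)
        try:
            records.append(IncidenceRecord(fips=fips, year=year, rate=rate))
        except ValidationError as exc:
            raise RowParseError(str(exc), line) from None
    return records


def assemble_panel(
    records: list[IncidenceRecord],
    year_range: tuple[int, int],
) -> IncidencePanel:
    """Arrange records into a dense panel over ``year_range`` (inclusive).

    Rows are sorted lexicographically by FIPS; (fips, year) pairs absent
    from ``records`` are NaN. Duplicate records that agree are de-duplicated;
    duplicates with conflicting rates raise :class:`PanelIntegrityError`.
    """
    first, last = year_range
    if first > last:
        raise ValidationError(f"empty year range {year_range}")
    in_range = [r for r in records if first <= r.year <= last]
    if not in_range:
        raise ValidationError(f"no records inside year range {year_range}")

    seen: dict[tuple[str, int], float | None] = {}
    for r in in_range:
        key = (r.fips, r.year)
        if key in seen and seen[key] != r.rate:
            raise PanelIntegrityError(
                f"conflicting duplicate for {key}: {seen[key]} vs {r.rate}"
            )
        seen[key] = r.rate

    counties = sorted({f for f, _ in seen})
    years = list(range(first, last + 1))
    values = np.full((len(counties), len(years)), np.nan)
    row = {f: i for i, f in enumerate(counties)}
    for (fips, year), rate in seen.items():
        if rate is not None:
            values[row[fips], year - first] = rate
    return IncidencePanel(counties=counties, years=years, values=values)


def filter_complete(panel: IncidencePanel) -> tuple[IncidencePanel, list[str]]:
    """Complete-case filter: drop every county with any missing year.

    Returns the filtered panel (county order preserved) and the FIPS codes
    of dropped counties. No imputation is performed.
    """
    keep = ~np.isnan(panel.values).any(axis=1)
    dropped = [f for f, k in zip(panel.counties, keep) if not k]
    if not keep.any():
        raise EmptyPanelError("every county has missing data; nothing survives filtering")
    filtered = IncidencePanel(
        counties=[f for f, k in zip(panel.counties, keep) if k],
        years=list(panel.years),
        values=panel.values[keep].copy(),
    )
    return filtered, dropped


def write_wide_csv(panel: IncidencePanel, path) -> None:
    """Write a complete panel as wide CSV: header ``fips,<y1>,...,<yM>``."""
    if panel.n_counties == 0:
        raise EmptyPanelError("refusing to write an empty panel")
    if not panel.is_complete:
        raise ValidationError("panel has missing entries; filter before writing")
    df = panel.to_frame()
    df.insert(0, "fips", df.index)
    df.to_csv(path, index=False, float_format="%.10g")


def read_wide_csv(path) -> IncidencePanel:
    """Read a wide CSV produced by :func:`write_wide_csv`."""
    df = pd.read_csv(path, dtype={"fips": str}, keep_default_na=False,
                     na_values=sorted(MISSING_SENTINELS))
    if "fips" not in df.columns:
        raise SchemaError("wide CSV lacks a 'fips' column")
    try:
        years = [int(c) for c in df.columns if c != "fips"]
    except ValueError as exc:
        raise SchemaError(f"non-year column in wide CSV header: {exc}") from None
    counties = [str(f).zfill(5) for f in df["fips"]]
    values = df.drop(columns="fips").to_numpy(dtype=float)
    order = np.argsort(counties, kind="stable")
    return IncidencePanel(
        counties=[counties[i] for i in order],
        years=years,
        values=values[order],
    )
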