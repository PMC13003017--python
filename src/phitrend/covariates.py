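"""Covariate construction: climate region, management class, buffered SST.

Three covariates are attached to each growth observation:

* a climatic region from the latitude of the sampling location
  (tropical |lat| <= 23, subtropical 23 < |lat| <= 34, temperate beyond,
  poles included in temperate);
* a management class from family membership against two user-supplied
  family lists (managed = family has a formal stock assessment, unmanaged =
  catches reported but no assessment, unfished = neither; managed takes
  precedence);
* the mean annual sea-surface temperature within a 2-degree buffer of the
  location on a 1x1-degree grid, for the sampling year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .growth_metrics import ValidationError

logger = logging.getLogger(__name__)

REGIONS = ("tropical", "subtropical", "temperate")
MANAGEMENT_CLASSES = ("managed", "unmanaged", "unfished")

TROPICAL_LIMIT = 23.0
SUBTROPICAL_LIMIT = 34.0


@dataclass(frozen=True)
class Region:
    label: str

    def __post_init__(self) -> None:
        if self.label not in REGIONS:
            raise ValidationError(f"unknown region {self.label!r}")


@dataclass(frozen=True)
class ManagementClass:
    label: str
    basis: str = "no match"

    def __post_init__(self) -> None:
        if self.label not in MANAGEMENT_CLASSES:
            raise ValidationError(f"unknown management class {self.label!r}")


def classify_region(latitude: float) -> Region:
    """Map a latitude to its climate band; boundaries belong to the equatorward band."""
    if not (-90.0 <= latitude <= 90.0):
        raise ValidationError(f"latitude {latitude} outside [-90, 90]")
    a = abs(latitude)
    if a <= TROPICAL_LIMIT:
        return Region("tropical")
    if a <= SUBTROPICAL_LIMIT:
        return Region("subtropical")
    return Region("temperate")


def _normalise_family(name: str) -> str:
    return name.strip().casefold()


def classify_management(
    family: str,
    managed_families: Iterable[str],
    unmanaged_families: Iterable[str],
) -> ManagementClass:
    """Classify a family as managed / unmanaged / unfished.

    Managed (a formal stock assessment exists) takes precedence over
    unmanaged (reported or reconstructed catches only); families on neither
    list are unfished.  Matching is case-insensitive and whitespace-trimmed.
    """
    if not family or not family.strip():
        raise ValidationError("empty family name")
    fam = _normalise_family(family)
    managed = {_normalise_family(f) for f in managed_families}
    unmanaged = {_normalise_family(f) for f in unmanaged_families}
    if fam in managed:
        return ManagementClass("managed", basis=family.strip())
    if fam in unmanaged:
        return ManagementClass("unmanaged", basis=family.strip())
    return ManagementClass("unfished", basis="no match")


def read_family_list(path: str | Path) -> list[str]:
    """One family per line; '#' starts a provenance comment."""
    families = []
    for line in Path(path).read_text().splitlines():
        name = line.split("#", 1)[0].strip()
        if name:
            families.append(name)
    return families


# ---------------------------------------------------------------------------
# SST grid
# ---------------------------------------------------------------------------


@dataclass
class SSTGrid:
    """Annual-mean sea-surface temperature on a regular lon-lat lattice.

    ``values`` has shape (n_years, n_lat, n_lon) with NaN marking land or
    otherwise missing cells; ``lats``/``lons`` are cell-centre coordinates.
    """

    years: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.years), len(self.lats), len(self.lons)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match coordinates "
                f"({len(self.years)}, {len(self.lats)}, {len(self.lons)})"
            )

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "SSTGrid":
        import xarray as xr

        ds = xr.open_dataset(path)
        name = next(v for v in ("sst", "temperature", "temp") if v in ds)
        da = ds[name]
        lat = next(c for c in ("lat", "latitude") if c in da.coords)
        lon = next(c for c in ("lon", "longitude") if c in da.coords)
        time = next(c for c in ("year", "time") if c in da.coords)
        da = da.transpose(time, lat, lon)
        years = da[time].values
        if np.issubdtype(years.dtype, np.datetime64):
            years = pd.DatetimeIndex(years).year.to_numpy()
        return cls(years=years, lats=da[lat].values, lons=da[lon].values, values=da.values)

    def to_netcdf(self, path: str | Path) -> None:
        import xarray as xr

        ds = xr.Dataset(
            {"sst": (("year", "lat", "lon"), self.values)},
            coords={"year": self.years, "lat": self.lats, "lon": self.lons},
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SSTGrid":
        """Long-format CSV with columns year, lat, lon, sst (missing cells omitted)."""
        df = pd.read_csv(path)
        years = np.sort(df["year"].unique())
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        values = np.full((len(years), len(lats), len(lons)), np.nan)
        yi = {y: i for i, y in enumerate(years)}
        ai = {a: i for i, a in enumerate(lats)}
        oi = {o: i for i, o in enumerate(lons)}
        for row in df.itertuples(index=False):
            values[yi[row.year], ai[row.lat], oi[row.lon]] = row.sst
        return cls(years=years, lats=lats, lons=lons, values=values)

    def to_csv(self, path: str | Path) -> None:
        yy, aa, oo = np.meshgrid(self.years, self.lats, self.lons, indexing="ij")
        df = pd.DataFrame(
            {"year": yy.ravel(), "lat": aa.ravel(), "lon": oo.ravel(), "sst": self.values.ravel()}
        ).dropna(subset=["sst"])
        df.to_csv(path, index=False)

    # -- extraction --------------------------------------------------------

    def year_index(self, year: int, nearest: bool = False) -> int:
        hits = np.nonzero(self.years == year)[0]
        if hits.size:
            return int(hits[0])
        if nearest:
            idx = int(np.argmin(np.abs(self.years - year)))
            logger.warning("year %d not in grid, using nearest available %d", year, self.years[idx])
            return idx
        raise ValidationError(
            f"year {year} outside grid span {self.years.min()}-{self.years.max()}"
        )


def _wrapped_lon_delta(lons: np.ndarray, lon: float) -> np.ndarray:
    return (lons - lon + 180.0) % 360.0 - 180.0


def extract_mean_sst(
    grid: SSTGrid,
    latitude: float,
    longitude: float,
    year: int,
    buffer: float = 2.0,
    nearest_year: bool = False,
) -> float:
    """Unweighted mean SST over all non-missing cells within ``buffer`` degrees.

    Distance is planar in degree space (the buffer is specified in degrees on
    a 1-degree grid) with longitude wrapped at +-180 so buffers straddle the
    date line correctly.
    """
    if not (-90.0 <= latitude <= 90.0):
        raise ValidationError(f"latitude {latitude} outside [-90, 90]")
    ti = grid.year_index(int(year), nearest=nearest_year)
    dlat = grid.lats - latitude
    dlon = _wrapped_lon_delta(grid.lons, longitude)
    dist2 = dlat[:, None] ** 2 + dlon[None, :] ** 2
    mask = dist2 <= buffer**2
    vals = grid.values[ti][mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError(
            f"no ocean cell within {buffer} degrees of ({latitude}, {longitude}) in {year}"
        )
    return float(vals.mean())


def attach_covariates(
    obs: pd.DataFrame,
    grid: SSTGrid | None = None,
    managed_families: Sequence[str] = (),
    unmanaged_families: Sequence[str] = (),
    buffer: float = 2.0,
    nearest_year: bool = False,
) -> pd.DataFrame:
    """Attach region, management class and (optionally) mean SST columns."""
    out = obs.copy()
    out["region"] = [classify_region(lat).label for lat in out["latitude"]]
    out["management"] = [
        classify_management(fam, managed_families, unmanaged_families).label
        for fam in out["family"]
    ]
    if grid is not None:
        out["sst"] = [
            extract_mean_sst(grid, lat, lon, int(yr), buffer=buffer, nearest_year=nearest_year)
            for lat, lon, yr in zip(out["latitude"], out["longitude"], out["year"])
        ]
    return out
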