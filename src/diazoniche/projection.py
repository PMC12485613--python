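"""Gridded niche projection, dominance classification and hot-spot regions.

Fitted niche models are evaluated cellwise on monthly 1-degree global
fields of SST, dFe and P, back-transformed from log10 to linear
abundance, and annualized by averaging the 12 monthly abundance fields.
A cell is "dominated" by a taxon when that taxon contributes more than
a share threshold (default 75%) of the summed predicted nifH abundance
of the surveyed taxa and the summed abundance clears a floor.  Two
floors are in use as named presets: ``dominance-map`` (1e4 copies m-2,
for mapping dominant taxa) and ``hotspot`` (1e8 copies m-2, for
delineating candidate high-rate regions).  Qualifying cells are grouped
into connected regions (8-connectivity with longitudinal wrap) whose
areas are summed from latitude-weighted spherical cell areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import xarray as xr
from scipy import ndimage

from .gam import GamFit

__all__ = [
    "EARTH_RADIUS_KM",
    "THRESHOLD_PRESETS",
    "EnvGrid",
    "AbundanceMap",
    "DominanceMask",
    "Region",
    "cell_areas_km2",
    "project_taxon",
    "dominance",
    "hotspot_regions",
]

EARTH_RADIUS_KM = 6371.0

#: Named total-abundance floors (nifH copies m-2) for dominance masks.
THRESHOLD_PRESETS = {"dominance-map": 1e4, "hotspot": 1e8}

#: Rate floor (umol N m-2 d-1) delineating the high-rate category.
HIGH_RATE_THRESHOLD = 100.0


def _standard_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.ndim != 1 or lon.ndim != 1:
        raise ValueError("lat/lon must be 1-D coordinate vectors")
    if np.any(np.diff(lat) <= 0) or np.any(np.diff(lon) <= 0):
        raise ValueError("lat/lon must be strictly increasing")


@dataclass
class EnvGrid:
    """Monthly gridded covariates on 1-degree cell centers.

    ``data`` is an xarray Dataset with dims (month, lat, lon) and
    variables ``sst`` (degC), ``dfe`` (nM), ``p`` (uM); land/missing
    cells are NaN in every variable.
    """

    data: xr.Dataset

    def __post_init__(self) -> None:
        for v in ("sst", "dfe", "p"):
            if v not in self.data:
                raise ValueError(f"missing covariate field {v!r}")
            if tuple(self.data[v].dims) != ("month", "lat", "lon"):
                raise ValueError(f"{v} must have dims (month, lat, lon)")
        _standard_coords(self.data.lat.values, self.data.lon.values)

    @property
    def lat(self) -> np.ndarray:
        return self.data.lat.values

    @property
    def lon(self) -> np.ndarray:
        return self.data.lon.values

    @property
    def ocean_mask(self) -> np.ndarray:
        """True where all covariates are finite in at least one month."""
        finite = np.isfinite(self.data["sst"].values)
        for v in ("dfe", "p"):
            finite &= np.isfinite(self.data[v].values)
        return finite.any(axis=0)


@dataclass
class AbundanceMap:
    """Annualized predicted nifH abundance (copies m-2) for one taxon."""

    taxon: str
    lat: np.ndarray
    lon: np.ndarray
    abundance: np.ndarray  # (lat, lon), NaN over land
    extrapolated: np.ndarray  # boolean (lat, lon)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "abundance": (("lat", "lon"), self.abundance),
                "extrapolated": (("lat", "lon"), self.extrapolated.astype("i1")),
            },
            coords={"lat": self.lat, "lon": self.lon},
            attrs={"taxon": self.taxon, "units": "nifH copies m-2"},
        )


@dataclass
class DominanceMask:
    """Categorical dominance grid: taxon name per cell or '' (none)."""

    lat: np.ndarray
    lon: np.ndarray
    taxon: np.ndarray  # object array of taxon names, '' for none
    share_threshold: float
    abundance_threshold: float

    def cells_of(self, taxon: str) -> np.ndarray:
        return self.taxon == taxon


@dataclass
class Region:
    """One connected dominance region."""

    region_id: int
    taxon: str
    n_cells: int
    area_1e6_km2: float
    cells: np.ndarray = field(repr=False)  # boolean (lat, lon)


def cell_areas_km2(lat_centers: np.ndarray, dlon_deg: float = 1.0) -> np.ndarray:
    """Area of each 1-degree-latitude band cell, km2.

    Spherical formula A = R^2 * dlon * (sin(phi2) - sin(phi1)) with
    cell edges +/- half a degree around each center.
    """
    lat = np.asarray(lat_centers, dtype=float)
    phi1 = np.radians(lat - 0.5)
    phi2 = np.radians(lat + 0.5)
    dlam = np.radians(dlon_deg)
    return EARTH_RADIUS_KM**2 * dlam * (np.sin(phi2) - np.sin(phi1))


def project_taxon(
    fit: GamFit,
    env: EnvGrid,
    *,
    annualize: str = "linear",
) -> AbundanceMap:
    """Project one taxon's niche model onto the environmental grid.

    Per month, log10 abundance is predicted cellwise (covariates
    clamped to the training hull, clamped cells flagged) and
    back-transformed to copies m-2; the 12 monthly fields are averaged
    in linear abundance space (``annualize="linear"``, default) or in
    log10 space (``annualize="log"``).  Cells with any missing
    covariate in a month are excluded from that month; cells missing in
    all months are NaN.
    """
    if annualize not in ("linear", "log"):
        raise ValueError("annualize must be 'linear' or 'log'")
    ds = env.data
    months = ds.month.values
    nlat, nlon = ds.lat.size, ds.lon.size
    monthly = np.full((len(months), nlat, nlon), np.nan)
    flagged = np.zeros((nlat, nlon), dtype=bool)
    for i, m in enumerate(months):
        sst = ds["sst"].sel(month=m).values.ravel()
        dfe = ds["dfe"].sel(month=m).values.ravel()
        p = ds["p"].sel(month=m).values.ravel()
        ok = np.isfinite(sst) & np.isfinite(dfe) & np.isfinite(p)
        if not ok.any():
            continue
        log_pred, extrap = fit.predict(sst=sst[ok], dfe=dfe[ok], p=p[ok])
        cell = np.full(nlat * nlon, np.nan)
        cell[ok] = log_pred
        monthly[i] = cell.reshape(nlat, nlon)
        fl = np.zeros(nlat * nlon, dtype=bool)
        fl[ok] = extrap
        flagged |= fl.reshape(nlat, nlon)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # all-NaN columns (land cells) legitimately yield NaN means
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if annualize == "linear":
            annual = np.nanmean(10.0**monthly, axis=0)
        else:
            annual = 10.0 ** np.nanmean(monthly, axis=0)
    return AbundanceMap(
        taxon=fit.taxon,
        lat=ds.lat.values.copy(),
        lon=ds.lon.values.copy(),
        abundance=annual,
        extrapolated=flagged,
    )


def dominance(
    maps: Sequence[AbundanceMap],
    share_threshold: float = 0.75,
    abundance_threshold: float | str = "dominance-map",
) -> DominanceMask:
    """Classify each cell by its dominant taxon.

    A cell is assigned to taxon t iff N_t / sum(N) > ``share_threshold``
    (strict) and sum(N) > the abundance floor (strict); otherwise none.
    ``abundance_threshold`` may be a number (copies m-2) or a preset
    name from :data:`THRESHOLD_PRESETS`.
    """
    if isinstance(abundance_threshold, str):
        abundance_threshold = THRESHOLD_PRESETS[abundance_threshold]
    if not maps:
        raise ValueError("need at least one abundance map")
    lat, lon = maps[0].lat, maps[0].lon
    for m in maps[1:]:
        if not (np.array_equal(m.lat, lat) and np.array_equal(m.lon, lon)):
            raise ValueError("abundance maps are on different grids")
    stack = np.stack([m.abundance for m in maps])  # (taxon, lat, lon)
    with np.errstate(invalid="ignore"):
        total = np.nansum(stack, axis=0)
        all_nan = np.all(np.isnan(stack), axis=0)
        winner = np.nanargmax(np.where(np.isnan(stack), -np.inf, stack), axis=0)
        top = np.take_along_axis(stack, winner[None], axis=0)[0]
        share = np.divide(top, total, out=np.zeros_like(total), where=total > 0)
        qualifies = (
            ~all_nan & (total > abundance_threshold) & (share > share_threshold)
        )
    names = np.array([m.taxon for m in maps], dtype=object)
    taxon = np.where(qualifies, names[winner], "")
    taxon[all_nan] = ""
    return DominanceMask(
        lat=lat.copy(),
        lon=lon.copy(),
        taxon=taxon.astype(object),
        share_threshold=share_threshold,
        abundance_threshold=float(abundance_threshold),
    )


def _label_with_wrap(mask2d: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labels with east-west wrap at the date line."""
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(mask2d, structure=structure)
    if n == 0 or mask2d.shape[1] < 2:
        return labels, n
    # merge labels touching across the longitudinal seam (8-connectivity:
    # each west-edge cell sees the three east-edge cells in adjacent rows)
    parent = {i: i for i in range(1, n + 1)}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    west, east = labels[:, 0], labels[:, -1]
    nlat = labels.shape[0]
    for i in range(nlat):
        if west[i] == 0:
            continue
        for j in (i - 1, i, i + 1):
            if 0 <= j < nlat and east[j] != 0:
                union(west[i], east[j])
    remap = {}
    out = np.zeros_like(labels)
    next_id = 0
    for i in range(1, n + 1):
        r = find(i)
        if r not in remap:
            next_id += 1
            remap[r] = next_id
    for i in range(1, n + 1):
        out[labels == i] = remap[find(i)]
    return out, next_id


def hotspot_regions(
    mask: DominanceMask,
    taxon: str | None = None,
    rate_map: np.ndarray | None = None,
    rate_threshold: float = HIGH_RATE_THRESHOLD,
) -> list[Region]:
    """Connected dominance regions with latitude-weighted areas.

    Cells qualify when they are dominated (by ``taxon`` if given, by
    any taxon otherwise) and, when a ``rate_map`` (umol N m-2 d-1,
    same grid) is supplied, predicted rates exceed ``rate_threshold``
    (strict).  Components use 8-connectivity with longitudinal wrap;
    areas are reported in 1e6 km2.  An empty list is a valid result.
    """
    qualifying = mask.taxon != "" if taxon is None else mask.taxon == taxon
    if rate_map is not None:
        if rate_map.shape != qualifying.shape:
            raise ValueError("rate map grid mismatch")
        with np.errstate(invalid="ignore"):
            qualifying = qualifying & (rate_map > rate_threshold)
    labels, n = _label_with_wrap(qualifying)
    areas_band = cell_areas_km2(mask.lat)
    regions: list[Region] = []
    for rid in range(1, n + 1):
        cells = labels == rid
        area_km2 = float((cells * areas_band[:, None]).sum())
        cell_taxa = mask.taxon[cells]
        # region taxon: the (single) dominant taxon of its cells
        vals, counts = np.unique(cell_taxa.astype(str), return_counts=True)
        regions.append(
            Region(
                region_id=rid,
                taxon=str(vals[np.argmax(counts)]),
                n_cells=int(cells.sum()),
                area_1e6_km2=area_km2 / 1e6,
                cells=cells,
            )
        )
    regions.sort(key=lambda r: r.area_1e6_km2, reverse=True)
    return regions
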