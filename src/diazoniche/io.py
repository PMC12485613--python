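"""Validated file I/O: CSV tables and netCDF grids.

Every table the pipeline reads or writes has a declared schema
(required columns with types); reads fail loudly with the offending
column or the 1-based data row number — silent coercion is forbidden.
Grids travel as netCDF (classic format via xarray's scipy engine) with
dims (month, lat, lon), 1-degree cell centers and longitudes
normalized to -180..180.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .projection import AbundanceMap, EnvGrid

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table",
           "read_grid", "write_grid", "read_abundance_map", "write_abundance_map"]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


@dataclass(frozen=True)
class ColumnSpec:
    dtype: str  # "float", "int", "str"
    required: bool = True
    allow_nan: bool = False


def _cols(**kw: ColumnSpec) -> dict[str, ColumnSpec]:
    return kw


F = ColumnSpec("float")
FN = ColumnSpec("float", allow_nan=True)
S = ColumnSpec("str")
OPT_F = ColumnSpec("float", required=False, allow_nan=True)
OPT_S = ColumnSpec("str", required=False)

#: CSV schemas, by table name.
SCHEMAS: dict[str, dict[str, ColumnSpec]] = {
    "bottles": _cols(
        station=S, depth_m=F, par_level=F, fraction=S, replicate=S,
        a_pn_initial=F, a_pn_final=F, a_n2=F, pn_conc_umol_l=F,
        pn_mass_ug=FN, duration_d=F,
    ),
    "rates": _cols(
        station=S, depth_m=F, fraction=S, rate_nmol_l_d=F,
        sd_nmol_l_d=FN, lod1_nmol_l_d=F, lod2_nmol_l_d=FN, flags=S,
    ),
    "rate_profiles": _cols(
        station=S, areal_rate_umol_m2_d=F, n_depths=ColumnSpec("int"),
    ),
    "plates": _cols(
        phylotype=S, well_type=S, sample_id=S, copies_per_well=FN,
        ct=FN, volume_l=FN, scaling=FN,
    ),
    "nifh": _cols(
        station=S, phylotype=S, depth_m=F, copies_per_l=F, flag=S,
    ),
    "nifh_areal": _cols(
        station=S, phylotype=S, areal_copies_m2=F, share=FN,
    ),
    "database": _cols(
        lat=F, lon=F, taxon=S, nifh_areal=F, sst=F, dfe=F, p=F,
        rate=OPT_F, method=OPT_S,
    ),
    "regions": _cols(
        region=S, area_1e6_km2=F,
        comparison_flux_geometric_tg=OPT_F, comparison_flux_arithmetic_tg=OPT_F,
    ),
    "budget": _cols(
        region=S, area_1e6_km2=F, flux_geometric_tg=F, flux_arithmetic_tg=F,
        comparison_flux_geometric_tg=OPT_F, comparison_flux_arithmetic_tg=OPT_F,
        additional_flux_geometric_tg=OPT_F, additional_flux_arithmetic_tg=OPT_F,
    ),
    "incubation_truth": _cols(station=S, depth_m=F, true_rate_nmol_l_d=F),
    "qpcr_truth": _cols(sample_id=S, true_copies_per_well=F, true_copies_per_l=F),
    "database_truth": _cols(
        taxon=S, record=ColumnSpec("int"), log10_true_abundance=F,
        censored=S,
    ),
    "region_table": _cols(
        region_id=ColumnSpec("int"), taxon=S,
        n_cells=ColumnSpec("int"), area_1e6_km2=F,
    ),
}


def read_table(path: str, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises :class:`SchemaError` naming the missing column or the
    offending data row (1-based, excluding the header).
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c, s in spec.items() if s.required and c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in spec]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}")
    out = {}
    for col in df.columns:
        s = spec[col]
        raw = df[col]
        if s.dtype == "str":
            out[col] = raw
            continue
        empty = raw.str.strip() == ""
        converted = pd.to_numeric(raw.where(~empty), errors="coerce")
        bad = converted.isna() & ~empty
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise SchemaError(
                f"{path}: non-numeric value {raw[bad].iloc[0]!r} in column "
                f"{col!r} at data row {row}"
            )
        if not s.allow_nan and converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 1
            raise SchemaError(
                f"{path}: missing value in required column {col!r} at data row {row}"
            )
        if s.dtype == "int":
            out[col] = converted.astype("Int64")
        else:
            out[col] = converted.astype(float)
    return pd.DataFrame(out)


def write_table(df: pd.DataFrame, path: str, schema: str) -> None:
    """Validate a frame against a named schema and write it as CSV."""
    spec = SCHEMAS[schema]
    missing = [c for c, s in spec.items() if s.required and c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {schema}: missing column(s) {missing}")
    unknown = [c for c in df.columns if c not in spec]
    if unknown:
        raise SchemaError(f"cannot write {schema}: unknown column(s) {unknown}")
    df.to_csv(path, index=False)


def _normalize_lon(ds: xr.Dataset) -> xr.Dataset:
    lon = ds.lon.values
    if lon.max() > 180.0:
        ds = ds.assign_coords(lon=((lon + 180.0) % 360.0) - 180.0)
        ds = ds.sortby("lon")
    return ds


def read_grid(path: str) -> EnvGrid:
    """Read an environmental grid from netCDF.

    Accepts a ``time`` dimension as an alias for ``month`` and
    longitudes on 0..360, which are relabeled to -180..180.
    """
    ds = xr.open_dataset(path, engine="scipy").load()
    if "time" in ds.dims and "month" not in ds.dims:
        ds = ds.rename({"time": "month"})
    if "month" not in ds.dims:
        raise ValueError(f"{path}: no month/time dimension")
    for v in ("lat", "lon"):
        if v not in ds.coords:
            raise ValueError(f"{path}: missing coordinate {v!r}")
    ds = _normalize_lon(ds)
    return EnvGrid(ds)


def write_grid(env: EnvGrid, path: str) -> None:
    env.data.to_netcdf(path, engine="scipy")


def write_abundance_map(amap: AbundanceMap, path: str) -> None:
    amap.to_dataset().to_netcdf(path, engine="scipy")


def read_abundance_map(path: str) -> AbundanceMap:
    ds = xr.open_dataset(path, engine="scipy").load()
    return AbundanceMap(
        taxon=str(ds.attrs.get("taxon", "")),
        lat=ds.lat.values,
        lon=ds.lon.values,
        abundance=ds["abundance"].values,
        extrapolated=ds["extrapolated"].values.astype(bool),
    )
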