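"""Regional N2-fixation budgets in Tg N yr-1.

Depth-integrated rates (umol N m-2 d-1) over a region area (10^6 km2)
convert to an annual nitrogen mass flux with molar mass 14.007 g mol-1
and a 365-day year:

    flux[Tg N yr-1] = rate * 1e-6 mol * 14.007 g/mol * 365 d
                      * area * 1e12 m2 * 1e-12 Tg/g

Regional mean rates come in geometric and arithmetic flavours, with
optional exclusion of measurement methods known to bias low (the 15N2
gas-bubble method and the acetylene reduction assay).  The module also
converts areal nifH gene abundance into a cell-based estimate of the
fraction of bulk N2 fixation attributable to a single taxon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_MOLAR_MASS_G",
    "DAYS_PER_YEAR",
    "DEFAULT_METHOD_EXCLUSIONS",
    "RegionBudget",
    "regional_mean_rates",
    "flux_tg_per_year",
    "budget_table",
    "ucynb_contribution",
]

N_MOLAR_MASS_G = 14.007
DAYS_PER_YEAR = 365.0

#: Rate-measurement methods excluded from re-evaluated means by default.
DEFAULT_METHOD_EXCLUSIONS = frozenset({"bubble", "ARA"})


@dataclass
class RegionBudget:
    """One region's areal mean rates and annual fluxes."""

    region: str
    area_1e6_km2: float
    mean_rate_geometric: float
    mean_rate_arithmetic: float
    flux_geometric_tg: float
    flux_arithmetic_tg: float
    n_observations: int | None = None
    comparison_flux_geometric_tg: float | None = None
    comparison_flux_arithmetic_tg: float | None = None

    @property
    def additional_flux_geometric_tg(self) -> float | None:
        if self.comparison_flux_geometric_tg is None:
            return None
        return self.flux_geometric_tg - self.comparison_flux_geometric_tg

    @property
    def additional_flux_arithmetic_tg(self) -> float | None:
        if self.comparison_flux_arithmetic_tg is None:
            return None
        return self.flux_arithmetic_tg - self.comparison_flux_arithmetic_tg


def regional_mean_rates(
    rates: Sequence[float],
    methods: Sequence[str] | None = None,
    method_exclusions: Iterable[str] = DEFAULT_METHOD_EXCLUSIONS,
) -> tuple[float, float, int]:
    """Geometric and arithmetic mean areal rates over a selection.

    The geometric mean is exp(mean(ln r)) over strictly positive rates;
    zero or negative rates (non-detects) are excluded from it but kept
    in the arithmetic mean.  ``methods`` tags, when given, drop records
    whose method is in ``method_exclusions`` before either mean.

    Returns
    -------
    (geometric, arithmetic, n_used) with rates in umol N m-2 d-1.
    """
    r = np.asarray(rates, dtype=float)
    if methods is not None:
        if len(methods) != r.size:
            raise ValueError("methods must align with rates")
        excl = set(method_exclusions)
        keep = np.array([m not in excl for m in methods])
        r = r[keep]
    if r.size == 0:
        raise ValueError("no rates left after filtering")
    arith = float(r.mean())
    pos = r[r > 0]
    geo = float(np.exp(np.mean(np.log(pos)))) if pos.size else float("nan")
    return geo, arith, int(r.size)


def flux_tg_per_year(rate_umol_m2_d: float, area_1e6_km2: float) -> float:
    """Annual N flux, Tg N yr-1, from an areal rate and a region area."""
    if rate_umol_m2_d < 0 or area_1e6_km2 < 0:
        raise ValueError("rate and area must be non-negative")
    return (
        rate_umol_m2_d
        * 1e-6
        * N_MOLAR_MASS_G
        * DAYS_PER_YEAR
        * area_1e6_km2
        * 1e12
        * 1e-12
    )


def budget_table(
    regions: Sequence[tuple[str, float]],
    rates: tuple[float, float],
    comparison_fluxes: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-region and total fluxes from a shared pair of mean rates.

    A single (geometric, arithmetic) rate pair — measured in the
    observed region — is applied across every region area, mirroring
    the budget construction for regions without their own rate
    observations.  ``comparison_fluxes`` optionally supplies externally
    estimated (geometric, arithmetic) fluxes per region; an
    additional-flux column (re-evaluated minus comparison) is then
    attached.  A ``Total`` row sums all columns; values are unrounded.
    """
    names = [n for n, _ in regions]
    if len(set(names)) != len(names):
        raise ValueError("duplicate region names")
    geo_rate, arith_rate = rates
    rows = []
    for name, area in regions:
        if area <= 0:
            raise ValueError(f"region {name!r} has non-positive area")
        row = {
            "region": name,
            "area_1e6_km2": area,
            "flux_geometric_tg": flux_tg_per_year(geo_rate, area),
            "flux_arithmetic_tg": flux_tg_per_year(arith_rate, area),
        }
        if comparison_fluxes is not None and name in comparison_fluxes:
            cg, ca = comparison_fluxes[name]
            row["comparison_flux_geometric_tg"] = cg
            row["comparison_flux_arithmetic_tg"] = ca
            row["additional_flux_geometric_tg"] = row["flux_geometric_tg"] - cg
            row["additional_flux_arithmetic_tg"] = row["flux_arithmetic_tg"] - ca
        rows.append(row)
    df = pd.DataFrame(rows)
    total = {"region": "Total"}
    for col in df.columns:
        if col != "region":
            total[col] = float(df[col].sum())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def ucynb_contribution(
    nifh_areal: float,
    polyploidy: float,
    cell_rate_fmol_d: float,
    bulk_rate_umol_m2_d: float,
    *,
    uncertainty: Mapping[str, float] | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, tuple[float, float] | None]:
    """Fraction of bulk N2 fixation attributable to a taxon, %.

    Cells m-2 = nifh_areal / polyploidy (gene copies per cell); taxon
    rate = cells x cell-specific rate (fmol N cell-1 d-1, converted to
    umol with 1e-9); fraction = taxon rate / bulk rate x 100.  The
    fraction may exceed 100% and is never clipped.

    ``uncertainty`` maps any of {"nifh_areal", "polyploidy",
    "cell_rate", "bulk_rate"} to a lognormal geometric SD factor (>1);
    a seeded Monte-Carlo then yields a 95% CI.  With no uncertainty (or
    all factors 1) the CI collapses to the point estimate.
    """
    for name, v in (
        ("nifh_areal", nifh_areal),
        ("polyploidy", polyploidy),
        ("cell_rate_fmol_d", cell_rate_fmol_d),
        ("bulk_rate_umol_m2_d", bulk_rate_umol_m2_d),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")

    def fraction(na: float, pp: float, cr: float, br: float) -> float:
        cells_m2 = na / pp
        taxon_rate = cells_m2 * cr * 1e-9  # umol N m-2 d-1
        return taxon_rate / br * 100.0

    point = fraction(nifh_areal, polyploidy, cell_rate_fmol_d, bulk_rate_umol_m2_d)
    if not uncertainty:
        return point, None

    rng = np.random.default_rng(seed)

    def draws(center: float, key: str) -> np.ndarray:
        gsd = uncertainty.get(key, 1.0)
        if gsd < 1.0:
            raise ValueError(f"geometric SD factor for {key} must be >= 1")
        if gsd == 1.0:
            return np.full(n_draws, center)
        return center * np.exp(rng.normal(0.0, math.log(gsd), n_draws))

    fr = fraction(
        draws(nifh_areal, "nifh_areal"),
        draws(polyploidy, "polyploidy"),
        draws(cell_rate_fmol_d, "cell_rate"),
        draws(bulk_rate_umol_m2_d, "bulk_rate"),
    )
    lo, hi = np.percentile(fr, [2.5, 97.5])
    return point, (float(lo), float(hi))
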