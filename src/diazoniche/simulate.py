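"""Synthetic study data with known ground truth.

Every input the pipeline consumes can be generated here: per-bottle
15N2 incubation tables, qPCR plates, a global diazotroph database and
monthly 1-degree environmental climatologies.  Each generator hides
its ground truth (true rates, true copy numbers, noiseless niche
responses) in a separate sidecar structure so that downstream
estimators can be tested for recovery without the truth leaking into
the analysis-facing tables.

The default conditions emulate a (sub)tropical open-ocean study:
stations sampled at six light depths (100/50/25/10/1/0.1% of surface
PAR), 24-hour incubations, bulk N2-pool enrichment around 1.41 atom%
(SD 0.083) and 1.56 atom% (SD 0.077) for the <10 um fraction, qPCR
standards spanning 10^0..10^6 copies per well in triplicate, a global
database of 737 stations with lognormal abundance scatter of 0.5
log10 units around smooth niche response surfaces, and four modelled
taxa whose niches differ in thermal optimum, iron ramp and phosphate
peak.

All randomness flows from a single seed through independent
deterministic substreams, so a fixed seed regenerates byte-identical
datasets.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from . import rates as _rates
from .projection import EnvGrid
from .qpcr import QpcrPlate

__all__ = [
    "NicheTruth",
    "SimulationConfig",
    "default_niche_truths",
    "make_incubation_table",
    "make_qpcr_plate",
    "make_global_database",
    "make_env_grids",
]

PAR_LEVELS = (100.0, 50.0, 25.0, 10.0, 1.0, 0.1)


@dataclass
class NicheTruth:
    """The data-generating niche of one taxon.

    Each response maps a covariate value to its additive contribution
    to log10 areal abundance; ``intercept`` sets the overall level and
    ``noise_sd`` the SD of Gaussian scatter on the log10 scale.
    """

    taxon: str
    response_sst: Callable[[np.ndarray], np.ndarray]
    response_dfe: Callable[[np.ndarray], np.ndarray]
    response_p: Callable[[np.ndarray], np.ndarray]
    intercept: float
    noise_sd: float = 0.5

    def log10_abundance(self, sst, dfe, p) -> np.ndarray:
        out = (
            self.intercept
            + np.asarray(self.response_sst(np.asarray(sst, dtype=float)))
            + np.asarray(self.response_dfe(np.asarray(dfe, dtype=float)))
            + np.asarray(self.response_p(np.asarray(p, dtype=float)))
        )
        if not np.all(np.isfinite(out)):
            raise ValueError(f"niche responses for {self.taxon!r} are not finite")
        return out


def _bump(center: float, width: float, amplitude: float):
    def f(x):
        return amplitude * np.exp(-0.5 * ((x - center) / width) ** 2)

    return f


def _ramp(threshold: float, steepness: float, amplitude: float):
    """Saturating logistic ramp: ~0 below threshold, ~amplitude above."""

    def f(x):
        return amplitude / (1.0 + np.exp(-(x - threshold) / steepness))

    return f


def default_niche_truths() -> dict[str, NicheTruth]:
    """Niche truths for the four modelled cyanobacterial diazotrophs.

    UCYN-B: narrow warm thermal niche peaking at 27.5 degC, sharp
    decline in abundance below a dissolved-iron ramp at 0.2 nM, and a
    phosphate optimum near 0.1 uM.  The other three taxa shift those
    features (Trichodesmium warm/wider with a higher iron demand,
    UCYN-A cooler and broader, Richelia warm with the weakest overall
    abundance).
    """
    return {
        "UCYN-B": NicheTruth(
            "UCYN-B",
            response_sst=_bump(27.5, 3.0, 4.0),
            response_dfe=_ramp(0.2, 0.1, 1.5),
            response_p=_bump(0.1, 0.25, 2.0),
            intercept=4.5,
        ),
        "Trichodesmium": NicheTruth(
            "Trichodesmium",
            response_sst=_bump(26.5, 3.0, 3.0),
            response_dfe=_ramp(0.4, 0.08, 2.0),
            response_p=_bump(0.15, 0.2, 1.5),
            intercept=4.8,
        ),
        "UCYN-A": NicheTruth(
            "UCYN-A",
            response_sst=_bump(18.0, 6.0, 3.0),
            response_dfe=_ramp(0.1, 0.05, 1.0),
            response_p=_bump(0.4, 0.4, 1.5),
            intercept=5.0,
        ),
        "Richelia": NicheTruth(
            "Richelia",
            response_sst=_bump(27.0, 3.5, 3.0),
            response_dfe=_ramp(0.5, 0.1, 1.5),
            response_p=_bump(0.2, 0.25, 1.2),
            intercept=4.2,
        ),
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    # incubations
    n_stations: int = 12
    n_depths: int = 6
    duration_d: float = 1.0
    surface_rate_median_nmol_l_d: float = 5.0  # lognormal median across stations
    surface_rate_gsd: float = 2.0  # geometric SD factor
    rate_decay_scale_m: float = 60.0
    pn_conc_umol_l: float = 0.5
    apn_noise_sd: float = 0.00017  # IRMS repeatability on atom%
    light_attenuation_per_m: float = 0.06
    # qPCR
    standard_levels: tuple[float, ...] = (1e0, 1e1, 1e2, 1e3, 1e4, 1e5, 1e6)
    standard_replicates: int = 3
    qpcr_slope: float = -3.3219
    qpcr_intercept: float = 37.0
    ct_noise_sd: float = 0.1
    # global database
    n_db_records: int = 737
    sst_range: tuple[float, float] = (2.0, 32.0)
    dfe_range: tuple[float, float] = (0.01, 1.2)
    p_range: tuple[float, float] = (0.01, 1.5)
    nondetect_fraction: float = 0.18
    rate_fraction: float = 0.3
    method_probs: Mapping[str, float] = field(
        default_factory=lambda: {"dissolution": 0.5, "bubble": 0.3, "ARA": 0.2}
    )
    # regions for flux tests
    regions: tuple[tuple[str, float], ...] = (
        ("Western North Pacific", 7.18),
        ("South Pacific", 2.20),
        ("Indian Ocean", 5.10),
        ("South Atlantic", 0.45),
    )

    def validate(self) -> None:
        if self.n_depths < 2:
            raise ValueError("n_depths must be >= 2")
        if self.n_stations < 1:
            raise ValueError("n_stations must be >= 1")
        if any(c <= 0 for c in self.standard_levels):
            raise ValueError("standard copies must be positive")
        if not 0 <= self.nondetect_fraction < 1:
            raise ValueError("nondetect_fraction must be in [0, 1)")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic substream: one global seed, split per generator."""
        key = zlib.crc32(stream.encode("utf-8"))
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


def _par_depths(config: SimulationConfig) -> np.ndarray:
    """Depths (m) of the PAR sampling levels under exponential attenuation."""
    levels = np.array(PAR_LEVELS[: config.n_depths])
    depths = -np.log(levels / 100.0) / config.light_attenuation_per_m
    depths[0] = 5.0  # surface bottle drawn from ~5 m
    return depths


def make_incubation_table(
    config: SimulationConfig,
    *,
    noise: bool = True,
    true_rates: Mapping[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bottle incubation table plus a hidden-truth sidecar.

    Each station is sampled at ``n_depths`` PAR levels in duplicate
    (bulk fraction) plus one <10 um bottle per depth.  A station's true
    volumetric rate profile decays exponentially from a lognormal
    surface rate; duplicates share the true rate.  The measured
    A_PN_final is obtained by inverting the tracer rate equation at the
    bottle's drawn N2-pool enrichment and adding Gaussian measurement
    noise (none when ``noise=False``).

    Returns
    -------
    (bottles, truth) : bottles has one row per bottle with the columns
    of the ``bottles`` CSV schema; truth has one row per
    station x depth with the true rate in nmol N L-1 d-1.
    """
    config.validate()
    rng = config.rng("incubation")
    depths = _par_depths(config)
    rows, truth_rows = [], []
    for s in range(config.n_stations):
        station = f"ST{s + 1:02d}"
        if true_rates is not None and station in true_rates:
            profile = np.asarray(true_rates[station], dtype=float)
        else:
            surface = config.surface_rate_median_nmol_l_d * math.exp(
                rng.normal(0.0, math.log(config.surface_rate_gsd))
            )
            profile = surface * np.exp(-depths / config.rate_decay_scale_m)
        for d, (depth, par, true_rate) in enumerate(
            zip(depths, PAR_LEVELS, profile)
        ):
            truth_rows.append(
                {"station": station, "depth_m": depth, "true_rate_nmol_l_d": true_rate}
            )
            for fraction, reps in (("bulk", ("a", "b")), ("lt10um", ("a",))):
                if fraction == "bulk":
                    enr_mean, enr_sd = (
                        _rates.BULK_ENRICHMENT_ATOM_PCT,
                        _rates.BULK_ENRICHMENT_SD,
                    )
                    frac_rate = true_rate
                else:
                    enr_mean, enr_sd = (
                        _rates.SMALL_FRACTION_ENRICHMENT_ATOM_PCT,
                        _rates.SMALL_FRACTION_ENRICHMENT_SD,
                    )
                    frac_rate = 0.8 * true_rate  # small cells carry most fixation
                for rep in reps:
                    a_n2 = enr_mean + (rng.normal(0.0, enr_sd) if noise else 0.0)
                    a_n2 = max(a_n2, _rates.NATURAL_ABUNDANCE_ATOM_PCT + 0.1)
                    a0 = _rates.NATURAL_ABUNDANCE_ATOM_PCT
                    af = _rates.invert_rate(
                        frac_rate, a0, a_n2, config.pn_conc_umol_l, config.duration_d
                    )
                    if noise:
                        af += rng.normal(0.0, config.apn_noise_sd)
                    rows.append(
                        {
                            "station": station,
                            "depth_m": depth,
                            "par_level": par,
                            "fraction": fraction,
                            "replicate": rep,
                            "a_pn_initial": a0,
                            "a_pn_final": af,
                            "a_n2": a_n2,
                            "pn_conc_umol_l": config.pn_conc_umol_l,
                            "pn_mass_ug": config.pn_conc_umol_l * 14.007 * 4.5,
                            "duration_d": config.duration_d,
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def make_qpcr_plate(
    config: SimulationConfig,
    true_copies_per_well: Mapping[str, float],
    phylotype: str = "UCYN-B",
    *,
    volume_l: float = 4.5,
    scaling: float = 25.0,
    noise: bool = True,
) -> tuple[QpcrPlate, pd.DataFrame]:
    """One synthetic qPCR plate plus its hidden-truth sidecar.

    Standards at the configured dilution levels and unknowns at the
    given true copies per well get Ct values from the prescribed
    standard-curve slope/intercept plus Gaussian replicate noise.
    """
    config.validate()
    if any(c <= 0 for c in true_copies_per_well.values()):
        raise ValueError("true copies per well must be positive")
    rng = config.rng(f"qpcr-{phylotype}")
    sd = config.ct_noise_sd if noise else 0.0

    def ct_of(copies: float) -> float:
        return config.qpcr_slope * math.log10(copies) + config.qpcr_intercept

    standards = {
        float(c): [ct_of(c) + rng.normal(0.0, sd) for _ in range(config.standard_replicates)]
        for c in config.standard_levels
    }
    unknowns = {
        sid: (
            [ct_of(c) + rng.normal(0.0, sd) for _ in range(3)],
            volume_l,
            scaling,
        )
        for sid, c in true_copies_per_well.items()
    }
    plate = QpcrPlate(phylotype=phylotype, standards=standards, unknowns=unknowns)
    truth = pd.DataFrame(
        {
            "sample_id": list(true_copies_per_well),
            "true_copies_per_well": list(true_copies_per_well.values()),
            "true_copies_per_l": [
                c * scaling / volume_l for c in true_copies_per_well.values()
            ],
        }
    )
    return plate, truth


def make_global_database(
    config: SimulationConfig,
    niche_truths: Mapping[str, NicheTruth] | None = None,
    *,
    noise: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic global diazotroph database plus hidden-truth sidecar.

    ``n_db_records`` stations get covariates drawn uniformly over the
    configured ranges and, per taxon, a log10 areal abundance equal to
    the taxon's niche truth plus lognormal noise.  A configurable
    fraction of station-taxon rows is censored to non-detect (0), and
    a fraction of stations carries an areal N2-fixation rate with a
    measurement-method tag; bubble-method and acetylene-reduction
    rates are biased low to emulate their known underestimation.

    Returns
    -------
    (database, truth) : long-format tables, one row per station x taxon.
    """
    if niche_truths is None:
        niche_truths = default_niche_truths()
    if not niche_truths:
        raise ValueError("need at least one niche truth")
    config.validate()
    rng = config.rng("database")
    n = config.n_db_records
    lat = rng.uniform(-45.0, 45.0, n)
    lon = rng.uniform(-180.0, 180.0, n)
    sst = rng.uniform(*config.sst_range, n)
    dfe = rng.uniform(*config.dfe_range, n)
    p = rng.uniform(*config.p_range, n)

    has_rate = rng.random(n) < config.rate_fraction
    methods = rng.choice(
        list(config.method_probs),
        size=n,
        p=np.array(list(config.method_probs.values()))
        / sum(config.method_probs.values()),
    )

    rows, truth_rows = [], []
    rate = np.full(n, np.nan)
    for name, truth in niche_truths.items():
        log10_true = truth.log10_abundance(sst, dfe, p)
        log10_obs = log10_true + (
            rng.normal(0.0, truth.noise_sd, n) if noise and truth.noise_sd > 0 else 0.0
        )
        abundance = 10.0**log10_obs
        censored = rng.random(n) < config.nondetect_fraction if noise else np.zeros(n, bool)
        abundance = np.where(censored, 0.0, abundance)
        # areal rate loosely tied to the UCYN-B true abundance
        if name == "UCYN-B":
            base_rate = 10.0 ** (log10_true - 6.0) * 100.0  # umol N m-2 d-1
            bias = np.where(
                methods == "bubble", 0.6, np.where(methods == "ARA", 0.5, 1.0)
            )
            rate_noise = (
                np.exp(rng.normal(0.0, 0.3, n)) if noise else np.ones(n)
            )
            rate = np.where(has_rate, base_rate * bias * rate_noise, np.nan)
        for i in range(n):
            rows.append(
                {
                    "lat": lat[i],
                    "lon": lon[i],
                    "taxon": name,
                    "nifh_areal": abundance[i],
                    "sst": sst[i],
                    "dfe": dfe[i],
                    "p": p[i],
                    "rate": rate[i] if name == "UCYN-B" else np.nan,
                    "method": methods[i] if (name == "UCYN-B" and has_rate[i]) else "",
                }
            )
            truth_rows.append(
                {
                    "taxon": name,
                    "record": i,
                    "log10_true_abundance": log10_true[i],
                    "censored": bool(censored[i]),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def make_env_grids(config: SimulationConfig, *, constant: bool = False) -> EnvGrid:
    """Monthly 1-degree SST/dFe/P climatology with a synthetic land mask.

    Fields have smooth latitudinal structure with a seasonal SST cycle
    and zonal gradients in dFe; two idealized rectangular continents
    provide land (NaN) cells.  ``constant=True`` makes every field
    spatially and monthly uniform (useful for degenerate-case tests).
    """
    config.validate()
    lat = np.arange(-89.5, 90.0, 1.0)
    lon = np.arange(-179.5, 180.0, 1.0)
    months = np.arange(1, 13)
    glat, glon = np.meshgrid(lat, lon, indexing="ij")

    if constant:
        sst = np.full((12, lat.size, lon.size), 27.5)
        dfe = np.full_like(sst, 0.5)
        p = np.full_like(sst, 0.1)
    else:
        sst = np.empty((12, lat.size, lon.size))
        for i, m in enumerate(months):
            seasonal = 3.0 * np.cos(2 * np.pi * (m - 2) / 12) * np.sign(glat + 1e-9)
            sst[i] = -2.0 + 32.0 * np.cos(np.radians(glat)) ** 2 + seasonal * (
                np.abs(glat) / 90.0
            )
        dfe_base = 0.08 + 0.7 * np.exp(-0.5 * (glat / 25.0) ** 2) * (
            0.4 + 0.6 * (1 + np.sin(np.radians(glon + 60))) / 2
        )
        dfe = np.repeat(dfe_base[None], 12, axis=0)
        p_base = 0.03 + 1.4 * (np.abs(glat) / 90.0) ** 1.5
        p = np.repeat(p_base[None], 12, axis=0)

    # idealized continents
    land = np.zeros((lat.size, lon.size), dtype=bool)
    land |= (glat > -35) & (glat < 70) & (glon > -20) & (glon < 50)  # afro-eurasia-ish
    land |= (glat > -55) & (glat < 60) & (glon > -120) & (glon < -60)  # americas-ish
    for f in (sst, dfe, p):
        f[:, land] = np.nan

    ds = xr.Dataset(
        {
            "sst": (("month", "lat", "lon"), sst),
            "dfe": (("month", "lat", "lon"), dfe),
            "p": (("month", "lat", "lon"), p),
        },
        coords={"month": months, "lat": lat, "lon": lon},
        attrs={"title": "synthetic 1-degree monthly climatology"},
    )
    return EnvGrid(ds)
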