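"""N2 fixation rates from 15N2-dissolution incubations.

The tracer calculation converts the 15N enrichment of particulate
nitrogen (PN) accumulated over an incubation into a volumetric N2
fixation rate:

    rho = (A_PN_final - A_PN_initial) / (A_N2 - A_PN_initial)
          * [PN] / dt

with atom% 15N of the PN pool before (``A_PN_initial``) and after
(``A_PN_final``) incubation, atom% 15N of the dissolved N2 pool during
the incubation (``A_N2``), PN concentration in umol N L-1 and duration
in days.  Rates are reported in nmol N L-1 d-1.

Two detection limits accompany each rate: LOD-1 propagates the minimal
atom%-difference the mass spectrometer can resolve through the same
equation, and LOD-2 propagates the variability observed between
duplicate bottles (delta method) together with the uncertainty of the
N2-pool enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NATURAL_ABUNDANCE_ATOM_PCT",
    "BULK_ENRICHMENT_ATOM_PCT",
    "SMALL_FRACTION_ENRICHMENT_ATOM_PCT",
    "BULK_ENRICHMENT_SD",
    "SMALL_FRACTION_ENRICHMENT_SD",
    "GENERIC_MIN_DELTA_APN",
    "IncubationSample",
    "RateResult",
    "RateProfile",
    "n2_fixation_rate",
    "min_delta_apn",
    "lod1_rate",
    "lod2_rate",
    "evaluate_sample",
    "depth_integrate",
]

#: atom% 15N of particulate nitrogen at natural abundance.
NATURAL_ABUNDANCE_ATOM_PCT = 0.3663

#: Mean atom% 15N of the dissolved N2 pool in bulk incubations, and the
#: fixed standard deviation used in error propagation.
BULK_ENRICHMENT_ATOM_PCT = 1.41
BULK_ENRICHMENT_SD = 0.083

#: Same for the <10 um size-fractionated incubations.
SMALL_FRACTION_ENRICHMENT_ATOM_PCT = 1.56
SMALL_FRACTION_ENRICHMENT_SD = 0.077

#: Generic minimal resolvable difference in A_PN (atom%), used for
#: LOD-1 on all samples.
GENERIC_MIN_DELTA_APN = 0.00146

#: PN mass (ug N on filter) below which a sample is flagged as low-mass.
LOW_PN_MASS_UG = 10.0


class TracerError(ValueError):
    """The isotope tracer is not enriched above the initial PN pool."""


@dataclass
class IncubationSample:
    """One incubation bottle's isotope and PN measurements.

    Parameters
    ----------
    station : str
        Station identifier.
    depth_m : float
        Sampling depth in metres.
    par_level : float
        Percent of surface photosynthetically active radiation at the
        sampling depth (100, 50, 25, 10, 1 or 0.1).
    fraction : str
        ``"bulk"`` or ``"lt10um"`` (<10 um size fraction).
    a_pn_initial : float
        atom% 15N of PN at t0 (natural abundance if unamended).
    a_pn_final : float
        atom% 15N of PN at the end of the incubation.
    a_n2 : float
        atom% 15N of the dissolved N2 pool during the incubation.
    pn_conc_umol_l : float
        PN concentration, umol N L-1.
    pn_mass_ug : float
        PN mass on the filter, ug N; used only for QC flags.
    duration_d : float
        Incubation duration in days.
    replicate : str
        Replicate identifier within the bottle condition.
    """

    station: str
    depth_m: float
    par_level: float
    fraction: str
    a_pn_initial: float
    a_pn_final: float
    a_n2: float
    pn_conc_umol_l: float
    pn_mass_ug: float = float("nan")
    duration_d: float = 1.0
    replicate: str = "a"

    def validate(self) -> None:
        for name in ("a_pn_initial", "a_pn_final", "a_n2"):
            v = getattr(self, name)
            if not (0.0 < v < 100.0):
                raise ValueError(f"{name}={v!r} outside (0, 100) atom%")
        if self.a_n2 <= self.a_pn_initial:
            raise TracerError(
                f"A_N2={self.a_n2} must exceed A_PN_initial={self.a_pn_initial}"
            )
        if self.duration_d <= 0:
            raise ValueError(f"duration_d={self.duration_d} must be positive")
        if self.pn_conc_umol_l <= 0:
            raise ValueError(f"pn_conc_umol_l={self.pn_conc_umol_l} must be positive")


@dataclass
class RateResult:
    """A volumetric rate with its detection limits and QC flags."""

    rate_nmol_l_d: float
    lod1_nmol_l_d: float
    sd_nmol_l_d: float | None = None
    lod2_nmol_l_d: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def below_lod1(self) -> bool:
        return "below_lod1" in self.flags

    @property
    def below_lod2(self) -> bool:
        return "below_lod2" in self.flags


@dataclass
class RateProfile:
    """Ordered (depth, rate[, sd]) tuples for one station, surface first."""

    station: str
    depths_m: Sequence[float]
    rates: Sequence[float]
    sds: Sequence[float] | None = None

    def sorted(self) -> "RateProfile":
        order = np.argsort(np.asarray(self.depths_m, dtype=float))
        return RateProfile(
            station=self.station,
            depths_m=tuple(np.asarray(self.depths_m, dtype=float)[order]),
            rates=tuple(np.asarray(self.rates, dtype=float)[order]),
            sds=None
            if self.sds is None
            else tuple(np.asarray(self.sds, dtype=float)[order]),
        )


def _rate_from_delta(
    delta_apn: float,
    a_n2: float,
    a_pn_initial: float,
    pn_conc_umol_l: float,
    duration_d: float,
) -> float:
    # umol L-1 d-1 -> nmol L-1 d-1 (x1000)
    return delta_apn / (a_n2 - a_pn_initial) * pn_conc_umol_l / duration_d * 1000.0


def n2_fixation_rate(sample: IncubationSample, *, clip_negative: bool = True) -> float:
    """Volumetric N2 fixation rate of one bottle, nmol N L-1 d-1.

    Negative enrichment (final atom% below initial) yields a rate of 0
    when ``clip_negative`` (the default); the raw signed value is
    returned otherwise.
    """
    sample.validate()
    rho = _rate_from_delta(
        sample.a_pn_final - sample.a_pn_initial,
        sample.a_n2,
        sample.a_pn_initial,
        sample.pn_conc_umol_l,
        sample.duration_d,
    )
    if clip_negative and rho < 0:
        return 0.0
    return rho


def invert_rate(
    rate_nmol_l_d: float,
    a_pn_initial: float,
    a_n2: float,
    pn_conc_umol_l: float,
    duration_d: float,
) -> float:
    """A_PN_final that produces ``rate_nmol_l_d`` — the exact inverse of
    :func:`n2_fixation_rate`.  Used by the synthetic-data generator."""
    delta = rate_nmol_l_d / 1000.0 * duration_d / pn_conc_umol_l * (a_n2 - a_pn_initial)
    return a_pn_initial + delta


def min_delta_apn(sd_standards_atom_pct: float, n: int = 5) -> float:
    """Minimal resolvable A_PN difference: 3 x SD of replicate standard
    measurements (atom%).  ``n`` records how many standards entered the SD."""
    if sd_standards_atom_pct < 0:
        raise ValueError("standard deviation must be non-negative")
    return 3.0 * sd_standards_atom_pct


def lod1_rate(
    sample: IncubationSample, min_da: float = GENERIC_MIN_DELTA_APN
) -> float:
    """LOD-1: the rate equation evaluated at the minimal resolvable
    atom% difference, nmol N L-1 d-1."""
    sample.validate()
    return _rate_from_delta(
        min_da, sample.a_n2, sample.a_pn_initial, sample.pn_conc_umol_l, sample.duration_d
    )


def lod2_rate(
    duplicates: Sequence[IncubationSample],
    sd_a_n2: float = BULK_ENRICHMENT_SD,
    multiplier: float = 3.0,
) -> tuple[float, float]:
    """Delta-method rate SD from duplicate bottles, and LOD-2.

    The rate is a function of (A_PN_final, PN, A_N2); its first-order
    variance combines the between-duplicate SDs of A_PN_final and PN
    with the fixed SD of the N2-pool enrichment:

        var(rho) = (d rho/d Af)^2 sd_Af^2 + (d rho/d PN)^2 sd_PN^2
                 + (d rho/d A_N2)^2 sd_A_N2^2

    evaluated at the duplicate means.  LOD-2 = ``multiplier`` x sd.

    Returns
    -------
    (sd, lod2) in nmol N L-1 d-1.
    """
    if len(duplicates) != 2:
        raise ValueError("lod2_rate requires exactly two duplicate samples")
    a, b = duplicates
    for s in duplicates:
        s.validate()
    if (a.station, a.depth_m, a.fraction) != (b.station, b.depth_m, b.fraction):
        raise ValueError("duplicates must share station, depth and fraction")

    af = np.array([a.a_pn_final, b.a_pn_final])
    pn = np.array([a.pn_conc_umol_l, b.pn_conc_umol_l])
    a0 = float(np.mean([a.a_pn_initial, b.a_pn_initial]))
    an2 = float(np.mean([a.a_n2, b.a_n2]))
    dt = float(np.mean([a.duration_d, b.duration_d]))

    sd_af = float(np.std(af, ddof=1))
    sd_pn = float(np.std(pn, ddof=1))
    af_m, pn_m = float(af.mean()), float(pn.mean())

    denom = an2 - a0
    # partial derivatives of rho (nmol L-1 d-1)
    d_af = pn_m / (denom * dt) * 1000.0
    d_pn = (af_m - a0) / (denom * dt) * 1000.0
    d_an2 = -(af_m - a0) * pn_m / (denom**2 * dt) * 1000.0

    var = (d_af * sd_af) ** 2 + (d_pn * sd_pn) ** 2 + (d_an2 * sd_a_n2) ** 2
    sd = math.sqrt(var)
    return sd, multiplier * sd


def evaluate_sample(
    sample: IncubationSample,
    duplicate: IncubationSample | None = None,
    *,
    min_da: float = GENERIC_MIN_DELTA_APN,
    sd_a_n2: float | None = None,
    lod_multiplier: float = 3.0,
) -> RateResult:
    """Rate + LODs + flags for one bottle (optionally with its duplicate).

    ``sd_a_n2`` defaults to the fraction-appropriate fixed SD of the
    N2-pool enrichment (0.083 atom% bulk, 0.077 atom% <10 um).
    """
    raw = n2_fixation_rate(sample, clip_negative=False)
    flags: list[str] = []
    rate = raw
    if raw < 0:
        rate = 0.0
        flags.append("negative_enrichment")
    lod1 = lod1_rate(sample, min_da)
    if rate < lod1:
        flags.append("below_lod1")
    if not math.isnan(sample.pn_mass_ug) and sample.pn_mass_ug < LOW_PN_MASS_UG:
        flags.append("low_pn_mass")

    sd = lod2 = None
    if duplicate is not None:
        if sd_a_n2 is None:
            sd_a_n2 = (
                SMALL_FRACTION_ENRICHMENT_SD
                if sample.fraction == "lt10um"
                else BULK_ENRICHMENT_SD
            )
        sd, lod2 = lod2_rate([sample, duplicate], sd_a_n2, lod_multiplier)
        if rate < lod2:
            flags.append("below_lod2")
    if not flags:
        flags.append("ok")
    return RateResult(
        rate_nmol_l_d=rate,
        lod1_nmol_l_d=lod1,
        sd_nmol_l_d=sd,
        lod2_nmol_l_d=lod2,
        flags=tuple(flags),
    )


def depth_integrate(profile: RateProfile) -> float:
    """Trapezoidal depth integral of a volumetric-rate profile.

    The shallowest measured rate is extended unchanged to 0 m and the
    integral is truncated at the deepest sampled depth.  With rates in
    nmol N L-1 d-1 (= umol N m-3 d-1) and depths in metres the result
    is in umol N m-2 d-1.
    """
    p = profile.sorted()
    depths = np.asarray(p.depths_m, dtype=float)
    rates = np.asarray(p.rates, dtype=float)
    if depths.size < 2:
        raise ValueError("depth integration needs at least two depths")
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly increasing")
    if depths[0] > 0:
        depths = np.concatenate([[0.0], depths])
        rates = np.concatenate([[rates[0]], rates])
    return float(np.trapezoid(rates, depths))
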