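"""Absolute nifH gene quantification from qPCR plates.

A dilution series of plasmid standards (10^0 .. 10^6 copies per well)
run on each plate yields a standard curve Ct = slope * log10(copies) +
intercept; unknowns are inverted through the curve and converted to
copies per litre of seawater filtered.  Depth profiles of copies L-1
are trapezoid-integrated to areal abundances (copies m-2), and
community shares are computed across phylotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LOD_COPIES_PER_L",
    "LOQ_COPIES_PER_L",
    "PHYLOTYPES",
    "QpcrPlate",
    "StandardCurve",
    "NifhProfile",
    "fit_standard_curve",
    "quantify",
    "depth_integrate_nifh",
    "community_shares",
]

#: Assay detection and quantification limits, nifH copies per litre.
LOD_COPIES_PER_L = 25.0
LOQ_COPIES_PER_L = 250.0

#: The five phylotypes quantified by the assay set.
PHYLOTYPES = ("Trichodesmium", "UCYN-A1", "UCYN-A2/A3", "UCYN-B", "Het-1")

#: Ct-per-decade slope of a perfectly doubling assay: -1/log10(2).
PERFECT_SLOPE = -1.0 / math.log10(2.0)


class AssayFailure(ValueError):
    """The standard curve is unusable (non-negative slope or singular fit)."""


@dataclass
class StandardCurve:
    """Fitted standard curve: Ct = slope * log10(copies/well) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_levels: int

    @property
    def efficiency_pct(self) -> float:
        """Amplification efficiency, % ; 100% means perfect doubling."""
        return (10.0 ** (-1.0 / self.slope) - 1.0) * 100.0

    def copies_per_well(self, mean_ct: float) -> float:
        return 10.0 ** ((mean_ct - self.intercept) / self.slope)

    def ct_of(self, copies_per_well: float) -> float:
        return self.slope * math.log10(copies_per_well) + self.intercept


@dataclass
class QpcrPlate:
    """One 96-well plate: standards plus unknowns for a single phylotype.

    ``standards`` maps copies-per-well to replicate Ct values;
    ``unknowns`` maps sample id to (Ct replicates, filtered volume L,
    scaling factor).  The scaling factor converts copies per well to
    copies in the whole DNA extract (elution volume / template volume
    per reaction); it has no hidden default.
    """

    phylotype: str
    standards: Mapping[float, Sequence[float]]
    unknowns: Mapping[str, tuple[Sequence[float], float, float]] = field(
        default_factory=dict
    )

    def validate(self) -> None:
        if self.phylotype not in PHYLOTYPES:
            raise ValueError(f"unknown phylotype {self.phylotype!r}")
        copies = np.array(sorted(self.standards), dtype=float)
        if np.any(copies <= 0):
            raise ValueError("standard copies must be positive")
        if len(copies) < 3:
            raise ValueError("need at least three standard levels")
        decades = math.log10(copies[-1]) - math.log10(copies[0])
        if decades < 3 - 1e-9:
            raise ValueError("standards must span at least three decades")


def fit_standard_curve(
    standards: Mapping[float, Sequence[float]]
) -> StandardCurve:
    """OLS fit of mean Ct on log10 copies per well.

    Raises :class:`AssayFailure` on a non-negative slope (no
    amplification trend) or a degenerate design.
    """
    levels = sorted(standards)
    if len(levels) < 3:
        raise ValueError("need at least three standard levels")
    x = np.log10(np.asarray(levels, dtype=float))
    y = np.array([float(np.mean(standards[c])) for c in levels])
    if np.ptp(x) == 0:
        raise AssayFailure("standard levels are not distinct")
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise AssayFailure(f"non-negative standard-curve slope {slope:.3f}")
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(
        slope=float(slope), intercept=float(intercept), r_squared=r2, n_levels=len(levels)
    )


def quantify(
    ct_replicates: Sequence[float],
    curve: StandardCurve,
    volume_l: float,
    scaling: float,
    *,
    min_amplified: int = 2,
) -> tuple[float, str]:
    """Copies per litre for one unknown, with a QC flag.

    Non-amplified wells are recorded as NaN in ``ct_replicates`` and
    dropped before averaging; at least ``min_amplified`` amplified
    wells are required for an ``ok``/``<LOQ`` call.  If no well
    amplified the sample is reported as 0 copies L-1, flagged ``<LOD``.

    Returns
    -------
    (copies_per_litre, flag) with flag in {"ok", "<LOQ", "<LOD"}.
    """
    if volume_l <= 0:
        raise ValueError("filtered volume must be positive")
    if scaling <= 0:
        raise ValueError("scaling factor must be positive")
    cts = np.asarray(ct_replicates, dtype=float)
    amplified = cts[np.isfinite(cts)]
    if amplified.size == 0:
        return 0.0, "<LOD"
    mean_ct = float(amplified.mean())
    copies_l = curve.copies_per_well(mean_ct) * scaling / volume_l
    if copies_l < LOD_COPIES_PER_L or amplified.size < min_amplified:
        flag = "<LOD"
    elif copies_l < LOQ_COPIES_PER_L:
        flag = "<LOQ"
    else:
        flag = "ok"
    return copies_l, flag


@dataclass
class NifhProfile:
    """Depth profile of one phylotype's abundance at one station."""

    station: str
    phylotype: str
    depths_m: Sequence[float]
    copies_per_l: Sequence[float]
    flags: Sequence[str] | None = None


def depth_integrate_nifh(
    profile: NifhProfile, *, below_lod_value: float = 0.0
) -> float:
    """Areal nifH abundance, copies m-2, by trapezoidal integration.

    Copies L-1 are converted to copies m-3 (x1000); the shallowest
    value extends to 0 m and the integral stops at the deepest sampled
    depth.  Values flagged ``<LOD`` are substituted with
    ``below_lod_value`` (default 0); ``<LOQ`` values enter at face
    value.
    """
    depths = np.asarray(profile.depths_m, dtype=float)
    copies = np.asarray(profile.copies_per_l, dtype=float).copy()
    if depths.size < 2:
        raise ValueError("depth integration needs at least two depths")
    if np.any(copies < 0):
        raise ValueError("copies must be non-negative")
    if profile.flags is not None:
        flags = np.asarray(profile.flags, dtype=object)
        copies[flags == "<LOD"] = below_lod_value
    order = np.argsort(depths)
    depths, copies = depths[order], copies[order]
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly increasing")
    if depths[0] > 0:
        depths = np.concatenate([[0.0], depths])
        copies = np.concatenate([[copies[0]], copies])
    return float(np.trapezoid(copies * 1000.0, depths))


def community_shares(
    abundances: Mapping[str, float]
) -> tuple[dict[str, float], bool]:
    """Fractional shares of each phylotype in the summed abundance.

    Returns ``(shares, defined)``; when every abundance is zero the
    shares are NaN and ``defined`` is False.
    """
    if not abundances:
        raise ValueError("need at least one abundance")
    vals = np.array([abundances[k] for k in abundances], dtype=float)
    if np.any(vals < 0):
        raise ValueError("abundances must be non-negative")
    total = vals.sum()
    if total == 0:
        return {k: float("nan") for k in abundances}, False
    return {k: float(v / total) for k, v in zip(abundances, vals)}, True
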