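"""Per-taxon ecological niche models for diazotroph abundance.

The niche of each diazotroph phylotype is modelled as a Gaussian-family
generalized additive model of log10 depth-integrated nifH gene
abundance (copies m-2) on three environmental covariates:

    log10(N) ~ s(SST) + s(dFe) + s(P)

with one penalized cubic B-spline smooth per covariate (basis
dimension 6 by default).  The per-term penalty weights are chosen by
generalized cross-validation (a coordinate search over a log-spaced
grid); statsmodels' AIC-based ``select_penweight`` is available as an
alternative.  Fitted models expose centered partial-response curves
with 95% confidence bands, clamp-to-hull prediction for safe gridded
projection, and a JSON serialization (knots, coefficients, penalties
and dense effect grids) so projections are reproducible without
refitting.

Abundance zeros cannot enter a log10 response; by default they are
dropped before fitting (non-detects carry no usable magnitude), with a
detection-floor substitution available instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "DEFAULT_COVARIATES",
    "GamFit",
    "ResponseCurve",
    "fit_gam",
    "partial_response",
    "predict_log_abundance",
]

DEFAULT_COVARIATES = ("sst", "dfe", "p")

#: Number of points in the serialized partial-effect grids.
_GRID_N = 512


@dataclass
class ResponseCurve:
    """Centered partial effect of one covariate on log10 abundance."""

    covariate: str
    grid: np.ndarray
    effect: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    rug: np.ndarray | None = None

    @property
    def argmax(self) -> float:
        """Covariate value at which the partial effect peaks."""
        return float(self.grid[int(np.argmax(self.effect))])


@dataclass
class GamFit:
    """A fitted additive niche model for one taxon.

    Holds the fitted coefficients, per-term penalty weights, training
    medians/ranges (the prediction hull) and fit statistics.  When
    produced by :func:`fit_gam` the live statsmodels results object is
    retained and predictions go through it exactly; a model restored
    from JSON predicts from dense per-term effect grids instead.
    """

    taxon: str
    covariates: tuple[str, ...]
    intercept: float
    alpha: tuple[float, ...]
    n_used: int
    r_squared: float
    deviance_explained: float
    p_values: dict[str, float]
    medians: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    knots: dict[str, list[float]]
    degree: int
    coefficients: dict[str, list[float]]
    effect_grids: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    rug: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _results: object | None = field(default=None, repr=False, compare=False)
    _smoother: object | None = field(default=None, repr=False, compare=False)

    # -- raw (uncentered) per-term effects -------------------------------

    def _term_effect(self, covariate: str, x: np.ndarray) -> np.ndarray:
        """Spline contribution of one covariate, evaluated at clamped x."""
        lo, hi = self.ranges[covariate]
        xc = np.clip(np.asarray(x, dtype=float), lo, hi)
        if self._smoother is not None:
            k = self.covariates.index(covariate)
            basis = self._smoother.smoothers[k].transform(xc)
            return basis @ np.asarray(self.coefficients[covariate])
        grid, eff, _ = self.effect_grids[covariate]
        return np.interp(xc, grid, eff)

    def _term_se(self, covariate: str, x: np.ndarray) -> np.ndarray:
        lo, hi = self.ranges[covariate]
        xc = np.clip(np.asarray(x, dtype=float), lo, hi)
        if self._results is not None and self._smoother is not None:
            k = self.covariates.index(covariate)
            sm = self._smoother.smoothers[k]
            basis = sm.transform(xc)
            sl = self._param_slice(k)
            cov = np.asarray(self._results.cov_params())[np.ix_(sl, sl)]
            return np.sqrt(np.einsum("ij,jk,ik->i", basis, cov, basis))
        grid, _, se = self.effect_grids[covariate]
        return np.interp(xc, grid, se)

    def _param_slice(self, k: int) -> np.ndarray:
        start = 1
        for j in range(k):
            start += len(self.coefficients[self.covariates[j]])
        n = len(self.coefficients[self.covariates[k]])
        return np.arange(start, start + n)

    # -- prediction ------------------------------------------------------

    def predict(
        self, **covariate_values: float | np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """log10 abundance and an extrapolation flag per point.

        Covariates outside the training range are clamped to the hull
        boundary; the returned boolean array marks clamped points.
        """
        missing = set(self.covariates) - set(covariate_values)
        if missing:
            raise ValueError(f"missing covariates: {sorted(missing)}")
        arrays = {
            c: np.atleast_1d(np.asarray(covariate_values[c], dtype=float))
            for c in self.covariates
        }
        n = max(a.size for a in arrays.values())
        arrays = {c: np.broadcast_to(a, n).astype(float) for c, a in arrays.items()}
        extrapolated = np.zeros(n, dtype=bool)
        pred = np.full(n, self.intercept)
        for c in self.covariates:
            lo, hi = self.ranges[c]
            x = arrays[c]
            extrapolated |= (x < lo) | (x > hi)
            pred = pred + self._term_effect(c, x)
        return pred, extrapolated

    # -- serialization ---------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "format": "diazoniche-gam-v1",
            "taxon": self.taxon,
            "covariates": list(self.covariates),
            "intercept": self.intercept,
            "alpha": list(self.alpha),
            "degree": self.degree,
            "n_used": self.n_used,
            "r_squared": self.r_squared,
            "deviance_explained": self.deviance_explained,
            "p_values": self.p_values,
            "medians": self.medians,
            "ranges": {c: list(r) for c, r in self.ranges.items()},
            "knots": self.knots,
            "coefficients": self.coefficients,
            "effect_grids": {
                c: {
                    "grid": np.asarray(g).tolist(),
                    "effect": np.asarray(e).tolist(),
                    "se": np.asarray(s).tolist(),
                }
                for c, (g, e, s) in self.effect_grids.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GamFit":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        if payload.get("format") != "diazoniche-gam-v1":
            raise ValueError("not a diazoniche GAM fit file")
        return cls(
            taxon=payload["taxon"],
            covariates=tuple(payload["covariates"]),
            intercept=payload["intercept"],
            alpha=tuple(payload["alpha"]),
            n_used=payload["n_used"],
            r_squared=payload["r_squared"],
            deviance_explained=payload["deviance_explained"],
            p_values=payload["p_values"],
            medians=payload["medians"],
            ranges={c: tuple(r) for c, r in payload["ranges"].items()},
            knots=payload["knots"],
            degree=payload["degree"],
            coefficients=payload["coefficients"],
            effect_grids={
                c: (
                    np.asarray(d["grid"]),
                    np.asarray(d["effect"]),
                    np.asarray(d["se"]),
                )
                for c, d in payload["effect_grids"].items()
            },
        )


def _gcv_score(res, n: int) -> float:
    edf = float(np.sum(np.asarray(res.edf)))
    ssr = float(res.deviance)  # Gaussian deviance = residual sum of squares
    denom = max(n - edf, 1e-8)
    return n * ssr / denom**2


def _select_alpha_gcv(
    model_factory, n_terms: int, n: int, grid: np.ndarray, passes: int = 2
) -> list[float]:
    """Coordinate descent over per-term penalty weights, minimizing GCV."""
    alpha = [float(grid[len(grid) // 2])] * n_terms
    for _ in range(passes):
        for k in range(n_terms):
            best, best_score = alpha[k], np.inf
            for a in grid:
                trial = list(alpha)
                trial[k] = float(a)
                res = model_factory(trial).fit()
                score = _gcv_score(res, n)
                if score < best_score:
                    best, best_score = float(a), score
            alpha[k] = best
    return alpha


def fit_gam(
    records: pd.DataFrame,
    taxon: str,
    *,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    response: str = "nifh_areal",
    basis_df: int = 6,
    degree: int = 3,
    select: str | None = "gcv",
    alpha: Sequence[float] | None = None,
    zero_handling: str = "drop",
    floor: float | None = None,
    min_records: int = 50,
) -> GamFit:
    """Fit the additive niche model for one taxon.

    Parameters
    ----------
    records : DataFrame
        Must contain a ``taxon`` column (or be pre-filtered), the
        ``response`` abundance column (copies m-2, linear scale) and
        the covariate columns.
    select : {"gcv", "aic", None}
        Penalty-weight selection: GCV coordinate search (default),
        statsmodels' AIC-based optimizer, or none (requires ``alpha``).
    zero_handling : {"drop", "floor"}
        Drop non-detect (<= 0) abundances, or substitute ``floor``
        copies m-2 before taking log10.
    """
    df = records
    if "taxon" in df.columns:
        df = df[df["taxon"] == taxon]
    df = df.dropna(subset=[response, *covariates]).copy()

    y_lin = df[response].to_numpy(dtype=float)
    if zero_handling == "drop":
        keep = y_lin > 0
        df, y_lin = df[keep], y_lin[keep]
    elif zero_handling == "floor":
        if floor is None or floor <= 0:
            raise ValueError("floor substitution requires a positive floor")
        y_lin = np.where(y_lin > 0, y_lin, floor)
    else:
        raise ValueError(f"unknown zero_handling {zero_handling!r}")
    n = len(df)
    if n < min_records:
        raise ValueError(f"only {n} usable records for {taxon!r}; need >= {min_records}")
    if np.all(y_lin == 0):
        raise ValueError("all-zero response")

    df = df.reset_index(drop=True)
    work = df[list(covariates)].copy()
    work["__y"] = np.log10(y_lin)

    smoother = BSplines(
        work[list(covariates)],
        df=[basis_df] * len(covariates),
        degree=[degree] * len(covariates),
    )

    def factory(a):
        return GLMGam.from_formula("__y ~ 1", data=work, smoother=smoother, alpha=a)

    if alpha is not None:
        alpha_vec = [float(a) for a in alpha]
    elif select == "gcv":
        grid = np.logspace(-4, 8, 13)
        alpha_vec = _select_alpha_gcv(factory, len(covariates), n, grid)
    elif select == "aic":
        base = factory([1.0] * len(covariates))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alpha_vec = [float(a) for a in base.select_penweight()[0]]
    elif select is None:
        raise ValueError("select=None requires explicit alpha")
    else:
        raise ValueError(f"unknown select {select!r}")

    res = factory(alpha_vec).fit()

    dev = float(res.deviance)
    null_dev = float(res.null_deviance)
    r2 = 1.0 - dev / null_dev
    dev_expl = (null_dev - dev) / null_dev * 100.0

    p_values: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, c in enumerate(covariates):
            try:
                t = res.test_significance(k)
                p_values[c] = float(np.squeeze(t.pvalue))
            except Exception:  # pragma: no cover - degenerate designs
                p_values[c] = float("nan")

    params = np.asarray(res.params)
    coefficients: dict[str, list[float]] = {}
    i = 1
    for k, c in enumerate(covariates):
        nb = smoother.smoothers[k].basis.shape[1]
        coefficients[c] = params[i : i + nb].tolist()
        i += nb

    medians = {c: float(np.median(work[c])) for c in covariates}
    ranges = {
        c: (float(work[c].min()), float(work[c].max())) for c in covariates
    }
    knots = {
        c: np.asarray(smoother.smoothers[k].knots, dtype=float).tolist()
        for k, c in enumerate(covariates)
    }

    fit = GamFit(
        taxon=taxon,
        covariates=tuple(covariates),
        intercept=float(params[0]),
        alpha=tuple(alpha_vec),
        n_used=n,
        r_squared=r2,
        deviance_explained=dev_expl,
        p_values=p_values,
        medians=medians,
        ranges=ranges,
        knots=knots,
        degree=degree,
        coefficients=coefficients,
        effect_grids={},
        rug={c: work[c].to_numpy() for c in covariates},
        _results=res,
        _smoother=smoother,
    )
    # dense effect grids for serialization / refit-free projection
    for c in covariates:
        lo, hi = ranges[c]
        grid_x = np.linspace(lo, hi, _GRID_N)
        eff = fit._term_effect(c, grid_x)
        se = fit._term_se(c, grid_x)
        fit.effect_grids[c] = (grid_x, eff, se)
    return fit


def partial_response(fit: GamFit, covariate: str, n_grid: int = 200) -> ResponseCurve:
    """Centered partial response of one covariate with a 95% CI band.

    The other covariates are irrelevant to the additive partial effect;
    centering subtracts the mean effect over the covariate's observed
    values (rug) so curves are comparable across terms.
    """
    if covariate not in fit.covariates:
        raise ValueError(f"unknown covariate {covariate!r}")
    lo, hi = fit.ranges[covariate]
    grid = np.linspace(lo, hi, n_grid)
    eff = fit._term_effect(covariate, grid)
    se = fit._term_se(covariate, grid)
    rug = fit.rug.get(covariate)
    center_x = rug if rug is not None and len(rug) else grid
    center = float(np.mean(fit._term_effect(covariate, center_x)))
    eff_c = eff - center
    return ResponseCurve(
        covariate=covariate,
        grid=grid,
        effect=eff_c,
        ci_low=eff_c - 1.96 * se,
        ci_high=eff_c + 1.96 * se,
        rug=None if rug is None else np.asarray(rug),
    )


def predict_log_abundance(
    fit: GamFit,
    sst: float | np.ndarray,
    dfe: float | np.ndarray,
    p: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """log10 nifH copies m-2 at the given covariates (clamped to hull).

    Returns (prediction, extrapolation_flag) arrays.
    """
    return fit.predict(sst=sst, dfe=dfe, p=p)
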