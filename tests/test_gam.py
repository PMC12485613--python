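"""Niche-model fitting, partial responses, prediction and serialization."""

import numpy as np
import pandas as pd
import pytest

import diazoniche as dz
from diazoniche.gam import fit_gam, partial_response, predict_log_abundance
from diazoniche.simulate import NicheTruth


def _truth_centered(fit, truth, covariate, grid):
    resp = {
        "sst": truth.response_sst,
        "dfe": truth.response_dfe,
        "p": truth.response_p,
    }[covariate]
    return resp(grid) - np.mean(resp(fit.rug[covariate]))


def _poly_truth():
    """Responses inside the cubic-spline span: exact fit is possible."""
    return NicheTruth(
        "UCYN-B",
        response_sst=lambda x: 0.002 * (x - 20.0) ** 3 - 0.01 * (x - 20.0) ** 2,
        response_dfe=lambda x: 1.2 * x,
        response_p=lambda x: -0.8 * x**2 + x,
        intercept=6.0,
        noise_sd=1e-8,  # exactly zero residuals trip GLM's separation guard
    )


class TestFit:
    def test_noiseless_niche_recovered(self, sim_config):
        db, _ = dz.make_global_database(sim_config, noise=False)
        fit = fit_gam(db, "UCYN-B")
        assert fit.deviance_explained > 99.0

    def test_pure_noise_shrinks_to_flat(self, sim_config):
        db, _ = dz.make_global_database(sim_config)
        db = db[db.taxon == "UCYN-B"].copy()
        rng = np.random.default_rng(7)
        db["nifh_areal"] = 10.0 ** rng.normal(5.0, 0.5, len(db))
        fit = fit_gam(db, "UCYN-B")
        assert fit.deviance_explained < 5.0

    def test_recovery_of_known_niche(self, ucynb_fit):
        """Partial responses track the generating truth within 0.3
        log10 units over the central 90% of each covariate range, and
        the thermal optimum is recovered within 1 degC."""
        truth = dz.default_niche_truths()["UCYN-B"]
        for cov in ucynb_fit.covariates:
            rc = partial_response(ucynb_fit, cov, 200)
            lo, hi = np.percentile(ucynb_fit.rug[cov], [5, 95])
            m = (rc.grid >= lo) & (rc.grid <= hi)
            tr = _truth_centered(ucynb_fit, truth, cov, rc.grid)
            rmse = float(np.sqrt(np.mean((rc.effect[m] - tr[m]) ** 2)))
            assert rmse <= 0.3, f"{cov}: RMSE {rmse:.3f}"
        assert abs(partial_response(ucynb_fit, "sst").argmax - 27.5) <= 1.0

    def test_dfe_response_declines_sharply_below_ramp(self, ucynb_fit):
        rc = partial_response(ucynb_fit, "dfe", 300)
        at_low = rc.effect[np.searchsorted(rc.grid, 0.05)]
        at_ramp = rc.effect[np.searchsorted(rc.grid, 0.35)]
        assert at_ramp - at_low > 0.8  # steep rise across 0.2 nM

    def test_fit_statistics_match_definitions(self, synthetic_db):
        """R^2 and deviance explained agree with their textbook
        definitions recomputed from the model's own predictions."""
        db, _ = synthetic_db
        fit = fit_gam(db, "UCYN-B")
        sub = db[(db.taxon == "UCYN-B") & (db.nifh_areal > 0)]
        y = np.log10(sub.nifh_areal.to_numpy())
        pred, _ = fit.predict(
            sst=sub.sst.to_numpy(), dfe=sub.dfe.to_numpy(), p=sub.p.to_numpy()
        )
        ssr = float(np.sum((y - pred) ** 2))
        sst_tot = float(np.sum((y - y.mean()) ** 2))
        assert fit.r_squared == pytest.approx(1 - ssr / sst_tot, abs=1e-10)
        assert fit.deviance_explained == pytest.approx(
            (1 - ssr / sst_tot) * 100.0, abs=1e-8
        )
        assert 0.0 <= fit.deviance_explained <= 100.0

    def test_record_order_invariance(self, sim_config):
        db, _ = dz.make_global_database(sim_config)
        f1 = fit_gam(db, "UCYN-B")
        shuffled = db.sample(frac=1.0, random_state=3).reset_index(drop=True)
        f2 = fit_gam(shuffled, "UCYN-B")
        assert f1.intercept == pytest.approx(f2.intercept, rel=1e-9)
        assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-9)

    def test_zero_handling_drop_vs_floor(self, sim_config):
        import dataclasses

        cfg = dataclasses.replace(sim_config, nondetect_fraction=0.2, seed=4)
        db, _ = dz.make_global_database(cfg)
        n_total = int((db.taxon == "UCYN-B").sum())
        fit_drop = fit_gam(db, "UCYN-B")
        assert fit_drop.n_used < n_total
        fit_floor = fit_gam(db, "UCYN-B", zero_handling="floor", floor=1e3)
        assert fit_floor.n_used == n_total

    def test_too_few_records_rejected(self, synthetic_db):
        db, _ = synthetic_db
        with pytest.raises(ValueError):
            fit_gam(db.head(40), "UCYN-B")

    def test_per_term_p_values_significant(self, ucynb_fit):
        assert all(p < 0.001 for p in ucynb_fit.p_values.values())


class TestPrediction:
    def test_centering_identity_at_medians(self, ucynb_fit):
        med = ucynb_fit.medians
        pred, _ = ucynb_fit.predict(**med)
        manual = ucynb_fit.intercept + sum(
            ucynb_fit._term_effect(c, np.array([med[c]]))[0]
            for c in ucynb_fit.covariates
        )
        assert pred[0] == pytest.approx(manual, abs=1e-12)

    def test_exact_at_training_points_for_in_span_truth(self, sim_config):
        """With an in-span (polynomial) generating truth and no
        penalty, the fit interpolates the noiseless response exactly."""
        db, truth_df = dz.make_global_database(sim_config, {"UCYN-B": _poly_truth()})
        fit = fit_gam(db, "UCYN-B", select=None, alpha=(0.0, 0.0, 0.0))
        sub = db[db.taxon == "UCYN-B"]
        pred, extrap = predict_log_abundance(
            fit, sub.sst.to_numpy(), sub.dfe.to_numpy(), sub.p.to_numpy()
        )
        truth = truth_df.log10_true_abundance.to_numpy()
        assert not extrap.any()
        assert np.max(np.abs(pred - truth)) < 1e-6

    def test_clamped_extrapolation_equals_boundary(self, ucynb_fit):
        lo, hi = ucynb_fit.ranges["sst"]
        med = ucynb_fit.medians
        outside, flag_out = ucynb_fit.predict(sst=hi + 5.0, dfe=med["dfe"], p=med["p"])
        boundary, flag_in = ucynb_fit.predict(sst=hi, dfe=med["dfe"], p=med["p"])
        assert outside[0] == pytest.approx(boundary[0], abs=1e-12)
        assert flag_out[0] and not flag_in[0]

    def test_flat_truth_curve_within_ci_of_zero(self, sim_config):
        flat = NicheTruth(
            "UCYN-B",
            response_sst=lambda x: np.zeros_like(x),
            response_dfe=lambda x: np.zeros_like(x),
            response_p=lambda x: np.zeros_like(x),
            intercept=5.0,
            noise_sd=0.3,
        )
        db, _ = dz.make_global_database(sim_config, {"UCYN-B": flat})
        fit = fit_gam(db, "UCYN-B")
        for cov in fit.covariates:
            rc = partial_response(fit, cov, 100)
            assert np.all(rc.ci_low <= 0.05) and np.all(rc.ci_high >= -0.05)

    def test_unknown_covariate_rejected(self, ucynb_fit):
        with pytest.raises(ValueError):
            partial_response(ucynb_fit, "salinity")


class TestSerialization:
    def test_json_round_trip_predictions_agree(self, ucynb_fit, tmp_path):
        path = tmp_path / "fit.json"
        ucynb_fit.to_json(path)
        restored = dz.GamFit.from_json(str(path))
        rng = np.random.default_rng(0)
        sst = rng.uniform(*ucynb_fit.ranges["sst"], 50)
        dfe = rng.uniform(*ucynb_fit.ranges["dfe"], 50)
        p = rng.uniform(*ucynb_fit.ranges["p"], 50)
        a, _ = ucynb_fit.predict(sst=sst, dfe=dfe, p=p)
        b, _ = restored.predict(sst=sst, dfe=dfe, p=p)
        assert np.max(np.abs(a - b)) < 1e-3
        assert restored.n_used == ucynb_fit.n_used
        assert restored.alpha == ucynb_fit.alpha

    def test_rejects_foreign_json(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text('{"hello": 1}')
        with pytest.raises(ValueError):
            dz.GamFit.from_json(str(path))
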