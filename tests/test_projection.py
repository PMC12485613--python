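"""Grid projection, dominance classification and region extraction."""

import numpy as np
import pytest

import diazoniche as dz
from diazoniche.projection import (
    EARTH_RADIUS_KM,
    AbundanceMap,
    DominanceMask,
    _label_with_wrap,
    cell_areas_km2,
)


def _map(taxon, values, lat=None, lon=None):
    values = np.asarray(values, dtype=float)
    nlat, nlon = values.shape
    lat = np.arange(nlat) + 0.5 if lat is None else lat
    lon = np.arange(nlon) + 0.5 if lon is None else lon
    return AbundanceMap(
        taxon=taxon,
        lat=np.asarray(lat, dtype=float),
        lon=np.asarray(lon, dtype=float),
        abundance=values,
        extrapolated=np.zeros_like(values, dtype=bool),
    )


class TestCellAreas:
    def test_global_closure_4pi_r_squared(self):
        lat = np.arange(-89.5, 90.0, 1.0)
        total = cell_areas_km2(lat).sum() * 360.0
        sphere = 4.0 * np.pi * EARTH_RADIUS_KM**2
        assert abs(total / sphere - 1.0) < 1e-4

    def test_equatorial_cell_area(self):
        # ~ (111.19 km)^2
        area = cell_areas_km2(np.array([0.0]))[0]
        assert area == pytest.approx(1.236e4, rel=1e-3)

    def test_polar_cells_smaller(self):
        areas = cell_areas_km2(np.array([0.0, 60.0, 89.5]))
        assert areas[0] > areas[1] > areas[2] > 0


class TestProjection:
    def test_constant_fields_give_constant_map(self, ucynb_fit, sim_config):
        env = dz.make_env_grids(sim_config, constant=True)
        amap = dz.project_taxon(ucynb_fit, env)
        ocean = np.isfinite(amap.abundance)
        vals = amap.abundance[ocean]
        assert vals.size > 0
        assert np.allclose(vals, vals[0], rtol=1e-12)

    def test_land_cells_stay_missing(self, ucynb_fit, env_grid):
        amap = dz.project_taxon(ucynb_fit, env_grid)
        land = ~env_grid.ocean_mask
        assert land.any()
        assert np.all(np.isnan(amap.abundance[land]))

    def test_cellwise_oracle(self, ucynb_fit, env_grid):
        """The map value equals a from-scratch single-cell prediction
        (per-month predict, back-transform, average) at random cells."""
        amap = dz.project_taxon(ucynb_fit, env_grid)
        ds = env_grid.data
        rng = np.random.default_rng(1)
        ocean = np.argwhere(env_grid.ocean_mask)
        for i, j in ocean[rng.choice(len(ocean), 20, replace=False)]:
            monthly = []
            for m in ds.month.values:
                sst = float(ds.sst.sel(month=m).values[i, j])
                dfe = float(ds.dfe.sel(month=m).values[i, j])
                p = float(ds.p.sel(month=m).values[i, j])
                if not (np.isfinite(sst) and np.isfinite(dfe) and np.isfinite(p)):
                    continue
                lp, _ = ucynb_fit.predict(sst=sst, dfe=dfe, p=p)
                monthly.append(10.0 ** lp[0])
            assert amap.abundance[i, j] == pytest.approx(np.mean(monthly), rel=1e-9)

    def test_annualized_map_bounded_by_monthly_extremes(self, ucynb_fit, env_grid):
        ds = env_grid.data
        amap = dz.project_taxon(ucynb_fit, env_grid)
        monthly = []
        for m in ds.month.values:
            sst = ds.sst.sel(month=m).values
            dfe = ds.dfe.sel(month=m).values
            p = ds.p.sel(month=m).values
            lp, _ = ucynb_fit.predict(
                sst=sst.ravel(), dfe=dfe.ravel(), p=p.ravel()
            )
            field = 10.0 ** lp.reshape(sst.shape)
            field[~np.isfinite(sst)] = np.nan
            monthly.append(field)
        stack = np.stack(monthly)
        ocean = np.isfinite(amap.abundance)
        lo = np.min(stack, axis=0)[ocean]
        hi = np.max(stack, axis=0)[ocean]
        vals = amap.abundance[ocean]
        assert np.all(vals >= lo - 1e-9) and np.all(vals <= hi + 1e-9)


class TestDominance:
    def test_single_taxon_everywhere(self):
        m1 = _map("UCYN-B", np.full((4, 6), 1e9))
        m2 = _map("Trichodesmium", np.zeros((4, 6)))
        mask = dz.dominance([m1, m2], abundance_threshold=1e4)
        assert np.all(mask.taxon == "UCYN-B")

    def test_share_exactly_at_threshold_is_none(self):
        m1 = _map("UCYN-B", np.full((2, 2), 3e8))
        m2 = _map("Trichodesmium", np.full((2, 2), 1e8))
        mask = dz.dominance([m1, m2], share_threshold=0.75, abundance_threshold=1e4)
        assert np.all(mask.taxon == "")  # 0.75 is not > 0.75

    def test_abundance_floor_strict(self):
        m1 = _map("UCYN-B", np.full((2, 2), 1e4))
        mask = dz.dominance([m1], abundance_threshold=1e4)
        assert np.all(mask.taxon == "")

    def test_grid_mismatch_rejected(self):
        m1 = _map("a", np.zeros((2, 2)))
        m2 = _map("b", np.zeros((2, 3)))
        with pytest.raises(ValueError):
            dz.dominance([m1, m2])

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        maps = [_map(t, 10 ** rng.uniform(2, 9, (5, 5))) for t in "abcd"]
        base = dz.dominance(maps, abundance_threshold=1e5)
        scaled = [
            _map(m.taxon, 10.0 * m.abundance) for m in maps
        ]
        rescaled = dz.dominance(scaled, abundance_threshold=1e6)
        assert np.array_equal(base.taxon, rescaled.taxon)

    def test_matches_brute_force_classifier(self):
        """dominance() agrees with an exhaustive per-cell check."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            maps = [_map(t, 10 ** rng.uniform(2, 9, (5, 5))) for t in "abcd"]
            thr = 10 ** rng.uniform(3, 8)
            share = rng.uniform(0.4, 0.9)
            mask = dz.dominance(maps, share_threshold=share, abundance_threshold=thr)
            for i in range(5):
                for j in range(5):
                    vals = {m.taxon: m.abundance[i, j] for m in maps}
                    total = sum(vals.values())
                    best = max(vals, key=vals.get)
                    expect = (
                        best
                        if total > thr and vals[best] / total > share
                        else ""
                    )
                    assert mask.taxon[i, j] == expect


class TestRegions:
    def test_single_equatorial_cell_area(self):
        taxon = np.full((3, 5), "", dtype=object)
        taxon[1, 2] = "UCYN-B"
        mask = DominanceMask(
            lat=np.array([-1.5, 0.0, 1.5]),
            lon=np.arange(5, dtype=float),
            taxon=taxon,
            share_threshold=0.75,
            abundance_threshold=1e8,
        )
        regions = dz.hotspot_regions(mask)
        assert len(regions) == 1
        assert regions[0].area_1e6_km2 * 1e6 == pytest.approx(1.236e4, rel=1e-3)

    def test_empty_mask_gives_empty_list(self):
        mask = DominanceMask(
            lat=np.arange(3, dtype=float),
            lon=np.arange(3, dtype=float),
            taxon=np.full((3, 3), "", dtype=object),
            share_threshold=0.75,
            abundance_threshold=1e8,
        )
        assert dz.hotspot_regions(mask) == []

    def test_dateline_wrap_merges_regions(self):
        taxon = np.full((3, 360), "", dtype=object)
        taxon[1, 0] = taxon[1, -1] = "UCYN-B"
        mask = DominanceMask(
            lat=np.array([-0.5, 0.5, 1.5]),
            lon=np.arange(-179.5, 180.0, 1.0),
            taxon=taxon,
            share_threshold=0.75,
            abundance_threshold=1e8,
        )
        regions = dz.hotspot_regions(mask)
        assert len(regions) == 1 and regions[0].n_cells == 2

    def test_diagonal_cells_connect(self):
        m = np.zeros((4, 4), dtype=bool)
        m[0, 0] = m[1, 1] = m[2, 2] = True
        labels, n = _label_with_wrap(m)
        assert n == 1

    def test_rate_mask_filters_cells(self):
        taxon = np.full((2, 2), "UCYN-B", dtype=object)
        mask = DominanceMask(
            lat=np.array([0.0, 1.0]),
            lon=np.array([0.0, 1.0]),
            taxon=taxon,
            share_threshold=0.75,
            abundance_threshold=1e8,
        )
        rate = np.array([[150.0, 50.0], [150.0, 150.0]])
        regions = dz.hotspot_regions(mask, rate_map=rate, rate_threshold=100.0)
        assert sum(r.n_cells for r in regions) == 3
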