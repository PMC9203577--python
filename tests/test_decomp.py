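import numpy as np
import pandas as pd
import pytest

from neevar import (
    NH_SEASONS,
    RegionMask,
    UndefinedCorrelationError,
    aggregate_contributions,
    aggregate_global,
    build_anomaly_cube,
    contribution_map,
    correlations,
    default_bands,
    make_compensation_scenario,
    generate_fieldset,
    partial_corr,
    pearson,
    remove_region,
)
from neevar.anomalies import AnomalyCube, GlobalAnnualSeries
from neevar.decomp import sign_consistency
from neevar.grid import GridGeometry


def naive_pearson(a, b):
    """Two-pass loop oracle for the Pearson correlation."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    sab = saa = sbb = 0.0
    for x, y in zip(a, b):
        sab += (x - ma) * (y - mb)
        saa += (x - ma) ** 2
        sbb += (y - mb) ** 2
    return sab / np.sqrt(saa * sbb)


def closed_form_partial(a, b, c):
    r_ab, r_ac, r_bc = naive_pearson(a, b), naive_pearson(a, c), naive_pearson(b, c)
    return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))


class TestPearson:
    def test_perfect_correlations(self):
        a = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(a, a) == pytest.approx(1.0)
        assert pearson(a, -2 * a) == pytest.approx(-1.0)

    def test_zero_variance_is_undefined_not_zero(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson(np.ones(5), np.arange(5.0))

    def test_matches_loop_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b = rng.standard_normal((2, 12))
            assert pearson(a, b) == pytest.approx(naive_pearson(a, b), abs=1e-13)


class TestPartialCorr:
    def test_orthogonal_control_reduces_to_pearson(self):
        rng = np.random.default_rng(3)
        a, b, z = rng.standard_normal((3, 200))
        # orthogonalize a and b against z (and the mean) by construction
        for v in (a, b):
            v -= v.mean()
        z -= z.mean()
        a = a - z * (a @ z) / (z @ z)
        b = b - z * (b @ z) / (z @ z)
        assert partial_corr(a, b, z) == pytest.approx(pearson(a, b), abs=1e-12)

    def test_series_equal_to_control_is_undefined(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(20)
        b = rng.standard_normal(20)
        with pytest.raises(UndefinedCorrelationError):
            partial_corr(a, b, a)

    def test_residual_method_equals_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c = rng.standard_normal((3, 15))
            assert partial_corr(a, b, c) == pytest.approx(
                closed_form_partial(a, b, c), abs=1e-12
            )


def _manual_cube(nee, geom, years, tws=None, temp=None, excluded=()):
    shape = nee.shape
    zeros = np.zeros(shape)
    return AnomalyCube(
        geometry=geom,
        years=years,
        nee=nee,
        tws=zeros if tws is None else tws,
        temp=zeros if temp is None else temp,
        detrend_mode="whole-series",
        excluded_years=excluded,
    )


def _series(years, x_g, t_g, tws_g):
    return GlobalAnnualSeries(years=years, x_g=x_g, t_g=t_g, tws_g=tws_g)


class TestContributionMap:
    def test_single_active_cell_month_collapses_to_global_r(self):
        geom = GridGeometry(np.array([0.0]), np.array([0.0]), np.array([[True]]))
        rng = np.random.default_rng(6)
        years = np.arange(2000, 2012)
        nee = np.zeros((12, 12, 1, 1))
        nee[:, 4, 0, 0] = rng.standard_normal(12)  # only May varies
        t_g = rng.standard_normal(12)
        tws_g = rng.standard_normal(12)
        x_g = nee.sum(axis=(1, 2, 3))
        cmap = contribution_map(_manual_cube(nee, geom, years), _series(years, x_g, t_g, tws_g))
        assert cmap.c_t[4, 0, 0] == pytest.approx(pearson(x_g, t_g), abs=1e-12)
        assert cmap.c_tws[4, 0, 0] == pytest.approx(-pearson(x_g, tws_g), abs=1e-12)

    def test_zero_variance_cell_months_contribute_exact_zero(self):
        geom = GridGeometry(np.array([0.0]), np.array([0.0, 90.0]),
                            np.array([[True, True]]))
        rng = np.random.default_rng(7)
        years = np.arange(2000, 2010)
        nee = np.zeros((10, 12, 1, 2))
        nee[:, :, 0, 0] = rng.standard_normal((10, 12))
        nee[:, 3, 0, 1] = 2.5  # constant: zero variance, correlation undefined
        x_g = nee.sum(axis=(1, 2, 3))
        series = _series(years, x_g, rng.standard_normal(10), rng.standard_normal(10))
        cmap = contribution_map(_manual_cube(nee, geom, years), series)
        assert cmap.c_t[3, 0, 1] == 0.0
        assert cmap.c_tws[3, 0, 1] == 0.0
        assert cmap.zero_variance[3, 0, 1]
        assert not cmap.zero_variance[3, 0, 0]

    def test_additivity_identity_on_random_cube(self, tiny_geometry):
        rng = np.random.default_rng(8)
        years = np.arange(2000, 2012)
        nee = rng.standard_normal((12, 12) + tiny_geometry.shape)
        x_g = nee.sum(axis=(1, 2, 3))
        series = _series(years, x_g, rng.standard_normal(12), rng.standard_normal(12))
        cmap = contribution_map(_manual_cube(nee, tiny_geometry, years), series)
        assert cmap.c_t.sum() == pytest.approx(cmap.r_t, rel=1e-10)
        assert cmap.c_tws.sum() == pytest.approx(-cmap.r_tws, rel=1e-10)

    def test_scale_and_translation_invariance(self, tiny_geometry):
        rng = np.random.default_rng(9)
        years = np.arange(2000, 2015)
        nee = rng.standard_normal((15, 12) + tiny_geometry.shape)
        t_g = rng.standard_normal(15)
        tws_g = rng.standard_normal(15)
        x_g = nee.sum(axis=(1, 2, 3))
        base = contribution_map(
            _manual_cube(nee, tiny_geometry, years), _series(years, x_g, t_g, tws_g)
        )
        scaled = contribution_map(
            _manual_cube(3.5 * nee, tiny_geometry, years),
            _series(years, 3.5 * x_g, t_g, tws_g),
        )
        shifted = contribution_map(
            _manual_cube(nee, tiny_geometry, years),
            _series(years, x_g, t_g + 10.0, tws_g - 7.0),
        )
        np.testing.assert_allclose(scaled.c_t, base.c_t, atol=1e-12)
        np.testing.assert_allclose(scaled.c_tws, base.c_tws, atol=1e-12)
        np.testing.assert_allclose(shifted.c_t, base.c_t, atol=1e-12)
        np.testing.assert_allclose(shifted.c_tws, base.c_tws, atol=1e-12)


@pytest.fixture(scope="module")
def pipeline(toy_fieldset):
    fieldset, _ = toy_fieldset
    cube = build_anomaly_cube(fieldset)
    series = aggregate_global(cube)
    return fieldset, cube, series, contribution_map(cube, series)


class TestAggregation:

    def test_whole_globe_share_is_100_percent(self, pipeline):
        fieldset, _, _, cmap = pipeline
        globe = [RegionMask("globe", fieldset.geometry.land_mask)]
        summary = aggregate_contributions(cmap, globe)
        row = summary.iloc[0]
        assert row["C_T"] == pytest.approx(cmap.r_t, abs=1e-12)
        assert row["C_TWS"] == pytest.approx(-cmap.r_tws, abs=1e-12)
        assert row["share_T"] * np.sign(cmap.r_t) == pytest.approx(1.0, abs=1e-12)
        assert abs(row["share_TWS"]) == pytest.approx(1.0, abs=1e-12)

    def test_complementary_regions_add_to_global(self, pipeline):
        fieldset, _, _, cmap = pipeline
        land = fieldset.geometry.land_mask
        west = land.copy()
        west[:, land.shape[1] // 2:] = False
        east = land & ~west
        summary = aggregate_contributions(
            cmap, [RegionMask("west", west), RegionMask("east", east)]
        )
        assert summary["C_T"].sum() == pytest.approx(cmap.r_t, abs=1e-12)
        assert summary["C_TWS"].sum() == pytest.approx(-cmap.r_tws, abs=1e-12)

    def test_nh_season_sums_reproduce_annual_exactly(self, pipeline):
        fieldset, _, _, cmap = pipeline
        bands = default_bands(fieldset.geometry)
        seasons = {"annual": tuple(range(1, 13)), **NH_SEASONS}
        summary = aggregate_contributions(cmap, bands, seasons).set_index(
            ["region", "season"]
        )
        for region in ("NH", "tropics", "south"):
            season_sum = sum(
                summary.loc[(region, s), "C_T"] for s in NH_SEASONS
            )
            assert season_sum == pytest.approx(summary.loc[(region, "annual"), "C_T"], abs=1e-12)

    def test_empty_region_flagged(self, pipeline):
        fieldset, _, _, cmap = pipeline
        empty = RegionMask("none", np.zeros(fieldset.geometry.shape, dtype=bool))
        summary = aggregate_contributions(cmap, [empty])
        assert summary.iloc[0]["empty"]
        assert summary.iloc[0]["C_T"] == 0.0

    def test_compensation_scenario_spring_cancels_summer(self):
        fieldset, _ = generate_fieldset(make_compensation_scenario(1.0, n_years=20, seed=2))
        cube = build_anomaly_cube(fieldset, excluded_years=())
        series = aggregate_global(cube)
        cmap = contribution_map(cube, series)
        summary = aggregate_contributions(
            cmap, default_bands(fieldset.geometry), dict(NH_SEASONS)
        ).set_index(["region", "season"])
        mam = summary.loc[("NH", "MAM"), "C_T"]
        jja = summary.loc[("NH", "JJA"), "C_T"]
        # the planted construction is antisymmetric up to a tiny detrending
        # alias; cancellation holds to well below a percent of the summer term
        assert abs(mam + jja) < 1e-3 * abs(jja)

    def test_removing_positive_contributor_shrinks_absolute_r(self, pipeline):
        fieldset, cube, series, cmap = pipeline
        bands = default_bands(fieldset.geometry)
        summary = aggregate_contributions(cmap, bands).set_index("region")
        for band in bands:
            reduced_cube = remove_region(cube, band)
            reduced_series = aggregate_global(reduced_cube)
            r_before = abs(correlations(series).r_tws)
            r_after = abs(correlations(reduced_series).r_tws)
            contribution = summary.loc[band.name, "C_TWS"]
            if contribution > 0.05:
                assert r_after < r_before


class TestSignConsistency:
    def _maps(self, toy_fieldset, flips):
        fieldset, _ = toy_fieldset
        cube = build_anomaly_cube(fieldset)
        series = aggregate_global(cube)
        base = contribution_map(cube, series)
        maps = []
        for flip in flips:
            m = contribution_map(cube, series)
            if flip:
                m.c_t = -m.c_t
                m.c_tws = -m.c_tws
            maps.append(m)
        return fieldset, maps

    def test_identical_maps_fully_agree(self, toy_fieldset):
        fieldset, maps = self._maps(toy_fieldset, [False] * 3)
        result = sign_consistency(maps, default_bands(fieldset.geometry))
        assert result["all_agree"].all()
        assert result["majority_agree"].all()

    def test_negated_map_breaks_full_agreement(self, toy_fieldset):
        fieldset, maps = self._maps(toy_fieldset, [False, False, True])
        result = sign_consistency(maps, default_bands(fieldset.geometry))
        assert not result["all_agree"].any()

    def test_eleven_of_fourteen_rule(self, toy_fieldset):
        fieldset, maps = self._maps(toy_fieldset, [False] * 11 + [True] * 3)
        result = sign_consistency(maps, default_bands(fieldset.geometry))
        assert not result["all_agree"].any()
        assert result["majority_agree"].all()
        assert (result["n_agree_with_mean"] == 11).all()
        # a 10-of-14 split fails the "more than 10 of 14" rule
        fieldset, maps = self._maps(toy_fieldset, [False] * 10 + [True] * 4)
        result = sign_consistency(maps, default_bands(fieldset.geometry))
        assert not result["majority_agree"].any()

    def test_mismatched_grids_rejected(self, toy_fieldset):
        fieldset, maps = self._maps(toy_fieldset, [False, False])
        other, _ = generate_fieldset(
            __import__("neevar").SimConfig(seed=1, n_years=5, lat_step=30, lon_step=30)
        )
        cube = build_anomaly_cube(other, excluded_years=())
        series = aggregate_global(cube)
        maps.append(contribution_map(cube, series))
        with pytest.raises(ValueError, match="mismatched"):
            sign_consistency(maps, default_bands(fieldset.geometry))
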