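"""Gap-model unit tests: allometry, light competition, fluxes, dynamics."""

import math

import numpy as np
import pytest

from gapflux import (
    Landscape,
    Patch,
    SimConfig,
    Tree,
    allometry,
    annual_step,
    compute_light_profile,
    dbh_from_biomass,
    default_pfts,
    run_succession,
    tree_annual_fluxes,
)
from conftest import single_pft


class TestAllometry:
    def test_power_law_limits(self):
        pft = default_pfts()[0]
        h, cd, la, b = allometry(pft, 1e-9)
        assert h < 1e-3 and b < 1e-12 and cd < 1e-6 and la < 1e-9

    def test_height_scaling_sqrt(self):
        pft = single_pft(h1=0.5)[0]
        h1, *_ = allometry(pft, 0.2)
        h2, *_ = allometry(pft, 0.4)
        assert h2 / h1 == pytest.approx(math.sqrt(2), rel=1e-12)

    @pytest.mark.parametrize("dbh", [0.01, 0.1, 0.5])
    @pytest.mark.parametrize("pft", default_pfts(), ids=lambda p: p.name)
    def test_biomass_matches_hand_evaluation(self, pft, dbh):
        # independent scalar evaluation of (pi/4) D^2 H form rho
        _, _, _, b = allometry(pft, dbh)
        height = pft.h0 * dbh**pft.h1
        expected = math.pi / 4.0 * dbh * dbh * height * pft.form * pft.rho
        assert b == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        pft = default_pfts()[0]
        with pytest.raises(ValueError):
            allometry(pft, 0.0)
        with pytest.raises(ValueError):
            allometry(pft, pft.d_max * 1.01)

    def test_biomass_inversion_roundtrip(self):
        pft = default_pfts()[2]
        d = np.array([0.02, 0.3, 1.0])
        _, _, _, b = allometry(pft, d)
        np.testing.assert_allclose(dbh_from_biomass(pft, b), d, rtol=1e-12)


class TestLightProfile:
    def test_empty_patch_full_light(self):
        profile = compute_light_profile(Patch(index=0), k=0.6)
        np.testing.assert_array_equal(profile, 1.0)

    def test_single_tree_attenuation(self):
        # one crown holding exactly LAI = 1 above the floor, k = 0.6
        pfts = single_pft(la0=400.0)
        tree = Tree.from_dbh(pfts[0], 1.0)  # leaf area 400 = patch area
        patch = Patch(index=0, trees=[tree])
        profile = compute_light_profile(patch, k=0.6, pfts=pfts)
        assert profile[0] == pytest.approx(math.exp(-0.6), rel=1e-12)
        assert profile[-1] == 1.0

    def test_stacked_crowns_multiply_and_match_bruteforce(self):
        pfts = single_pft()
        trees = [Tree.from_dbh(pfts[0], d) for d in (0.3, 0.8)]
        patch = Patch(index=0, trees=trees)
        profile = compute_light_profile(patch, k=0.6, pfts=pfts)

        # oracle: explicit 0.5 m layer accumulation of leaf area from above
        la_layer = np.zeros(200)
        for t in trees:
            top = math.ceil(t.height / 0.5) - 1
            base = min(int(t.height * (1 - pfts[0].f_crown) / 0.5), top)
            la_layer[base:top + 1] += t.leaf_area / (top - base + 1)
        lai_above = np.concatenate(
            [np.cumsum(la_layer[::-1])[::-1][1:], [0.0]]) / 400.0
        np.testing.assert_allclose(profile, np.exp(-0.6 * lai_above), rtol=1e-12)

        # attenuation of both crowns = product of single-crown attenuations
        single = [compute_light_profile(Patch(index=0, trees=[t]), k=0.6,
                                        pfts=pfts) for t in trees]
        np.testing.assert_allclose(profile, single[0] * single[1], rtol=1e-12)

    def test_adding_tree_never_increases_light(self):
        pfts = single_pft()
        trees = [Tree.from_dbh(pfts[0], d) for d in (0.2, 0.5, 0.9)]
        previous = compute_light_profile(Patch(index=0, trees=[]), k=0.6, pfts=pfts)
        for n in range(1, 4):
            current = compute_light_profile(
                Patch(index=0, trees=trees[:n]), k=0.6, pfts=pfts)
            assert np.all(current <= previous + 1e-15)
            previous = current

    def test_profile_non_increasing_downwards(self):
        pfts = default_pfts()
        trees = [Tree.from_dbh(pfts[i], d)
                 for i, d in [(0, 0.3), (1, 0.6), (3, 1.0)]]
        profile = compute_light_profile(Patch(index=0, trees=trees), k=0.6,
                                        pfts=pfts)
        assert np.all(np.diff(profile) >= -1e-15)
        assert profile[-1] == 1.0


class TestTreeFluxes:
    def test_darkness_gives_negative_npp(self):
        pft = default_pfts()[0]
        tree = Tree.from_dbh(pft, 0.3)
        gpp, npp = tree_annual_fluxes(tree, pft, light=0.0)
        assert gpp == 0.0
        assert npp == pytest.approx(
            -(1 - pft.r_growth) * pft.r_main * tree.biomass, rel=1e-12)

    def test_light_response_arithmetic(self):
        # p(I) = alpha I pmax / (alpha I + pmax) at alpha=2, pmax=1, I=0.5
        pft = single_pft(alpha=2.0, pmax=1.0, la0=1.0, la1=2.0)[0]
        tree = Tree.from_dbh(pft, 1.0)  # leaf area exactly 1
        gpp, _ = tree_annual_fluxes(tree, pft, light=0.5)
        assert gpp == pytest.approx(0.5, rel=1e-12)

    def test_saturation_approaches_pmax(self):
        pft = single_pft(alpha=500.0, pmax=0.002, la0=1.0)[0]
        tree = Tree.from_dbh(pft, 1.0)
        gpp, _ = tree_annual_fluxes(tree, pft, light=1.0)
        assert gpp == pytest.approx(pft.pmax, rel=0.01)

    def test_light_domain_error(self):
        pft = default_pfts()[0]
        tree = Tree.from_dbh(pft, 0.3)
        with pytest.raises(ValueError):
            tree_annual_fluxes(tree, pft, light=1.5)


class TestAnnualStep:
    def test_empty_landscape_stays_empty_without_seeds(self):
        pfts = single_pft(i_seed=0.0)
        cfg = SimConfig(n_replicates=1, years=1, plot_edge=100.0)
        land = Landscape(cfg, pfts)
        rng = np.random.default_rng(0)
        for _ in range(5):
            annual_step(land, rng)
        assert land.n_trees == 0

    def test_single_tree_growth_matches_scalar_integration(self):
        pfts = single_pft(m_b=0.0, i_seed=0.0)
        p = pfts[0]
        cfg = SimConfig(n_replicates=1, years=1, plot_edge=100.0)
        land = Landscape(cfg, pfts)
        land.add_trees(np.array([0]), np.array([0.05]), np.array([0]))
        rng = np.random.default_rng(0)
        history = []
        for _ in range(30):
            annual_step(land, rng)
            history.append(land.dbh[0])
        # oracle: scalar re-integration of the growth equation at full light
        b_coef = math.pi / 4.0 * p.h0 * p.form * p.rho
        rate = p.alpha * p.pmax / (p.alpha + p.pmax)
        d = 0.05
        expected = []
        for _ in range(30):
            biomass = b_coef * d ** (2.0 + p.h1)
            gpp = rate * p.la0 * d**p.la1
            npp = (1 - p.r_growth) * (gpp - p.r_main * biomass)
            assert npp > 0
            biomass += (1 - (d / p.d_max) ** 2) * npp
            d = (biomass / b_coef) ** (1.0 / (2.0 + p.h1))
            expected.append(d)
        np.testing.assert_allclose(history, expected, rtol=1e-9)
        assert np.all(np.diff([0.05] + list(history)) > 0)

    def test_step_is_deterministic_under_fixed_seed(self):
        cfg = SimConfig(n_replicates=1, years=1, plot_edge=100.0, rng_seed=5)
        states = []
        for _ in range(2):
            land = Landscape(cfg)
            rng = np.random.default_rng(123)
            for _ in range(15):
                annual_step(land, rng)
            states.append((land.dbh.copy(), land.patch.copy(), land.pft.copy()))
        np.testing.assert_array_equal(states[0][0], states[1][0])
        np.testing.assert_array_equal(states[0][1], states[1][1])
        np.testing.assert_array_equal(states[0][2], states[1][2])

    def test_carbon_bookkeeping_for_survivors(self):
        """Surviving trees grow by exactly their stem-allocated share of NPP."""
        cfg = SimConfig(n_replicates=1, years=1, plot_edge=100.0)
        land = Landscape(cfg)
        rng = np.random.default_rng(7)
        for _ in range(25):
            annual_step(land, rng)
        before = land.biomass.copy()
        from gapflux.gap_model import _fluxes_and_growth, _light_for_trees
        light, _ = _light_for_trees(land)
        _fluxes_and_growth(land, light)
        np.testing.assert_allclose(land.biomass - before, land.stem_inc,
                                   rtol=1e-9, atol=1e-15)


class TestRunSuccession:
    def test_year_zero_is_bare_ground(self, small_run):
        totals = small_run.plot_totals()
        year0 = totals[totals.year == 0]
        assert (year0[["agb", "gpp", "npp"]] == 0).all().all()

    def test_full_run_is_deterministic(self):
        cfg = SimConfig(n_replicates=2, years=25, plot_edge=100.0, rng_seed=9)
        a = run_succession(cfg)
        b = run_succession(cfg)
        np.testing.assert_array_equal(a.agb, b.agb)
        np.testing.assert_array_equal(a.gpp, b.gpp)
        np.testing.assert_array_equal(a.profile, b.profile)

    def test_replicates_are_independent_streams(self):
        cfg = SimConfig(n_replicates=2, years=25, plot_edge=100.0, rng_seed=9)
        res = run_succession(cfg)
        assert not np.array_equal(res.agb[0], res.agb[1])

    def test_biomass_grows_from_bare_ground(self, small_run):
        totals = small_run.plot_totals().groupby("year")["agb"].mean()
        assert totals.loc[60] > totals.loc[10] > totals.loc[2]

    def test_npp_never_exceeds_gpp(self, small_run):
        assert np.all(small_run.npp <= small_run.gpp + 1e-12)

    def test_tree_table_schema(self):
        cfg = SimConfig(n_replicates=1, years=5, plot_edge=100.0,
                        record_trees=True, rng_seed=1)
        res = run_succession(cfg)
        assert res.trees is not None
        assert {"replicate", "year", "patch_x", "patch_y", "pft", "dbh_m",
                "height_m", "biomass_t", "gpp_t_yr",
                "npp_t_yr"} <= set(res.trees.columns)
        assert (res.trees.biomass_t > 0).all()
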