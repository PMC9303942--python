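"""Simulator unit tests: grids, rates, stepping and equilibria."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from mnyield.sizespectrum import (
    CommunityState,
    FishingPolicy,
    GearSelectivity,
    ResourceParams,
    SizeSpectrumModel,
    SpeciesParams,
    build_grid,
    feeding_kernel,
    fishing_mortality,
    trawl_selectivity,
)

from conftest import FAST_EQ


def toy_species(name="toy", w_inf=1000.0, gamma=1e-11, ks=4.0, alpha=0.6,
                mu_b0=0.6, **overrides):
    base = dict(
        name=name, w_min=1e-3, w_inf=w_inf, w_mat=0.25 * w_inf,
        L_inf=(w_inf / 0.01) ** (1 / 3), h=30.0, n=0.75, gamma=gamma, q=0.8,
        beta=100.0, sigma=1.3, alpha=alpha, ks=ks, p=0.75, mu_b0=mu_b0,
        erepro=0.1, R_max=1e6,
    )
    base.update(overrides)
    return SpeciesParams(**base)


def toy_resource(kappa=1e9, w_res_max=10.0):
    return ResourceParams(kappa=kappa, lam=2.05, r0=4.0, w_res_max=w_res_max)


def toy_model(species=None, **kwargs):
    species = species or [toy_species()]
    gears = [
        GearSelectivity(gear=f"g_{sp.name}", species=sp.name,
                        w50=0.05 * sp.w_inf, slope=3.0)
        for sp in species
    ]
    kwargs.setdefault("n_bins", 50)
    return SizeSpectrumModel(species, toy_resource(), gears, **kwargs)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

class TestBuildGrid:
    def test_log_spacing_hits_powers_of_ten(self):
        grid = build_grid(1e-3, 1e3, 7)
        assert np.allclose(grid.w, 10.0 ** np.arange(-3, 4))

    def test_span_and_uniform_log_step(self):
        grid = build_grid(1e-3, 1e5, 100)
        assert grid.w[0] == pytest.approx(1e-3)
        assert grid.w[-1] / grid.w[0] == pytest.approx(1e8)
        steps = np.diff(np.log(grid.w))
        assert np.allclose(steps, math.log(1e8) / 99)

    def test_resource_grid_extends_below(self):
        grid = build_grid(1e-3, 1e3, 40, resource_decades=3.0)
        assert grid.w_full[0] <= 1e-3 * 10 ** -2.99
        assert np.allclose(grid.w_full[grid.fish_offset :], grid.w)

    def test_dw_matches_node_spacing(self):
        grid = build_grid(0.5, 800.0, 30)
        assert np.allclose(grid.dw[:-1], np.diff(grid.w))

    @pytest.mark.parametrize(
        "args", [(1.0, 1.0, 5), (0.0, 10.0, 5), (1.0, 10.0, 1), (-1.0, 5.0, 9)]
    )
    def test_degenerate_inputs_raise(self, args):
        with pytest.raises(ValueError):
            build_grid(*args)


# ---------------------------------------------------------------------------
# kernel and selectivity
# ---------------------------------------------------------------------------

class TestFeedingKernel:
    def test_mode_at_beta_ratio(self):
        assert feeding_kernel(100.0, 1.0, beta=100.0, sigma=1.3) == 1.0

    def test_symmetric_in_log_displacement(self):
        beta, sigma, prey = 50.0, 0.8, 2.0
        up = feeding_kernel(beta * prey * math.exp(sigma), prey, beta, sigma)
        down = feeding_kernel(beta * prey * math.exp(-sigma), prey, beta, sigma)
        assert up == pytest.approx(down, rel=1e-12)
        assert up == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_log_integral_matches_gaussian_mass(self):
        # integral of the kernel over ln(prey mass) is sigma * sqrt(2 pi)
        beta, sigma, pred = 100.0, 1.3, 50.0
        val, _ = quad(
            lambda lnp: feeding_kernel(pred, math.exp(lnp), beta, sigma),
            -30, 30,
        )
        assert val == pytest.approx(sigma * math.sqrt(2 * math.pi), rel=1e-8)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            feeding_kernel(-1.0, 1.0, 100.0, 1.3)
        with pytest.raises(ValueError):
            feeding_kernel(1.0, 1.0, 0.5, 1.3)
        with pytest.raises(ValueError):
            feeding_kernel(1.0, 1.0, 100.0, 0.0)


class TestSelectivityAndFishing:
    def test_sigmoid_half_at_w50(self):
        w = np.array([1.0, 20.0, 400.0])
        s = trawl_selectivity(w, w50=20.0, slope=3.0)
        assert s[1] == pytest.approx(0.5)
        assert np.all((s >= 0) & (s <= 1))
        assert s[0] < s[1] < s[2]

    def test_flat_selectivity_identity(self):
        # w50 far below the grid makes S ~ 1 everywhere: F = Q * E
        w = np.geomspace(1.0, 1e3, 20)
        sel = GearSelectivity(gear="g", species="a", w50=1e-12, slope=5.0, Q=1.0)
        policy = FishingPolicy(efforts={"g": 0.5}, selectivities=(sel,))
        F = fishing_mortality(policy, "a", w)
        assert np.allclose(F, 0.5)

    def test_zero_effort_gives_zero(self):
        w = np.geomspace(1.0, 1e3, 10)
        sel = GearSelectivity(gear="g", species="a", w50=10.0, slope=3.0)
        policy = FishingPolicy(efforts={"g": 0.0}, selectivities=(sel,))
        assert np.all(fishing_mortality(policy, "a", w) == 0)

    def test_two_gear_hand_sum(self):
        w = np.geomspace(1.0, 1e3, 10)
        sels = (
            GearSelectivity(gear="g1", species="a", w50=1e-12, slope=5.0, Q=1.0),
            GearSelectivity(gear="g2", species="a", w50=1e-12, slope=5.0, Q=0.5),
        )
        policy = FishingPolicy(efforts={"g1": 1.0, "g2": 2.0}, selectivities=sels)
        assert np.allclose(fishing_mortality(policy, "a", w), 2.0)

    def test_additive_over_gears(self):
        w = np.geomspace(1.0, 1e3, 30)
        s1 = GearSelectivity(gear="g1", species="a", w50=5.0, slope=2.0, Q=0.7)
        s2 = GearSelectivity(gear="g2", species="a", w50=50.0, slope=4.0, Q=1.3)
        both = fishing_mortality(
            FishingPolicy({"g1": 0.8, "g2": 1.1}, (s1, s2)), "a", w
        )
        single = fishing_mortality(
            FishingPolicy({"g1": 0.8}, (s1,)), "a", w
        ) + fishing_mortality(FishingPolicy({"g2": 1.1}, (s2,)), "a", w)
        assert np.allclose(both, single)

    def test_unknown_species_and_negative_effort_raise(self):
        w = np.geomspace(1.0, 1e3, 5)
        sel = GearSelectivity(gear="g", species="a", w50=10.0, slope=3.0)
        with pytest.raises(KeyError):
            fishing_mortality(FishingPolicy({"g": 1.0}, (sel,)), "b", w)
        with pytest.raises(ValueError):
            FishingPolicy({"g": -1.0}, (sel,))


# ---------------------------------------------------------------------------
# rates on constructed states
# ---------------------------------------------------------------------------

class TestFeedingLevel:
    def test_no_prey_no_resource_gives_zero(self):
        m = toy_model()
        state = CommunityState(
            N=np.zeros((1, m.grid.n_bins)), N_res=np.zeros(m.grid.w_full.size)
        )
        assert np.all(m.feeding_level(state) == 0)

    def test_saturates_towards_one(self):
        m = toy_model()
        state = m.initial_state()
        state.N *= 1e12
        state.N_res *= 1e12
        f = m.feeding_level(state)
        assert np.all(f > 0.999)
        assert np.all(f <= 1.0)

    def test_single_prey_bin_scalar_oracle(self):
        m = toy_model()
        sp = m.species[0]
        b = 10  # resource bin holding all the prey
        state = CommunityState(
            N=np.zeros((1, m.grid.n_bins)), N_res=np.zeros(m.grid.w_full.size)
        )
        state.N_res[b] = 5.0
        wp = m.grid.w_full[b]
        w = m.grid.w
        E_expected = (
            sp.gamma
            * w**sp.q
            * feeding_kernel(w, wp, sp.beta, sp.sigma)
            * 5.0
            * wp
            * m.grid.dw_full[b]
        )
        f_expected = E_expected / (E_expected + sp.h * w**sp.n)
        assert np.allclose(m.feeding_level(state)[0], f_expected, rtol=1e-12)


class TestGrowthAndRecruitment:
    def test_zero_feeding_floors_growth(self):
        m = toy_model()
        g = m.growth_rate(np.zeros((1, m.grid.n_bins)))
        assert np.all(g == 0)

    def test_growth_vanishes_at_asymptotic_mass(self):
        m = toy_model()
        g = m.growth_rate(np.full((1, m.grid.n_bins), 0.8))
        at_winf = m.grid.w >= m.species[0].w_inf
        assert np.all(g[0, at_winf] == 0)

    def test_juvenile_energy_budget_scalar_oracle(self):
        m = toy_model()
        sp = m.species[0]
        f = np.full((1, m.grid.n_bins), 0.7)
        g = m.growth_rate(f)
        k = 5  # far below maturation: psi ~ 0
        w = m.grid.w[k]
        expected = (0.7 * sp.alpha * sp.h * w**sp.n - sp.ks * w**sp.p) * (
            1.0 - m.psi[0, k]
        )
        assert m.psi[0, k] < 1e-6
        assert g[0, k] == pytest.approx(expected, rel=1e-12)

    def test_beverton_holt_cap_and_midpoint(self):
        # metabolism-free, food-rich species so reproduction energy is positive
        m = toy_model([toy_species(ks=0.0, gamma=1e-9)])
        state = m.initial_state()
        _, repro = m.growth_and_repro(m.feeding_level(state))
        E_repro = float(np.sum(repro * state.N * m.grid.dw, axis=1)[0])
        R_di = m.erepro[0] * E_repro / (2 * m.w_min_arr[0])
        R = m.recruitment(state)[0]
        assert R == pytest.approx(m.R_max[0] * R_di / (m.R_max[0] + R_di))
        assert R <= m.R_max[0]
        # hand arithmetic: R_di = 3 R_max -> R = 0.75 R_max
        m.R_max[0] = R_di / 3.0
        assert m.recruitment(state)[0] == pytest.approx(0.75 * m.R_max[0])
        m.R_max[0] = 1e6  # restore

    def test_zero_spawning_biomass_gives_zero(self):
        m = toy_model()
        state = CommunityState(
            N=np.zeros((1, m.grid.n_bins)), N_res=m.res_cc.copy()
        )
        assert m.recruitment(state)[0] == 0.0


class TestMortality:
    def test_empty_community_leaves_background_only(self):
        m = toy_model()
        state = CommunityState(
            N=np.zeros((1, m.grid.n_bins)), N_res=np.zeros(m.grid.w_full.size)
        )
        mu = m.total_mortality(state)
        sp = m.species[0]
        assert np.allclose(mu, sp.mu_b0 * sp.w_inf ** (sp.n - 1.0))

    def test_predator_cohort_raises_prey_mortality(self):
        species = [
            toy_species("prey", w_inf=50.0),
            toy_species("pred", w_inf=5e4, gamma=1e-9),
        ]
        m = toy_model(species)
        empty = CommunityState(
            N=np.zeros((2, m.grid.n_bins)), N_res=np.zeros(m.grid.w_full.size)
        )
        with_pred = empty.copy()
        k = np.searchsorted(m.grid.w, 1e4)
        with_pred.N[1, k] = 1.0
        mu0 = m.total_mortality(empty)
        mu1 = m.total_mortality(with_pred)
        prey_band = np.searchsorted(m.grid.w, 1e4 / 100.0)
        assert mu1[0, prey_band] > mu0[0, prey_band]

    def test_single_predator_one_bin_quadrature_oracle(self):
        species = [
            toy_species("prey", w_inf=50.0),
            toy_species("pred", w_inf=5e4, gamma=1e-9),
        ]
        m = toy_model(species)
        state = CommunityState(
            N=np.zeros((2, m.grid.n_bins)), N_res=np.zeros(m.grid.w_full.size)
        )
        k = np.searchsorted(m.grid.w, 1e4)
        state.N[1, k] = 2.5
        pred = m.species[1]
        w_pred = m.grid.w[k]
        f = m.feeding_level(state)  # only trivial cannibalistic feeding
        assert np.all(f < 1e-3)
        mu = m.total_mortality(state)
        b = np.searchsorted(m.grid.w, 100.0)
        w_prey = m.grid.w[b]
        expected = (
            (1.0 - f[1, k])
            * feeding_kernel(w_pred, w_prey, pred.beta, pred.sigma)
            * pred.gamma
            * w_pred**pred.q
            * 2.5
            * m.grid.dw[k]
        )
        background = m.mu_b[0]
        assert mu[0, b] - background == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def frozen_model():
    """A model with no growth, no predation, no background mortality."""
    sp = toy_species(gamma=0.0, ks=0.0, alpha=1e-12, mu_b0=0.0)
    return toy_model([sp])


class TestStep:
    def test_conservation_without_rates(self):
        m = frozen_model()
        state = m.initial_state()
        state.N_res = m.res_cc.copy()
        out = m.step(state, None, dt=0.1)
        assert np.allclose(out.N, state.N, rtol=1e-12)
        assert np.allclose(out.N_res, state.N_res, rtol=1e-12)

    def test_constant_mortality_decays_exponentially(self):
        sp = toy_species(gamma=0.0, ks=0.0, alpha=1e-12, mu_b0=0.5 / 1000.0 ** -0.25)
        m = toy_model([sp])
        state = m.initial_state()
        N0 = state.N.copy()
        for _ in range(100):  # 10 years at dt = 0.1
            state = m.step(state, None, dt=0.1)
        mask = N0 > 0
        ratio = state.N[mask] / N0[mask]
        assert np.allclose(ratio, math.exp(-0.5 * 10.0), rtol=1e-2)

    def test_negative_dt_raises(self):
        m = frozen_model()
        with pytest.raises(ValueError):
            m.step(m.initial_state(), None, dt=-0.1)

    def test_numpy_path_matches_compiled_path(self):
        m = toy_model()
        state = m.initial_state()
        F = np.zeros((1, m.grid.n_bins))
        N_a, R_a = m._advance(state.N.copy(), state.N_res.copy(), F, 0.1)
        N_b, R_b = m._advance_numpy(state.N.copy(), state.N_res.copy(), F, 0.1)
        assert np.allclose(N_a, N_b, rtol=1e-10)
        assert np.allclose(R_a, R_b, rtol=1e-10)

    def test_densities_stay_non_negative(self, model3, state3):
        policy = model3.policy_for_species_F([1.5, 1.5, 1.5])
        out = model3.step(state3, policy)
        assert np.all(out.N >= 0)
        assert np.all(out.N_res >= 0)


class TestEquilibrium:
    def test_t_max_zero_returns_input_unconverged(self, model3, state3):
        out, report = model3.project_to_equilibrium(None, state=state3, t_max=0.0)
        assert not report.converged
        assert np.allclose(out.N, state3.N)

    def test_unfished_default_community_converges(self, model15):
        state, report = model15.project_to_equilibrium()
        assert report.converged
        assert report.t_final < 600.0
        assert np.all(model15.biomass(state) > 0)

    def test_restart_from_equilibrium_converges_immediately(self, model3, state3):
        _, report = model3.project_to_equilibrium(None, state=state3, **FAST_EQ)
        assert report.converged
        assert report.n_steps <= 150  # one trailing window of simulation

    def test_equilibrium_independent_of_initial_condition(self, model3, state3):
        # perturbed states in the attractor's basin return to the same
        # equilibrium (the community can hold alternative stable states under
        # very different initial spectra, so this is a basin property)
        alt = state3.copy()
        alt.N *= 1.5
        alt.N_res = model3.res_cc.copy()
        other, report = model3.project_to_equilibrium(None, state=alt, **FAST_EQ)
        assert report.converged
        B1 = model3.biomass(state3)
        B2 = model3.biomass(other)
        assert np.allclose(B1, B2, rtol=1e-2)

    def test_invalid_tolerance_raises(self, model3):
        with pytest.raises(ValueError):
            model3.project_to_equilibrium(None, tol=0.0)


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

class TestYieldAndIndicators:
    def test_zero_effort_zero_yield(self, model3, state3):
        assert np.all(model3.species_yield(state3, None) == 0)

    def test_yield_linear_in_abundance(self, model3, state3):
        policy = model3.policy_for_species_F([0.3, 0.3, 0.3])
        c1 = model3.species_yield(state3, policy)
        doubled = state3.copy()
        doubled.N *= 2.0
        c2 = model3.species_yield(doubled, policy)
        assert np.allclose(c2, 2.0 * c1)

    def test_one_bin_yield_scalar_oracle(self):
        m = toy_model()
        state = CommunityState(
            N=np.zeros((1, m.grid.n_bins)), N_res=np.zeros(m.grid.w_full.size)
        )
        k = 30
        state.N[0, k] = 7.0
        F = np.zeros((1, m.grid.n_bins))
        F[0, k] = 0.4
        expected = 0.4 * 7.0 * m.grid.w[k] * m.grid.dw[k] / 1e6
        assert m.species_yield(state, F)[0] == pytest.approx(expected, rel=1e-12)

    def test_empty_community_indicators(self, model3):
        empty = CommunityState(
            N=np.zeros((model3.n_species, model3.grid.n_bins)),
            N_res=np.zeros(model3.grid.w_full.size),
        )
        ind = model3.biomass_indicators(empty)
        assert ind["community_biomass"] == 0
        assert ind["fishable_biomass"] == 0
        assert math.isnan(ind["mean_max_size"])

    def test_single_species_mean_size_is_L_inf(self, model1):
        state, _ = model1.project_to_equilibrium(**FAST_EQ)
        ind = model1.biomass_indicators(state)
        assert ind["mean_max_size"] == pytest.approx(model1.species[0].L_inf)

    def test_two_species_weighted_mean_size(self):
        species = [
            toy_species("a", w_inf=10.0, L_inf=10.0),
            toy_species("b", w_inf=1.25e4, L_inf=50.0),
        ]
        m = toy_model(species)
        state = CommunityState(
            N=np.zeros((2, m.grid.n_bins)), N_res=np.zeros(m.grid.w_full.size)
        )
        # biomasses in ratio 1:3
        k = 10
        wdw = m.grid.w[k] * m.grid.dw[k]
        state.N[0, k] = 1.0 / wdw
        state.N[1, k] = 3.0 / wdw
        assert m.mean_max_size(state) == pytest.approx(40.0)

    def test_single_species_biomass_non_increasing_in_effort(self, model1):
        biomasses = []
        state = None
        for E in [0.0, 0.3, 0.8, 1.5]:
            policy = model1.policy_for_species_F([E])
            state, _ = model1.project_to_equilibrium(
                policy, state=state, **FAST_EQ
            )
            biomasses.append(float(model1.biomass(state)[0]))
        assert all(b1 >= b2 * 0.999 for b1, b2 in zip(biomasses, biomasses[1:]))
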