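"""NPZD-OA column model: forcing, reactions, conservation, constrained closures."""

import warnings

import numpy as np
import pytest

from pdeclosure.npdde import solve_forward
from pdeclosure.oa import (BioParams, ColumnDiffusionTerm, ColumnPhysics,
                           ReactionTerm, biogeochem_rhs, column_rhs,
                           forcing_and_profiles, make_column_system,
                           mortality_library, npzd_to_npz_states,
                           oa_closure_builder, spinup_init, ta_from_salinity)

BIO = BioParams()
PHYS = ColumnPhysics()


class TestForcingAndProfiles:
    def test_diffusivity_endpoints(self):
        """K_z equals the surface value at z = 0 and the bottom value at D_z,
        whatever the mixed-layer depth."""
        for t in (0.0, 100.0, 250.0):
            K = PHYS.K_z(np.array([0.0, PHYS.D_z]), t)
            assert K[0] == pytest.approx(PHYS.K_z0)
            assert K[1] == pytest.approx(PHYS.K_zb)

    def test_irradiance_decays_with_depth(self):
        I, Kz, S, TA = forcing_and_profiles(np.array([0.0, 50.0]), 180.0, PHYS)
        assert I[1] == pytest.approx(I[0] * np.exp(-0.067 * 50.0))

    def test_alkalinity_regression_value(self):
        assert ta_from_salinity(30.0) == pytest.approx(2.05060)

    def test_alkalinity_branch_continuity(self):
        lo = (198.10 + 61.75 * 32.34) / 1000
        hi = (744.41 + 44.86 * 32.34) / 1000
        assert abs(hi - lo) < 1e-4
        assert ta_from_salinity(32.339) == pytest.approx(lo, abs=1e-4)
        assert ta_from_salinity(32.341) == pytest.approx(hi, abs=1e-4)

    def test_salinity_profile_monotone_in_range(self):
        S = PHYS.salinity(np.linspace(0, PHYS.D_z, 50))
        assert np.all(np.diff(S) > 0)
        assert 31.4 < S[0] < S[-1] < 32.8


class TestReactions:
    def test_michaelis_menten_midpoint(self):
        st = np.zeros((1, 6))
        st[0, :4] = [BIO.K_N, 1.0, 0.0, 0.0]
        # f(N) = 1/2 at N = K_N: growth is half the light-limited maximum
        I = 100.0
        fI = (1 - np.exp(-BIO.alpha * I / BIO.mu_max)) * np.exp(-BIO.beta * I / BIO.mu_max)
        r = biogeochem_rhs(st, I, BIO, "npzd_oa", "quadratic")
        assert r[0, 1] == pytest.approx(0.5 * BIO.mu_max * fI * 1.0 - BIO.m_P)

    @pytest.mark.parametrize("mortality", ["linear", "quadratic"])
    def test_total_biomass_conserved(self, mortality):
        rng = np.random.default_rng(1)
        st = np.abs(rng.normal(1.0, 0.5, size=(20, 6)))
        r = biogeochem_rhs(st, 80.0, BIO, "npzd_oa", mortality)
        assert np.allclose(r[:, :4].sum(axis=1), 0.0, atol=1e-13)

    def test_quadratic_minus_linear_missing_physics_pattern(self):
        """The closure target: the quadratic mortality adds -0.02998 Z^2 to Z,
        +0.02998 Z^2 to D and (C_Z - C_D) * 0.02998 Z^2 = -0.05621 Z^2 to DIC,
        and nothing to N, P, TA."""
        rng = np.random.default_rng(2)
        st = np.abs(rng.normal(1.0, 0.5, size=(12, 6)))
        Z2 = st[:, 2] ** 2
        d = (biogeochem_rhs(st, 80.0, BIO, "npzd_oa", "quadratic")
             - biogeochem_rhs(st, 80.0, BIO, "npzd_oa", "linear"))
        assert np.allclose(d[:, 2], -0.02998 * Z2)
        assert np.allclose(d[:, 3], +0.02998 * Z2)
        assert np.allclose(d[:, 4], -0.0562125 * Z2)
        assert np.allclose(d[:, [0, 1, 5]], 0.0)

    def test_negative_concentration_warns(self):
        st = np.zeros((1, 6))
        st[0, 0] = -1.0
        with pytest.warns(UserWarning, match="negative"):
            biogeochem_rhs(st, 50.0, BIO, "npzd_oa", "linear")

    def test_npz_aggregation_consistency(self):
        """NPZ reactions conserve N + P + Z."""
        rng = np.random.default_rng(3)
        st = np.abs(rng.normal(1.0, 0.5, size=(8, 5)))
        r = biogeochem_rhs(st, 80.0, BIO, "npz_oa", "linear")
        assert np.allclose(r[:, :3].sum(axis=1), 0.0, atol=1e-13)


class TestColumn:
    def test_uniform_state_diffusion_free(self):
        term = ColumnDiffusionTerm(PHYS.grid(), PHYS)
        u = np.ones((PHYS.N_z, 6)) * np.array([1, 2, 3, 4, 5, 6.0])
        assert np.allclose(term.eval(u, 50.0), 0.0, atol=1e-12)

    def test_pure_diffusion_conserves_depth_integral(self):
        sysm = make_column_system("npzd_oa", BIO, PHYS, diffusion=True)
        sysm.lowfi_terms = [t for t in sysm.lowfi_terms
                            if isinstance(t, ColumnDiffusionTerm)]
        rng = np.random.default_rng(4)
        u0 = np.abs(rng.normal(2.0, 0.5, size=(PHYS.N_z, 6)))
        traj = solve_forward(sysm, u0, [30.0], rtol=1e-9, atol=1e-11)
        col0 = u0.sum(axis=0)
        col1 = traj.states[0].sum(axis=0)
        assert np.allclose(col1, col0, rtol=1e-7)

    def test_no_diffusion_is_nodewise(self):
        """With K_z = 0 the reactions at each depth are independent."""
        r = column_rhs(np.ones((PHYS.N_z, 6)), 10.0, BIO, PHYS)
        react = ReactionTerm(PHYS.grid(), BIO, PHYS, "npzd_oa", "quadratic")
        only = react.eval(np.ones((PHYS.N_z, 6)), 10.0)
        # uniform state: diffusion contributes nothing, so they agree
        assert np.allclose(r, only, atol=1e-12)

    def test_reaction_vjp_matches_finite_differences(self):
        react = ReactionTerm(PHYS.grid(), BIO, PHYS, "npzd_oa", "quadratic")
        rng = np.random.default_rng(5)
        u = np.abs(rng.normal(1.0, 0.3, size=(PHYS.N_z, 6)))
        lam = rng.normal(size=(PHYS.N_z, 6))
        v = rng.normal(size=(PHYS.N_z, 6))
        eps = 1e-7
        fd = np.sum(lam * (react.eval(u + eps * v, 3.0) - react.eval(u, 3.0))) / eps
        assert fd == pytest.approx(np.sum(react.vjp(u, 3.0, lam) * v), rel=1e-5)


class TestSpinup:
    def test_biomass_preserved_and_seeded(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s0 = spinup_init(BIO, PHYS, days=30.0)
        z = PHYS.grid().x
        assert np.allclose(s0[:, :4].sum(axis=1), PHYS.T_bio(z), atol=1e-10)
        assert s0[:, 4] == pytest.approx(BIO.C_P * s0[:, 0])
        assert np.allclose(s0[:, 5], ta_from_salinity(PHYS.salinity(z)))

    def test_long_spinup_reaches_equilibrium(self):
        """Extended spin-up: reaction tendencies fall below 1e-6 relative."""
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no convergence warning allowed
            s = spinup_init(BIO, PHYS, days=2000.0)
        I = PHYS.irradiance(PHYS.grid().x, 0.0, BIO.k_W)
        r = biogeochem_rhs(s, I, BIO, "npzd_oa", "quadratic", check_negative=False)
        assert np.linalg.norm(r[:, :4]) / np.linalg.norm(s[:, :4]) < 1e-6

    def test_short_spinup_warns_when_unconverged(self):
        with pytest.warns(UserWarning, match="spin-up"):
            spinup_init(BIO, PHYS, days=5.0)


class TestOneWayCoupling:
    def test_carbonate_does_not_feed_back(self):
        """Perturbing DIC/TA initial conditions leaves the biology unchanged
        up to adaptive-stepping noise at the solver tolerance (the coupling
        is structurally one-way: the reaction Jacobian is block-triangular)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s0 = spinup_init(BIO, PHYS)
        sysm = make_column_system("npzd_oa", BIO, PHYS, "quadratic")
        times = np.round(np.arange(1.0, 20.001, 1.0), 10)
        a = solve_forward(sysm, s0, times).states
        s0b = s0.copy()
        s0b[:, 4] += 100.0
        s0b[:, 5] += 1.0
        b = solve_forward(sysm, s0b, times).states
        assert np.abs(a[:, :, :4] - b[:, :, :4]).max() < 1e-4


class TestClosureBuilders:
    def test_2a_biomass_conservation_exact(self):
        closure, _ = oa_closure_builder("2a", BIO)
        rng = np.random.default_rng(6)
        closure.set_params(rng.normal(size=closure.n_params))
        out = closure.eval({"Z": np.abs(rng.normal(1, 0.5, size=20))})
        assert np.allclose(out[:, :4].sum(axis=1), 0.0, atol=1e-13)

    def test_2a_z2_only_reproduces_missing_physics(self):
        """With only the Z-channel Z^2 coefficient set to c the contribution
        pattern is (0, 0, cZ^2, -cZ^2) and -(C_Z - C_D) c Z^2 on DIC."""
        closure, _ = oa_closure_builder("2a", BIO)
        W = np.zeros((3, 4))
        W[2, 1] = -0.02998
        closure.set_params(W.ravel())
        Z = np.abs(np.random.default_rng(7).normal(1, 0.5, size=10))
        out = closure.eval({"Z": Z})
        assert np.allclose(out[:, 0], 0.0) and np.allclose(out[:, 1], 0.0)
        assert np.allclose(out[:, 2], -0.02998 * Z**2)
        assert np.allclose(out[:, 3], +0.02998 * Z**2)
        assert np.allclose(out[:, 4], -0.0562125 * Z**2)
        assert np.allclose(out[:, 5], 0.0)

    def test_2b_markovian_touches_only_z(self):
        """The aggregated-model mortality closure is a pure Z sink (export
        to the unresolved detritus pool): P, N, DIC and TA receive no
        Markovian contribution."""
        mark, deep = oa_closure_builder("2b", BIO)
        mark.set_params(np.random.default_rng(8).normal(size=mark.n_params))
        out = mark.eval({"Z": np.abs(np.random.default_rng(9).normal(1, 0.5, 12))})
        assert np.allclose(out[:, [0, 1, 3, 4]], 0.0)
        assert not np.allclose(out[:, 2], 0.0)

    def test_2b_deep_closure_ignores_carbonate_states(self):
        """DIC and TA are not kernel inputs (one-way coupling) and the
        carbonate output rows follow the aggregated model's bookkeeping
        exactly: DIC = -C_P dP - C_Z dZ, TA = -dN / rho_w."""
        _, deep = oa_closure_builder("2b", BIO)
        assert "DIC" not in deep.inputs and "TA" not in deep.inputs
        deep.init_params(np.random.default_rng(10))
        rng = np.random.default_rng(11)
        inp = {k: np.abs(rng.normal(1, 0.3, size=6)) for k in ("N", "P", "Z")}
        inp["I"] = np.abs(rng.normal(50, 10, size=6))
        out = deep.eval(inp)
        assert np.allclose(out[:, 3], -BIO.C_P * out[:, 1] - BIO.C_Z * out[:, 2])
        assert np.allclose(out[:, 4], -out[:, 0] / BIO.rho_w)

    def test_npzd_to_npz_aggregation(self):
        s = np.arange(12.0).reshape(2, 1, 6)
        a = npzd_to_npz_states(s)
        assert a[0, 0, 0] == s[0, 0, 0] + s[0, 0, 3]
        assert a.shape == (2, 1, 5)
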