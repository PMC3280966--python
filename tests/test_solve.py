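import numpy as np
import pytest

from lungbud.params import ParamSet
from lungbud.solve import (BoundaryCondition, System, integrate,
                           run_to_steady)


class TestBoundaryCondition:
    def test_buffer_width_follows_diffusion_length_rule(self, reference_params):
        bc = BoundaryCondition(kind="open_farfield", t_max=100.0)
        assert bc.buffer_width(reference_params) == pytest.approx(
            np.sqrt(reference_params.D_cav * 100.0))
        assert BoundaryCondition(kind="no_flux").buffer_width(reference_params) == 0.0

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            BoundaryCondition(kind="periodic")


class TestFixedPointAndDecay:
    def test_zero_is_fixed_point_without_production(self, tissue_mesh,
                                                    reference_params):
        pr = reference_params.replace(nu_f=0.0, nu_s=0.0, rho0=0.0, rho1=0.0)
        traj, steady, _ = integrate(tissue_mesh, pr, BoundaryCondition(kind="no_flux"),
                                    t_end=3.0, perturbation=0.0, seed=0)
        st = traj[-1]
        assert np.abs(st.f).max() == 0.0
        assert np.abs(st.s).max() == 0.0
        assert np.abs(st.p).max() == 0.0

    def test_decay_only_follows_exponential_closed_form(self, tissue_mesh,
                                                        reference_params):
        # productions off, uniform initial data, no-flux: c(t) = c0 e^{-delta t}
        pr = reference_params.replace(nu_f=0.0, nu_s=0.0, rho0=0.0, rho1=0.0,
                                      delta_f=0.5, delta_s=1.0, Gamma=0.0)
        N = tissue_mesh.n_nodes
        init = {"f": np.ones(N), "s": 2 * np.ones(N), "p": np.zeros(N)}
        traj, _, _ = integrate(tissue_mesh, pr, BoundaryCondition(kind="no_flux"),
                               t_end=2.0, dt0=0.002, dt_max=0.02,
                               initial=init, seed=0)
        st = traj[-1]
        assert st.f.mean() == pytest.approx(np.exp(-0.5 * st.t), rel=0.02)
        assert st.s.mean() == pytest.approx(2 * np.exp(-1.0 * st.t), rel=0.02)

    def test_run_to_steady_reports_steadiness(self, tissue_mesh, reference_params):
        pr = reference_params.replace(nu_f=0.0, nu_s=0.0, rho0=0.0, rho1=0.0)
        rep = run_to_steady(tissue_mesh, pr, BoundaryCondition(kind="no_flux"),
                            tol=1e-6, t_max=100.0, seed=0)
        assert rep.steady
        assert np.abs(rep.state.f).max() < 1e-5


class TestSystem:
    def test_compartment_weights_partition_mass(self, buffered_mesh,
                                                reference_params):
        sys_ = System(buffered_mesh, reference_params, BoundaryCondition())
        total = sys_.w_lum + sys_.w_epi + sys_.w_mes + sys_.w_int
        assert np.allclose(total, sys_.w_all)
        assert sys_.w_all.sum() == pytest.approx(
            buffered_mesh.element_areas().sum())

    def test_vectorised_reactions_match_per_label_reference(self, buffered_mesh,
                                                            reference_params):
        """The solver's weighted nodal kinetics must agree with the scalar
        per-subdomain reaction_rates contract."""
        from lungbud.params import reaction_rates
        sys_ = System(buffered_mesh, reference_params, BoundaryCondition())
        rng = np.random.default_rng(5)
        N = buffered_mesh.n_nodes
        U = {a: np.abs(rng.standard_normal(N)) for a in ("f", "s", "p")}
        rates = sys_.reaction(U)
        expect = {a: np.zeros(N) for a in ("f", "s", "p")}
        weights = {1: sys_.w_lum, 2: sys_.w_epi, 3: sys_.w_mes, 4: sys_.w_int}
        for lab, w in weights.items():
            df, ds, dp = reaction_rates((U["f"], U["s"], U["p"]),
                                        reference_params, lab)
            expect["f"] += w * df
            expect["s"] += w * ds
            expect["p"] += w * dp
        for a in ("f", "s", "p"):
            assert np.allclose(rates[a], expect[a], rtol=1e-12, atol=1e-12)

    def test_jacobian_matches_finite_difference_residual(self, reference_params):
        from lungbud.geometry import LungGeometry, build_geometry
        from lungbud.mesh import make_mesh
        mesh = make_mesh(build_geometry(LungGeometry(Lfar=2.0)), 0.5)
        sys_ = System(mesh, reference_params, BoundaryCondition(t_max=10.0))
        N = mesh.n_nodes
        rng = np.random.default_rng(0)
        U0 = {a: np.abs(rng.standard_normal(N)) for a in sys_.species}
        U1 = {a: np.abs(rng.standard_normal(N)) for a in sys_.species}
        for a in sys_.species:
            U0[a][sys_.fixed[a]] = 0.0
            U1[a][sys_.fixed[a]] = 0.0
        J = sys_.jacobian(U1, 0.25).toarray()
        x = sys_.pack(U1)
        G0 = sys_.residual(U1, U0, 0.25)
        free = np.concatenate([~sys_.fixed[a] for a in sys_.species])
        idx = np.where(free)[0][::7]
        for j in idx:
            xp = x.copy()
            xp[j] += 1e-7
            fd = (sys_.residual(sys_.unpack(xp), U0, 0.25) - G0) / 1e-7
            assert np.allclose(J[:, j], fd, rtol=5e-4, atol=5e-5)

    def test_ptc_has_no_flux_into_cavities(self, buffered_mesh, reference_params):
        """Cavity elements contribute nothing to the Ptc stiffness, so Ptc
        stays identically zero inside the lumen and interstitial space."""
        sys_ = System(buffered_mesh, reference_params, BoundaryCondition(t_max=20.0))
        traj, _, _ = integrate(buffered_mesh, reference_params,
                               BoundaryCondition(t_max=20.0), t_end=5.0,
                               seed=3, system=sys_)
        st = traj[-1]
        interior_cavity = (sys_.w_all > 0) & (sys_.w_tis == 0)
        assert np.abs(st.p[interior_cavity]).max() == 0.0
        assert st.p.max() > 0  # but Ptc is produced in the tissue


class TestDeterminism:
    def test_identical_config_and_seed_reproduce_bitwise(self, buffered_mesh,
                                                         reference_params):
        bc = BoundaryCondition(t_max=10.0)
        t1, _, _ = integrate(buffered_mesh, reference_params, bc, t_end=6.0, seed=9)
        t2, _, _ = integrate(buffered_mesh, reference_params, bc, t_end=6.0, seed=9)
        assert np.array_equal(t1[-1].f, t2[-1].f)
        assert np.array_equal(t1[-1].p, t2[-1].p)

    def test_different_seed_perturbs_trajectory(self, buffered_mesh,
                                                reference_params):
        bc = BoundaryCondition(t_max=10.0)
        t1, _, _ = integrate(buffered_mesh, reference_params, bc, t_end=6.0, seed=1)
        t2, _, _ = integrate(buffered_mesh, reference_params, bc, t_end=6.0, seed=2)
        assert not np.array_equal(t1[-1].f, t2[-1].f)
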