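import numpy as np
import pytest

from lungbud.config import make_fixture
from lungbud.params import ParamSet, SchnakenbergParams, schnakenberg_limit
from lungbud.turing import (dispersion, fastest_growing_wavelength,
                            homogeneous_jacobian, homogeneous_rates,
                            is_turing_unstable, schnakenberg_dispersion_bounds,
                            schnakenberg_jacobian, uniform_steady_state)


class TestUniformSteadyState:
    def test_zero_production_gives_origin(self):
        pr = ParamSet(nu_f=0.0, nu_s=0.0, rho0=0.0, rho1=0.0)
        ss, n = uniform_steady_state(pr)
        assert np.allclose(ss, 0.0, atol=1e-8)

    def test_reference_point_has_positive_root(self, reference_params):
        ss, n = uniform_steady_state(reference_params)
        assert ss is not None
        assert (ss > 0).all()
        assert np.abs(homogeneous_rates(ss, reference_params)).max() < 1e-8

    def test_jacobian_matches_finite_differences(self, reference_params):
        ss, _ = uniform_steady_state(reference_params)
        J = homogeneous_jacobian(ss, reference_params)
        eps = 1e-7
        for j in range(3):
            x1 = ss.copy()
            x1[j] += eps
            fd = (homogeneous_rates(x1, reference_params)
                  - homogeneous_rates(ss, reference_params)) / eps
            assert np.allclose(J[:, j], fd, rtol=1e-4, atol=1e-6)


class TestDispersion:
    def test_equal_diffusivities_cannot_destabilise_stable_kinetics(self):
        # with D_i = d for all species, eigenvalues shift by -d k^2
        rng = np.random.default_rng(1)
        for _ in range(10):
            A = rng.standard_normal((3, 3))
            A -= 2 * np.eye(3) * np.abs(np.linalg.eigvals(A).real).max()
            res = dispersion(A, [0.7, 0.7, 0.7])
            assert res.stable_at_zero
            assert res.k_lo is None

    def test_schnakenberg_band_matches_closed_form(self):
        sp = make_fixture("schnakenberg_point")
        (k_lo, k_hi), stable0 = schnakenberg_dispersion_bounds(sp)
        assert stable0
        J = schnakenberg_jacobian(sp)
        res = dispersion(J, [sp.D_u, sp.D_v], k_grid=np.logspace(-2, 1.5, 600))
        assert res.turing_positive
        assert res.k_lo == pytest.approx(k_lo, rel=1e-3)
        assert res.k_hi == pytest.approx(k_hi, rel=1e-3)

    def test_fastest_wavelength_matches_grid_argmax(self):
        sp = make_fixture("schnakenberg_point")
        J = schnakenberg_jacobian(sp)
        res = dispersion(J, [sp.D_u, sp.D_v])
        lam = fastest_growing_wavelength(res)
        # brute-force oracle on a fine grid
        ks = np.linspace(res.k_lo, res.k_hi, 4000)
        vals = [np.max(np.linalg.eigvals(J - k ** 2 * np.diag([sp.D_u, sp.D_v])).real)
                for k in ks]
        k_star = ks[int(np.argmax(vals))]
        assert lam == pytest.approx(2 * np.pi / k_star, rel=0.05)
        assert fastest_growing_wavelength(
            dispersion(J, [1.0, 1.0])) is None

    def test_reference_multiset_turing_band_at_weak_binding(self, reference_params):
        """The reference rate multiset supports a genuine diffusion-driven
        instability of the well-mixed kinetics in the weak-binding regime,
        with a wavelength of a few lumen radii."""
        pr = reference_params.replace(Gamma=0.003)
        ok, ss, disp = is_turing_unstable(pr)
        assert ok
        assert disp.stable_at_zero
        k_lo, k_hi = disp.band
        assert 0 < k_lo < k_hi
        lam = fastest_growing_wavelength(disp)
        assert 1.0 < lam < 6.0

    def test_calibrated_reference_surrogate_is_stable(self, reference_params):
        """At the calibrated binding strength the well-mixed surrogate is
        linearly stable at every wavenumber: on the bud the pattern is
        carried by the epithelium/mesenchyme source separation rather than
        a homogeneous Turing band (see docs/methods.md)."""
        ok, ss, disp = is_turing_unstable(reference_params)
        assert ss is not None and (ss > 0).all()
        assert disp.stable_at_zero
        assert not ok


class TestSchnakenbergOracleEquivalence:
    def test_three_species_dispersion_reduces_to_two_species(self, reference_params):
        """With FGF10 frozen (f-row and f-column decoupled) and negligible
        SHH decay, the (s, p) dispersion equals the mapped classical
        Schnakenberg dispersion to high accuracy."""
        pr = reference_params.replace(delta_s=0.0)
        sp = schnakenberg_limit(pr, f_const=1.0)
        beta = pr.nu_s * 1.0 / (pr.K_s ** 2 + 1.0)
        # uniform steady state of the reduced (s, p) system from the mapping
        u, v = sp.steady_state
        p0, s0 = u / sp.lam, v / sp.mu
        # reduced 2x2 reaction Jacobian in (s, p) variables
        G = pr.Gamma
        c_s, c_p = G * p0 ** 2, 2 * G * s0 * p0
        net = pr.rho1 - 2 * pr.delta_c
        Jsp = np.array([[-pr.delta_c * c_s, -pr.delta_c * c_p],
                        [net * c_s, net * c_p - pr.delta_p]])
        res3 = dispersion(Jsp, [pr.D_s, pr.D_p])
        J2 = schnakenberg_jacobian(sp)
        for k in (0.0, 0.5, 1.0, 2.0, 5.0):
            lam3 = np.max(np.linalg.eigvals(
                Jsp - k ** 2 * np.diag([pr.D_s, pr.D_p])).real)
            # classical form evolves in tau = delta_p * t; space is shared,
            # so wavenumbers map one-to-one and rates scale by delta_p
            lam2 = np.max(np.linalg.eigvals(
                J2 - k ** 2 * np.diag([sp.D_u, sp.D_v])).real) * pr.delta_p
            assert lam3 == pytest.approx(lam2, abs=1e-8)

    def test_single_receptor_stoichiometry_admits_no_turing_band(self):
        """With a 1:1 SHH:Ptc complex (m_P = 1) the receptor nullcline loses
        the quadratic autocatalysis and no point in a coarse neighbourhood
        scan of the (Turing-capable, weak-binding) reference multiset is
        diffusion-driven unstable, unlike its m_P = 2 counterpart."""
        base = ParamSet(Gamma=0.003)
        ok2, _, _ = is_turing_unstable(base)
        assert ok2   # the m_P = 2 counterpart is unstable
        rng = np.random.default_rng(7)
        found = 0
        for _ in range(40):
            factors = 10 ** rng.uniform(-0.5, 0.5, size=4)
            pr = base.replace(m_P=1).scaled(
                nu_s=factors[0], rho1=factors[1], delta_p=factors[2],
                Gamma=factors[3])
            ok, ss, disp = is_turing_unstable(pr)
            found += bool(ok)
        assert found == 0
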