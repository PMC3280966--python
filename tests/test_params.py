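import numpy as np
import pytest
from scipy.integrate import solve_ivp

from lungbud.params import (EPITHELIUM, LUMEN, MESENCHYME, ParamSet, Scales,
                            hill_activation, hill_repression, qssa_complex,
                            reaction_rates, redimensionalize,
                            schnakenberg_limit, dimensionless_speed)


class TestHillFunctions:
    def test_repression_limits_and_half_saturation(self):
        assert hill_repression(0.0, K=1.0, n=2) == 1.0
        assert hill_repression(1.0, K=1.0, n=2) == pytest.approx(0.5)
        assert hill_repression(10.0, K=1.0, n=2) == pytest.approx(1.0 / 101.0)

    def test_activation_limits(self):
        assert hill_activation(0.0, K=1.0, n=2) == 0.0
        assert hill_activation(1.0, K=1.0, n=2) == pytest.approx(0.5)
        assert hill_activation(1e6, K=1.0, n=2) == pytest.approx(1.0, abs=1e-9)

    def test_monotonicity(self):
        c = np.linspace(0, 5, 50)
        assert (np.diff(hill_repression(c, 1.0, 2)) <= 0).all()
        assert (np.diff(hill_activation(c, 1.0, 2)) >= 0).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hill_repression(-0.1, 1.0, 2)
        with pytest.raises(ValueError):
            hill_activation(-0.1, 1.0, 2)


class TestQssaComplex:
    def test_trivial_values(self):
        assert qssa_complex(0.0, 1.0) == 0.0
        assert qssa_complex(1.0, 1.0, Gamma=1.0) == 1.0
        assert qssa_complex(2.0, 3.0, Gamma=1.0) == pytest.approx(18.0)

    def test_matches_explicit_complex_ode_equilibrium(self):
        # independent oracle: integrate dc/dt = k_on s p^2 - (k_off+dc)*c
        k_on, k_off, delta_c = 1.3, 0.7, 1.1
        s, p = 0.8, 1.7
        sol = solve_ivp(lambda t, c: k_on * s * p ** 2 - (k_off + delta_c) * c,
                        (0, 200), [0.0], rtol=1e-10, atol=1e-12)
        gamma = k_on / (k_off + delta_c)
        assert sol.y[0, -1] == pytest.approx(qssa_complex(s, p, Gamma=gamma),
                                             rel=1e-8)


class TestParamSet:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ParamSet(D_f=-1.0)
        with pytest.raises(ValueError):
            ParamSet(n=0)
        with pytest.raises(ValueError):
            ParamSet(D_cav=0.5)  # below tissue diffusivities

    def test_scaled_and_replace(self):
        pr = ParamSet()
        assert pr.scaled(nu_f=2.0).nu_f == pytest.approx(2 * pr.nu_f)
        assert pr.replace(n=3).n == 3

    def test_dict_roundtrip_rejects_unknown_keys(self):
        pr = ParamSet()
        assert ParamSet.from_dict(pr.to_dict()) == pr
        with pytest.raises(ValueError, match="unknown"):
            ParamSet.from_dict({**pr.to_dict(), "bogus": 1})


class TestReactionRates:
    def test_zero_state_in_lumen_is_fixed_point(self, reference_params):
        df, ds, dp = reaction_rates((0.0, 0.0, 0.0), reference_params, LUMEN)
        assert (df, ds, dp) == (0.0, 0.0, 0.0)

    def test_epithelial_shh_production_at_half_saturation(self, reference_params):
        pr = reference_params
        df, ds, dp = reaction_rates((pr.K_s, 0.0, 0.0), pr, EPITHELIUM)
        assert ds == pytest.approx(pr.nu_s / 2)
        assert df == pytest.approx(-pr.delta_f * pr.K_s)

    def test_mesenchymal_production_and_consumption(self, reference_params):
        pr = reference_params
        s, p = 1.2, 0.7
        c = pr.Gamma * s * p ** 2
        df, ds, dp = reaction_rates((0.0, s, p), pr, MESENCHYME)
        assert df == pytest.approx(pr.nu_f / (1 + c ** pr.n))
        assert ds == pytest.approx(-pr.delta_s * s - pr.delta_c * c)
        assert dp == pytest.approx(pr.rho0 + pr.rho1 * c
                                   - pr.delta_p * p - 2 * pr.delta_c * c)

    def test_unknown_label_rejected(self, reference_params):
        with pytest.raises(ValueError):
            reaction_rates((0.0, 0.0, 0.0), reference_params, 7)


class TestSchnakenbergLimit:
    def test_zero_basal_ptc_production_gives_a_zero(self):
        pr = ParamSet(rho0=0.0, delta_s=0.0)
        sp = schnakenberg_limit(pr, f_const=1.0)
        assert sp.a == 0.0

    def test_mapping_transforms_rates_to_classical_form(self):
        """With FGF10 frozen and negligible SHH decay, the rescaled SHH/Ptc
        rates equal the classical Schnakenberg right-hand side."""
        pr = ParamSet(delta_s=0.0)
        f0 = 2.0
        sp = schnakenberg_limit(pr, f_const=f0)
        beta = pr.nu_s * f0 ** 2 / (pr.K_s ** 2 + f0 ** 2)
        rng = np.random.default_rng(3)
        for s, p in rng.uniform(0.05, 3.0, size=(20, 2)):
            ds = beta - pr.delta_c * pr.Gamma * s * p ** 2
            dp = (pr.rho0 - pr.delta_p * p
                  + (pr.rho1 - 2 * pr.delta_c) * pr.Gamma * s * p ** 2)
            u, v = sp.lam * p, sp.mu * s
            du_dtau = sp.lam * dp / pr.delta_p
            dv_dtau = sp.mu * ds / pr.delta_p
            assert du_dtau == pytest.approx(sp.a - u + u ** 2 * v, rel=1e-10)
            assert dv_dtau == pytest.approx(sp.b - u ** 2 * v, rel=1e-10)

    def test_homogeneous_steady_state_matches_root_finding(self):
        from scipy.optimize import fsolve
        pr = ParamSet(delta_s=0.0)
        sp = schnakenberg_limit(pr, f_const=1.0)
        u0, v0 = sp.steady_state
        res = fsolve(lambda x: [sp.a - x[0] + x[0] ** 2 * x[1],
                                sp.b - x[0] ** 2 * x[1]], [u0, v0], full_output=False)
        assert np.allclose([u0, v0], res)

    def test_no_autocatalysis_rejected(self):
        with pytest.raises(ValueError, match="autocatalysis"):
            schnakenberg_limit(ParamSet(rho1=0.5), f_const=1.0)


class TestRedimensionalize:
    def test_identity_scales_return_dimensionless_values(self, reference_params):
        out = redimensionalize(reference_params, Scales(L=1.0, T=1.0))
        assert out["D_f"] == reference_params.D_f
        assert out["delta_s"] == reference_params.delta_s

    def test_anchor_values(self, reference_params):
        # T derived by inverting the Ptc diffusivity anchor: 0.02 L^2/T = 0.05
        sc = Scales(L=50.0, T=1000.0)
        out = redimensionalize(reference_params, sc)
        assert out["D_p"] == pytest.approx(0.05)     # µm²/s
        assert out["D_f"] == pytest.approx(12.5)     # µm²/s
        assert out["D_s"] == pytest.approx(2.5)
        assert out["D_cav"] == pytest.approx(100.0)

    def test_growth_speed_conversion(self):
        # 14 µm/h with L=50 µm, T=1000 s
        assert dimensionless_speed(14.0) == pytest.approx(0.0778, rel=1e-3)
        assert dimensionless_speed(3.6) == pytest.approx(0.02, rel=1e-9)
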