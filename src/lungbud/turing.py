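"""Linear stability analysis: uniform steady states and dispersion relations.

The diffusion-driven (Turing) character of the patterning mechanism is
established on a spatially homogeneous surrogate in which all production
terms are active (the configuration corresponding to a no-flux, one-tissue
domain): the homogeneous steady state must be stable to uniform
perturbations (k = 0) and unstable within a finite band of wavenumbers.
A classical Schnakenberg closed form serves as an independent oracle for
the two-species limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .params import (ParamSet, SchnakenbergParams, hill_activation,
                     hill_repression, qssa_complex)

__all__ = [
    "DispersionResult",
    "homogeneous_rates",
    "homogeneous_jacobian",
    "uniform_steady_state",
    "dispersion",
    "fastest_growing_wavelength",
    "schnakenberg_dispersion_bounds",
    "schnakenberg_jacobian",
    "is_turing_unstable",
]


def homogeneous_rates(x, params: ParamSet):
    """Reaction RHS of the well-mixed surrogate (all productions active)."""
    f, s, p = x
    pr = params
    c = qssa_complex(s, p, pr.Gamma, pr.n_S, pr.m_P)
    df = pr.nu_f * hill_repression(c, pr.K_f, pr.n) - pr.delta_f * f
    ds = pr.nu_s * hill_activation(f, pr.K_s, pr.n) - pr.delta_s * s - pr.delta_c * c
    dp = pr.rho0 + pr.rho1 * c - pr.delta_p * p - pr.m_P * pr.delta_c * c
    return np.array([df, ds, dp], dtype=float)


def homogeneous_jacobian(x, params: ParamSet) -> np.ndarray:
    """Analytic Jacobian of :func:`homogeneous_rates` at state ``x``."""
    f, s, p = (float(v) for v in x)
    pr = params
    c = pr.Gamma * s ** pr.n_S * p ** pr.m_P
    c_s = pr.Gamma * pr.n_S * s ** (pr.n_S - 1) * p ** pr.m_P if s > 0 or pr.n_S == 1 else 0.0
    c_p = pr.Gamma * pr.m_P * s ** pr.n_S * p ** (pr.m_P - 1) if p > 0 or pr.m_P == 1 else 0.0
    Kfn = pr.K_f ** pr.n
    dHrep = -pr.n * c ** (pr.n - 1) * Kfn / (Kfn + c ** pr.n) ** 2
    Ksn = pr.K_s ** pr.n
    dHact = pr.n * Ksn * f ** (pr.n - 1) / (Ksn + f ** pr.n) ** 2
    net = pr.rho1 - pr.m_P * pr.delta_c
    return np.array([
        [-pr.delta_f, pr.nu_f * dHrep * c_s, pr.nu_f * dHrep * c_p],
        [pr.nu_s * dHact, -pr.delta_s - pr.delta_c * c_s, -pr.delta_c * c_p],
        [0.0, net * c_s, net * c_p - pr.delta_p],
    ])


def uniform_steady_state(params: ParamSet, multistart: int = 40,
                         seed: int = 0, tol: float = 1e-10):
    """Non-negative root(s) of the well-mixed reaction RHS.

    Returns ``(state, n_roots)`` where ``state`` is the root with the
    largest Ptc concentration among the distinct non-negative roots found
    by multistart root-finding (the patterning-relevant branch), or
    ``(None, 0)`` if no non-negative root exists.
    """
    pr = params
    rng = np.random.default_rng(seed)
    # All uniform steady states of the surrogate are strictly positive
    # (zero-order production of f and p), so root-find in log space, which
    # also keeps the Hill terms in their domain.
    guesses = [
        np.array([pr.nu_f / max(pr.delta_f, 1e-12),
                  pr.nu_s / max(pr.delta_s, 1e-12),
                  pr.rho0 / max(pr.delta_p, 1e-12)]),
        np.ones(3),
    ]
    lo, hi = -3, 4
    for _ in range(multistart):
        guesses.append(10 ** rng.uniform(lo, hi, size=3))

    def rates_log(y):
        return homogeneous_rates(np.exp(y), pr)

    def jac_log(y):
        x = np.exp(y)
        return homogeneous_jacobian(x, pr) * x[None, :]

    roots = []
    for g in guesses:
        sol = optimize.root(rates_log, np.log(np.asarray(g, dtype=float)),
                            jac=jac_log, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        x = np.exp(sol.x)
        if np.max(np.abs(homogeneous_rates(x, pr))) > 1e-8:
            continue
        if not any(np.allclose(x, r, rtol=1e-6, atol=1e-9) for r in roots):
            roots.append(x)
    if not roots:
        return None, 0
    best = max(roots, key=lambda r: r[2])
    return best, len(roots)


@dataclass
class DispersionResult:
    """Growth rate of spatial perturbations versus wavenumber."""

    k: np.ndarray
    lambda_max: np.ndarray          # max Re eigenvalue of J - k^2 D at each k
    stable_at_zero: bool
    k_lo: float | None              # unstable band boundaries (None if empty)
    k_hi: float | None

    @property
    def turing_positive(self) -> bool:
        return self.stable_at_zero and self.k_lo is not None

    @property
    def band(self):
        return (self.k_lo, self.k_hi) if self.k_lo is not None else None


def _relmax(J, D, k):
    return float(np.max(np.linalg.eigvals(J - k ** 2 * np.diag(D)).real))


def dispersion(J: np.ndarray, D, k_grid=None, tol: float = 1e-6) -> DispersionResult:
    """Dispersion relation Reλ_max(k) for the linearisation J - k² diag(D).

    ``J`` is the reaction Jacobian at a uniform steady state and ``D`` the
    species diffusivities.  Band boundaries are refined by bisection of
    Reλ_max to ``tol``.
    """
    D = np.asarray(D, dtype=float)
    if k_grid is None:
        k_grid = np.logspace(-2, 2, 400)
    k_grid = np.asarray(k_grid, dtype=float)
    lam = np.array([_relmax(J, D, k) for k in k_grid])
    lam0 = _relmax(J, D, 0.0)
    stable0 = lam0 < 0
    k_lo = k_hi = None
    pos = np.where(lam > 0)[0]
    if pos.size:
        i0, i1 = pos[0], pos[-1]

        def f(k):
            return _relmax(J, D, k)

        if i0 == 0:
            k_lo = k_grid[0]
        else:
            k_lo = optimize.bisect(f, k_grid[i0 - 1], k_grid[i0], xtol=tol)
        if i1 == len(k_grid) - 1:
            k_hi = k_grid[-1]
        else:
            k_hi = optimize.bisect(f, k_grid[i1], k_grid[i1 + 1], xtol=tol)
    return DispersionResult(k=k_grid, lambda_max=lam, stable_at_zero=stable0,
                            k_lo=k_lo, k_hi=k_hi)


def fastest_growing_wavelength(result: DispersionResult):
    """2π over the wavenumber maximising Reλ_max; None for an empty band."""
    if result.k_lo is None:
        return None
    # the 400-point logarithmic grid resolves the peak to well under 3%
    i = int(np.argmax(result.lambda_max))
    return 2.0 * np.pi / float(result.k[i])


def schnakenberg_jacobian(sp: SchnakenbergParams) -> np.ndarray:
    """Reaction Jacobian of u_t = a - u + u²v, v_t = b - u²v at the steady state."""
    u, v = sp.steady_state
    return np.array([[-1.0 + 2.0 * u * v, u ** 2],
                     [-2.0 * u * v, -u ** 2]])


def schnakenberg_dispersion_bounds(sp: SchnakenbergParams):
    """Closed-form Turing band of the classical Schnakenberg model.

    The band follows from the quadratic (in k²)
    h(k²) = D_u D_v k⁴ − (D_v f_u + D_u g_v) k² + det J;
    instability requires h < 0.  Returns (k_lo, k_hi) or None, plus the
    stability flag at k = 0.
    """
    J = schnakenberg_jacobian(sp)
    f_u, g_v = J[0, 0], J[1, 1]
    detJ = float(np.linalg.det(J))
    trJ = f_u + g_v
    stable0 = (trJ < 0) and (detJ > 0)
    b2 = sp.D_v * f_u + sp.D_u * g_v
    disc = b2 ** 2 - 4.0 * sp.D_u * sp.D_v * detJ
    if b2 <= 0 or disc <= 0:
        return None, stable0
    r1 = (b2 - np.sqrt(disc)) / (2.0 * sp.D_u * sp.D_v)
    r2 = (b2 + np.sqrt(disc)) / (2.0 * sp.D_u * sp.D_v)
    if r2 <= 0:
        return None, stable0
    return (np.sqrt(max(r1, 0.0)), np.sqrt(r2)), stable0


def is_turing_unstable(params: ParamSet, k_grid=None):
    """One-call Turing verdict for the homogeneous surrogate of a ParamSet.

    Returns ``(verdict, steady_state, DispersionResult)``; verdict is False
    with ``None`` results when no positive uniform steady state exists.
    """
    ss, nroots = uniform_steady_state(params)
    if ss is None:
        return False, None, None
    J = homogeneous_jacobian(ss, params)
    D = np.array([params.D_f, params.D_s, params.D_p])
    disp = dispersion(J, D, k_grid=k_grid)
    return disp.turing_positive, ss, disp
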