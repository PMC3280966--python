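"""Implicit reaction–diffusion solver on a fixed lung-bud mesh.

Backward-Euler time stepping with (modified) Newton iterations and an
adaptive step size, driving the system from zero initial concentrations
(plus a small seeded symmetry-breaking perturbation) to its patterned
steady state.  Kinetics are compartment-gated through per-node lumped
subdomain masses; diffusion is per-element with cavity values for the
freely diffusing ligands and zero cavity diffusivity for the membrane
receptor Ptc.

Supports both the three-species quasi-steady-state model and the full
four-species model with an explicit SHH–Ptc complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from . import fem
from .mesh import Mesh
from .params import ParamSet

__all__ = ["BoundaryCondition", "FieldState", "SolveReport", "System",
           "integrate", "run_to_steady", "SolverError"]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class BoundaryCondition:
    """Far-field treatment.

    ``open_farfield`` imposes the zero bulk concentration on the outer
    boundary of a buffer whose width follows the diffusion-length rule
    sqrt(D_cav · t_max); ``no_flux`` closes the lung boundary (used on
    tissue-only domains together with rescaled production/decay).
    """

    kind: str = "open_farfield"
    t_max: float = 150.0

    def __post_init__(self) -> None:
        if self.kind not in ("open_farfield", "no_flux"):
            raise ValueError(f"unknown boundary condition kind {self.kind!r}")
        if self.kind == "open_farfield" and self.t_max <= 0:
            raise ValueError("open_farfield requires t_max > 0")

    def buffer_width(self, params: ParamSet) -> float:
        if self.kind == "no_flux":
            return 0.0
        return float(np.sqrt(params.D_cav * self.t_max))


@dataclass
class FieldState:
    """Nodal concentrations at one time point."""

    f: np.ndarray
    s: np.ndarray
    p: np.ndarray
    t: float
    mesh: Mesh
    c: np.ndarray | None = None

    def copy(self) -> "FieldState":
        return FieldState(self.f.copy(), self.s.copy(), self.p.copy(),
                          self.t, self.mesh,
                          None if self.c is None else self.c.copy())

    @property
    def fields(self):
        out = {"f": self.f, "s": self.s, "p": self.p}
        if self.c is not None:
            out["c"] = self.c
        return out


@dataclass
class SolveReport:
    state: FieldState
    steady: bool
    residual_history: list
    n_steps: int
    wall_time: float
    hmax: float
    config_hash: str | None = None


class System:
    """Assembled spatial operators plus vectorised compartment kinetics.

    ``noise`` maps parameter names to nodal multiplicative factor fields
    (1 + ξ(x)); diffusivity factors are averaged onto elements.
    """

    SPECIES_QSSA = ("f", "s", "p")
    SPECIES_FULL = ("f", "s", "p", "c")

    def __init__(self, mesh: Mesh, params: ParamSet, bc: BoundaryCondition,
                 model: str = "qssa", noise: dict | None = None,
                 homogeneous: bool = False):
        if model not in ("qssa", "full"):
            raise ValueError(f"unknown model {model!r}")
        self.params = params
        self.bc = bc
        self.model = model
        self.noise = dict(noise or {})
        #: treat the whole tissue as one compartment with every production
        #: term active (the configuration of the linear stability analysis
        #: and of the mesenchyme-free culture)
        self.homogeneous = homogeneous
        self.species = self.SPECIES_FULL if model == "full" else self.SPECIES_QSSA
        self.set_mesh(mesh)

    # ------------------------------------------------------------------ mesh
    def _nodal_factor(self, name):
        return self.noise.get(name, 1.0)

    def _element_factor(self, name, mesh):
        fac = self.noise.get(name)
        if fac is None:
            return 1.0
        return np.asarray(fac)[mesh.tris].mean(axis=1)

    def set_mesh(self, mesh: Mesh) -> None:
        self.mesh = mesh
        basis = fem.P1Basis(mesh.points, mesh.tris)
        self.basis = basis
        self.M = fem.mass(basis)
        mlab = fem.lumped_mass_by_label(basis, mesh.labels)
        N = mesh.n_nodes
        z = np.zeros(N)
        self.w_lum = mlab.get(1, z)
        self.w_epi = mlab.get(2, z)
        self.w_mes = mlab.get(3, z)
        self.w_int = mlab.get(4, z)
        self.w_all = self.w_lum + self.w_epi + self.w_mes + self.w_int
        self.w_tis = self.w_epi + self.w_mes
        if self.homogeneous:
            self.w_epi = self.w_mes = self.w_tis
        pr = self.params
        tissue = np.isin(mesh.labels, (2, 3))
        d_f = np.where(tissue, pr.D_f, pr.D_cav) * self._element_factor("D_f", mesh)
        d_s = np.where(tissue, pr.D_s, pr.D_cav) * self._element_factor("D_s", mesh)
        d_p = np.where(tissue, pr.D_p, 0.0) * self._element_factor("D_p", mesh)
        self.K = {"f": fem.stiffness(basis, d_f),
                  "s": fem.stiffness(basis, d_s),
                  "p": fem.stiffness(basis, d_p)}
        if self.model == "full":
            self.K["c"] = sparse.csr_matrix((N, N))
        # Dirichlet projector for the open far field (all species; p and c
        # are identically zero in the buffer anyway)
        self.dirichlet = (mesh.outer if self.bc.kind == "open_farfield"
                          else np.zeros(N, dtype=bool))
        # the membrane-bound species have no degrees of freedom inside the
        # cavities: pin pure-cavity nodes to zero
        cavity_only = self.w_tis == 0.0
        self.fixed = {a: self.dirichlet for a in ("f", "s")}
        for a in ("p", "c"):
            self.fixed[a] = self.dirichlet | cavity_only

    # ------------------------------------------------------------ kinetics
    def reaction(self, U: dict, jac: bool = False):
        """Mass-integrated nodal reaction rates (and diagonal Jacobian blocks).

        Returns ``rates[name]`` (length-N arrays); with ``jac=True`` also a
        dict of nodal derivative arrays ``J[(a, b)] = d rate_a / d b``.
        """
        pr = self.params
        nf = self._nodal_factor
        f, s, p = U["f"], U["s"], U["p"]
        fc = np.maximum(f, 0.0)
        sc = np.maximum(s, 0.0)
        pc = np.maximum(p, 0.0)
        if self.model == "full":
            c = U["c"]
            cc = np.maximum(c, 0.0)
        else:
            cc = pr.Gamma * sc ** pr.n_S * pc ** pr.m_P
        Kfn = pr.K_f ** pr.n
        cn = cc ** pr.n
        Hrep = Kfn / (Kfn + cn)
        Ksn = pr.K_s ** pr.n
        fn = fc ** pr.n
        Hact = fn / (Ksn + fn)

        w_all, w_tis, w_mes, w_epi = self.w_all, self.w_tis, self.w_mes, self.w_epi
        nu_f = pr.nu_f * nf("nu_f")
        nu_s = pr.nu_s * nf("nu_s")
        rho0 = pr.rho0 * nf("rho0")
        rho1 = pr.rho1 * nf("rho1")
        d_f = pr.delta_f * nf("delta_f")
        d_s = pr.delta_s * nf("delta_s")
        d_p = pr.delta_p * nf("delta_p")
        d_c = pr.delta_c * nf("delta_c")

        rates = {}
        rates["f"] = w_mes * nu_f * Hrep - w_all * d_f * f
        if self.model == "full":
            k_on = pr.k_on * nf("k_on")
            k_off = pr.k_off * nf("k_off")
            B = k_on * sc ** pr.n_S * pc ** pr.m_P - k_off * c
            rates["s"] = w_epi * nu_s * Hact - w_all * d_s * s - w_tis * B
            rates["p"] = (w_mes * (rho0 + rho1 * cc)
                          - w_tis * (d_p * p + pr.m_P * B))
            rates["c"] = w_tis * (B - d_c * c)
        else:
            rates["s"] = w_epi * nu_s * Hact - w_all * d_s * s - w_tis * d_c * cc
            rates["p"] = (w_mes * (rho0 + rho1 * cc)
                          - w_tis * (d_p * p + pr.m_P * d_c * cc))
        if not jac:
            return rates

        # Hill derivatives (clamped fields: zero slope below zero)
        dHrep_dc = -pr.n * cc ** (pr.n - 1) * Kfn / (Kfn + cn) ** 2
        dHact_df = pr.n * Ksn * fc ** (pr.n - 1) / (Ksn + fn) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            if pr.n_S == 1:
                c_s = pr.Gamma * pc ** pr.m_P
            else:
                c_s = pr.Gamma * pr.n_S * sc ** (pr.n_S - 1) * pc ** pr.m_P
            c_p = pr.Gamma * pr.m_P * sc ** pr.n_S * pc ** (pr.m_P - 1)
        c_s = np.nan_to_num(c_s)
        c_p = np.nan_to_num(c_p)
        J = {}
        J[("f", "f")] = -w_all * d_f
        J[("s", "f")] = w_epi * nu_s * dHact_df
        if self.model == "full":
            k_on = pr.k_on * nf("k_on")
            k_off = pr.k_off * nf("k_off")
            B_s = k_on * (c_s / max(pr.Gamma, 1e-300))
            B_p = k_on * (c_p / max(pr.Gamma, 1e-300))
            J[("f", "c")] = w_mes * nu_f * dHrep_dc
            J[("s", "s")] = -w_all * d_s - w_tis * B_s
            J[("s", "p")] = -w_tis * B_p
            J[("s", "c")] = w_tis * k_off * np.ones_like(f)
            J[("p", "s")] = -w_tis * pr.m_P * B_s
            J[("p", "p")] = -w_tis * (d_p + pr.m_P * B_p)
            J[("p", "c")] = w_mes * rho1 + w_tis * pr.m_P * k_off
            J[("c", "s")] = w_tis * B_s
            J[("c", "p")] = w_tis * B_p
            J[("c", "c")] = -w_tis * (k_off + d_c)
        else:
            J[("f", "s")] = w_mes * nu_f * dHrep_dc * c_s
            J[("f", "p")] = w_mes * nu_f * dHrep_dc * c_p
            J[("s", "s")] = -w_all * d_s - w_tis * d_c * c_s
            J[("s", "p")] = -w_tis * d_c * c_p
            J[("p", "s")] = (w_mes * rho1 - w_tis * pr.m_P * d_c) * c_s
            J[("p", "p")] = (w_mes * rho1 - w_tis * pr.m_P * d_c) * c_p - w_tis * d_p
        return rates, J

    # ---------------------------------------------------------- linear algebra
    def jacobian(self, U: dict, dt: float, M=None, A=None) -> sparse.csc_matrix:
        M = self.M if M is None else M
        _, Jr = self.reaction(U, jac=True)
        n = self.mesh.n_nodes
        keep = {a: sparse.diags((~self.fixed[a]).astype(float))
                for a in self.species}
        blocks = []
        for a in self.species:
            row = []
            for b in self.species:
                blk = None
                if a == b:
                    blk = M / dt + self.K[a]
                    if A is not None:
                        blk = blk + A
                d = Jr.get((a, b))
                if d is not None:
                    dd = sparse.diags(np.broadcast_to(-np.asarray(d, float), (n,)))
                    blk = dd if blk is None else blk + dd
                if blk is not None:
                    blk = keep[a] @ blk @ keep[b]
                    if a == b:
                        blk = blk + sparse.diags(self.fixed[a].astype(float))
                row.append(blk)
            blocks.append(row)
        return sparse.bmat(blocks, format="csc")

    def residual(self, U1: dict, U0: dict, dt: float, M=None, M0=None, A=None):
        M = self.M if M is None else M
        M0 = M if M0 is None else M0
        rates = self.reaction(U1)
        out = []
        for a in self.species:
            g = (M @ U1[a] - M0 @ U0[a]) / dt + self.K[a] @ U1[a] - rates[a]
            if A is not None:
                g = g + A @ U1[a]
            g = np.where(self.fixed[a], U1[a], g)
            out.append(g)
        return np.concatenate(out)

    def pack(self, U):
        return np.concatenate([U[a] for a in self.species])

    def unpack(self, x):
        n = self.mesh.n_nodes
        return {a: x[i * n:(i + 1) * n] for i, a in enumerate(self.species)}


def _initial_state(system: System, seed: int, amplitude: float = 1e-6):
    """Zero concentrations plus a seeded perturbation of f in the mesenchyme.

    Turing pattern selection from uniform initial data relies on numerical
    noise; making the perturbation explicit and seeded keeps runs
    bit-reproducible.
    """
    N = system.mesh.n_nodes
    rng = np.random.default_rng(seed)
    U = {a: np.zeros(N) for a in system.species}
    mes = system.w_mes > 0
    U["f"][mes] = amplitude * rng.standard_normal(int(mes.sum()))
    return U


REFRESH_INTERVAL = 4


class _LUCache:
    """Factorisation reused across time steps while dt and state drift slowly."""

    def __init__(self):
        self.lu = None
        self.dt = None

    def invalidate(self):
        self.lu = None
        self.dt = None


def step(system: System, U0: dict, dt: float, M=None, M0=None, A=None,
         max_newton: int = 12, ntol: float = 1e-9, cache: _LUCache | None = None,
         guess: dict | None = None):
    """One backward-Euler step with modified Newton iterations.

    The Jacobian factorisation is reused across iterations (and, via
    ``cache``, across steps); it is refreshed when convergence stalls.
    ``guess`` seeds the Newton iteration (e.g. a linear predictor).
    Returns ``(U1, n_iter)`` or ``(None, n_iter)`` on failure.
    """
    U1 = {a: v.copy() for a, v in (guess or U0).items()}
    own = _LUCache() if cache is None else cache
    if own.dt != dt:
        own.invalidate()
    scale = max(1.0, *(np.abs(v).max() for v in U0.values()))
    built_at = -10
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for it in range(max_newton):
            G = system.residual(U1, U0, dt, M=M, M0=M0, A=A)
            if not np.all(np.isfinite(G)):
                own.invalidate()
                return None, it
            if own.lu is None or it - built_at >= REFRESH_INTERVAL:
                own.lu = splu(system.jacobian(U1, dt, M=M, A=A))
                own.dt = dt
                built_at = it
            delta = own.lu.solve(-G)
            dmax = np.abs(delta).max()
            if not np.isfinite(dmax) or dmax > 1e4 * scale:
                own.invalidate()
                return None, it + 1      # diverging: give up early
            x = system.pack(U1) + delta
            U1 = system.unpack(x)
            if dmax < ntol * scale + 1e-14:
                return U1, it + 1
    own.invalidate()
    return None, max_newton


def integrate(mesh: Mesh, params: ParamSet, bc: BoundaryCondition,
              t_end: float, dt0: float = 0.01, dt_max: float = 5.0,
              dt_min: float = 1e-8, model: str = "qssa",
              noise: dict | None = None, seed: int = 0,
              perturbation: float = 1e-6, initial: dict | None = None,
              save_every: float = np.inf, steady_tol: float = 0.0,
              system: System | None = None):
    """Integrate the reaction–diffusion system on a fixed mesh.

    Returns ``(trajectory, steady, residual_history)`` where trajectory is a
    list of :class:`FieldState` including the final state.  If
    ``steady_tol > 0`` the run stops early once the max-norm rate of change
    per unit time falls below it.
    """
    sys_ = system if system is not None else System(mesh, params, bc,
                                                    model=model, noise=noise)
    U = initial if initial is not None else _initial_state(sys_, seed, perturbation)
    t = 0.0
    dt = dt0
    traj = [FieldState(U["f"].copy(), U["s"].copy(), U["p"].copy(), t, mesh,
                       U.get("c", np.zeros(0)).copy() if "c" in U else None)]
    hist = []
    last_save = 0.0
    steady = False
    n_steps = 0
    cache = _LUCache()
    since_fail = 100
    U_prev = None
    dt_prev = None
    while t < t_end - 1e-12:
        dt_try = min(dt, t_end - t)
        guess = None
        if U_prev is not None and dt_prev is not None and dt_prev > 0:
            r = dt_try / dt_prev
            guess = {a: U[a] + r * (U[a] - U_prev[a]) for a in sys_.species}
        U1, iters = step(sys_, U, dt_try, cache=cache, guess=guess)
        if U1 is None:
            dt *= 0.4
            since_fail = 0
            U_prev = None
            if dt < dt_min:
                raise SolverError(
                    f"time step collapsed below {dt_min} at t={t:.4g} "
                    f"(Newton not converging)")
            continue
        rate = max(np.abs(U1[a] - U[a]).max() for a in sys_.species) / dt_try
        hist.append((t + dt_try, rate))
        U_prev = U
        dt_prev = dt_try
        U = U1
        t += dt_try
        n_steps += 1
        since_fail += 1
        # dt doubling keeps the factorisation reusable between changes; hold
        # back for a few steps after a Newton failure to avoid thrashing
        if iters <= 6 and dt < dt_max and since_fail >= 4:
            dt = min(dt * 2.0, dt_max)
        elif iters >= 10:
            dt = max(dt * 0.5, dt_min)
        if t - last_save >= save_every:
            traj.append(FieldState(U["f"].copy(), U["s"].copy(), U["p"].copy(),
                                   t, mesh,
                                   U["c"].copy() if "c" in U else None))
            last_save = t
        if steady_tol > 0 and rate < steady_tol and t > 10 * dt0:
            steady = True
            break
    final = FieldState(U["f"].copy(), U["s"].copy(), U["p"].copy(), t, mesh,
                       U["c"].copy() if "c" in U else None)
    if not traj or traj[-1].t < t:
        traj.append(final)
    return traj, steady, hist


def run_to_steady(mesh: Mesh, params: ParamSet, bc: BoundaryCondition,
                  tol: float = 1e-6, t_max: float = 150.0,
                  model: str = "qssa", noise: dict | None = None,
                  seed: int = 0, config_hash: str | None = None,
                  dt_max: float = 5.0) -> SolveReport:
    """Drive the system to steady state (or report non-steadiness at t_max)."""
    import time as _time

    t0 = _time.perf_counter()
    traj, steady, hist = integrate(mesh, params, bc, t_end=t_max,
                                   dt_max=dt_max, model=model, noise=noise,
                                   seed=seed, steady_tol=tol)
    return SolveReport(state=traj[-1], steady=steady, residual_history=hist,
                       n_steps=len(hist), wall_time=_time.perf_counter() - t0,
                       hmax=mesh.hmax, config_hash=config_hash)
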