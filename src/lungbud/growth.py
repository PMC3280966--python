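"""Reaction–diffusion dynamics on a growing lung stalk.

The bud elongates one-dimensionally along its axis; concentrations obey
the reaction–diffusion equations extended by advection–dilution transport
∇·(u c), so that growth conserves mass rather than concentration.  Three
growth modes are supported:

* ``uniform`` — homogeneous relative growth (stretching) at rate μ, giving
  exponential elongation h(t) = h0·e^{μt};
* ``tip``     — new material inserted in a zone of fixed depth behind the
  tip, the proximal stalk at rest, constant elongation speed v;
* ``graded``  — axial growth distributed between stalk and tip zone with a
  prescribed tip-to-stalk rate ratio, at constant elongation speed v.

Numerically the mesh moves with the material (arbitrary
Lagrangian–Eulerian with the structured mesh following the parametric
domain), so the discrete update M(t₁)c₁ − M(t₀)c₀ = Δt(−Kc₁ − A(w)c₁ + R)
conserves ∫c exactly under pure growth; ``w`` is the material-minus-mesh
relative velocity.  When accumulated stretch degrades the axial
resolution, the stalk is remeshed and fields are transferred by
interpolation in the parametric coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fem
from .mesh import Mesh, remesh_axial
from .params import ParamSet
from .patterns import PatternConfig, branch_events, detect_spots, classify_mode
from .solve import (BoundaryCondition, FieldState, System, _LUCache,
                    _initial_state, step, SolverError)

__all__ = ["GrowthSpec", "uniform_growth_height", "grow_and_solve",
           "branch_site_location_mode"]


@dataclass(frozen=True)
class GrowthSpec:
    """Growth protocol of the stalk."""

    mode: str = "tip"
    v: float = 0.078            # elongation speed (tip, graded)
    mu: float = 0.0             # relative rate, uniform mode (1/time)
    ratio_tip_stalk: float = 1.0
    tip_zone: float = 1.0       # depth of the tip growth zone below the cap
    t_end: float = 86.4

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "tip", "graded"):
            raise ValueError(f"unknown growth mode {self.mode!r}")
        if self.v < 0 or self.mu < 0:
            raise ValueError("growth speeds/rates must be >= 0")
        if self.ratio_tip_stalk < 1.0:
            raise ValueError("tip/stalk growth-rate ratio must be >= 1")
        if self.tip_zone <= 0:
            raise ValueError("tip growth zone depth must be positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")

    def height(self, h0: float, t: float) -> float:
        if self.mode == "uniform":
            return uniform_growth_height(h0, self.mu, t)
        return h0 + self.v * t

    def material_velocity(self, y, h: float):
        """Axial material velocity profile u(y) at stalk length h."""
        y = np.asarray(y, dtype=float)
        if self.mode == "uniform":
            return self.mu * np.minimum(y, h)
        w = min(self.tip_zone, h)
        if self.mode == "tip":
            return self.v * np.clip((y - (h - w)) / w, 0.0, 1.0)
        # graded: stalk rate mu_s, tip zone rate r*mu_s, elongation speed v
        r = self.ratio_tip_stalk
        mu_s = self.v / ((h - w) + r * w)
        return mu_s * (np.minimum(y, h - w)
                       + r * np.clip(y - (h - w), 0.0, w))


def uniform_growth_height(h0: float, mu: float, t) -> float:
    """Exponential stalk elongation h(t) = h0·e^{μt} under homogeneous growth."""
    if mu < 0:
        raise ValueError("growth rate must be >= 0")
    return h0 * np.exp(mu * np.asarray(t, dtype=float))


def grow_and_solve(mesh0: Mesh, params: ParamSet, bc: BoundaryCondition,
                   growth: GrowthSpec, seed: int = 0,
                   model: str = "qssa", noise: dict | None = None,
                   dt0: float = 0.01, dt_max: float = 1.0,
                   dt_min: float = 1e-8, perturbation: float = 1e-6,
                   save_every: float = 2.0, remesh_stretch: float = 1.5,
                   reactions: bool = True, initial: dict | None = None):
    """Integrate the model while the stalk elongates; returns a trajectory.

    The trajectory is a list of :class:`FieldState` (each carrying its
    mesh, hence the instantaneous domain height).  ``reactions=False``
    switches off all kinetics (the mass-conservation control).
    """
    pr = params if reactions else params.replace(
        nu_f=0.0, nu_s=0.0, rho0=0.0, rho1=0.0, delta_f=0.0, delta_s=0.0,
        delta_p=0.0, delta_c=0.0)
    system = System(mesh0, pr, bc, model=model, noise=noise)
    U = ({a: v.copy() for a, v in initial.items()} if initial is not None
         else _initial_state(system, seed, perturbation))
    mesh = mesh0
    h_built = mesh.h     # stalk length at last (re)meshing
    t = 0.0
    dt = dt0
    traj = [FieldState(U["f"].copy(), U["s"].copy(), U["p"].copy(), t, mesh,
                       U["c"].copy() if "c" in U else None)]
    last_save = 0.0
    cache = _LUCache()
    since_fail = 100
    U_prev = None
    dt_prev = None
    while t < growth.t_end - 1e-12:
        dt_try = min(dt, growth.t_end - t)
        h0_step = mesh.h
        h1 = growth.height(mesh0.h, t + dt_try) if growth.mode != "uniform" \
            else uniform_growth_height(mesh0.h, growth.mu, t + dt_try)
        # move the mesh with the stalk
        M0 = system.M
        mesh1 = mesh.with_height(h1)
        system.set_mesh(mesh1)
        # relative (material - mesh) velocity, axial
        y = mesh1.points[:, 1]
        u_mat = growth.material_velocity(y, h1)
        hdot = (h1 - h0_step) / dt_try
        u_mesh = hdot * np.minimum(y / h1, 1.0)
        w = np.zeros_like(mesh1.points)
        w[:, 1] = u_mat - u_mesh
        A = fem.advection(system.basis, w)
        cache.invalidate()
        guess = None
        if U_prev is not None and dt_prev:
            r = dt_try / dt_prev
            guess = {a: U[a] + r * (U[a] - U_prev[a]) for a in system.species}
        U1, iters = step(system, U, dt_try, M0=M0, A=A, cache=cache, guess=guess)
        if U1 is None:
            system.set_mesh(mesh)    # roll back
            dt *= 0.4
            since_fail = 0
            U_prev = None
            if dt < dt_min:
                raise SolverError(f"growth step collapsed at t={t:.4g}")
            continue
        U_prev = U
        dt_prev = dt_try
        U = U1
        mesh = mesh1
        t += dt_try
        since_fail += 1
        if iters <= 6 and dt < dt_max and since_fail >= 4:
            dt = min(dt * 2.0, dt_max)
        elif iters >= 10:
            dt = max(dt * 0.5, dt_min)
        # remesh when the stalk has stretched too far
        if h1 / h_built > remesh_stretch:
            mesh, transfer = remesh_axial(mesh, h1)
            U = {a: transfer(v) for a, v in U.items()}
            if noise:
                noise = {k: (transfer(np.asarray(v, float))
                             if np.ndim(v) else v) for k, v in noise.items()}
                system = System(mesh, pr, bc, model=model, noise=noise)
            else:
                system.set_mesh(mesh)
            h_built = h1
            cache.invalidate()
            U_prev = None
        if t - last_save >= save_every or t >= growth.t_end - 1e-12:
            traj.append(FieldState(U["f"].copy(), U["s"].copy(),
                                   U["p"].copy(), t, mesh,
                                   U["c"].copy() if "c" in U else None))
            last_save = t
    return traj


def establishment_time(trajectory, config: PatternConfig = PatternConfig(),
                       min_amplitude: float = 0.01):
    """First time at which the FGF10 field shows a classified pattern.

    Snapshots still at seed-noise amplitude (below ``min_amplitude``) do
    not count as patterned.
    """
    for st in trajectory:
        if st.f.max() < min_amplitude:
            continue
        spots = detect_spots(st.mesh, st.f, config)
        if classify_mode(spots) != "none":
            return st.t
    return None


def branch_site_location_mode(growth: GrowthSpec, trajectory,
                              config: PatternConfig = PatternConfig(),
                              behind_window: float = 2.0,
                              establish_margin: float = 5.0) -> str:
    """Where do new FGF10 maxima first appear relative to the tip?

    Events during initial pattern establishment are excluded; each later
    event is scored as behind-tip (within ``behind_window`` of the cap
    apex) or proximal.  Returns ``behind_tip``, ``proximal``, ``mixed`` or
    ``none`` (no post-establishment events).
    """
    events = branch_events(trajectory, config)
    t_est = establishment_time(trajectory, config)
    if t_est is None:
        return "none"
    ev = [e for e in events if e.t > t_est + establish_margin]
    if not ev:
        return "none"
    behind = sum(1 for e in ev if e.distance_behind_tip <= behind_window)
    frac = behind / len(ev)
    if frac >= 0.75:
        return "behind_tip"
    if frac <= 0.25:
        return "proximal"
    return "mixed"
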