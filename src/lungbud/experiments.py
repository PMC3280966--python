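"""Drivers for the in-silico studies.

Each driver wires together the geometry, solver, growth and pattern
modules to reproduce one study design: the one-at-a-time sensitivity scan,
spatial parameter-noise robustness on the growing domain, growth-mode and
growth-speed selection, the mutant scenarios, and the mesenchyme-free
culture limit.  Protocol constants (domain sizes, run lengths, growth
speeds) are module-level and documented; all stochastic inputs derive
from explicit seeds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import sparse

from .geometry import LungGeometry, build_geometry
from .growth import GrowthSpec, grow_and_solve, branch_site_location_mode
from .mesh import Mesh, make_mesh
from .params import ParamSet, Scales, dimensionless_speed
from .patterns import PatternConfig, PatternReport, analyze, branch_events, detect_spots, classify_mode
from .solve import BoundaryCondition, System, integrate, run_to_steady

__all__ = [
    "KINETIC_PARAMS", "FAST_GROWTH_UM_H", "SLOW_GROWTH_UM_H",
    "derive_seed", "classify_steady", "gaussian_random_field", "noise_fields",
    "ScanResult", "sensitivity_scan", "noise_robustness", "growth_protocol",
    "classify_growth_run", "mutant_suite", "ptc_onset_time",
    "mesenchyme_free", "culture_mesh",
]

#: dimensionless kinetic/transport parameters subject to scans and noise
#: (geometry is never varied)
KINETIC_PARAMS = ("D_f", "D_s", "D_p", "D_cav", "nu_f", "nu_s", "rho0",
                  "rho1", "delta_f", "delta_s", "delta_p", "delta_c")

#: tip elongation speeds in µm/h: the fast speed drives lateral branching,
#: the ~4-fold slower speed bifurcation
FAST_GROWTH_UM_H = 14.0
SLOW_GROWTH_UM_H = 3.6

#: default protocol constants: steady-state classification runs use an
#: elongated stalk (the reference pattern carries tip plus several flank
#: maxima there); growth runs start from a short bud
STEADY_T_END = 400.0
STEADY_H0 = 6.0
STEADY_REFERENCE_H0 = STEADY_H0
GROWTH_H0 = 2.0
#: growth runs are compared at a fixed simulated time (the duration in
#: which the fast protocol elongates by ~4 length units)
GROWTH_T_END = 51.5


def derive_seed(base: int, stream: str) -> int:
    """Per-module sub-seed from the global seed and a stream label."""
    digest = hashlib.sha256(f"{base}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def classify_steady(params: ParamSet, h0: float = STEADY_H0,
                    hmax: float = 0.2, t_end: float = STEADY_T_END,
                    seed: int = 1, bc: BoundaryCondition | None = None,
                    config: PatternConfig = PatternConfig(),
                    geometry: LungGeometry | None = None):
    """Steady-state run plus phenotype; the workhorse of the scans.

    Returns ``(PatternReport, steady_flag, final FieldState)``.
    """
    if bc is None:
        bc = BoundaryCondition(t_max=t_end)
    if geometry is None:
        geometry = LungGeometry(h0=h0)
    if bc.kind == "open_farfield" and geometry.Lfar == 0.0:
        geometry = geometry.with_buffer(bc.buffer_width(params))
    mesh = make_mesh(build_geometry(geometry), hmax)
    traj, steady, _ = integrate(mesh, params, bc, t_end=t_end, seed=seed,
                                steady_tol=1e-6)
    state = traj[-1]
    rep = analyze(state, config)
    return rep, steady, state


# --------------------------------------------------------------------------
# sensitivity scan

@dataclass
class ScanResult:
    reference_class: str
    table: pd.DataFrame          # parameter, factor, pattern_class, steady

    def classes(self, name: str) -> dict:
        sub = self.table[self.table.parameter == name]
        return dict(zip(sub.factor, sub.pattern_class))

    def preserved_at(self, rel: float) -> dict:
        """Per-parameter: is the class preserved at factors (1±rel)?"""
        out = {}
        for name in self.table.parameter.unique():
            cl = self.classes(name)
            out[name] = all(cl.get(round(f, 6), self.reference_class)
                            == self.reference_class
                            for f in (1.0 - rel, 1.0 + rel))
        return out

    def switch_threshold(self, name: str) -> float:
        """Smallest tested |factor-1| at which the class changes (inf if none)."""
        cl = self.classes(name)
        devs = sorted({abs(f - 1.0) for f in cl if f != 1.0})
        for d in devs:
            for f in (1.0 - d, 1.0 + d):
                if round(f, 6) in cl and cl[round(f, 6)] != self.reference_class:
                    return d
        return np.inf


def sensitivity_scan(params: ParamSet, factors=(0.7, 0.8, 1.2, 1.3),
                     names=KINETIC_PARAMS, seed: int = 1,
                     h0: float = STEADY_H0, hmax: float = 0.2,
                     t_end: float = STEADY_T_END,
                     config: PatternConfig = PatternConfig()) -> ScanResult:
    """One-at-a-time multiplicative perturbation of every parameter.

    Non-steady runs are recorded with their end-time class and
    ``steady=False`` rather than dropped.
    """
    ref_rep, ref_steady, _ = classify_steady(params, h0=h0, hmax=hmax,
                                             t_end=t_end, seed=seed,
                                             config=config)
    rows = [{"parameter": "(reference)", "factor": 1.0,
             "pattern_class": ref_rep.pattern_class, "steady": ref_steady,
             "n_spots": ref_rep.n_spots}]
    for name in names:
        for fac in factors:
            try:
                pr = params.scaled(**{name: fac})
            except ValueError:
                rows.append({"parameter": name, "factor": fac,
                             "pattern_class": "invalid", "steady": False,
                             "n_spots": 0})
                continue
            try:
                rep, steady, _ = classify_steady(pr, h0=h0, hmax=hmax,
                                                 t_end=t_end, seed=seed,
                                                 config=config)
                cls = rep.pattern_class if steady else rep.pattern_class
                rows.append({"parameter": name, "factor": fac,
                             "pattern_class": cls, "steady": steady,
                             "n_spots": rep.n_spots})
            except Exception:
                rows.append({"parameter": name, "factor": fac,
                             "pattern_class": "unresolved", "steady": False,
                             "n_spots": 0})
    return ScanResult(reference_class=ref_rep.pattern_class,
                      table=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# spatial parameter noise

def gaussian_random_field(mesh: Mesh, sd: float, corr_length: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Zero-mean nodal Gaussian field with short-range spatial correlation.

    Nodal white noise is smoothed with a Gaussian kernel of width
    ``corr_length`` (about one cell diameter by default, making the
    perturbation cell-scale rather than mesh-scale) and rescaled to the
    requested standard deviation.
    """
    xi = rng.standard_normal(mesh.n_nodes)
    if corr_length > 0:
        tree = cKDTree(mesh.points)
        pairs = tree.sparse_distance_matrix(tree, 3.0 * corr_length,
                                            output_type="coo_matrix")
        w = np.exp(-0.5 * (pairs.data / corr_length) ** 2)
        K = sparse.coo_matrix((w, (pairs.row, pairs.col)),
                              shape=pairs.shape).tocsr()
        norm = np.asarray(K.sum(axis=1)).ravel()
        xi = K @ xi / norm
        s = xi.std()
        if s > 0:
            xi = xi / s
    return sd * xi


def noise_fields(mesh: Mesh, sd: float, corr_length: float, seed: int,
                 names=KINETIC_PARAMS, clip: float = 0.05) -> dict:
    """One independent multiplicative factor field (1+ξ) per parameter.

    Factors are clipped below at ``clip`` so that rates and diffusivities
    stay positive.
    """
    rng = np.random.default_rng(seed)
    return {name: np.clip(1.0 + gaussian_random_field(mesh, sd, corr_length, rng),
                          clip, None)
            for name in names}


def growth_protocol(speed_um_h: float = FAST_GROWTH_UM_H,
                    t_end: float | None = None, mode: str = "tip",
                    ratio: float = 1.0, scales: Scales = Scales()) -> GrowthSpec:
    """The tip-growth protocol in dimensionless units (default: fast/lateral)."""
    v = dimensionless_speed(speed_um_h, scales)
    if t_end is None:
        # compare protocols at the same simulated time: the window in which
        # the fast protocol elongates by ~4 length units
        t_end = GROWTH_T_END
    return GrowthSpec(mode=mode, v=v, ratio_tip_stalk=ratio, t_end=t_end)


def classify_growth_run(params: ParamSet, growth: GrowthSpec,
                        noise: dict | None = None, seed: int = 0,
                        h0: float = GROWTH_H0, hmax: float = 0.2,
                        config: PatternConfig = PatternConfig(),
                        save_every: float = 2.0):
    """Run the growing-domain protocol and classify the final pattern.

    Returns ``(final PatternReport, trajectory)``.
    """
    bc = BoundaryCondition(t_max=growth.t_end)
    geom = LungGeometry(h0=h0, Lfar=bc.buffer_width(params))
    mesh = make_mesh(build_geometry(geom), hmax)
    traj = grow_and_solve(mesh, params, bc, growth, seed=seed, noise=noise,
                          save_every=save_every)
    return analyze(traj[-1], config), traj


def noise_robustness(params: ParamSet, sd: float, replicates: int = 10,
                     corr_length: float = 0.1, seed: int = 0,
                     growth: GrowthSpec | None = None, hmax: float = 0.2,
                     h0: float = GROWTH_H0,
                     reference_class: str = "lateral") -> dict:
    """Fraction of noisy replicates preserving the reference growth pattern.

    Per replicate, every kinetic parameter is multiplied by an independent
    spatial factor field (1+ξ); the tip-growth lateral protocol is run and
    the final pattern classified.  Failed runs count as non-preserving.
    """
    if growth is None:
        growth = growth_protocol()
    bc = BoundaryCondition(t_max=growth.t_end)
    geom = LungGeometry(h0=h0, Lfar=bc.buffer_width(params))
    mesh = make_mesh(build_geometry(geom), hmax)
    results = []
    for rep in range(replicates):
        rep_seed = derive_seed(seed, f"noise:{sd}:{rep}")
        noise = (noise_fields(mesh, sd, corr_length, rep_seed)
                 if sd > 0 else None)
        try:
            traj = grow_and_solve(mesh, params, bc, growth, seed=rep_seed,
                                  noise=noise, save_every=np.inf)
            cls = analyze(traj[-1]).pattern_class
        except Exception:
            cls = "failed"
        results.append({"replicate": rep, "seed": rep_seed, "class": cls})
    frac = np.mean([r["class"] == reference_class for r in results])
    return {"sd": sd, "fraction_preserved": float(frac), "replicates": results}


# --------------------------------------------------------------------------
# mutants

def ptc_onset_time(params: ParamSet, h0: float = 2.0, hmax: float = 0.2,
                   t_end: float = 60.0, seed: int = 1,
                   threshold_factor: float = 2.0):
    """Time at which mesenchymal Ptc first exceeds twice its basal level.

    The basal level is the uncoupled steady state ρ0/δ_p; emergence is the
    first crossing of ``threshold_factor`` times it, linearly interpolated
    between snapshots.  Returns None if never crossed.
    """
    bc = BoundaryCondition(t_max=t_end)
    geom = LungGeometry(h0=h0, Lfar=bc.buffer_width(params))
    mesh = make_mesh(build_geometry(geom), hmax)
    traj, _, _ = integrate(mesh, params, bc, t_end=t_end, seed=seed,
                           save_every=1.0, dt_max=1.0)
    basal = params.rho0 / params.delta_p
    thr = threshold_factor * basal
    mes = mesh.mesenchyme_nodes()
    prev_t, prev_v = 0.0, 0.0
    for st in traj:
        v = float(st.p[mes].max())
        if v >= thr:
            if v == prev_v:
                return st.t
            return prev_t + (thr - prev_v) * (st.t - prev_t) / (v - prev_v)
        prev_t, prev_v = st.t, v
    return None


def mutant_suite(params: ParamSet, seed: int = 1, hmax: float = 0.2,
                 h0: float = 6.0,
                 nu_s_series=(200.0, 400.0, 900.0, 1700.0),
                 rho_factors=(1.0, 2.0, 4.0)) -> pd.DataFrame:
    """Mutant scenarios versus wildtype on equally sized domains.

    Scenarios: reduced FGF10 expression (ν_f × 0.75), enhanced SHH
    diffusion (D_s × 2 and × 6), the SHH-expression series (Ptc onset
    time), and scaled-up Ptc production (max SHH response).  Returns a
    tidy table of scenario → metrics.
    """
    rows = []

    def steady_metrics(tag, pr):
        rep, steady, st = classify_steady(pr, h0=h0, hmax=hmax, seed=seed)
        rows.append({"scenario": tag, "metric": "n_spots", "value": rep.n_spots})
        rows.append({"scenario": tag, "metric": "mean_spacing",
                     "value": rep.mean_spacing})
        rows.append({"scenario": tag, "metric": "max_shh",
                     "value": float(st.s.max())})
        rows.append({"scenario": tag, "metric": "class",
                     "value": rep.pattern_class})
        return rep, st

    steady_metrics("wildtype", params)
    steady_metrics("nu_f_x0.75", params.scaled(nu_f=0.75))
    steady_metrics("D_s_x2", params.scaled(D_s=2.0))
    steady_metrics("D_s_x6", params.scaled(D_s=6.0))
    for fac in rho_factors:
        tag = f"rho_x{fac:g}"
        pr = params.scaled(rho0=fac, rho1=fac)
        rep, steady, st = classify_steady(pr, h0=2.0, hmax=hmax, seed=seed)
        rows.append({"scenario": tag, "metric": "max_shh",
                     "value": float(st.s.max())})
        # effective Ptc production rate per unit mesenchyme area
        sys_ = System(st.mesh, pr, BoundaryCondition(t_max=STEADY_T_END))
        c = pr.Gamma * np.maximum(st.s, 0) ** pr.n_S * np.maximum(st.p, 0) ** pr.m_P
        w = sys_.w_mes
        eff = float((w * (pr.rho0 + pr.rho1 * c)).sum() / w.sum())
        rows.append({"scenario": tag, "metric": "ptc_production_rate",
                     "value": eff})
    for nus in nu_s_series:
        pr = params.replace(nu_s=nus)
        onset = ptc_onset_time(pr, hmax=hmax, seed=seed)
        rows.append({"scenario": f"nu_s_{nus:g}", "metric": "ptc_onset_time",
                     "value": onset})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# mesenchyme-free culture

def culture_mesh(h0: float = 2.0, hmax: float = 0.2,
                 Rc: float = 2.0) -> Mesh:
    """Tissue-only bud-shaped culture domain (no cavities, no buffer).

    All elements are treated as one tissue in which both the SHH source
    and the receptor module operate (the homogeneous configuration of the
    linear stability analysis).
    """
    geom = LungGeometry(h0=h0, Lfar=0.0, Rc=Rc)
    mesh = make_mesh(build_geometry(geom), hmax)
    mesh.labels = np.full_like(mesh.labels, 3)
    return mesh


def reduced_culture_steady_state(params: ParamSet, f_const: float):
    """Uniform steady state of the frozen-FGF10 SHH/Ptc block, or None."""
    from scipy.optimize import brentq

    pr = params
    beta = pr.nu_s * float(hill_activation_safe(f_const, pr.K_s, pr.n))
    net = pr.rho1 - pr.m_P * pr.delta_c
    G = pr.Gamma

    def s_of_p(p):
        return beta / (pr.delta_s + pr.delta_c * G * p ** 2)

    def F(p):
        return pr.rho0 - pr.delta_p * p + net * G * s_of_p(p) * p ** 2

    ps = np.linspace(1e-9, 1e4, 40000)
    vals = F(ps)
    roots = []
    for i in range(len(ps) - 1):
        if vals[i] * vals[i + 1] < 0:
            roots.append(brentq(F, ps[i], ps[i + 1]))
    if not roots:
        return None
    p0 = max(roots)
    return float(s_of_p(p0)), float(p0)


def hill_activation_safe(f, K, n):
    f = max(float(f), 0.0)
    return f ** n / (K ** n + f ** n)


def culture_dispersion_verdict(params: ParamSet, f_const: float):
    """Diffusion-driven instability verdict of the reduced culture system."""
    from .turing import dispersion

    ss = reduced_culture_steady_state(params, f_const)
    if ss is None:
        return False, None
    s0, p0 = ss
    pr = params
    G = pr.Gamma
    c_s = G * p0 ** 2
    c_p = pr.m_P * G * s0 * p0
    net = pr.rho1 - pr.m_P * pr.delta_c
    J = np.array([[-pr.delta_s - pr.delta_c * c_s, -pr.delta_c * c_p],
                  [net * c_s, net * c_p - pr.delta_p]])
    res = dispersion(J, [pr.D_s, pr.D_p])
    return bool(res.turing_positive), ss


def mesenchyme_free(params: ParamSet, f_consts=(0.0, 0.05, 1.0),
                    hmax: float = 0.2, h0: float = 2.0, t_end: float = 400.0,
                    seed: int = 1) -> pd.DataFrame:
    """SHH-Ptc patterning at frozen, spatially uniform FGF10.

    FGF10 is clamped by removing its kinetics (no production, no decay,
    uniform value, no-flux domain) on a tissue-only culture domain with
    both production terms active everywhere, so the SHH/Ptc block runs as
    the reduced two-species system.  The run starts from the reduced
    uniform steady state plus a seeded relative perturbation, and the
    presence of a Ptc pattern is cross-checked against the dispersion
    relation of the same reduced system.
    """
    rows = []
    mesh = culture_mesh(h0=h0, hmax=hmax)
    bc = BoundaryCondition(kind="no_flux")
    for f0 in f_consts:
        pr = params.replace(nu_f=0.0, delta_f=0.0)
        verdict, ss = culture_dispersion_verdict(params, f0)
        N = mesh.n_nodes
        rng = np.random.default_rng(derive_seed(seed, f"culture:{f0}"))
        if ss is None:
            s_init = np.zeros(N)
            p_init = np.zeros(N)
        else:
            s_init = ss[0] * (1.0 + 1e-3 * rng.standard_normal(N))
            p_init = ss[1] * (1.0 + 1e-3 * rng.standard_normal(N))
        init = {"f": np.full(N, float(f0)),
                "s": np.clip(s_init, 0.0, None),
                "p": np.clip(p_init, 0.0, None)}
        system = System(mesh, pr, bc, homogeneous=True)
        traj, steady, _ = integrate(mesh, pr, bc, t_end=t_end, seed=seed,
                                    initial=init, steady_tol=1e-6,
                                    system=system)
        st = traj[-1]
        spots = detect_spots(mesh, st.p, PatternConfig())
        cv = float(st.p.std() / max(st.p.mean(), 1e-12)) if st.p.max() > 0 else 0.0
        patterned = bool(len(spots) >= 2 and cv > 0.1)
        rows.append({"f_const": f0, "patterned": patterned,
                     "n_spots": len(spots), "cv_p": cv,
                     "turing_verdict": verdict,
                     "class": classify_mode(spots)})
    return pd.DataFrame(rows)
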