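"""From FGF10 fields to branching phenotypes.

Steady-state or time-resolved FGF10 concentration fields are reduced to
the phenotype vocabulary of branching morphogenesis: local concentration
maxima ("spots") in the mesenchyme, their position relative to the bud tip
(tip / shoulder / proximal), the pattern class

* ``elongation``  — a single tip-centred maximum,
* ``lateral``     — a tip maximum plus flank maxima along the stalk
                     (domain/lateral branching),
* ``bifurcation`` — maxima on the shoulders of the tip with no tip
                     maximum (planar bifurcation; a 2D slice cannot
                     distinguish planar from orthogonal),
* ``none``        — no maxima near the tip region,

inter-spot axial spacings, and the timeline of new-spot ("branch")
events on growing domains.  Since the underlying experimental readout is
qualitative, the thresholds are explicit, configurable and reported with
every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .mesh import Mesh

__all__ = ["PatternConfig", "Spot", "PatternReport", "detect_spots",
           "classify_mode", "axial_spacing", "branch_events", "analyze"]


@dataclass(frozen=True)
class PatternConfig:
    """Thresholds of the phenotype extraction.

    ``theta_rel``: relative peak threshold (fraction of the global max);
    ``r_merge``: maxima closer than this merge into one spot;
    ``tip_half_angle``: half-opening (radians) of the apex cone on the cap
    within which a spot counts as the tip maximum;
    ``tip_axial_margin``: the tip zone also extends this far below the cap
    base; ``shoulder_depth``: spots within this axial distance of the cap
    base (but outside the apex cone) are shoulder spots.
    """

    theta_rel: float = 0.3
    r_merge: float = 0.3
    tip_half_angle: float = np.deg2rad(30.0)
    tip_axial_margin: float = 0.25
    shoulder_depth: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_rel < 1.0):
            raise ValueError("theta_rel must lie in (0, 1)")
        if self.r_merge < 0:
            raise ValueError("r_merge must be >= 0")


@dataclass
class Spot:
    node: int
    x: float
    y: float
    value: float
    zone: str       # "tip" | "shoulder" | "proximal"

    @property
    def position(self):
        return np.array([self.x, self.y])


@dataclass
class PatternReport:
    spots: list
    pattern_class: str
    spacings: np.ndarray
    config: PatternConfig
    events: list = field(default_factory=list)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def mean_spacing(self):
        return float(np.mean(self.spacings)) if len(self.spacings) else None

    @property
    def min_spacing(self):
        return float(np.min(self.spacings)) if len(self.spacings) else None

    def to_dict(self) -> dict:
        return {
            "class": self.pattern_class,
            "n_spots": self.n_spots,
            "spots": [{"x": s.x, "y": s.y, "value": s.value, "zone": s.zone}
                      for s in self.spots],
            "spacings": list(map(float, self.spacings)),
            "theta_rel": self.config.theta_rel,
            "r_merge": self.config.r_merge,
        }


def _adjacency(mesh: Mesh) -> sparse.csr_matrix:
    tri = mesh.tris
    edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    N = mesh.n_nodes
    A = sparse.coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
                          shape=(N, N))
    return ((A + A.T) > 0).tocsr()


def _zone(x: float, y: float, mesh: Mesh, cfg: PatternConfig) -> str:
    h = mesh.h
    if y >= h - cfg.tip_axial_margin:
        # on/above the cap: tip if within the apex cone
        ang = np.arctan2(y - h, x) if y > h else 0.0
        if y > h and abs(np.pi / 2 - ang) <= cfg.tip_half_angle:
            return "tip"
        return "shoulder"
    if y >= h - cfg.shoulder_depth:
        return "shoulder"
    return "proximal"


def detect_spots(mesh: Mesh, f: np.ndarray, config: PatternConfig = PatternConfig()):
    """Local maxima of f restricted to the mesenchyme.

    A node is a candidate if it exceeds every mesh neighbour and the
    relative threshold; candidates within ``r_merge`` of a stronger spot
    are merged into it.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < -1e-9 * max(1.0, np.abs(f).max())):
        f = np.maximum(f, 0.0)
    fmax = f.max()
    if fmax <= 0:
        return []
    A = _adjacency(mesh)
    mes = mesh.mesenchyme_nodes()
    cand = []
    for i in np.where(mes)[0]:
        nb = A.indices[A.indptr[i]:A.indptr[i + 1]]
        if (f[i] >= config.theta_rel * fmax and np.all(f[i] >= f[nb])
                and f[i] - f[nb].min() > 1e-6 * fmax):  # reject plateaus
            cand.append(i)
    cand.sort(key=lambda i: -f[i])
    kept = []
    for i in cand:
        pi = mesh.points[i]
        if all(np.hypot(*(pi - mesh.points[j])) > config.r_merge for j in kept):
            kept.append(i)
    return [Spot(node=int(i), x=float(mesh.points[i, 0]),
                 y=float(mesh.points[i, 1]), value=float(f[i]),
                 zone=_zone(mesh.points[i, 0], mesh.points[i, 1], mesh, config))
            for i in kept]


def classify_mode(spots: list) -> str:
    """Assign the pattern class from the tagged spot list."""
    if not spots:
        return "none"
    zones = {s.zone for s in spots}
    if "tip" in zones:
        return "elongation" if zones == {"tip"} else "lateral"
    if "shoulder" in zones:
        return "bifurcation"
    return "none"


def axial_spacing(spots: list, r_merge: float = 0.3,
                  axis_tol: float = 0.3) -> np.ndarray:
    """Consecutive axial gaps between branch sites along each flank.

    Branch sites on the left and right flank are independent (they
    frequently stagger), so gaps are measured along each side separately
    — matching a concentration profile taken along one side of the bud —
    with near-axis (tip) spots contributing to both sides.  Within a side,
    axial positions closer than ``r_merge`` are merged.  Returns the
    pooled gap list; empty for fewer than two sites on every side.
    """
    if len(spots) < 2:
        return np.array([])
    gaps = []
    for side in (+1, -1):
        ys = np.sort([s.y for s in spots
                      if side * s.x > -axis_tol])
        if len(ys) < 2:
            continue
        clusters = [[ys[0]]]
        for y in ys[1:]:
            if y - clusters[-1][-1] <= r_merge:
                clusters[-1].append(y)
            else:
                clusters.append([y])
        centers = np.array([np.mean(c) for c in clusters])
        gaps.extend(np.diff(centers))
    return np.asarray(gaps)


@dataclass
class BranchEvent:
    t: float
    x: float
    y: float
    tip_y: float

    @property
    def distance_behind_tip(self) -> float:
        return self.tip_y - self.y


def branch_events(trajectory, config: PatternConfig = PatternConfig(),
                  track_radius: float = 0.6, debounce_frac: float = 0.05,
                  min_amplitude: float = 0.01):
    """Timeline of new-spot events along a trajectory of field states.

    Spots are tracked across snapshots by nearest-neighbour matching
    within ``track_radius``; an unmatched spot opens a provisional event
    that is confirmed once it persists for the debounce window (a fraction
    of the run duration), filtering out remeshing artefacts.  Snapshots
    whose field maximum is below ``min_amplitude`` (the seed-noise phase
    before the instability has amplified) carry no spots.  Events store
    the axial position of the new maximum and the instantaneous tip
    position (cap apex).
    """
    if not trajectory:
        return []
    t0, t1 = trajectory[0].t, trajectory[-1].t
    debounce = debounce_frac * max(t1 - t0, 1e-12)
    tracked = []      # list of [x, y, last_seen_t]
    pending = []      # list of [x, y, first_t, last_t, tip_y]
    confirmed = []
    for st in trajectory:
        mesh = st.mesh
        spots = (detect_spots(mesh, st.f, config)
                 if st.f.max() >= min_amplitude else [])
        tip_y = mesh.h + mesh.domain.interfaces[2]   # apex of the mesenchyme cap
        for tr in tracked:
            tr[3] = False
        for s in spots:
            pos = np.array([s.x, s.y])
            matched = False
            for tr in tracked:
                if np.hypot(pos[0] - tr[0], pos[1] - tr[1]) <= track_radius:
                    tr[0], tr[1], tr[2], tr[3] = s.x, s.y, st.t, True
                    matched = True
                    break
            if matched:
                continue
            for pe in pending:
                if np.hypot(pos[0] - pe[0], pos[1] - pe[1]) <= track_radius:
                    pe[0], pe[1], pe[3] = s.x, s.y, st.t
                    matched = True
                    if st.t - pe[2] >= debounce:
                        confirmed.append(BranchEvent(t=pe[2], x=pe[0], y=pe[1],
                                                     tip_y=pe[4]))
                        tracked.append([pe[0], pe[1], st.t, True])
                        pending.remove(pe)
                    break
            if not matched:
                pending.append([s.x, s.y, st.t, st.t, tip_y])
        # drop pending/tracked spots that vanished
        pending = [pe for pe in pending if st.t - pe[3] <= debounce]
        tracked = [tr for tr in tracked if tr[3] or st.t - tr[2] <= debounce]
    confirmed.sort(key=lambda e: e.t)
    return confirmed


def analyze(state, config: PatternConfig = PatternConfig()) -> PatternReport:
    """Full phenotype of a single field state."""
    spots = detect_spots(state.mesh, state.f, config)
    return PatternReport(spots=spots, pattern_class=classify_mode(spots),
                         spacings=axial_spacing(spots, config.r_merge),
                         config=config)
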