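"""Boundary-fitted triangular meshes of the lung-bud domain.

The mesher exploits the stadium-annulus structure of the geometry: nodes
lie on level curves of the distance-from-spine field (vertical sides plus a
semicircular cap), with levels placed exactly on the subdomain interfaces
so that every element carries a single subdomain label and the labelled
areas converge to the analytic ones at O(hmax²).  Radial spacing is
uniform (≈ hmax) through the tissue and coarsens geometrically through the
far-field buffer, where fields are smooth and near zero.

The parametric structure (level index, curve section, axial fraction) is
retained on the mesh, which makes the moving-mesh growth machinery and
conservative axial remeshing straightforward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BudDomain, GeometryError

__all__ = ["Mesh", "make_mesh", "MeshingError"]

# node kinds
SPINE, SIDE_R, ARC, SIDE_L = 0, 1, 2, 3


class MeshingError(RuntimeError):
    """Mesh generation failure; carries the geometry spec for reproduction."""


@dataclass
class Mesh:
    """Conforming triangular mesh with subdomain labels and parametric metadata."""

    points: np.ndarray          # (N, 2) node coordinates
    tris: np.ndarray            # (M, 3) node indices, counter-clockwise
    labels: np.ndarray          # (M,) subdomain label in {1, 2, 3, 4}
    hmax: float
    h: float                    # current stalk length
    domain: BudDomain
    # parametric metadata
    levels: np.ndarray          # (Nr+1,) level radii, levels[0] = 0
    Ny: int
    Na: int
    node_level: np.ndarray      # (N,) level index
    node_kind: np.ndarray       # (N,) SPINE | SIDE_R | ARC | SIDE_L
    node_param: np.ndarray      # (N,) axial fraction xi (spine/side) or angle (arc)
    outer: np.ndarray           # (N,) bool: outer far-field boundary
    base: np.ndarray            # (N,) bool: y = 0 cut

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_elements(self) -> int:
        return len(self.tris)

    # -- geometric quantities -------------------------------------------------

    def element_areas(self) -> np.ndarray:
        p = self.points[self.tris]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def subdomain_areas(self) -> dict:
        areas = self.element_areas()
        return {lab: float(areas[self.labels == lab].sum())
                for lab in (1, 2, 3, 4) if np.any(self.labels == lab)}

    def element_quality(self) -> np.ndarray:
        """Per-element shape quality 4√3·A / Σl² (1 for equilateral)."""
        p = self.points[self.tris]
        l2 = ((p[:, [1, 2, 0]] - p[:, [0, 1, 2]]) ** 2).sum(axis=2).sum(axis=1)
        return 4.0 * np.sqrt(3.0) * self.element_areas() / l2

    # -- growth support -------------------------------------------------------

    def coords_at_height(self, h: float) -> np.ndarray:
        """Node coordinates of the same parametric mesh with stalk length h."""
        return _node_coords(self.domain, self.levels, self.node_level,
                            self.node_kind, self.node_param, h)

    def with_height(self, h: float) -> "Mesh":
        """Same connectivity and parameters, stalk elongated to h."""
        m = Mesh(points=self.coords_at_height(h), tris=self.tris,
                 labels=self.labels, hmax=self.hmax, h=h, domain=self.domain,
                 levels=self.levels, Ny=self.Ny, Na=self.Na,
                 node_level=self.node_level, node_kind=self.node_kind,
                 node_param=self.node_param, outer=self.outer, base=self.base)
        return m

    def mesenchyme_nodes(self) -> np.ndarray:
        """Boolean mask of nodes touching a mesenchyme element."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[np.unique(self.tris[self.labels == 3])] = True
        return mask

    def tissue_nodes(self) -> np.ndarray:
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[np.unique(self.tris[np.isin(self.labels, (2, 3))])] = True
        return mask


def _tip_weight(y, h, blend):
    return np.clip(1.0 - (h - np.asarray(y, float)) / blend, 0.0, 1.0)


def _node_coords(domain: BudDomain, levels, node_level, node_kind,
                 node_param, h) -> np.ndarray:
    d = levels[node_level].astype(float)
    blend = domain.spec.deformation.blend_width
    x = np.zeros_like(d)
    y = np.zeros_like(d)
    side = (node_kind == SIDE_R) | (node_kind == SIDE_L)
    spine = node_kind == SPINE
    arc = node_kind == ARC
    # axial positions
    y[side | spine] = node_param[side | spine] * h
    # deformed radii
    w = np.zeros_like(d)
    w[side | spine] = _tip_weight(y[side | spine], h, blend)
    w[arc] = 1.0
    dd = domain.radius_map(d, w)
    sign = np.where(node_kind == SIDE_L, -1.0, 1.0)
    x[side] = sign[side] * dd[side]
    th = node_param[arc]
    x[arc] = dd[arc] * np.cos(th)
    y[arc] = h + dd[arc] * np.sin(th)
    return np.column_stack([x, y])


def _radial_levels(domain: BudDomain, hmax: float, buffer_ratio: float = 1.35):
    rc, re, Rc, Rout = domain.interfaces
    levels = [0.0]
    for a, b in ((0.0, rc), (rc, re), (re, Rc)):
        n = max(1, int(np.ceil((b - a) / hmax)))
        levels.extend(np.linspace(a, b, n + 1)[1:])
    if Rout > Rc:
        d = Rc
        step = hmax
        while d + 1.5 * step < Rout:
            d += step
            levels.append(d)
            step *= buffer_ratio
        levels.append(Rout)
    return np.asarray(levels)


def make_mesh(domain: BudDomain, hmax: float, Ny: int | None = None) -> Mesh:
    """Generate a labelled conforming mesh of the bud domain.

    ``hmax`` bounds the element size in the tissue; ``Ny`` (the number of
    axial intervals along the stalk) defaults to ceil(h/hmax) and is
    exposed so that growth runs can re-mesh a lengthening stalk.
    """
    if hmax <= 0:
        raise MeshingError(f"hmax must be positive, got {hmax}")
    g = domain.spec
    h = domain.h
    if h <= 0:
        raise MeshingError(f"stalk length must be positive, got {h} "
                           f"(geometry: {g})")
    levels = _radial_levels(domain, hmax)
    Nr = len(levels) - 1
    if Ny is None:
        Ny = max(2, int(np.ceil(h / hmax)))
    Na = max(8, int(np.ceil(np.pi * g.Rc / hmax)))
    T = 2 * Ny + Na  # curve parameter range 0..T per level

    # --- nodes ---------------------------------------------------------------
    level_l, kind_l, param_l = [], [], []
    # spine (level 0): axial fractions 0..1
    for j in range(Ny + 1):
        level_l.append(0)
        kind_l.append(SPINE)
        param_l.append(j / Ny)
    spine_ids = np.arange(Ny + 1)

    idx = np.empty((Nr + 1, T + 1), dtype=int)
    # level 0 curve indices map onto spine nodes
    for t in range(T + 1):
        if t <= Ny:
            idx[0, t] = spine_ids[t]
        elif t <= Ny + Na:
            idx[0, t] = spine_ids[Ny]
        else:
            idx[0, t] = spine_ids[T - t]

    nid = Ny + 1
    for i in range(1, Nr + 1):
        for t in range(T + 1):
            if t <= Ny:                       # right side, bottom to top
                kind, par = SIDE_R, t / Ny
            elif t <= Ny + Na:                # cap arc, right to left
                k = t - Ny
                kind, par = ARC, np.pi * k / Na
            else:                             # left side, top to bottom
                kind, par = SIDE_L, (T - t) / Ny
            level_l.append(i)
            kind_l.append(kind)
            param_l.append(par)
            idx[i, t] = nid
            nid += 1

    node_level = np.asarray(level_l)
    node_kind = np.asarray(kind_l)
    node_param = np.asarray(param_l)
    points = _node_coords(domain, levels, node_level, node_kind, node_param, h)

    # --- elements ------------------------------------------------------------
    rc, re, Rc, Rout = domain.interfaces
    tris, labs = [], []
    for i in range(Nr):
        dmid = 0.5 * (levels[i] + levels[i + 1])
        if dmid < rc:
            lab = 1
        elif dmid < re:
            lab = 2
        elif dmid < Rc:
            lab = 3
        else:
            lab = 4
        inner, outer_row = idx[i], idx[i + 1]
        for t in range(T):
            n00, n01 = inner[t], inner[t + 1]
            n10, n11 = outer_row[t], outer_row[t + 1]
            if n00 == n01:      # degenerate at the spine apex
                tris.append((n00, n10, n11))
            else:
                tris.append((n00, n11, n01))
                tris.append((n00, n10, n11))
            labs.extend([lab] * (1 if n00 == n01 else 2))
    tris = np.asarray(tris, dtype=int)
    labels = np.asarray(labs, dtype=int)

    outer = node_level == Nr
    base = np.zeros(len(points), dtype=bool)
    base[(node_kind == SPINE) & (node_param == 0.0)] = True
    base[((node_kind == SIDE_R) | (node_kind == SIDE_L)) & (node_param == 0.0)] = True

    m = Mesh(points=points, tris=tris, labels=labels, hmax=hmax, h=h,
             domain=domain, levels=levels, Ny=Ny, Na=Na,
             node_level=node_level, node_kind=node_kind,
             node_param=node_param, outer=outer, base=base)
    areas = m.element_areas()
    if np.any(areas <= 0):
        raise MeshingError(
            f"mesher produced {int((areas <= 0).sum())} non-positive elements "
            f"for geometry {g!r}, hmax={hmax}")
    return m


def remesh_axial(mesh: Mesh, h: float) -> tuple:
    """Regenerate the mesh at stalk length h with refreshed axial resolution.

    Returns ``(new_mesh, transfer)`` where ``transfer(field)`` maps a nodal
    field from the old mesh (at its current height) onto the new mesh by
    linear interpolation in the axial fraction within each level curve
    (arc and spine-apex values carry over directly).
    """
    new = make_mesh(mesh.domain, mesh.hmax, Ny=max(2, int(np.ceil(h / mesh.hmax))))
    new = new.with_height(h)

    # Build per-(level, kind) interpolation tables.
    plans = []  # (new_ids, old_ids_sorted, xi_old, xi_new) or direct copies
    for lev in range(len(mesh.levels)):
        for kind in (SPINE, SIDE_R, SIDE_L):
            om = (mesh.node_level == lev) & (mesh.node_kind == kind)
            nm = (new.node_level == lev) & (new.node_kind == kind)
            if not om.any() or not nm.any():
                continue
            oid = np.where(om)[0]
            order = np.argsort(mesh.node_param[oid])
            oid = oid[order]
            plans.append(("interp", np.where(nm)[0], oid,
                          mesh.node_param[oid], new.node_param[nm]))
        om = (mesh.node_level == lev) & (mesh.node_kind == ARC)
        nm = (new.node_level == lev) & (new.node_kind == ARC)
        if om.any():
            oid = np.where(om)[0][np.argsort(mesh.node_param[om])]
            nid = np.where(nm)[0][np.argsort(new.node_param[nm])]
            plans.append(("copy", nid, oid, None, None))

    def transfer(field: np.ndarray) -> np.ndarray:
        out = np.zeros(new.n_nodes, dtype=float)
        for mode, nid, oid, xi_o, xi_n in plans:
            if mode == "copy":
                out[nid] = field[oid]
            else:
                out[nid] = np.interp(xi_n, xi_o, field[oid])
        return out

    return new, transfer
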