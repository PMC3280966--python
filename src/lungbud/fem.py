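"""Linear (P1) finite-element assembly on labelled triangular meshes.

Provides the operators needed by the reaction–diffusion solvers: stiffness
matrices with per-element diffusivity, consistent and lumped mass matrices,
per-subdomain lumped masses (used to gate compartmentalised kinetics), and
the advection–dilution operator ∫ φ_i ∇·(w φ_j) for moving-domain runs.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["P1Basis", "stiffness", "mass", "lumped_mass",
           "lumped_mass_by_label", "advection"]


class P1Basis:
    """Cached per-element geometry: areas and constant shape-function gradients."""

    def __init__(self, points: np.ndarray, tris: np.ndarray):
        self.points = points
        self.tris = tris
        p = points[tris]                      # (M, 3, 2)
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        self.area = 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
        if np.any(self.area <= 0):
            raise ValueError("mesh contains non-positively oriented elements")
        x, y = p[..., 0], p[..., 1]
        # grad phi_i = (b_i, c_i) / (2A)
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        inv2A = 1.0 / (2.0 * self.area)
        self.gradx = b * inv2A[:, None]       # (M, 3)
        self.grady = c * inv2A[:, None]
        self.n_nodes = len(points)
        # scatter indices for 3x3 element blocks
        self._rows = np.repeat(tris, 3, axis=1).ravel()
        self._cols = np.tile(tris, (1, 3)).ravel()

    def _scatter(self, ke: np.ndarray) -> sparse.csr_matrix:
        """Assemble (M, 3, 3) element matrices into a global CSR matrix."""
        A = sparse.coo_matrix((ke.reshape(len(self.tris), 9).ravel(),
                               (self._rows, self._cols)),
                              shape=(self.n_nodes, self.n_nodes))
        return A.tocsr()


def stiffness(basis: P1Basis, d_elem) -> sparse.csr_matrix:
    """∫ d ∇φ_i·∇φ_j with piecewise-constant diffusivity d per element."""
    d_elem = np.broadcast_to(np.asarray(d_elem, float), basis.area.shape)
    gx, gy = basis.gradx, basis.grady
    ke = (gx[:, :, None] * gx[:, None, :] + gy[:, :, None] * gy[:, None, :])
    ke = ke * (d_elem * basis.area)[:, None, None]
    return basis._scatter(ke)


def mass(basis: P1Basis) -> sparse.csr_matrix:
    """Consistent mass matrix ∫ φ_i φ_j."""
    me = (np.ones((3, 3)) + np.eye(3)) / 12.0
    ke = me[None, :, :] * basis.area[:, None, None]
    return basis._scatter(ke)


def lumped_mass(basis: P1Basis) -> np.ndarray:
    """Row-sum lumped mass vector (each element spreads area/3 to its nodes)."""
    m = np.zeros(basis.n_nodes)
    np.add.at(m, basis.tris.ravel(), np.repeat(basis.area / 3.0, 3))
    return m


def lumped_mass_by_label(basis: P1Basis, labels: np.ndarray) -> dict:
    """Lumped mass vectors restricted to each subdomain label."""
    out = {}
    for lab in np.unique(labels):
        m = np.zeros(basis.n_nodes)
        sel = labels == lab
        np.add.at(m, basis.tris[sel].ravel(), np.repeat(basis.area[sel] / 3.0, 3))
        out[int(lab)] = m
    return out


def advection(basis: P1Basis, w_nodal: np.ndarray) -> sparse.csr_matrix:
    """Conservative transport operator A_ij = ∫ φ_i ∇·(w φ_j).

    ``w_nodal`` is an (N, 2) nodal velocity field interpolated with P1.
    Using ∇·(w φ_j) = w·∇φ_j + φ_j ∇·w with element-wise P1 interpolation:
    ∫ φ_i (w·∇φ_j) = ∇φ_j · (A/12)(Σ_k w_k + w_i) and
    ∫ φ_i φ_j (∇·w) = (∇·w)(A/12)(1 + δ_ij).

    Row sums reduce to boundary flux terms (Σ_i φ_i ≡ 1), so total mass is
    conserved exactly whenever w·n = 0 on the boundary.
    """
    w = np.asarray(w_nodal, float)
    we = w[basis.tris]                        # (M, 3, 2)
    wsum = we.sum(axis=1)                     # (M, 2)
    # divergence of the P1 velocity, constant per element
    divw = (we[..., 0] * basis.gradx).sum(axis=1) + (we[..., 1] * basis.grady).sum(axis=1)
    A12 = basis.area / 12.0
    # ∫ φ_i w dx  -> (M, 3, 2)
    int_phi_w = A12[:, None, None] * (wsum[:, None, :] + we)
    gradj = np.stack([basis.gradx, basis.grady], axis=2)   # (M, 3, 2)
    ke = np.einsum("mia,mja->mij", int_phi_w, gradj)
    ke += (divw * A12)[:, None, None] * (np.ones((3, 3)) + np.eye(3))[None]
    return basis._scatter(ke)
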