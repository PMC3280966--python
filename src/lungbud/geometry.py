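"""Idealised lung-bud cross-section geometry.

The embryonic lung tip is modelled as a cylinder sliced axially: a 2D
stadium-shaped bud (rectangular stalk capped by a semicircular tip) made of
four concentric compartments around the stalk axis — lumen (1, inner radius
``rc``), epithelium (2, thickness ``we``), mesenchyme (3, outer radius
``Rc``) — embedded in interstitial space (4) that extends to a far-field
buffer of width ``Lfar``.  All lengths are dimensionless in units of
``rc``.  The stalk axis is the y axis with the base at y = 0 and the tip
cap centred at y = h0.

Deformations model the robustness protocols: the tip epithelial or
mesenchymal radius scaled up (with a smooth blend along the shoulder), or
the stalk truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Deformation", "LungGeometry", "BudDomain", "build_geometry",
           "apply_deformation", "GeometryError"]


class GeometryError(ValueError):
    """Raised when a geometry specification violates its invariants."""


@dataclass(frozen=True)
class Deformation:
    """Tip-local scaling of interface radii and stalk truncation."""

    tip_epithelium_scale: float = 1.0
    tip_mesenchyme_scale: float = 1.0
    stalk_truncation_fraction: float = 0.0
    #: axial distance below the tip over which the scaling blends to 1
    blend_width: float = 1.0

    def __post_init__(self) -> None:
        if self.tip_epithelium_scale <= 0 or self.tip_mesenchyme_scale <= 0:
            raise GeometryError("deformation scales must be positive")
        if not (0.0 <= self.stalk_truncation_fraction < 1.0):
            raise GeometryError("stalk truncation fraction must lie in [0, 1)")
        if self.blend_width <= 0:
            raise GeometryError("blend width must be positive")

    @property
    def is_identity(self) -> bool:
        return (self.tip_epithelium_scale == 1.0
                and self.tip_mesenchyme_scale == 1.0
                and self.stalk_truncation_fraction == 0.0)


@dataclass(frozen=True)
class LungGeometry:
    """Geometry specification of the idealised bud cross-section."""

    rc: float = 1.0
    we: float = 0.2
    Rc: float = 2.0
    h0: float = 2.0
    Lfar: float = 10.0
    deformation: Deformation = field(default_factory=Deformation)

    def __post_init__(self) -> None:
        if min(self.rc, self.we) <= 0:
            raise GeometryError(
                f"need rc > 0 and we > 0 (epithelium of zero thickness is "
                f"degenerate); got rc={self.rc}, we={self.we}")
        if not (self.rc < self.rc + self.we < self.Rc):
            raise GeometryError(
                f"radii must satisfy rc < rc+we < Rc; got rc={self.rc}, "
                f"rc+we={self.rc + self.we}, Rc={self.Rc}")
        if self.Lfar < 0:
            raise GeometryError("far-field buffer width must be >= 0")
        if self.h0 < 0:
            raise GeometryError("initial stalk length must be >= 0")
        d = self.deformation
        ge, gm = d.tip_epithelium_scale, d.tip_mesenchyme_scale
        if not (ge * (self.rc + self.we) < gm * self.Rc):
            raise GeometryError(
                "tip deformation breaks the epithelium < mesenchyme ordering: "
                f"{ge}*(rc+we)={ge * (self.rc + self.we)} !< "
                f"{gm}*Rc={gm * self.Rc}")
        if self.Lfar > 0 and gm * self.Rc >= self.Rc + self.Lfar:
            raise GeometryError("tip mesenchyme deformation exceeds the buffer")

    @property
    def stalk_length(self) -> float:
        """Effective stalk length after truncation."""
        return self.h0 * (1.0 - self.deformation.stalk_truncation_fraction)

    @property
    def outer_radius(self) -> float:
        return self.Rc + self.Lfar

    def with_buffer(self, Lfar: float) -> "LungGeometry":
        return replace(self, Lfar=Lfar)


def apply_deformation(spec: LungGeometry, deformation: Deformation) -> LungGeometry:
    """Return the geometry with the deformation protocol applied.

    Scales compose with any pre-existing deformation; truncation fractions
    compose multiplicatively on the remaining stalk.
    """
    d0 = spec.deformation
    combined = Deformation(
        tip_epithelium_scale=d0.tip_epithelium_scale * deformation.tip_epithelium_scale,
        tip_mesenchyme_scale=d0.tip_mesenchyme_scale * deformation.tip_mesenchyme_scale,
        stalk_truncation_fraction=1.0 - (1.0 - d0.stalk_truncation_fraction)
        * (1.0 - deformation.stalk_truncation_fraction),
        blend_width=deformation.blend_width,
    )
    return replace(spec, deformation=combined)


def stadium_area(radius: float, stalk: float) -> float:
    """Area of a stadium: rectangle 2*radius x stalk plus a half disc."""
    return 2.0 * radius * stalk + 0.5 * np.pi * radius ** 2


@dataclass(frozen=True)
class BudDomain:
    """Labelled planar domain: interface radii, stalk length, deformation map.

    The subdomains are nested stadium annuli around the spine segment from
    (0, 0) to (0, h); a point at distance ``d`` from the spine belongs to
    the lumen (d < rc), epithelium (rc..rc+we), mesenchyme (rc+we..Rc) or
    interstitial buffer (Rc..Rc+Lfar).  Deformations remap ``d`` near the
    tip.
    """

    spec: LungGeometry

    @property
    def h(self) -> float:
        return self.spec.stalk_length

    @property
    def interfaces(self) -> tuple:
        g = self.spec
        return (g.rc, g.rc + g.we, g.Rc, g.Rc + g.Lfar)

    def radius_map(self, d, tip_weight):
        """Deformed distance-from-spine for tip weight in [0, 1].

        ``tip_weight`` is 1 on the cap and decays to 0 over the blend width
        below the shoulder; the returned radius interpolates between the
        undeformed and fully tip-deformed radial maps.
        """
        d = np.asarray(d, dtype=float)
        w = np.asarray(tip_weight, dtype=float)
        g = self.spec
        dd = g.deformation
        if dd.tip_epithelium_scale == 1.0 and dd.tip_mesenchyme_scale == 1.0:
            return d * np.ones_like(w)
        re = g.rc + g.we
        Rout = g.outer_radius if g.Lfar > 0 else g.Rc
        # fully deformed anchors
        re_t = dd.tip_epithelium_scale * re
        Rc_t = dd.tip_mesenchyme_scale * g.Rc
        xp = np.array([0.0, re, g.Rc, Rout])
        fp = np.array([0.0, re_t, Rc_t, Rout])
        if g.Lfar == 0:
            xp, fp = xp[:3], fp[:3]
        d_tip = np.interp(d, xp, fp)
        return d + w * (d_tip - d)

    def subdomain_areas(self) -> dict:
        """Closed-form subdomain areas of the *undeformed* domain."""
        rc, re, Rc, Rout = self.interfaces
        h = self.h
        a = {}
        a[1] = stadium_area(rc, h)
        a[2] = stadium_area(re, h) - a[1]
        a[3] = stadium_area(Rc, h) - stadium_area(re, h)
        a[4] = stadium_area(Rout, h) - stadium_area(Rc, h)
        return a

    def total_area(self) -> float:
        return stadium_area(self.interfaces[-1], self.h)


def build_geometry(spec: LungGeometry) -> BudDomain:
    """Validate a geometry spec and return the labelled planar domain."""
    # dataclass validation runs in __post_init__; re-run for mutated specs
    LungGeometry(rc=spec.rc, we=spec.we, Rc=spec.Rc, h0=spec.h0,
                 Lfar=spec.Lfar, deformation=spec.deformation)
    return BudDomain(spec=spec)
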