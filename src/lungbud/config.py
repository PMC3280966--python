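"""Run configuration, serialisation, provenance and test fixtures.

A :class:`RunConfig` bundles everything a simulation needs — geometry,
kinetic parameters, boundary condition, optional growth and noise
protocols, mesh resolution, tolerances and the global seed — and
round-trips through YAML with strict (unknown keys rejected) validation.
The SHA-256 hash of the canonical serialisation identifies a run;
identical (config, seed) pairs produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .geometry import Deformation, LungGeometry, build_geometry
from .growth import GrowthSpec
from .mesh import make_mesh
from .params import ParamSet, Scales
from .solve import BoundaryCondition

__all__ = ["RunConfig", "NoiseSpec", "load_config", "save_config",
           "reference_config", "reference_params", "reference_scales",
           "make_fixture", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseSpec:
    """Spatial parameter-variability protocol.

    Every kinetic parameter is multiplied by (1 + ξ(x)) with ξ a zero-mean
    Gaussian random field of standard deviation ``sd`` (the "half width")
    and correlation length ``corr_length`` (about one cell diameter, so
    the perturbation is cell-autonomous rather than mesh-node-autonomous);
    geometric parameters are not varied.
    """

    sd: float = 0.2
    corr_length: float = 0.1
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("noise sd must be >= 0")
        if self.corr_length <= 0:
            raise ConfigError("noise correlation length must be positive")
        if self.replicates < 1:
            raise ConfigError("need at least one replicate")


_SECTIONS = {
    "geometry": (LungGeometry, ("rc", "we", "Rc", "h0", "Lfar")),
    "params": (ParamSet, tuple(ParamSet.__dataclass_fields__)),
    "bc": (BoundaryCondition, ("kind", "t_max")),
    "growth": (GrowthSpec, tuple(GrowthSpec.__dataclass_fields__)),
    "noise": (NoiseSpec, tuple(NoiseSpec.__dataclass_fields__)),
}


@dataclass(frozen=True)
class RunConfig:
    geometry: LungGeometry = field(default_factory=LungGeometry)
    params: ParamSet = field(default_factory=ParamSet)
    bc: BoundaryCondition = field(default_factory=BoundaryCondition)
    growth: GrowthSpec | None = None
    noise: NoiseSpec | None = None
    hmax: float = 0.2
    steady_tol: float = 1e-6
    seed: int = 0
    outdir: str = "runs"

    def to_dict(self) -> dict:
        d = {
            "geometry": asdict(self.geometry),
            "params": asdict(self.params),
            "bc": asdict(self.bc),
            "hmax": self.hmax,
            "steady_tol": self.steady_tol,
            "seed": self.seed,
            "outdir": self.outdir,
        }
        d["geometry"]["deformation"] = asdict(self.geometry.deformation)
        if self.growth is not None:
            d["growth"] = asdict(self.growth)
        if self.noise is not None:
            d["noise"] = asdict(self.noise)
        return d

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def build_mesh(self):
        """Mesh per this config, applying the open-far-field buffer rule."""
        geom = self.geometry
        if self.bc.kind == "open_farfield" and geom.Lfar == 0.0:
            geom = geom.with_buffer(self.bc.buffer_width(self.params))
        return make_mesh(build_geometry(geom), self.hmax)


def _build_section(name: str, payload: dict):
    cls, keys = _SECTIONS[name]
    unknown = set(payload) - set(keys) - ({"deformation"} if name == "geometry" else set())
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    payload = dict(payload)
    if name == "geometry" and "deformation" in payload:
        dd = payload["deformation"]
        unknown = set(dd) - set(Deformation.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown deformation keys: {sorted(unknown)}")
        payload["deformation"] = Deformation(**dd)
    try:
        return cls(**payload)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid section {name!r}: {e}") from e


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    top_keys = set(_SECTIONS) | {"hmax", "steady_tol", "seed", "outdir"}
    unknown = set(raw) - top_keys
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kw = {}
    for name in _SECTIONS:
        if name in raw:
            kw[name] = _build_section(name, raw[name] or {})
    for name in ("hmax", "steady_tol", "seed", "outdir"):
        if name in raw:
            kw[name] = raw[name]
    cfg = RunConfig(**kw)
    if cfg.hmax <= 0:
        raise ConfigError("hmax must be positive")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def reference_config() -> RunConfig:
    """The bundled calibrated reference configuration (lateral class)."""
    with resources.files("lungbud.data").joinpath("reference.yaml").open() as fh:
        return config_from_dict(yaml.safe_load(fh))


def reference_params() -> ParamSet:
    return reference_config().params


def reference_scales() -> Scales:
    with resources.files("lungbud.data").joinpath("table2_scales.yaml").open() as fh:
        d = yaml.safe_load(fh)
    return Scales(L=d["L_um"], T=d["T_s"])


# --------------------------------------------------------------------------
# fixtures

def make_fixture(kind: str, seed: int = 0):
    """Deterministic synthetic inputs with known ground truth.

    Kinds: ``gaussian_spots_field`` (a tissue-only mesh plus a field of
    Gaussian bumps at known mesenchyme locations; returns (mesh, field,
    centers)); ``tiny_mesh`` (a coarse solver smoke-test mesh);
    ``schnakenberg_point`` (a textbook Turing-unstable two-species
    parameter point).
    """
    rng = np.random.default_rng(seed)
    if kind == "tiny_mesh":
        geom = LungGeometry(h0=2.0, Lfar=2.0)
        return make_mesh(build_geometry(geom), 0.4)
    if kind == "gaussian_spots_field":
        geom = LungGeometry(h0=4.0, Lfar=0.0)
        mesh = make_mesh(build_geometry(geom), 0.15)
        # well-separated anchor sites in the right/left mesenchyme and the cap
        anchors = np.array([[1.6, 0.6], [-1.6, 2.2], [0.0, 4.0 + 1.6]])
        centers = anchors + rng.uniform(-0.1, 0.1, size=anchors.shape)
        f = np.zeros(mesh.n_nodes)
        for cx, cy in centers:
            d2 = ((mesh.points - [cx, cy]) ** 2).sum(axis=1)
            f += np.exp(-d2 / (2 * 0.25 ** 2))
        return mesh, f, centers
    if kind == "schnakenberg_point":
        from .params import SchnakenbergParams
        return SchnakenbergParams(a=0.05, b=1.0, D_u=1.0, D_v=100.0)
    raise ConfigError(f"unknown fixture kind {kind!r}")
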