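"""Bar-and-hinge wing-section model built from an unfolded crease pattern.

Every retained radial fold line becomes a strut of two mass-bearing
cylindrical bars: a proximal bar from the fan-centre circle to the ring
fold and a distal bar from the ring fold to the outer tip.  The proximal
joint (3 rotational DoF, ``rx`` about the fan axis carrying the pleating
angle ``alpha_i``) anchors each strut to the base; the distal joint is a
single hinge about the local ring-fold direction with angle ``delta_i``,
limited to fold to 180 degrees and to overbend by 3 degrees in the open
state, with the range flipped in sign for every second strut (the
mountain/valley alternation of the radial folds).

The elasticity of the resilin-bearing vein patches is lumped into one
tension-only spring-damper tendon per distal joint, attached to the
proximal and distal bar at a configurable fraction of each bar's length
from the joint (default 0.2, which puts the flat-state tendon length near
11 cm for the standard upscaled geometry).  Two zero-stiffness guide
tendons per fan unit span the ring fold between neighbouring struts; they
exert no elastic force and only constrain the relative configuration
(see docs/methods.md for why they carry a length limit by default).

Units follow the raw simulation number system: cm, kg, N, s (torques in
N·cm); energies are converted to Joules only in the energetics module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import CreasePattern, FanParams, Strut, struts

__all__ = ["Bar", "Joint", "Tendon", "ModelConfig", "WingModel", "build_wing_model"]


@dataclass(frozen=True)
class Bar:
    """A mass-bearing cylindrical bar on a fold line (lengths in cm)."""

    name: str
    endpoints: np.ndarray  # (2, 3)
    diameter: float = 0.1
    density: float = 1.25e-3  # kg / cm^3

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.endpoints[1] - self.endpoints[0]))

    @property
    def mass(self) -> float:
        """Cylinder mass rho * pi * (d/2)^2 * L, kg."""
        return self.density * math.pi * (self.diameter / 2.0) ** 2 * self.length

    @property
    def axis(self) -> np.ndarray:
        d = self.endpoints[1] - self.endpoints[0]
        return d / np.linalg.norm(d)

    def inertia_com(self) -> np.ndarray:
        """Inertia tensor about the centre of mass, world-aligned (kg cm^2)."""
        m, L, rad = self.mass, self.length, self.diameter / 2.0
        i_ax = 0.5 * m * rad**2
        i_perp = m * (3.0 * rad**2 + L**2) / 12.0
        a = self.axis
        # I = i_perp * (1 - a a^T) + i_ax * a a^T
        return i_perp * (np.eye(3) - np.outer(a, a)) + i_ax * np.outer(a, a)


@dataclass(frozen=True)
class Joint:
    """A hinge (distal) or stacked-hinge triplet (proximal) of one strut.

    ``sign`` is the mountain/valley alternation ``(-1)**(i+1)``; for distal
    joints it flips the fold/overbend range: sign +1 folds to -180 deg and
    overbends to +3 deg, sign -1 the reverse.
    """

    index: int
    kind: str  # "proximal" | "distal"
    position: np.ndarray  # (3,)
    axis: np.ndarray  # (3,) unit; rx axis for proximal
    sign: int
    range_deg: tuple[float, float] | None
    dof: tuple[str, ...] = ("rx",)


@dataclass(frozen=True)
class Tendon:
    """A spatial tendon between two bar attachment sites.

    ``role`` is "elastic" (stiffness ``k``, tension-only) or "guide"
    (zero stiffness, zero damping; optional length limit).  Attachment
    sites are ``(strut_index, segment, distance_from_joint_cm)``.
    """

    name: str
    site_a: tuple[int, str, float]
    site_b: tuple[int, str, float]
    k: float  # N/cm
    l_r: float  # cm
    damping: float  # N s / cm
    l_init: float  # flat-state length, cm
    role: str = "elastic"
    limit: tuple[float, float] | None = None  # length range, cm

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("tendon stiffness must be >= 0")
        if self.role == "guide" and self.k != 0:
            raise ValueError("guide tendons have zero stiffness")


@dataclass(frozen=True)
class ModelConfig:
    """Physical and numerical model parameters (raw cm/kg/N/s units)."""

    bar_diameter: float = 0.1  # cm
    bar_density: float = 1.25e-3  # kg/cm^3
    attachment_fraction: float = 0.2  # of each bar length, from the distal joint
    # proximal rx axis: "fan" pleats each strut about the fan's central
    # axis (the radial fold of the section as a whole); "strut" twists each
    # strut about its own radial fold line instead
    proximal_axis: str = "fan"
    # lateral offset of the proximal tendon attachment off the bar axis,
    # standing in for the half-width of the broadened vein patch (cm);
    # alternates side with the strut sign
    patch_offset: float = 1.0
    guide_offset: float = 1.0  # cm beyond the ring point on the distal bars
    tendon_damping: float = 0.01  # N per (cm/s)
    overbend_deg: float = 3.0
    fold_limit_deg: float = 180.0
    # the radial pleat is complete when neighbouring panels stack, i.e. at
    # +/-90 deg of alternating pleating rotation; beyond that the fan would
    # pass through itself (no contact forces are modelled, so a compliant
    # range stands in for the physical stop)
    proximal_range_deg: tuple[float, float] | None = (-90.0, 90.0)
    lock_proximal_ryz: bool = True
    guide_limited: bool = False
    guide_slack: float = 0.0  # cm added to the flat length limit when limited
    gravity: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class WingModel:
    """Complete bar-and-hinge description of one fan wing section."""

    params: FanParams
    config: ModelConfig
    struts: list[Strut]
    bars: list[Bar]
    joints: list[Joint]
    tendons: list[Tendon]

    @property
    def n_struts(self) -> int:
        return len(self.struts)

    @property
    def total_mass(self) -> float:
        return float(sum(b.mass for b in self.bars))

    def elastic_tendons(self) -> list[Tendon]:
        return [t for t in self.tendons if t.role == "elastic"]

    def guide_tendons(self) -> list[Tendon]:
        return [t for t in self.tendons if t.role == "guide"]

    def with_tendons(self, k: float, l_r: float) -> "WingModel":
        """A copy of the model with new elastic stiffness / resting length."""
        tendons = [
            replace(t, k=k, l_r=l_r) if t.role == "elastic" else t for t in self.tendons
        ]
        return WingModel(self.params, self.config, self.struts, self.bars, self.joints, tendons)


def _to3(p: np.ndarray) -> np.ndarray:
    return np.array([p[0], p[1], 0.0])


def _site_position(strut: Strut, segment: str, dist: float) -> np.ndarray:
    q = _to3(strut.ring_point)
    if segment == "proximal":
        other = _to3(strut.proximal_anchor)
    elif segment == "distal":
        other = _to3(strut.tip)
    else:
        raise ValueError(f"unknown segment {segment!r}")
    u = (other - q) / np.linalg.norm(other - q)
    return q + dist * u


def build_wing_model(
    pattern: CreasePattern,
    k: float = 10.0,
    l_r: float = 0.0,
    config: ModelConfig | None = None,
) -> WingModel:
    """Assemble the bar-and-hinge model for an unfolded fan pattern.

    Parameters
    ----------
    pattern : CreasePattern
        The unfolded (flat) pattern; its ``2n + 1`` retained radial fold
        lines become the struts.
    k : float
        Elastic tendon stiffness, N/cm.
    l_r : float
        Tendon resting length, cm.
    config : ModelConfig, optional
        Geometry-independent model parameters.
    """
    if pattern.state != "unfolded":
        raise ValueError("build_wing_model expects an unfolded pattern")
    if k < 0:
        raise ValueError("tendon stiffness must be >= 0")
    cfg = config or ModelConfig()
    sts = struts(pattern)
    if not sts:
        raise ValueError("pattern has no retained fold lines (missing ring fold)")

    bars: list[Bar] = []
    joints: list[Joint] = []
    tendons: list[Tendon] = []

    fan_axis = np.array([1.0, 0.0, 0.0])  # O -> A direction
    for s in sts:
        p, q, t = _to3(s.proximal_anchor), _to3(s.ring_point), _to3(s.tip)
        bars.append(Bar(f"prox{s.index}", np.array([p, q]), cfg.bar_diameter, cfg.bar_density))
        bars.append(Bar(f"dist{s.index}", np.array([q, t]), cfg.bar_diameter, cfg.bar_density))
        if cfg.proximal_axis == "strut":
            ax = (q - p) / np.linalg.norm(q - p)  # radial fold line itself
        elif cfg.proximal_axis == "fan":
            ax = fan_axis.copy()
        else:
            raise ValueError(f"unknown proximal_axis {cfg.proximal_axis!r}")
        joints.append(
            Joint(
                index=s.index,
                kind="proximal",
                position=p,
                axis=ax,
                sign=s.sign,
                range_deg=cfg.proximal_range_deg,
                dof=("rx",) if cfg.lock_proximal_ryz else ("rx", "ry", "rz"),
            )
        )
        if s.sign > 0:
            rng = (-cfg.fold_limit_deg, cfg.overbend_deg)
        else:
            rng = (-cfg.overbend_deg, cfg.fold_limit_deg)
        joints.append(
            Joint(
                index=s.index,
                kind="distal",
                position=q,
                axis=_to3(s.ring_axis),
                sign=s.sign,
                range_deg=rng,
                dof=("rx",),
            )
        )

    # one elastic tendon per distal joint, spanning it along the strut
    for s in sts:
        d_prox = cfg.attachment_fraction * s.proximal_length
        d_dist = cfg.attachment_fraction * s.distal_length
        a = _site_position(s, "proximal", d_prox)
        b = _site_position(s, "distal", d_dist)
        tendons.append(
            Tendon(
                name=f"elastic{s.index}",
                site_a=(s.index, "proximal", d_prox),
                site_b=(s.index, "distal", d_dist),
                k=k,
                l_r=l_r,
                damping=cfg.tendon_damping,
                l_init=float(np.linalg.norm(b - a)),
                role="elastic",
            )
        )
    # Zero-stiffness guide tendons between neighbouring struts, attached
    # just distal of the ring points so they run parallel to the ring fold
    # on its distal side.  They track the ring-fold spacing: slack under
    # the synchronized ring fold, taut against pleating and asymmetric
    # configurations.
    for sa, sb in zip(sts[:-1], sts[1:]):
        da = min(cfg.guide_offset, sa.distal_length)
        db = min(cfg.guide_offset, sb.distal_length)
        pa = _site_position(sa, "distal", da)
        pb = _site_position(sb, "distal", db)
        l0 = float(np.linalg.norm(pb - pa))
        tendons.append(
            Tendon(
                name=f"guide{sa.index}_{sb.index}",
                site_a=(sa.index, "distal", da),
                site_b=(sb.index, "distal", db),
                k=0.0,
                l_r=0.0,
                damping=0.0,
                l_init=l0,
                role="guide",
                limit=(0.0, l0 + cfg.guide_slack) if cfg.guide_limited else None,
            )
        )

    return WingModel(pattern.params, cfg, sts, bars, joints, tendons)
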