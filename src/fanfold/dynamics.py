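"""Reduced-coordinate dynamics for the bar-and-hinge wing section.

Each strut is a fixed-base serial chain of two rigid bodies: the proximal
bar rotating about the fan axis through its anchor (pleating angle
``alpha``) and the distal bar hinged at the ring-fold crossing about the
local ring-fold axis (fold angle ``delta``).  Struts interact through the
tendons spanning the distal joints and the guide tendons spanning the ring
fold.  The equations of motion are evaluated exactly (mass matrix from
body Jacobians, velocity-product terms from a Newton-Euler pass with zero
joint acceleration) and integrated with the semi-implicit Euler scheme

    v[t+h] = v[t] + h * a[t]
    q[t+h] = q[t] + h * v[t+h]

Joint limits are compliant: beyond the range a stiff torsional
spring-damper pushes back, so fold angles may transiently exceed 180
degrees, as they do with a compliant-constraint engine.  Tendon forces are
tension-only.  All quantities are raw simulation numbers in cm / kg / N /
N·cm / s; energies are converted to Joules in the energetics module.

Everything is vectorised over a batch of model instances that share the
geometry but may differ in tendon stiffness, resting length and applied
torque — one batched run advances a whole parameter-sweep column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Tendon, WingModel

__all__ = [
    "SimConfig",
    "SimState",
    "Trajectory",
    "DivergenceError",
    "tendon_force",
    "semi_implicit_euler_step",
    "BatchSim",
    "run_phase",
    "run_simulation",
]

class DivergenceError(RuntimeError):
    """Simulation produced non-finite state or runaway velocities."""

    def __init__(self, msg: str, state=None):
        super().__init__(msg)
        self.state = state


@dataclass(frozen=True)
class SimConfig:
    """Integrator and constraint-compliance settings.

    ``h`` is the timestep in seconds (0.005 s for the wing-folding runs).
    ``limit_stiffness`` / ``limit_damping`` shape the compliant joint
    limits (N·cm/rad, N·cm·s/rad); ``guide_stiffness`` / ``guide_damping``
    shape the guide-tendon length limit (N/cm, N·s/cm).
    """

    h: float = 0.005
    duration: float = 10.0
    gravity: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # compliant joint limits: the fold-side stop of the distal hinges
    # absorbs an arriving flap (the flap lands on the stack), while the
    # pleat stop of the proximal joints is lightly damped and bounces —
    # the persistent rattling that re-kicks not-yet-folded joints
    limit_stiffness: float = 3000.0
    limit_damping: float = 30.0
    alpha_limit_damping: float = 3.0
    guide_stiffness: float = 300.0
    guide_damping: float = 3.0
    # small viscous damping on every hinge (N·cm·s/rad), the counterpart of
    # the constant tendon damping: it lets folds settle where the
    # tension-only tendon is slack and exerts no force at all
    joint_damping: float = 0.01
    record_stride: int = 10
    divergence_velocity: float = 1e6

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("timestep h must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


@dataclass
class SimState:
    """Generalized state of a batch of wing models.

    ``q`` / ``v`` / ``a`` have shape (B, S, 2): per instance, per strut,
    the pleating angle alpha and fold angle delta (radians and rad/s).
    """

    q: np.ndarray
    v: np.ndarray
    a: np.ndarray
    t: float = 0.0


@dataclass
class Trajectory:
    """Recorded time series of one simulation run.

    Angles are stored in degrees (API convention); tendon lengths in cm;
    torques in N·cm; kinetic energy in raw N·cm units.  ``events``
    collects named detection times in seconds.
    """

    times: np.ndarray  # (T,)
    alpha: np.ndarray  # (T, S) degrees
    delta: np.ndarray  # (T, S) degrees
    tendon_lengths: np.ndarray  # (T, S) elastic tendon lengths, cm
    guide_lengths: np.ndarray  # (T, G)
    tendon_forces: np.ndarray  # (T, S) N
    torque_alpha: np.ndarray  # (T, S) applied proximal torques, N·cm
    torque_delta: np.ndarray  # (T, S)
    kinetic_energy: np.ndarray  # (T,)
    signs: np.ndarray  # (S,)
    k: float
    l_r: float
    h: float
    events: dict = field(default_factory=dict)
    diverged: bool = False

    def __len__(self):
        return len(self.times)

    def extend(self, other: "Trajectory") -> "Trajectory":
        """Concatenate a follow-on phase recorded from the same state."""
        out = Trajectory(
            times=np.concatenate([self.times, other.times[1:]]),
            alpha=np.concatenate([self.alpha, other.alpha[1:]]),
            delta=np.concatenate([self.delta, other.delta[1:]]),
            tendon_lengths=np.concatenate([self.tendon_lengths, other.tendon_lengths[1:]]),
            guide_lengths=np.concatenate([self.guide_lengths, other.guide_lengths[1:]]),
            tendon_forces=np.concatenate([self.tendon_forces, other.tendon_forces[1:]]),
            torque_alpha=np.concatenate([self.torque_alpha, other.torque_alpha[1:]]),
            torque_delta=np.concatenate([self.torque_delta, other.torque_delta[1:]]),
            kinetic_energy=np.concatenate([self.kinetic_energy, other.kinetic_energy[1:]]),
            signs=self.signs,
            k=self.k,
            l_r=self.l_r,
            h=self.h,
            events={**self.events, **other.events},
            diverged=self.diverged or other.diverged,
        )
        return out


def tendon_force(tendon: Tendon, l_t: float, dldt: float = 0.0) -> float:
    """Tension in one tendon at length ``l_t`` and lengthening rate ``dldt``.

    Zero at or below the resting length (the tendon contracts freely, like
    compressed resilin); above it, a linear spring ``k (l - l_r)`` plus a
    viscous term ``c dl/dt``, clamped to pure tension.  Units: N.
    """
    if tendon.k < 0:
        raise ValueError("tendon stiffness must be >= 0")
    if l_t < 0:
        raise ValueError("tendon length must be >= 0")
    if tendon.role == "guide" or tendon.k == 0.0:
        return 0.0
    if l_t <= tendon.l_r:
        return 0.0
    return max(0.0, tendon.k * (l_t - tendon.l_r) + tendon.damping * dldt)


def semi_implicit_euler_step(q: np.ndarray, v: np.ndarray, a: np.ndarray, h: float):
    """One semi-implicit Euler update: velocity first, then position."""
    v_new = v + h * a
    q_new = q + h * v_new
    return q_new, v_new


def _rodrigues(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotation matrices about unit axes; axis (...,3), angle (...)."""
    c = np.cos(angle)[..., None, None]
    s = np.sin(angle)[..., None, None]
    K = np.zeros(axis.shape[:-1] + (3, 3))
    ax, ay, az = axis[..., 0], axis[..., 1], axis[..., 2]
    K[..., 0, 1], K[..., 0, 2] = -az, ay
    K[..., 1, 0], K[..., 1, 2] = az, -ax
    K[..., 2, 0], K[..., 2, 1] = -ay, ax
    eye = np.broadcast_to(np.eye(3), K.shape)
    return eye + s * K + (1.0 - c) * (K @ K)


class _Compiled:
    """Constant per-strut arrays extracted from a WingModel."""

    def __init__(self, model: WingModel):
        sts = model.struts
        S = len(sts)
        self.S = S
        self.signs = np.array([s.sign for s in sts], dtype=float)
        self.anchor = np.zeros((S, 3))
        self.axis1 = np.zeros((S, 3))  # proximal rx axis, world frame at q=0
        self.hinge2_loc = np.zeros((S, 3))  # ring point rel anchor (body1 frame)
        self.axis2_loc = np.zeros((S, 3))
        self.com1_loc = np.zeros((S, 3))
        self.com2_loc = np.zeros((S, 3))  # rel ring point (body2 frame)
        self.m1 = np.zeros(S)
        self.m2 = np.zeros(S)
        self.I1_loc = np.zeros((S, 3, 3))
        self.I2_loc = np.zeros((S, 3, 3))
        bars = {b.name: b for b in model.bars}
        prox_joints = {j.index: j for j in model.joints if j.kind == "proximal"}
        for idx, s in enumerate(sts):
            b1, b2 = bars[f"prox{s.index}"], bars[f"dist{s.index}"]
            p, q = b1.endpoints
            t = b2.endpoints[1]
            self.anchor[idx] = p
            self.axis1[idx] = prox_joints[s.index].axis
            self.hinge2_loc[idx] = q - p
            ax = np.zeros(3)
            ax[:2] = s.ring_axis
            self.axis2_loc[idx] = ax / np.linalg.norm(ax)
            self.com1_loc[idx] = (q - p) / 2.0
            self.com2_loc[idx] = (t - q) / 2.0
            self.m1[idx], self.m2[idx] = b1.mass, b2.mass
            self.I1_loc[idx] = b1.inertia_com()
            self.I2_loc[idx] = b2.inertia_com()

        order = {s.index: i for i, s in enumerate(sts)}
        # elastic tendon sites: site1 on body1 (rel anchor), site2 on body2
        # (rel ring point); one per strut
        self.site1_loc = np.zeros((S, 3))
        self.site2_loc = np.zeros((S, 3))
        elastic = sorted(model.elastic_tendons(), key=lambda t: t.site_a[0])
        if len(elastic) != S:
            raise ValueError("expected one elastic tendon per strut")
        patch = getattr(model.config, "patch_offset", 0.0)
        for t in elastic:
            j = order[t.site_a[0]]
            u1 = self.hinge2_loc[j] / np.linalg.norm(self.hinge2_loc[j])
            self.site1_loc[j] = self.hinge2_loc[j] - t.site_a[2] * u1
            if patch:
                # lateral half-width of the broadened vein patch: offsets
                # the proximal attachment off the bar axis, in-plane,
                # alternating side with the strut sign
                n_lat = np.array([-u1[1], u1[0], 0.0])
                self.site1_loc[j] = self.site1_loc[j] + sts[j].sign * patch * n_lat
            u2 = self.com2_loc[j] / np.linalg.norm(self.com2_loc[j])
            self.site2_loc[j] = t.site_b[2] * u2
        self.tendon_damping = np.array([t.damping for t in elastic])

        guides = model.guide_tendons()
        self.G = len(guides)
        self.guide_a = np.array([order[g.site_a[0]] for g in guides], dtype=int)
        self.guide_b = np.array([order[g.site_b[0]] for g in guides], dtype=int)
        self.guide_site_a = np.zeros((self.G, 3))
        self.guide_site_b = np.zeros((self.G, 3))
        self.guide_lmax = np.full(self.G, np.inf)
        for gi, g in enumerate(guides):
            ja, jb = order[g.site_a[0]], order[g.site_b[0]]
            ua = self.com2_loc[ja] / np.linalg.norm(self.com2_loc[ja])
            ub = self.com2_loc[jb] / np.linalg.norm(self.com2_loc[jb])
            self.guide_site_a[gi] = g.site_a[2] * ua
            self.guide_site_b[gi] = g.site_b[2] * ub
            if g.limit is not None:
                self.guide_lmax[gi] = g.limit[1]

        self.delta_range = np.zeros((S, 2))
        for jt in (jt for jt in model.joints if jt.kind == "distal"):
            self.delta_range[order[jt.index]] = np.radians(jt.range_deg)
        self.alpha_range = None
        prox = [jt for jt in model.joints if jt.kind == "proximal"]
        if prox and prox[0].range_deg is not None:
            self.alpha_range = np.radians(np.array([jt.range_deg for jt in prox]))


class BatchSim:
    """Vectorised simulation of B instances of one wing-model geometry.

    ``k`` and ``l_r`` are scalars or per-instance arrays of length B.
    """

    def __init__(self, model: WingModel, k, l_r, config: SimConfig, B: int | None = None):
        self.model = model
        self.cfg = config
        self.c = _Compiled(model)
        k = np.atleast_1d(np.asarray(k, dtype=float))
        l_r = np.atleast_1d(np.asarray(l_r, dtype=float))
        if np.any(k < 0):
            raise ValueError("tendon stiffness must be >= 0")
        B = B or max(k.size, l_r.size)
        if k.size not in (1, B) or l_r.size not in (1, B):
            raise ValueError("k and l_r must be scalars or length-B arrays")
        self.B = B
        self.k = np.broadcast_to(
            (k if k.size == B else np.repeat(k, B))[:, None], (B, self.c.S)
        ).copy()
        self.l_r = np.broadcast_to(
            (l_r if l_r.size == B else np.repeat(l_r, B))[:, None], (B, self.c.S)
        ).copy()
        self.state = SimState(
            q=np.zeros((B, self.c.S, 2)),
            v=np.zeros((B, self.c.S, 2)),
            a=np.zeros((B, self.c.S, 2)),
            t=0.0,
        )
        # Initial flat state a: the taut tendons press every fold angle
        # into its overbend limit ("pulling all joints in the positive
        # direction, to a 3 degree position"), giving the cambered, locked
        # open wing.  Exact zero would sit on the unstable barrier top.
        lo, hi = self.c.delta_range[:, 0], self.c.delta_range[:, 1]
        self.state.q[..., 1] = np.where(np.abs(hi) < np.abs(lo), hi, lo)
        self.gravity = np.asarray(config.gravity, dtype=float)
        self.diverged = np.zeros(B, dtype=bool)
        self._settled = False

    # -- kinematics ------------------------------------------------------

    def _kinematics(self, q: np.ndarray, v: np.ndarray):
        c = self.c
        alpha, delta = q[..., 0], q[..., 1]

        shape = q.shape[:2] + (3,)
        a1 = np.broadcast_to(c.axis1, shape)
        R1 = _rodrigues(a1, alpha)
        R2rel = _rodrigues(np.broadcast_to(c.axis2_loc, shape), delta)
        R2 = R1 @ R2rel

        anchor = np.broadcast_to(c.anchor, shape)
        hinge2 = anchor + (R1 @ c.hinge2_loc[..., None])[..., 0]
        com1 = anchor + (R1 @ c.com1_loc[..., None])[..., 0]
        com2 = hinge2 + (R2 @ c.com2_loc[..., None])[..., 0]
        site1 = anchor + (R1 @ c.site1_loc[..., None])[..., 0]
        site2 = hinge2 + (R2 @ c.site2_loc[..., None])[..., 0]

        a2 = (R1 @ c.axis2_loc[..., None])[..., 0]

        w1 = a1 * v[..., 0:1]
        w2 = w1 + a2 * v[..., 1:2]

        I1w = R1 @ c.I1_loc @ np.swapaxes(R1, -1, -2)
        I2w = R2 @ c.I2_loc @ np.swapaxes(R2, -1, -2)

        return dict(
            R2=R2, anchor=anchor, hinge2=hinge2, com1=com1, com2=com2,
            site1=site1, site2=site2, a1=a1, a2=a2, w1=w1, w2=w2, I1w=I1w, I2w=I2w,
        )

    def _mass_and_bias(self, kin, v):
        c = self.c
        a1, a2 = kin["a1"], kin["a2"]
        anchor, hinge2 = kin["anchor"], kin["hinge2"]
        com1, com2 = kin["com1"], kin["com2"]
        I1w, I2w = kin["I1w"], kin["I2w"]
        w1, w2 = kin["w1"], kin["w2"]
        m1 = c.m1[None, :]
        m2 = c.m2[None, :]

        jv1_1 = np.cross(a1, com1 - anchor)
        jv2_1 = np.cross(a1, com2 - anchor)
        jv2_2 = np.cross(a2, com2 - hinge2)

        def dot(x, y):
            return np.sum(x * y, axis=-1)

        I1a1 = (I1w @ a1[..., None])[..., 0]
        I2a1 = (I2w @ a1[..., None])[..., 0]
        I2a2 = (I2w @ a2[..., None])[..., 0]

        M11 = m1 * dot(jv1_1, jv1_1) + dot(a1, I1a1) + m2 * dot(jv2_1, jv2_1) + dot(a1, I2a1)
        M12 = m2 * dot(jv2_1, jv2_2) + dot(a1, I2a2)
        M22 = m2 * dot(jv2_2, jv2_2) + dot(a2, I2a2)

        # Newton-Euler velocity-product terms (zero joint acceleration):
        # the distal hinge axis rotates with body 1, so with constant joint
        # rates the distal body still has angular acceleration w1 x a2 * ddelta.
        dw2 = np.cross(w1, a2) * v[..., 1:2]
        ac1 = np.cross(w1, np.cross(w1, com1 - anchor))
        aQ = np.cross(w1, np.cross(w1, hinge2 - anchor))
        ac2 = aQ + np.cross(dw2, com2 - hinge2) + np.cross(w2, np.cross(w2, com2 - hinge2))

        g = self.gravity
        f1 = m1[..., None] * (ac1 - g)
        f2 = m2[..., None] * (ac2 - g)
        t1 = np.cross(w1, (I1w @ w1[..., None])[..., 0])
        t2 = (I2w @ dw2[..., None])[..., 0] + np.cross(w2, (I2w @ w2[..., None])[..., 0])

        bias1 = dot(jv1_1, f1) + dot(a1, t1) + dot(jv2_1, f2) + dot(a1, t2)
        bias2 = dot(jv2_2, f2) + dot(a2, t2)
        return M11, M12, M22, bias1, bias2

    def _tendon_generalized(self, kin, out_tau, out_D, out_K, record=None):
        """Elastic tendon and guide forces.

        The small elastic-tendon damping is applied explicitly inside the
        tension-only force law; the (stiffer) guide-limit damping is
        accumulated into the per-strut damping matrix ``out_D`` and the
        spring gradients into ``out_K`` — both handled implicitly in the
        velocity update, which keeps constraint-grade stiffness stable at
        the working timestep.
        """
        c = self.c
        a1, a2 = kin["a1"], kin["a2"]
        anchor, hinge2 = kin["anchor"], kin["hinge2"]
        site1, site2 = kin["site1"], kin["site2"]
        w1, w2 = kin["w1"], kin["w2"]

        d = site2 - site1
        l = np.linalg.norm(d, axis=-1)
        u = d / np.maximum(l, 1e-12)[..., None]
        vs1 = np.cross(w1, site1 - anchor)
        vs2 = np.cross(w1, site2 - anchor) + np.cross(w2 - w1, site2 - hinge2)
        ldot = np.sum(u * (vs2 - vs1), axis=-1)

        active = l > self.l_r
        F = np.where(
            active,
            np.maximum(self.k * (l - self.l_r) + c.tendon_damping * ldot, 0.0),
            0.0,
        )
        jx_a = np.cross(a1, site2 - site1)  # d(site2-site1)/d alpha
        jx_d = np.cross(a2, site2 - hinge2)  # d(site2-site1)/d delta
        dl_da = np.sum(u * jx_a, axis=-1)
        dl_dd = np.sum(u * jx_d, axis=-1)
        out_tau[..., 0] -= F * dl_da
        out_tau[..., 1] -= F * dl_dd
        # implicit spring stabilisation: axial stiffness k u u^T plus the
        # transverse geometric term (F/l)(I - u u^T), which dominates near
        # the fold where the attachment points nearly coincide
        ka = np.where(active, self.k, 0.0)
        ft = F / np.maximum(l, 1e-9)
        g_aa = np.sum(jx_a * jx_a, axis=-1)
        g_dd = np.sum(jx_d * jx_d, axis=-1)
        g_ad = np.sum(jx_a * jx_d, axis=-1)
        out_K[..., 0, 0] += ka * dl_da**2 + ft * (g_aa - dl_da**2)
        out_K[..., 1, 1] += ka * dl_dd**2 + ft * (g_dd - dl_dd**2)
        out_K[..., 0, 1] += ka * dl_da * dl_dd + ft * (g_ad - dl_da * dl_dd)
        if record is not None:
            record["l"] = l.copy()
            record["F"] = F.copy()

        if c.G:
            ga, gb = c.guide_a, c.guide_b
            R2 = kin["R2"]
            pa = hinge2[:, ga] + (R2[:, ga] @ c.guide_site_a[..., None])[..., 0]
            pb = hinge2[:, gb] + (R2[:, gb] @ c.guide_site_b[..., None])[..., 0]
            dg = pb - pa
            lg = np.linalg.norm(dg, axis=-1)
            ug = dg / np.maximum(lg, 1e-12)[..., None]
            over = lg - c.guide_lmax
            engaged = over > 0
            Fg = np.where(engaged, self.cfg.guide_stiffness * over, 0.0)
            dla_a = np.sum(ug * np.cross(a1[:, ga], pa - anchor[:, ga]), axis=-1)
            dld_a = np.sum(ug * np.cross(a2[:, ga], pa - hinge2[:, ga]), axis=-1)
            dla_b = np.sum(ug * np.cross(a1[:, gb], pb - anchor[:, gb]), axis=-1)
            dld_b = np.sum(ug * np.cross(a2[:, gb], pb - hinge2[:, gb]), axis=-1)
            # tension pulls endpoint a along +ug and endpoint b along -ug
            np.add.at(out_tau[..., 0], (slice(None), ga), Fg * dla_a)
            np.add.at(out_tau[..., 1], (slice(None), ga), Fg * dld_a)
            np.add.at(out_tau[..., 0], (slice(None), gb), -Fg * dla_b)
            np.add.at(out_tau[..., 1], (slice(None), gb), -Fg * dld_b)
            # damping/stiffness (dl/dq_i)(dl/dq_j) blocks, within-strut only
            cg = np.where(engaged, self.cfg.guide_damping, 0.0)
            kg = np.where(engaged, self.cfg.guide_stiffness, 0.0)
            for coef, out in ((cg, out_D), (kg, out_K)):
                np.add.at(out[..., 0, 0], (slice(None), ga), coef * dla_a**2)
                np.add.at(out[..., 1, 1], (slice(None), ga), coef * dld_a**2)
                np.add.at(out[..., 0, 1], (slice(None), ga), coef * dla_a * dld_a)
                np.add.at(out[..., 0, 0], (slice(None), gb), coef * dla_b**2)
                np.add.at(out[..., 1, 1], (slice(None), gb), coef * dld_b**2)
                np.add.at(out[..., 0, 1], (slice(None), gb), coef * dla_b * dld_b)
            if record is not None:
                record["lg"] = lg.copy()

    def _limit_torques(self, q, v, out_tau, out_D, out_K):
        """Compliant joint-limit springs (damping/stiffness implicit)."""
        c, cfg = self.c, self.cfg
        lo, hi = c.delta_range[:, 0], c.delta_range[:, 1]
        delta = q[..., 1]
        over_hi = delta - hi
        over_lo = lo - delta
        tau = np.where(over_hi > 0, -cfg.limit_stiffness * over_hi, 0.0)
        tau = np.where(over_lo > 0, cfg.limit_stiffness * over_lo, tau)
        out_tau[..., 1] += tau
        active = (over_hi > 0) | (over_lo > 0)
        out_D[..., 1, 1] += np.where(active, cfg.limit_damping, 0.0)
        out_K[..., 1, 1] += np.where(active, cfg.limit_stiffness, 0.0)
        if c.alpha_range is not None:
            alo, ahi = c.alpha_range[:, 0], c.alpha_range[:, 1]
            alpha = q[..., 0]
            ta = np.where(alpha > ahi, -cfg.limit_stiffness * (alpha - ahi), 0.0)
            ta = np.where(alpha < alo, cfg.limit_stiffness * (alo - alpha), ta)
            out_tau[..., 0] += ta
            a_active = (alpha > ahi) | (alpha < alo)
            out_D[..., 0, 0] += np.where(a_active, cfg.alpha_limit_damping, 0.0)
            out_K[..., 0, 0] += np.where(a_active, cfg.limit_stiffness, 0.0)

    # -- stepping --------------------------------------------------------

    def forces_and_accel(self, tau_alpha, tau_delta, record=None):
        """Generalized accelerations for applied torques (B, S), N·cm.

        Constraint damping D is handled implicitly:
        (M + h D) a = tau - bias - D v, so stiff limit/guide dampers remain
        stable at the working timestep.
        """
        st = self.state
        h = self.cfg.h
        kin = self._kinematics(st.q, st.v)
        M11, M12, M22, b1, b2 = self._mass_and_bias(kin, st.v)
        tau = np.zeros_like(st.q)
        tau[..., 0] = tau_alpha
        tau[..., 1] = tau_delta
        D = np.zeros(st.q.shape[:2] + (2, 2))
        D[..., 0, 0] = self.cfg.joint_damping
        D[..., 1, 1] = self.cfg.joint_damping
        K = np.zeros_like(D)
        self._tendon_generalized(kin, tau, D, K, record)
        self._limit_torques(st.q, st.v, tau, D, K)
        D[..., 1, 0] = D[..., 0, 1]
        K[..., 1, 0] = K[..., 0, 1]

        v1, v2 = st.v[..., 0], st.v[..., 1]
        rhs1 = tau[..., 0] - b1 - (D[..., 0, 0] * v1 + D[..., 0, 1] * v2)
        rhs2 = tau[..., 1] - b2 - (D[..., 1, 0] * v1 + D[..., 1, 1] * v2)
        A11 = M11 + h * D[..., 0, 0] + h * h * K[..., 0, 0]
        A12 = M12 + h * D[..., 0, 1] + h * h * K[..., 0, 1]
        A22 = M22 + h * D[..., 1, 1] + h * h * K[..., 1, 1]
        det = A11 * A22 - A12 * A12
        acc = np.empty_like(st.q)
        acc[..., 0] = (A22 * rhs1 - A12 * rhs2) / det
        acc[..., 1] = (A11 * rhs2 - A12 * rhs1) / det
        return acc

    def step(self, tau_alpha, tau_delta, record=None):
        """Advance one semi-implicit Euler step of width ``cfg.h``."""
        st = self.state
        acc = self.forces_and_accel(tau_alpha, tau_delta, record)
        acc[self.diverged] = 0.0
        st.a = acc
        st.q, st.v = semi_implicit_euler_step(st.q, st.v, acc, self.cfg.h)
        st.t += self.cfg.h
        flat_q = st.q.reshape(self.B, -1)
        flat_v = st.v.reshape(self.B, -1)
        bad = ~np.all(np.isfinite(flat_q), axis=1)
        bad |= np.any(np.abs(flat_v) > self.cfg.divergence_velocity, axis=1)
        bad |= ~np.all(np.isfinite(flat_v), axis=1)
        newly = bad & ~self.diverged
        if np.any(newly):
            self.diverged |= bad
            st.q[newly] = np.nan_to_num(st.q[newly], nan=0.0, posinf=0.0, neginf=0.0)
        st.v[self.diverged] = 0.0

    def settle(self, duration: float = 5.0, extra_damping: float = 1.0):
        """Relax to the locked flat state before actuation.

        Runs unactuated with strong additional joint damping, then zeroes
        the velocities: every fold angle rests against its overbend limit
        at the force balance with the taut tendons (the cambered open
        wing), so actuated runs start from equilibrium, not from a guess.
        """
        cfg = self.cfg
        base = cfg.joint_damping
        object.__setattr__(cfg, "joint_damping", base + extra_damping)
        try:
            zeros = np.zeros((self.B, self.c.S))
            for _ in range(int(round(duration / cfg.h))):
                self.step(zeros, zeros)
        finally:
            object.__setattr__(cfg, "joint_damping", base)
        self.state.v[:] = 0.0
        self.state.t = 0.0

    def set_folded(self, pleat_deg: float = 90.0, settle_duration: float = 5.0):
        """Place the batch in the folded state b and relax it.

        Every fold angle is set onto its fold-side limit (the +/-180 deg
        stack, alternating with the strut signs) and the pleating angles to
        the folded radial configuration; a short damped settle then finds
        the nearby equilibrium.  Unfolding studies start here, making them
        independent of any particular folding run.
        """
        lo, hi = self.c.delta_range[:, 0], self.c.delta_range[:, 1]
        fold_side = np.where(np.abs(lo) > np.abs(hi), lo, hi)
        self.state.q[..., 1] = fold_side
        self.state.q[..., 0] = -self.c.signs * np.radians(pleat_deg)
        self.state.v[:] = 0.0
        self.settle(settle_duration)
        self._settled = True

    def kinetic_energy(self):
        """Total kinetic energy per instance, raw N·cm units."""
        kin = self._kinematics(self.state.q, self.state.v)
        M11, M12, M22, _, _ = self._mass_and_bias(kin, self.state.v)
        v1, v2 = self.state.v[..., 0], self.state.v[..., 1]
        e = 0.5 * (M11 * v1**2 + 2 * M12 * v1 * v2 + M22 * v2**2)
        return e.sum(axis=-1)

    def tendon_lengths(self):
        """Current elastic tendon lengths (B, S), cm."""
        kin = self._kinematics(self.state.q, self.state.v)
        return np.linalg.norm(kin["site2"] - kin["site1"], axis=-1)


@dataclass
class _PhaseRecord:
    times: np.ndarray
    q: np.ndarray  # (T, B, S, 2) radians
    tlen: np.ndarray
    glen: np.ndarray
    tforce: np.ndarray
    tau_a: np.ndarray
    tau_d: np.ndarray
    ke: np.ndarray
    diverged: np.ndarray


def run_phase(
    sim: BatchSim,
    duration: float,
    m_alpha,
    m_delta,
    dir_alpha: float,
    dir_delta: float,
    record_stride: int | None = None,
) -> _PhaseRecord:
    """Advance ``sim`` for ``duration`` seconds under constant torques.

    ``m_alpha`` / ``m_delta`` are magnitudes (scalar or per-instance (B,)),
    applied with the strut alternation signs times ``dir_*`` (N·cm).
    """
    cfg = sim.cfg
    if not sim._settled:
        sim.settle()
        sim._settled = True
    stride = record_stride or cfg.record_stride
    B, S, G = sim.B, sim.c.S, sim.c.G
    ma = np.broadcast_to(np.asarray(m_alpha, dtype=float).reshape(-1, 1), (B, S))
    md = np.broadcast_to(np.asarray(m_delta, dtype=float).reshape(-1, 1), (B, S))
    tau_a = ma * sim.c.signs[None, :] * dir_alpha
    tau_d = md * sim.c.signs[None, :] * dir_delta

    n_steps = int(round(duration / cfg.h))
    n_rec = n_steps // stride + 1
    rec = _PhaseRecord(
        times=np.empty(n_rec),
        q=np.empty((n_rec, B, S, 2)),
        tlen=np.empty((n_rec, B, S)),
        glen=np.empty((n_rec, B, max(G, 1))),
        tforce=np.empty((n_rec, B, S)),
        tau_a=np.empty((n_rec, B, S)),
        tau_d=np.empty((n_rec, B, S)),
        ke=np.empty((n_rec, B)),
        diverged=np.zeros((n_rec, B), dtype=bool),
    )

    scratch: dict = {}
    kin0 = sim._kinematics(sim.state.q, sim.state.v)
    tau0 = np.zeros_like(sim.state.q)
    D0 = np.zeros(sim.state.q.shape[:2] + (2, 2))
    sim._tendon_generalized(kin0, tau0, D0, D0.copy(), scratch)

    def snapshot(i):
        rec.times[i] = sim.state.t
        rec.q[i] = sim.state.q
        rec.tlen[i] = scratch.get("l", 0.0)
        if G:
            rec.glen[i] = scratch.get("lg", 0.0)
        rec.tforce[i] = scratch.get("F", 0.0)
        rec.tau_a[i] = tau_a
        rec.tau_d[i] = tau_d
        rec.ke[i] = sim.kinetic_energy()
        rec.diverged[i] = sim.diverged

    snapshot(0)
    ri = 1
    for istep in range(1, n_steps + 1):
        scratch = {}
        sim.step(tau_a, tau_d, scratch)
        if istep % stride == 0:
            snapshot(ri)
            ri += 1
    rec.times = rec.times[:ri]
    rec.q = rec.q[:ri]
    rec.tlen = rec.tlen[:ri]
    rec.glen = rec.glen[:ri]
    rec.tforce = rec.tforce[:ri]
    rec.tau_a = rec.tau_a[:ri]
    rec.tau_d = rec.tau_d[:ri]
    rec.ke = rec.ke[:ri]
    rec.diverged = rec.diverged[:ri]
    return rec


def phase_to_trajectories(sim: BatchSim, rec: _PhaseRecord) -> list[Trajectory]:
    """Slice a batched phase record into per-instance trajectories."""
    out = []
    G = sim.c.G
    for i in range(sim.B):
        out.append(
            Trajectory(
                times=rec.times.copy(),
                alpha=np.degrees(rec.q[:, i, :, 0]),
                delta=np.degrees(rec.q[:, i, :, 1]),
                tendon_lengths=rec.tlen[:, i].copy(),
                guide_lengths=rec.glen[:, i, :G].copy(),
                tendon_forces=rec.tforce[:, i].copy(),
                torque_alpha=rec.tau_a[:, i].copy(),
                torque_delta=rec.tau_d[:, i].copy(),
                kinetic_energy=rec.ke[:, i].copy(),
                signs=sim.c.signs.copy(),
                k=float(sim.k[i, 0]),
                l_r=float(sim.l_r[i, 0]),
                h=sim.cfg.h,
                diverged=bool(rec.diverged[-1, i]),
            )
        )
    return out


def run_simulation(model: WingModel, schedule, config: SimConfig) -> Trajectory:
    """Simulate one wing model under an actuation schedule.

    The run is deterministic: identical inputs produce identical
    trajectories.  Divergence freezes the state and flags the trajectory
    instead of raising, so parameter sweeps can continue past bad cells.
    """
    elastic = model.elastic_tendons()
    sim = BatchSim(model, elastic[0].k, elastic[0].l_r, config)
    rec = run_phase(
        sim,
        config.duration,
        schedule.M_alpha,
        schedule.M_delta,
        schedule.dir_alpha,
        schedule.dir_delta,
    )
    return phase_to_trajectories(sim, rec)[0]
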