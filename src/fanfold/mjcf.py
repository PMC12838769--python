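"""MJCF (MuJoCo-dialect XML) emission of the wing-section model.

The emitted document mirrors the bar-and-hinge model one-to-one: one body
chain per strut (proximal bar with stacked rx/ry/rz hinges at the anchor,
distal bar with a limited hinge about the local ring-fold axis), spatial
tendons with stiffness/damping/springlength, and torque actuators on the
proximal and distal rx joints.  Numbers are the raw cm/kg/N·cm quantities
of the model; the header records the unit convention.  Output is
deterministic: the same model yields byte-identical XML.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from xml.dom import minidom

import numpy as np

from .model import WingModel

__all__ = ["emit_model_xml"]


def _fmt(x) -> str:
    return np.format_float_positional(
        float(x), precision=12, unique=True, trim="0", fractional=False
    )


def _vec(v) -> str:
    return " ".join(_fmt(x) for x in v)


def emit_model_xml(model: WingModel) -> str:
    """Serialise ``model`` as an MJCF XML string."""
    if not model.bars or not model.struts:
        raise ValueError("cannot emit XML for an empty model")
    cfg = model.config
    root = ET.Element("mujoco", model=f"fanfold_wing_n{model.params.n}")
    ET.SubElement(
        root,
        "compiler",
        angle="degree",
        autolimits="false",
        # raw unit convention: lengths cm, masses kg, forces N, torques N*cm
    )
    ET.SubElement(root, "option", timestep="0.005", integrator="Euler",
                  gravity=_vec(cfg.gravity))
    default = ET.SubElement(root, "default")
    ET.SubElement(
        default, "geom", type="capsule", size=_fmt(cfg.bar_diameter / 2.0),
        density=_fmt(cfg.bar_density),
    )

    world = ET.SubElement(root, "worldbody")
    bars = {b.name: b for b in model.bars}
    joints = {(j.kind, j.index): j for j in model.joints}
    site_of: dict[tuple[int, str, float], str] = {}

    for s in model.struts:
        bprox = bars[f"prox{s.index}"]
        bdist = bars[f"dist{s.index}"]
        pj = joints[("proximal", s.index)]
        dj = joints[("distal", s.index)]
        p, q = bprox.endpoints
        t = bdist.endpoints[1]

        body_p = ET.SubElement(world, "body", name=f"prox{s.index}", pos=_vec(p))
        for dof, axis in zip(pj.dof, (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))):
            attrs = dict(name=f"alpha{s.index}_{dof}", axis=_vec(pj.axis if dof == "rx" else axis))
            if pj.range_deg is not None and dof == "rx":
                attrs["limited"] = "true"
                attrs["range"] = _vec(pj.range_deg)
            ET.SubElement(body_p, "joint", **attrs)
        ET.SubElement(body_p, "geom", name=f"bar_prox{s.index}", fromto=_vec(np.r_[np.zeros(3), q - p]))

        body_d = ET.SubElement(body_p, "body", name=f"dist{s.index}", pos=_vec(q - p))
        ET.SubElement(
            body_d, "joint", name=f"delta{s.index}", axis=_vec(dj.axis),
            limited="true", range=_vec(dj.range_deg),
        )
        ET.SubElement(body_d, "geom", name=f"bar_dist{s.index}", fromto=_vec(np.r_[np.zeros(3), t - q]))

        for tn in model.tendons:
            for site_key, seg in ((tn.site_a, "a"), (tn.site_b, "b")):
                strut_idx, segment, dist = site_key
                if strut_idx != s.index or site_key in site_of:
                    continue
                if segment == "proximal":
                    u = (p - q) / np.linalg.norm(p - q)
                    pos = (q - p) + dist * u
                    parent = body_p
                else:
                    u = (t - q) / np.linalg.norm(t - q)
                    pos = dist * u
                    parent = body_d
                name = f"site_{tn.name}_{seg}"
                ET.SubElement(parent, "site", name=name, pos=_vec(pos))
                site_of[site_key] = name

    tend = ET.SubElement(root, "tendon")
    for tn in model.tendons:
        attrs = dict(
            name=tn.name,
            stiffness=_fmt(tn.k),
            damping=_fmt(tn.damping),
            springlength=_fmt(tn.l_r),
        )
        if tn.limit is not None:
            attrs["limited"] = "true"
            attrs["range"] = _vec(tn.limit)
        sp = ET.SubElement(tend, "spatial", **attrs)
        ET.SubElement(sp, "site", site=site_of[tn.site_a])
        ET.SubElement(sp, "site", site=site_of[tn.site_b])

    act = ET.SubElement(root, "actuator")
    for s in model.struts:
        ET.SubElement(act, "motor", name=f"m_alpha{s.index}", joint=f"alpha{s.index}_rx")
        ET.SubElement(act, "motor", name=f"m_delta{s.index}", joint=f"delta{s.index}")

    raw = ET.tostring(root, encoding="unicode")
    pretty = minidom.parseString(raw).toprettyxml(indent="  ")
    return pretty
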