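"""Fan crease-pattern generation for dermapteran-style hindwing folding.

The anal fan of the earwig hindwing is abstracted as ``n`` repeating fan
units.  Four parameters fix the geometry: the proximal and distal segment
lengths of the radial fold lines, the radius ``r`` of the fan-centre circle
on which the fold lines are anchored, and the angular width ``theta`` of one
segment.  The folded configuration is constructed first (all pleats stacked
onto the central axis); the flat, unfolded crease pattern is then derived by
mirroring each unit across its base chord, inserting the intercalary fold
lines, and deflecting the distal sub-segments across the transversal ring
fold.  Flat-foldability of the simplified construction requires
``n * theta <= 90`` degrees.

Conventions
-----------
* The fan centre ``O`` is at the origin, the tip point ``A`` on the +x axis,
  and the first anchor ``H1`` lies in the -y half-plane ("clockwise").
* Angles cross the API boundary in degrees and are handled in radians
  internally.
* The deflection angle ``phi_i`` is reported as the acute angle between the
  incident radial fold line and the ring-fold line M-N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FanParams",
    "FoldLine",
    "CreasePattern",
    "Strut",
    "check_flat_foldability",
    "build_folded_geometry",
    "unfold_pattern",
]

_EPS_PARALLEL = 1e-12


class GeometryError(ValueError):
    """Raised for degenerate or non-foldable constructions."""


@dataclass(frozen=True)
class FanParams:
    """Geometric input parameters of an ``n``-unit fan section.

    Parameters
    ----------
    l_proximal, l_distal : float
        Lengths of the proximal and distal portion of the radial fold
        lines, cm.
    r : float
        Radius of the fan-centre circle, cm.
    theta : float
        Angular width of one fan segment, degrees.
    n : int
        Number of fan units (>= 1).
    """

    l_proximal: float = 25.0
    l_distal: float = 25.0
    r: float = 5.0
    theta: float = 15.0
    n: int = 1

    def __post_init__(self) -> None:
        for name in ("l_proximal", "l_distal", "r"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive finite length")
        if not np.isfinite(self.theta) or self.theta <= 0:
            raise ValueError("theta must be a positive angle in degrees")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("n must be an integer >= 1")

    @property
    def theta_rad(self) -> float:
        return float(np.radians(self.theta))


@dataclass(frozen=True)
class FoldLine:
    """One fold segment of a crease pattern.

    ``assignment`` is "M" (mountain), "V" (valley) or "B" (boundary).
    ``kind`` distinguishes the radial main lines, the intercalary radial
    lines and the transversal ring-fold segments.  Fold lines flagged
    ``auxiliary`` are needed to compute deflection angles of the last unit
    but are not carried into the simulation model.
    """

    start: tuple[str, ...]  # point names (start, end)
    coords: np.ndarray  # (2, 2) array, rows = endpoints
    assignment: str
    kind: str
    index: int
    auxiliary: bool = False

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.coords[1] - self.coords[0]))


@dataclass
class CreasePattern:
    """Named points, fold lines and deflection angles of a fan pattern.

    ``state`` is "folded" for the stacked construction geometry and
    "unfolded" for the flat crease pattern.  ``phi`` holds the deflection
    angles ``phi_1 .. phi_{n+2}`` in degrees (acute-angle convention, see
    module docstring; the convention is also recorded in ``meta``).
    """

    params: FanParams
    state: str
    points: dict[str, np.ndarray]
    fold_lines: list[FoldLine]
    phi: np.ndarray
    meta: dict = field(default_factory=dict)
    ring_axes: dict = field(default_factory=dict)  # (kind, index) -> unit 2-vector

    @property
    def n_computed_folds(self) -> int:
        """Number of computed radial fold lines (2n + 3)."""
        return len(
            {
                (f.kind, f.index)
                for f in self.fold_lines
                if f.kind in ("radial_main", "radial_intercalary")
            }
        )

    @property
    def n_model_folds(self) -> int:
        """Number of radial fold lines retained for the model (2n + 1)."""
        return len(
            {
                (f.kind, f.index)
                for f in self.fold_lines
                if f.kind in ("radial_main", "radial_intercalary") and not f.auxiliary
            }
        )


@dataclass(frozen=True)
class Strut:
    """Model-facing description of one retained radial fold line.

    ``proximal_anchor`` is the base end on the fan-centre circle,
    ``ring_point`` the crossing with the ring fold and ``tip`` the outer
    end.  ``ring_axis`` is the unit direction of the ring fold at the
    crossing, used as the distal hinge axis.  ``sign`` encodes the
    mountain/valley alternation, ``(-1)**(j+1)`` for strut ``j`` (1-based).
    """

    index: int
    kind: str
    assignment: str
    sign: int
    proximal_anchor: np.ndarray
    ring_point: np.ndarray
    tip: np.ndarray
    ring_axis: np.ndarray

    @property
    def proximal_length(self) -> float:
        return float(np.linalg.norm(self.ring_point - self.proximal_anchor))

    @property
    def distal_length(self) -> float:
        return float(np.linalg.norm(self.tip - self.ring_point))

    @property
    def kink_angle(self) -> float:
        """In-plane deviation of the distal segment from the proximal
        direction, radians (zero for a straight fold line)."""
        u = self.ring_point - self.proximal_anchor
        w = self.tip - self.ring_point
        c = float(np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w)))
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# elementary planar isometries


def _reflect(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Reflect point ``p`` across the line through ``a`` and ``b``."""
    d = b - a
    nrm = np.linalg.norm(d)
    if nrm < _EPS_PARALLEL:
        raise GeometryError("reflection line is degenerate")
    d = d / nrm
    v = p - a
    return a + 2.0 * np.dot(v, d) * d - v


def _reflect_dir(v: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = b - a
    d = d / np.linalg.norm(d)
    return 2.0 * np.dot(v, d) * d - v


def _rotate(p: np.ndarray, center: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    v = p - center
    return center + np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _intersect_lines(p: np.ndarray, u: np.ndarray, q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Intersection of lines p + t*u and q + s*v."""
    den = u[0] * v[1] - u[1] * v[0]
    if abs(den) < _EPS_PARALLEL * max(1.0, np.linalg.norm(u) * np.linalg.norm(v)):
        raise GeometryError("fold lines are parallel; intersection is degenerate")
    t = ((q[0] - p[0]) * v[1] - (q[1] - p[1]) * v[0]) / den
    return p + t * u


def _angle_of(v: np.ndarray) -> float:
    return float(np.arctan2(v[1], v[0]))


# ---------------------------------------------------------------------------
# operations


def check_flat_foldability(params: FanParams) -> bool:
    """Whether the simplified fan construction is flat-foldable.

    The condition is ``n * theta <= 90`` degrees: beyond a quarter circle
    the mirrored units of the pattern would overlap and the pleats can no
    longer stack flat.
    """
    return params.n * params.theta <= 90.0


def build_folded_geometry(params: FanParams) -> CreasePattern:
    """Construct the folded-state geometry of the fan section.

    The fan centre ``O`` carries a circle of radius ``r``; ``A`` lies on the
    +x axis at ``l_proximal + l_distal`` from ``O``; the ring-fold line
    ``M-N`` is vertical at ``x = l_proximal``.  Anchors ``H_0 .. H_{n+2}``
    sit on the circle at angular spacing ``theta``, starting diametrically
    opposite ``A`` and proceeding clockwise (into the -y half-plane).  The
    radial lines ``H_i - A`` cross ``M-N`` in the points ``F_i`` at the
    deflection angles ``phi_i``.
    """
    if not check_flat_foldability(params):
        raise GeometryError(
            f"not flat-foldable: n*theta = {params.n * params.theta:.6g} deg > 90 deg"
        )
    n = params.n
    th = params.theta_rad
    L = params.l_proximal + params.l_distal

    O = np.zeros(2)
    A = np.array([L, 0.0])
    M = np.array([params.l_proximal, params.r])
    N = np.array([params.l_proximal, -params.r])

    points: dict[str, np.ndarray] = {"O": O, "A": A, "M": M, "N": N}
    H = []
    for i in range(n + 3):
        ang = np.pi + i * th  # clockwise from H0 = (-r, 0)
        Hi = params.r * np.array([np.cos(ang), np.sin(ang)])
        points[f"H{i}"] = Hi
        H.append(Hi)

    mn_dir = np.array([0.0, 1.0])
    phi = np.empty(n + 2)
    fold_lines: list[FoldLine] = []
    for i in range(1, n + 3):
        d = A - H[i]
        if abs(d[0]) < _EPS_PARALLEL:
            raise GeometryError(f"radial line H{i}-A is parallel to M-N")
        F = _intersect_lines(H[i], d, N, mn_dir)
        points[f"F{i}"] = F
        cosang = abs(np.dot(d, mn_dir)) / np.linalg.norm(d)
        phi[i - 1] = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
        # acute angle between the radial line and M-N
        phi[i - 1] = min(phi[i - 1], 180.0 - phi[i - 1])
        aux = i == n + 2
        fold_lines.append(
            FoldLine((f"H{i}", f"F{i}"), np.array([H[i], F]), "M", "radial_main", i, aux)
        )
        fold_lines.append(
            FoldLine((f"F{i}", "A"), np.array([F, A]), "M", "radial_main", i, aux)
        )
    fold_lines.append(FoldLine(("M", "N"), np.array([M, N]), "V", "ring", 0, False))

    return CreasePattern(
        params=params,
        state="folded",
        points=points,
        fold_lines=fold_lines,
        phi=phi,
        meta={"phi_convention": "acute angle between radial fold line and M-N, degrees"},
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def unfold_pattern(folded: CreasePattern, params: FanParams | None = None) -> CreasePattern:
    """Derive the flat, unfolded crease pattern from the folded geometry.

    Each radial line ``H_i - A`` is mirrored across the base chord
    ``H_{i-1} - H_i`` (giving ``A'_i`` and the mirrored ring point
    ``F'_i``); the intercalary lines ``H_i - B_i`` are obtained by rotating
    the mirrored line by ``theta`` about ``H_i`` toward the next unit, and
    their ring points ``V_i`` by intersecting with the next unit's mirrored
    ring line.  The distal sub-segments are then deflected across the local
    ring-fold line: reflecting the straight continuation of each proximal
    segment across the ring line deviates it by exactly ``180 - 2 * phi_i``
    degrees, which is the ``phi_i`` deflection of the construction.  All
    steps are planar isometries, so segment lengths are preserved and the
    pattern folds back onto the folded-state geometry.
    """
    if folded.state != "folded":
        raise ValueError("unfold_pattern expects a folded-state pattern")
    params = params or folded.params
    n = params.n
    th = params.theta_rad
    pts_in = folded.points
    A = pts_in["A"]
    H = [pts_in[f"H{i}"] for i in range(n + 3)]
    F = {i: pts_in[f"F{i}"] for i in range(1, n + 3)}
    mn_dir = np.array([0.0, 1.0])

    points: dict[str, np.ndarray] = {k: v.copy() for k, v in pts_in.items()}

    # steps 6-7: mirror each radial line across its base chord
    Ap: dict[int, np.ndarray] = {}
    Fp: dict[int, np.ndarray] = {}
    ring_dir: dict[int, np.ndarray] = {}
    for i in range(1, n + 3):
        a, b = H[i - 1], H[i]
        Ap[i] = _reflect(A, a, b)
        Fp[i] = _reflect(F[i], a, b)
        ring_dir[i] = _reflect_dir(mn_dir, a, b)
        points[f"A'{i}"] = Ap[i]
        points[f"F'{i}"] = Fp[i]

    # steps 8-9: intercalary lines H_i - B_i and their ring points V_i.
    # The mirror flips orientation, so the construction's clockwise rotation
    # is realised with whichever sign places B_i angularly between A'_i and
    # A'_{i+1} as seen from H_i.
    B: dict[int, np.ndarray] = {}
    V: dict[int, np.ndarray] = {}
    for i in range(1, n + 2):
        base = _angle_of(Ap[i] - H[i])
        ref = _angle_of(Ap[i + 1] - H[i])
        toward_next = np.sign((ref - base + np.pi) % (2 * np.pi) - np.pi) or 1.0
        Bi = _rotate(Ap[i], H[i], toward_next * th)
        B[i] = Bi
        V[i] = _intersect_lines(H[i], Bi - H[i], Fp[i + 1], ring_dir[i + 1])
        points[f"B{i}"] = Bi
        points[f"V{i}"] = V[i]

    # steps 10-11: deflect distal sub-segments across the local ring line
    App: dict[int, np.ndarray] = {}
    Bp: dict[int, np.ndarray] = {}
    # The unfolded distal direction is the proximal direction mirrored
    # across the local ring-fold line (a flat vertex reflects crease
    # directions; reflecting the continuation instead would re-fold the
    # ring fold).  The local ring line of a radial main is its unit's
    # mirrored M-N image; for an intercalary line it is the same image
    # rotated by theta along with the rest of the unit.  Mirroring across
    # it deviates the distal segment from the straight continuation by
    # exactly 180 - 2*phi_i degrees, i.e. the phi_i deflection.
    ring_axes: dict = {}
    for i in range(1, n + 3):
        u = _unit(Fp[i] - H[i])
        g = ring_dir[i]
        w = _reflect_dir(-u, Fp[i], Fp[i] + g)
        App[i] = Fp[i] + np.linalg.norm(A - F[i]) * w
        points[f"A''{i}"] = App[i]
        points[f"F''{i}"] = Fp[i]
        ring_axes[("radial_main", i)] = g.copy()
    for i in range(1, n + 2):
        v = _unit(V[i] - H[i])
        dist_len = np.linalg.norm(Ap[i] - H[i]) - np.linalg.norm(V[i] - H[i])
        if dist_len <= 0:
            raise GeometryError(f"ring point V{i} lies beyond the tip of intercalary line {i}")
        base = _angle_of(Ap[i] - H[i])
        ref = _angle_of(Ap[i + 1] - H[i])
        toward_next = np.sign((ref - base + np.pi) % (2 * np.pi) - np.pi) or 1.0
        c, s = np.cos(toward_next * th), np.sin(toward_next * th)
        g = np.array(
            [c * ring_dir[i][0] - s * ring_dir[i][1], s * ring_dir[i][0] + c * ring_dir[i][1]]
        )
        w = _reflect_dir(-v, V[i], V[i] + g)
        Bp[i] = V[i] + dist_len * w
        points[f"B'{i}"] = Bp[i]
        points[f"V'{i}"] = V[i]
        ring_axes[("radial_intercalary", i)] = g.copy()

    # assemble fold lines: radial mains, intercalaries, ring polyline
    fold_lines: list[FoldLine] = []
    # radial mains are mountain folds, intercalaries valley folds: the
    # M/V alternation of the fan runs across the interleaved families
    for i in range(1, n + 3):
        aux = i == n + 2
        fold_lines.append(
            FoldLine((f"H{i}", f"F'{i}"), np.array([H[i], Fp[i]]), "M", "radial_main", i, aux)
        )
        fold_lines.append(
            FoldLine(
                (f"F'{i}", f"A''{i}"), np.array([Fp[i], App[i]]), "M", "radial_main", i, aux
            )
        )
    for i in range(1, n + 2):
        aux = i == n + 1
        fold_lines.append(
            FoldLine(
                (f"H{i}", f"V{i}"), np.array([H[i], V[i]]), "V", "radial_intercalary", i, aux
            )
        )
        fold_lines.append(
            FoldLine(
                (f"V{i}", f"B'{i}"), np.array([V[i], Bp[i]]), "V", "radial_intercalary", i, aux
            )
        )
    ring_seq: list[tuple[str, np.ndarray]] = []
    for i in range(1, n + 2):
        ring_seq.append((f"F'{i}", Fp[i]))
        ring_seq.append((f"V{i}", V[i]))
    ring_seq.append((f"F'{n + 2}", Fp[n + 2]))
    for j in range(len(ring_seq) - 1):
        (na, pa), (nb, pb) = ring_seq[j], ring_seq[j + 1]
        aux = j >= 2 * params.n  # segments touching only auxiliary radials
        fold_lines.append(
            FoldLine((na, nb), np.array([pa, pb]), "V" if j % 2 == 0 else "M", "ring", j + 1, aux)
        )

    pattern = CreasePattern(
        params=params,
        state="unfolded",
        points=points,
        fold_lines=fold_lines,
        phi=folded.phi.copy(),
        meta=dict(folded.meta),
        ring_axes=ring_axes,
    )
    pattern.meta["deflection"] = "distal segments reflected across local ring line (180 - 2*phi_i)"
    _check_no_crossings(pattern)
    return pattern


def struts(pattern: CreasePattern) -> list[Strut]:
    """Model-facing struts of an unfolded pattern.

    Returns the ``2n + 1`` retained radial fold lines, ordered
    main_1, intercalary_1, main_2, ... with alternating signs
    ``(-1)**(j+1)``.  The ring axis at each crossing is the (bisecting)
    direction of the adjacent ring-fold segments.
    """
    if pattern.state != "unfolded":
        raise ValueError("struts() expects an unfolded pattern")
    n = pattern.params.n
    pts = pattern.points

    out: list[Strut] = []
    for j in range(1, 2 * n + 2):
        if j % 2 == 1:
            i = (j + 1) // 2
            anchor, ring, tip = pts[f"H{i}"], pts[f"F'{i}"], pts[f"A''{i}"]
            kind, assignment = "radial_main", "M"
        else:
            i = j // 2
            anchor, ring, tip = pts[f"H{i}"], pts[f"V{i}"], pts[f"B'{i}"]
            kind, assignment = "radial_intercalary", "V"
        out.append(
            Strut(
                index=j,
                kind=kind,
                assignment=assignment,
                sign=(-1) ** (j + 1),
                proximal_anchor=anchor.copy(),
                ring_point=ring.copy(),
                tip=tip.copy(),
                ring_axis=pattern.ring_axes[(kind, i)].copy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# self-intersection check


def _segments_cross(p1, p2, q1, q2, tol=1e-12) -> bool:
    """Proper intersection test; shared endpoints are allowed."""
    for a, b in ((p1, q1), (p1, q2), (p2, q1), (p2, q2)):
        if np.linalg.norm(a - b) < 1e-9:
            return False
    d1 = p2 - p1
    d2 = q2 - q1
    den = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(den) < tol:
        return False
    t = ((q1[0] - p1[0]) * d2[1] - (q1[1] - p1[1]) * d2[0]) / den
    s = ((q1[0] - p1[0]) * d1[1] - (q1[1] - p1[1]) * d1[0]) / den
    return tol < t < 1 - tol and tol < s < 1 - tol


def _check_no_crossings(pattern: CreasePattern) -> None:
    # Auxiliary lines are construction scaffolding for the deflection
    # angles of the last unit; at the flat-foldability boundary they may
    # sweep back over the retained pattern, which is harmless.
    lines = [f for f in pattern.fold_lines if not f.auxiliary]
    for a in range(len(lines)):
        for b in range(a + 1, len(lines)):
            if _segments_cross(lines[a].coords[0], lines[a].coords[1], lines[b].coords[0], lines[b].coords[1]):
                raise GeometryError(
                    f"fold lines {lines[a].start} and {lines[b].start} cross away from shared vertices"
                )
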