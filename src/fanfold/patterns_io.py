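"""Crease-pattern export: FOLD (JSON), SVG and CSV.

The FOLD writer emits the subset of the FOLD spec used by origami tools
(``vertices_coords``, ``edges_vertices``, ``edges_assignment``); mountain
folds are "M", valley folds "V".  The SVG writer draws mountain folds as
solid and valley folds as dashed strokes.  Coordinates are centimetres.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .geometry import CreasePattern

__all__ = ["export_pattern", "read_fold"]

_FORMATS = ("FOLD", "SVG", "CSV")


def export_pattern(pattern: CreasePattern, path: str | Path, format: str | None = None) -> Path:
    """Write ``pattern`` to ``path`` in the requested format.

    ``format`` is one of ``"FOLD"``, ``"SVG"``, ``"CSV"``; when omitted it
    is inferred from the path suffix.  Returns the written path.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").upper()
    format = format.upper()
    if format not in _FORMATS:
        raise ValueError(f"unsupported export format {format!r}; expected one of {_FORMATS}")
    if not pattern.fold_lines:
        raise ValueError("cannot export an empty pattern (no fold lines)")

    if format == "FOLD":
        payload = _to_fold(pattern)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif format == "SVG":
        path.write_text(_to_svg(pattern))
    else:
        _to_csv(pattern, path)
    return path


def _vertex_table(pattern: CreasePattern):
    names: list[str] = []
    index: dict[str, int] = {}
    for line in pattern.fold_lines:
        for name in line.start:
            if name not in index:
                index[name] = len(names)
                names.append(name)
    coords = [pattern.points[name].tolist() for name in names]
    return names, index, coords


def _to_fold(pattern: CreasePattern) -> dict:
    names, index, coords = _vertex_table(pattern)
    edges, assignments = [], []
    for line in pattern.fold_lines:
        edges.append([index[line.start[0]], index[line.start[1]]])
        assignments.append(line.assignment)
    return {
        "file_spec": 1.1,
        "file_creator": "fanfold",
        "file_classes": ["singleModel"],
        "frame_classes": ["creasePattern"] if pattern.state == "unfolded" else ["foldedForm"],
        "frame_unit": "cm",
        "vertices_coords": coords,
        "edges_vertices": edges,
        "edges_assignment": assignments,
        "fanfold:vertex_names": names,
        "fanfold:phi_deg": pattern.phi.tolist(),
        "fanfold:phi_convention": pattern.meta.get("phi_convention", ""),
    }


def read_fold(path: str | Path) -> dict:
    """Read back a FOLD file written by :func:`export_pattern`.

    Returns the decoded JSON dict with ``vertices_coords`` as an ndarray.
    """
    payload = json.loads(Path(path).read_text())
    payload["vertices_coords"] = np.asarray(payload["vertices_coords"], dtype=float)
    return payload


def _to_svg(pattern: CreasePattern) -> str:
    pts = np.array([line.coords for line in pattern.fold_lines]).reshape(-1, 2)
    lo, hi = pts.min(axis=0) - 2, pts.max(axis=0) + 2
    w, h = hi - lo
    rows = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="{lo[0]:.3f} {-hi[1]:.3f} {w:.3f} {h:.3f}">',
        f'<g fill="none" stroke-width="{max(w, h) / 400:.4f}">',
    ]
    style = {
        "M": 'stroke="#c22"',
        "V": 'stroke="#24c" stroke-dasharray="0.8 0.5"',
        "B": 'stroke="#222"',
    }
    for line in pattern.fold_lines:
        (x1, y1), (x2, y2) = line.coords
        rows.append(
            f'<line x1="{x1:.6f}" y1="{-y1:.6f}" x2="{x2:.6f}" y2="{-y2:.6f}" {style[line.assignment]}/>'
        )
    rows += ["</g>", "</svg>"]
    return "\n".join(rows)


def _to_csv(pattern: CreasePattern, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["kind", "index", "assignment", "auxiliary", "x1_cm", "y1_cm", "x2_cm", "y2_cm"]
        )
        for line in pattern.fold_lines:
            (x1, y1), (x2, y2) = line.coords
            writer.writerow(
                [
                    line.kind,
                    line.index,
                    line.assignment,
                    int(line.auxiliary),
                    f"{x1:.12g}",
                    f"{y1:.12g}",
                    f"{x2:.12g}",
                    f"{y2:.12g}",
                ]
            )
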