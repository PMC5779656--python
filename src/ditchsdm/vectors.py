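"""Vector input/output: network polylines (GeoJSON) and occurrence points.

The survey workflow produces line features for the ditch network and point
records for species occurrences. Lines round-trip through GeoJSON
LineStrings; occurrences through CSV with columns
``species, row, col, presence``. Survey points in projected coordinates snap
to the nearest ditch cell centre within one cell size (the GPS accuracy of
the field protocol); farther points are rejected and reported.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, shape

from .grids import Grid
from .network import Cell, DitchGraph, OccurrenceSet

__all__ = [
    "write_network_geojson",
    "read_network_geojson",
    "write_occurrences_csv",
    "read_occurrences_csv",
    "snap_points_to_network",
]


def write_network_geojson(graph: DitchGraph, template: Grid, path: str | Path) -> Path:
    """Write the ditch network as GeoJSON LineStrings (one per unbranched ditch)."""
    path = Path(path)
    features = []
    for i, line in enumerate(graph.branch_polylines(template)):
        features.append(
            {
                "type": "Feature",
                "properties": {"ditch_id": i, "length_m": float(LineString(line).length)},
                "geometry": {"type": "LineString", "coordinates": [list(p) for p in line]},
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_network_geojson(path: str | Path) -> list[np.ndarray]:
    """Read LineString features; returns one (n, 2) vertex array per line."""
    doc = json.loads(Path(path).read_text())
    lines: list[np.ndarray] = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type == "LineString":
            lines.append(np.asarray(geom.coords, dtype=float))
        elif geom.geom_type == "MultiLineString":
            lines.extend(np.asarray(g.coords, dtype=float) for g in geom.geoms)
        else:
            raise ValueError(f"unsupported geometry type {geom.geom_type} (lines expected)")
    return lines


def write_occurrences_csv(occurrences: list[OccurrenceSet], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for occ in occurrences:
        for r, c in occ.presences:
            rows.append({"species": occ.species, "row": r, "col": c, "presence": 1})
        for r, c in occ.absences:
            rows.append({"species": occ.species, "row": r, "col": c, "presence": 0})
    pd.DataFrame(rows, columns=["species", "row", "col", "presence"]).to_csv(path, index=False)
    return path


def read_occurrences_csv(path: str | Path) -> list[OccurrenceSet]:
    df = pd.read_csv(path)
    out = []
    for species, grp in df.groupby("species", sort=True):
        pres = [(int(r), int(c)) for r, c in grp.loc[grp.presence == 1, ["row", "col"]].values]
        absn = [(int(r), int(c)) for r, c in grp.loc[grp.presence == 0, ["row", "col"]].values]
        out.append(OccurrenceSet(species=str(species), presences=tuple(pres), absences=tuple(absn)))
    return out


def snap_points_to_network(
    points: np.ndarray,
    network_mask: Grid,
    tolerance: float | None = None,
) -> tuple[list[Cell], list[int]]:
    """Snap projected (x, y) survey points to the nearest ditch cell centre.

    Points farther than ``tolerance`` (default one cell size) from every
    ditch cell centre are rejected. Returns (snapped cells, indices of
    rejected points).
    """
    tolerance = network_mask.cell_size if tolerance is None else tolerance
    rows, cols = np.nonzero(network_mask.data > 0)
    if len(rows) == 0:
        return [], list(range(len(points)))
    centers = np.array([network_mask.cell_center(r, c) for r, c in zip(rows, cols)])
    snapped: list[Cell] = []
    rejected: list[int] = []
    for i, (x, y) in enumerate(np.atleast_2d(points)):
        d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
        k = int(np.argmin(d2))
        if np.sqrt(d2[k]) <= tolerance:
            snapped.append((int(rows[k]), int(cols[k])))
        else:
            rejected.append(i)
    return snapped, rejected
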