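"""Geometry and topology of the octagonal sound-seeking arena.

The arena is a regular octagon partitioned into eight peripheral chambers
(one per wall, each holding a speaker and a nosepoke port at the wall
midpoint) and one central chamber from which all others can be reached.
Chambers are indexed 0..7 counterclockwise; chamber ``k`` is paired with
wall ``k`` and port ``k``, and wall ``k`` is centered on the direction
``k * 45`` degrees from the arena centroid.

The physical build is specified by the vertex-to-vertex ("longest")
diagonal of 40 cm with a nominal wall length of 15 cm; for a perfectly
regular octagon these two numbers are mutually inconsistent by ~0.8 cm,
so the polygon is scaled to the diagonal (which fixes the outer extent)
and the nominal side length is kept as metadata.  The center region is a
smaller concentric octagon whose side equals the chamber entry width, so
each chamber is the convex quadrilateral between its wall and its entry
line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon

N_PORTS = 8

#: Region label for the central chamber.
CENTER = -1
#: Region label for points not inside the arena.
OUTSIDE = -2


@dataclass(frozen=True)
class ArenaGeometry:
    """Polygons, port positions and calibration for one arena build.

    All coordinates are in cm with the origin at the arena centroid.
    ``px_per_cm``/``origin_px`` describe the affine map from video pixel
    coordinates to arena cm for real (or synthetic pixel-space) pose data.
    """

    side_length: float          # nominal wall length, cm
    long_diagonal: float        # vertex-to-vertex diagonal, cm (sets the scale)
    entry_width: float          # width of each chamber's entry line, cm
    entry_to_speaker: float     # derived: entry line to wall midpoint, cm
    port_positions: np.ndarray  # (8, 2) wall midpoints, cm
    chamber_polygons: tuple     # 8 convex shapely Polygons
    center_polygon: Polygon
    n_ports: int = N_PORTS
    px_per_cm: float = 1.0
    origin_px: tuple = (0.0, 0.0)

    @property
    def octagon(self) -> Polygon:
        """Outer boundary (union of all nine regions)."""
        return shapely.union_all(list(self.chamber_polygons) + [self.center_polygon])


def build_geometry(side_length: float = 15.0, entry_width: float = 5.0,
                   long_diagonal: float = 40.0, px_per_cm: float = 1.0,
                   origin_px: tuple = (0.0, 0.0)) -> ArenaGeometry:
    """Construct the 8-chamber + center partition of the octagonal arena.

    Parameters
    ----------
    side_length : nominal wall length in cm (metadata; the polygon scale is
        set by ``long_diagonal``).
    entry_width : width of the entry line into each chamber, cm.  This sets
        the size of the central octagon: each of its sides is one chamber's
        entry line.
    long_diagonal : vertex-to-vertex diagonal of the outer octagon, cm.
    """
    if side_length <= 0 or long_diagonal <= 0:
        raise ValueError("arena dimensions must be positive")
    r_outer = long_diagonal / 2.0
    geo_side = 2.0 * r_outer * np.sin(np.pi / 8.0)
    if not 0 < entry_width < geo_side:
        raise ValueError("entry_width must be in (0, side length)")

    # vertex k at angle k*45 - 22.5 deg, so wall k is centered on k*45 deg
    vert_angles = np.deg2rad(45.0 * np.arange(N_PORTS) - 22.5)
    outer = r_outer * np.c_[np.cos(vert_angles), np.sin(vert_angles)]
    scale = entry_width / geo_side          # center octagon similar to outer
    inner = scale * outer

    chambers = []
    for k in range(N_PORTS):
        j = (k + 1) % N_PORTS
        chambers.append(Polygon([outer[k], outer[j], inner[j], inner[k]]))
    center = Polygon(inner)

    apothem = r_outer * np.cos(np.pi / 8.0)
    wall_angles = np.deg2rad(45.0 * np.arange(N_PORTS))
    ports = apothem * np.c_[np.cos(wall_angles), np.sin(wall_angles)]

    return ArenaGeometry(
        side_length=float(side_length),
        long_diagonal=float(long_diagonal),
        entry_width=float(entry_width),
        entry_to_speaker=float(apothem * (1.0 - scale)),
        port_positions=ports,
        chamber_polygons=tuple(chambers),
        center_polygon=center,
        px_per_cm=float(px_per_cm),
        origin_px=tuple(origin_px),
    )


def classify_points(geom: ArenaGeometry, xy) -> np.ndarray:
    """Vectorized region labels for an (n, 2) array of cm coordinates.

    Returns an int array: chamber index 0..7, ``CENTER`` or ``OUTSIDE``.
    Boundary points belong to a chamber (lowest index wins on shared
    chamber/chamber edges), never to the center: entries fire as early as
    possible.  Non-finite coordinates label as ``OUTSIDE``.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    x, y = xy[:, 0], xy[:, 1]
    labels = np.full(len(xy), OUTSIDE, dtype=int)
    ok = np.isfinite(x) & np.isfinite(y)
    xs = np.where(ok, x, 1e9)
    ys = np.where(ok, y, 1e9)
    for k in range(N_PORTS - 1, -1, -1):
        hit = shapely.intersects_xy(geom.chamber_polygons[k], xs, ys)
        labels[hit] = k
    free = labels == OUTSIDE
    hit = shapely.intersects_xy(geom.center_polygon, xs, ys) & free & ok
    labels[hit] = CENTER
    return labels


def classify_point(geom: ArenaGeometry, p) -> int:
    """Region label (0..7, CENTER, OUTSIDE) for a single point."""
    return int(classify_points(geom, np.asarray(p, dtype=float)[None, :])[0])


def is_adjacent(a: int, b: int) -> bool:
    """True iff ports a and b are neighbors on the octagon ring."""
    if not (0 <= a < N_PORTS and 0 <= b < N_PORTS):
        raise ValueError(f"port indices must be in 0..{N_PORTS - 1}")
    return (a - b) % N_PORTS in (1, N_PORTS - 1)


def cm_from_px(geom: ArenaGeometry, xy_px) -> np.ndarray:
    """Map pixel coordinates to arena cm using the session calibration."""
    xy_px = np.asarray(xy_px, dtype=float)
    return (xy_px - np.asarray(geom.origin_px)) / geom.px_per_cm


# -- serialization ----------------------------------------------------------

def geometry_to_dict(geom: ArenaGeometry) -> dict:
    return {
        "side_length": geom.side_length,
        "long_diagonal": geom.long_diagonal,
        "entry_width": geom.entry_width,
        "entry_to_speaker": geom.entry_to_speaker,
        "n_ports": geom.n_ports,
        "px_per_cm": geom.px_per_cm,
        "origin_px": list(geom.origin_px),
        "port_positions": geom.port_positions.tolist(),
        "chamber_polygons": [
            np.asarray(p.exterior.coords)[:-1].tolist() for p in geom.chamber_polygons
        ],
        "center_polygon": np.asarray(geom.center_polygon.exterior.coords)[:-1].tolist(),
    }


def geometry_from_dict(d: dict) -> ArenaGeometry:
    return ArenaGeometry(
        side_length=d["side_length"],
        long_diagonal=d["long_diagonal"],
        entry_width=d["entry_width"],
        entry_to_speaker=d["entry_to_speaker"],
        port_positions=np.asarray(d["port_positions"], dtype=float),
        chamber_polygons=tuple(Polygon(c) for c in d["chamber_polygons"]),
        center_polygon=Polygon(d["center_polygon"]),
        n_ports=d.get("n_ports", N_PORTS),
        px_per_cm=d.get("px_per_cm", 1.0),
        origin_px=tuple(d.get("origin_px", (0.0, 0.0))),
    )


def save_geometry(geom: ArenaGeometry, path) -> None:
    """Write geometry (explicit vertex lists) to .json or .yaml/.yml."""
    path = Path(path)
    d = geometry_to_dict(geom)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d))
    else:
        path.write_text(json.dumps(d, indent=1))


def load_geometry(path) -> ArenaGeometry:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return geometry_from_dict(d)
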