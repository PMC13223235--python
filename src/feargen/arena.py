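"""Geometry of the 3x3 open-field arena partition.

The open field is a square box partitioned into 9 equal square zones
(odor-corner zones, intermediate edge zones, and the center).  Odor
strainers hang in the four corners; the threat-predictive odor (MV) and the
perceptually similar odor (BA) always occupy adjacent corners, forming the
"danger" side, while the dissimilar odor (HEX) and the unscented corner form
the "safe" side.

Zones are indexed 0..8 as ``row * 3 + col`` with columns counted from the
left (x) and rows from the bottom (y).  Zone boundaries are half-open,
left/bottom inclusive, so every point of the arena belongs to exactly one
zone (the right/top arena edges are folded into the last column/row).
"""

from __future__ import annotations

import numpy as np

from ._exceptions import ValidationError

#: Default arena side lengths (18 x 18 inch box, stored unit-agnostically).
DEFAULT_ARENA: tuple[float, float] = (18.0, 18.0)

#: Default odor-corner assignment as fractional corner coordinates.
#: MV and BA share the bottom edge (adjacent corners); HEX and the
#: unscented corner ("NONE") share the top edge.
DEFAULT_CORNER_ODORS: dict[str, tuple[int, int]] = {
    "MV": (0, 0),
    "BA": (1, 0),
    "HEX": (1, 1),
    "NONE": (0, 1),
}

ODORS = ("MV", "BA", "HEX")

#: 4-adjacency of the 3x3 zone grid, used by the trajectory generator.
ZONE_NEIGHBORS: dict[int, tuple[int, ...]] = {}
for _r in range(3):
    for _c in range(3):
        _z = _r * 3 + _c
        _nb = []
        if _c > 0:
            _nb.append(_z - 1)
        if _c < 2:
            _nb.append(_z + 1)
        if _r > 0:
            _nb.append(_z - 3)
        if _r < 2:
            _nb.append(_z + 3)
        ZONE_NEIGHBORS[_z] = tuple(_nb)


def zone_index(x, y, arena: tuple[float, float] = DEFAULT_ARENA) -> np.ndarray:
    """Vectorized zone lookup for arena positions.

    Points outside the arena raise :class:`ValidationError` listing the
    offending sample indices.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w, h = arena
    bad = np.nonzero(np.atleast_1d((x < 0) | (x > w) | (y < 0) | (y > h)))[0]
    if bad.size:
        raise ValidationError(
            f"positions outside arena bounds at sample indices {bad.tolist()[:20]}"
        )
    col = np.minimum((x / (w / 3.0)).astype(int), 2)
    row = np.minimum((y / (h / 3.0)).astype(int), 2)
    return row * 3 + col


def zone_bounds(zone: int, arena: tuple[float, float] = DEFAULT_ARENA):
    """(xmin, xmax, ymin, ymax) of a zone rectangle."""
    if not 0 <= zone <= 8:
        raise ValidationError(f"zone index {zone} outside 0..8")
    w, h = arena
    col, row = zone % 3, zone // 3
    return (col * w / 3.0, (col + 1) * w / 3.0, row * h / 3.0, (row + 1) * h / 3.0)


def zone_center(zone: int, arena: tuple[float, float] = DEFAULT_ARENA):
    x0, x1, y0, y1 = zone_bounds(zone, arena)
    return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def corner_position(corner_frac: tuple[int, int],
                    arena: tuple[float, float] = DEFAULT_ARENA):
    """Arena coordinates of a fractional corner spec like ``(0, 1)``."""
    return (corner_frac[0] * arena[0], corner_frac[1] * arena[1])


def corner_zone(corner_frac: tuple[int, int]) -> int:
    """Zone index of the corner zone touching a given arena corner."""
    col = 0 if corner_frac[0] == 0 else 2
    row = 0 if corner_frac[1] == 0 else 2
    return row * 3 + col


def odor_corner_zones(
    corner_odors: dict[str, tuple[int, int]] | None = None,
) -> dict[str, int]:
    """Map odor name -> corner-zone index (includes the unscented corner)."""
    corner_odors = corner_odors or DEFAULT_CORNER_ODORS
    return {name: corner_zone(frac) for name, frac in corner_odors.items()}


def zone_labels(corner_odors: dict[str, tuple[int, int]] | None = None) -> list[str]:
    """Human-readable zone names ('MV', 'MV-BA', 'center', ...)."""
    zones = odor_corner_zones(corner_odors)
    by_zone = {z: name for name, z in zones.items()}
    labels = []
    for z in range(9):
        if z in by_zone:
            labels.append(by_zone[z])
        elif z == 4:
            labels.append("center")
        else:
            # intermediate zone between two corner zones
            col, row = z % 3, z // 3
            if row in (0, 2):  # horizontal edge
                a, b = by_zone[row * 3], by_zone[row * 3 + 2]
            else:  # vertical edge
                a, b = by_zone[col], by_zone[6 + col]
            labels.append(f"{a}-{b}")
    return labels
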