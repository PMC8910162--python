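"""Microscaffold geometry.

The scaffolds are hexagonal lattices microfabricated on a glass substrate,
either resting directly on the glass ("closed") or raised on vertical
micropillars ("open") so that cells can access the bottom plane.  Hexagons
are regular (one horizontal dimension ``D``) or elongated (bounding box
``l`` x ``L`` with the long side along the reference axis).  Structures are
named ``D8-open``, ``l7L14-closed`` and so on; :func:`parse_structure_name`
turns such a name into a :class:`ScaffoldSpec`.

Conventions
-----------
All lengths are in micrometres.  The total structure height defaults to
7 um, of which the pillars occupy the bottom ~3 um.  ``z = 0`` is the glass
substrate and increases upward.  The reference axis is a unit 2D vector in
the image plane: the direction of hexagon elongation for elongated
structures, and the direction perpendicular to one hexagon side for regular
ones.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

__all__ = [
    "ScaffoldSpec",
    "parse_structure_name",
    "pillar_lattice",
    "fold_angle_deg",
]

_NAME_RE_REGULAR = re.compile(r"^[dD](\d+(?:\.\d+)?)-(open|closed)$")
_NAME_RE_ELONGATED = re.compile(r"^[lL](\d+(?:\.\d+)?)[lL](\d+(?:\.\d+)?)-(open|closed)$")


def fold_angle_deg(theta: float) -> float:
    """Fold an in-plane angle (degrees) to the range [0, 90].

    Orientations are axial (a nucleus or filopodium axis has no sign), so
    angles are first reduced modulo 180 and then reflected about 90.
    Folding is idempotent.
    """
    a = float(theta) % 180.0
    return 180.0 - a if a > 90.0 else a


@dataclass
class ScaffoldSpec:
    """Geometry of one microstructure.

    Parameters
    ----------
    shape:
        ``"regular"`` or ``"elongated"``.
    D:
        Corner-to-corner horizontal dimension of a regular hexagon (um).
    l, L:
        Bounding-box width (across the elongation axis) and length (along
        it) of an elongated hexagon (um); requires ``0 < l <= L``.
    openness:
        ``"open"`` (lattice on pillars) or ``"closed"``.
    total_height:
        Height of the structure above the substrate (um), default 7.
    pillar_height:
        Height of the supporting pillars in open structures (um), default 3.
    reference_axis:
        Unit 2D vector (x, y) against which orientations are measured.
    """

    shape: str
    openness: str
    D: float | None = None
    l: float | None = None
    L: float | None = None
    total_height: float = 7.0
    pillar_height: float = 3.0
    reference_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        if self.shape not in ("regular", "elongated"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.openness not in ("open", "closed"):
            raise ValueError(f"unknown openness {self.openness!r}")
        if self.shape == "regular":
            if self.D is None or self.D <= 0:
                raise ValueError("regular hexagons need D > 0")
        else:
            if self.l is None or self.L is None or not (0 < self.l <= self.L):
                raise ValueError("elongated hexagons need 0 < l <= L")
        if not (0 < self.pillar_height < self.total_height):
            raise ValueError("need 0 < pillar_height < total_height")
        axis = np.asarray(self.reference_axis, dtype=float)
        n = float(np.hypot(*axis))
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("reference_axis must have unit norm")
        self.reference_axis = axis

    @property
    def name(self) -> str:
        """Canonical structure name, e.g. ``D8-open`` or ``l7L14-closed``."""
        if self.shape == "regular":
            return f"D{self.D:g}-{self.openness}"
        return f"l{self.l:g}L{self.L:g}-{self.openness}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScaffoldSpec):
            return NotImplemented
        return (
            self.name == other.name
            and np.isclose(self.total_height, other.total_height)
            and np.isclose(self.pillar_height, other.pillar_height)
            and np.allclose(self.reference_axis, other.reference_axis)
        )


def parse_structure_name(name: str) -> ScaffoldSpec:
    """Parse a structure name like ``"D8-open"`` or ``"l7L14-closed"``.

    Defaults of 7 um total height and 3 um pillar height are applied; the
    reference axis is (1, 0).

    Raises
    ------
    ValueError
        If the name is malformed or the dimensions are invalid.
    """
    name = name.strip()
    m = _NAME_RE_ELONGATED.match(name)
    if m:
        return ScaffoldSpec(
            shape="elongated", l=float(m.group(1)), L=float(m.group(2)), openness=m.group(3)
        )
    m = _NAME_RE_REGULAR.match(name)
    if m:
        return ScaffoldSpec(shape="regular", D=float(m.group(1)), openness=m.group(2))
    raise ValueError(
        f"cannot parse structure name {name!r}: expected D<number>-<open|closed>"
        " or l<number>L<number>-<open|closed>"
    )


def _unit_hexagon(spec: ScaffoldSpec) -> np.ndarray:
    """Vertices (6, 2) of one hexagon cell centred at the origin, in um.

    A flat-side-top regular hexagon of circumradius R = D/2 has its
    corner-to-corner dimension D along x.  Elongated hexagons are the same
    template scaled anisotropically so the bounding box is L (along the
    axis, x) by l (across it, y).
    """
    ang = np.deg2rad(60.0 * np.arange(6))
    verts = np.stack([np.cos(ang), np.sin(ang)], axis=1)  # circumradius 1
    if spec.shape == "regular":
        R = spec.D / 2.0
        return verts * R
    # unit template bbox: 2 along x, sqrt(3) along y
    sx = spec.L / 2.0
    sy = spec.l / np.sqrt(3.0)
    return verts * np.array([sx, sy])


def pillar_lattice(
    spec: ScaffoldSpec, extent: Tuple[float, float]
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Tile ``extent`` (um x um) with hexagon cells and return pillar sites.

    Pillars sit at the hexagon vertices.  Only cells whose vertices fall
    entirely inside the extent are returned.

    Returns
    -------
    centers : (n, 2) array
        Unique pillar (vertex) positions in um.
    cells : list of (6, 2) arrays
        Vertex polygons of the complete hexagon cells.
    """
    ex, ey = float(extent[0]), float(extent[1])
    if ex <= 0 or ey <= 0:
        raise ValueError("extent must be positive")
    hexagon = _unit_hexagon(spec)
    # flat-side-top tiling: centre columns at 1.5 R_x, rows at sqrt(3) R_y
    Rx = hexagon[:, 0].max()
    Ry = (2.0 / np.sqrt(3.0)) * hexagon[:, 1].max()
    dx = 1.5 * Rx
    dy = np.sqrt(3.0) * Ry
    ni = int(np.ceil(ex / dx)) + 2
    nj = int(np.ceil(ey / dy)) + 2
    cells: List[np.ndarray] = []
    for i in range(-1, ni):
        for j in range(-1, nj):
            cx = i * dx
            cy = j * dy + (dy / 2.0 if i % 2 else 0.0)
            verts = hexagon + np.array([cx, cy])
            if (
                verts[:, 0].min() >= 0
                and verts[:, 1].min() >= 0
                and verts[:, 0].max() <= ex
                and verts[:, 1].max() <= ey
            ):
                cells.append(verts)
    if not cells:
        warnings.warn(
            f"extent {extent} holds no complete {spec.name} hexagon cell", stacklevel=2
        )
        return np.empty((0, 2)), []
    allv = np.concatenate(cells, axis=0)
    # dedupe shared vertices at sub-nm resolution
    key = np.round(allv / 1e-4).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    centers = allv[np.sort(idx)]
    # rotate the whole lattice if the reference axis is not (1, 0)
    ax = spec.reference_axis
    if not np.allclose(ax, [1.0, 0.0]):
        rot = np.array([[ax[0], -ax[1]], [ax[1], ax[0]]])
        centers = centers @ rot.T
        cells = [c @ rot.T for c in cells]
    return centers, cells
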