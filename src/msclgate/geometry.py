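"""Coarse-grained pentameric MscL geometry.

The channel is represented by 5-fold symmetric rod centerlines: per subunit
an N-terminal helix, the pore-lining TM1, TM2 and a C-terminal helix, each an
ordered polyline of points in Å.  The channel axis is +z by convention; the
membrane normal coincides with it.  TM1 carries a residue -> arclength map
(residues 15..48, linearly spaced), which places the pore-lock connector
anchors and defines the constriction window used for pore-diameter
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .helices import HELIX_LENGTHS, HELIX_NAMES

TM1_FIRST_RESIDUE = 15
TM1_LAST_RESIDUE = 48

#: Default constriction window (residues on TM1) for pore-diameter scans.
DEFAULT_PORE_WINDOW = (19, 26)

N_SUBUNITS = 5


def tm1_residue_fraction(residue: int | np.ndarray) -> np.ndarray | float:
    """Arclength fraction of a TM1 residue: (i - 15) / 33."""
    return (np.asarray(residue, dtype=float) - TM1_FIRST_RESIDUE) / (
        TM1_LAST_RESIDUE - TM1_FIRST_RESIDUE
    )


@dataclass
class ChannelGeometry:
    """Rod centerlines of the pentamer.

    ``polylines[(s, helix)]`` is an (k, 3) array of points along the rod, in
    order from the cytoplasmic toward the periplasmic end for TM1 (from the
    TM1 junction outward for N, from the periplasmic top downward for TM2 and
    C).  The channel axis is +z through the origin.
    """

    polylines: dict[tuple[int, str], np.ndarray]
    genotype: str = "WT"
    state: str = "closed"
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        for key, pts in self.polylines.items():
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
                raise ValueError(f"polyline {key} must be an (k>=2, 3) array")
            self.polylines[key] = pts

    @property
    def tm1_residue_span(self) -> tuple[int, int]:
        return TM1_FIRST_RESIDUE, TM1_LAST_RESIDUE

    def polyline_length(self, subunit: int, helix: str) -> float:
        pts = self.polylines[(subunit, helix)]
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def point_at_arclength(self, subunit: int, helix: str, fraction: float) -> np.ndarray:
        """Point at a given arclength fraction along a rod centerline."""
        pts = self.polylines[(subunit, helix)]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        target = np.clip(fraction, 0.0, 1.0) * cum[-1]
        i = int(np.searchsorted(cum, target, side="right") - 1)
        i = min(i, len(seg) - 1)
        t = (target - cum[i]) / seg[i]
        return pts[i] + t * (pts[i + 1] - pts[i])

    def tm1_residue_point(self, subunit: int, residue: int) -> np.ndarray:
        return self.point_at_arclength(subunit, "TM1", float(tm1_residue_fraction(residue)))

    def pore_diameter(self, window: tuple[int, int] = DEFAULT_PORE_WINDOW) -> float:
        """Constriction diameter: 2x the minimum radial distance to the axis
        over TM1 residues in the window, across all subunits."""
        lo, hi = window
        radii = []
        for s in range(N_SUBUNITS):
            for res in range(lo, hi + 1):
                p = self.tm1_residue_point(s, res)
                radii.append(_radial_distance(p, self.axis))
        return 2.0 * float(min(radii))


def _radial_distance(point: np.ndarray, axis: np.ndarray) -> float:
    """Distance from a point to the axis line through the origin."""
    p = np.asarray(point, dtype=float)
    along = p @ axis
    return float(np.linalg.norm(p - along * axis))


def rotation_about_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# ---------------------------------------------------------------------------
# Idealized pentamer construction
# ---------------------------------------------------------------------------

#: Radius (Å) of the constriction residue R19 in each reference state.
CONSTRICTION_RADIUS = {("WT", "closed"): 4.0, ("G22N", "closed"): 5.5, "open": 14.0}

#: Radial span (Å) of the TM1 rod from the cytoplasmic to periplasmic end;
#: sets the closed-state TM1 tilt (sin(theta) = 12/47.33, ~15 deg).
TM1_RADIAL_SPAN = 12.0


def _subunit_frame(subunit: int) -> tuple[np.ndarray, np.ndarray]:
    """(radial unit vector, z unit vector) of a subunit's meridional plane."""
    phi = 2.0 * np.pi * subunit / N_SUBUNITS
    return np.array([np.cos(phi), np.sin(phi), 0.0]), np.array([0.0, 0.0, 1.0])


def ideal_geometry(genotype: str = "WT", state: str = "closed") -> ChannelGeometry:
    """Idealized 5-fold symmetric pentamer with the declared helix lengths.

    The closed WT constriction measures 8 Å (pore diameter), closed G22N
    11 Å and the open-target state 28 Å.  TM1 rods are straight and tilted;
    the N-terminal helix runs radially outward at the membrane inner surface
    from the TM1 cytoplasmic end; TM2 and the C-terminal helix complete each
    subunit but are mechanically peripheral.  The open-target state is the
    closed state with TM1 (and its attached N-terminus) translated radially
    outward — an idealized end point of the iris-like expansion.
    """
    if genotype not in ("WT", "G22N"):
        raise ValueError(f"unknown genotype {genotype!r}")
    if state not in ("closed", "open-target"):
        raise ValueError(f"unknown state {state!r}")
    r19_closed = CONSTRICTION_RADIUS[(genotype, "closed")]
    r19 = CONSTRICTION_RADIUS["open"] if state == "open-target" else r19_closed

    L1 = HELIX_LENGTHS["TM1"]
    f19 = float(tm1_residue_fraction(19))
    dr = TM1_RADIAL_SPAN
    dz = np.sqrt(L1 * L1 - dr * dr)
    # TM1 bottom (res 15) and top (res 48) radii from the res-19 radius
    r_bot = r19 - f19 * dr
    r_top = r_bot + dr

    LN = HELIX_LENGTHS["N"]
    L2 = HELIX_LENGTHS["TM2"]
    LC = HELIX_LENGTHS["C"]
    # TM2: periplasmic top outside TM1's top, running down and slightly out
    tm2_top_r, tm2_dr = 17.5, 5.0
    tm2_dz = np.sqrt(L2 * L2 - tm2_dr * tm2_dr)
    # C-terminal helix: from the TM2 cytoplasmic end down toward the axis
    c_end_r = 4.0

    polylines: dict[tuple[int, str], np.ndarray] = {}
    for s in range(N_SUBUNITS):
        e_r, e_z = _subunit_frame(s)
        tm1_bot = r_bot * e_r
        tm1_top = r_top * e_r + dz * e_z
        polylines[(s, "TM1")] = np.vstack([tm1_bot, tm1_top])
        # N-terminus: radially outward in the membrane plane from TM1 bottom
        polylines[(s, "N")] = np.vstack([tm1_bot, tm1_bot + LN * e_r])
        tm2_top = tm2_top_r * e_r + dz * e_z
        tm2_bot = (tm2_top_r + tm2_dr) * e_r + (dz - tm2_dz) * e_z
        polylines[(s, "TM2")] = np.vstack([tm2_top, tm2_bot])
        c_drop = np.sqrt(LC * LC - (tm2_top_r + tm2_dr - c_end_r) ** 2)
        c_end = c_end_r * e_r + (dz - tm2_dz - c_drop) * e_z
        polylines[(s, "C")] = np.vstack([tm2_bot, c_end])

    return ChannelGeometry(polylines=polylines, genotype=genotype, state=state)
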