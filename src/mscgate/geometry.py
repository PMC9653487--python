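"""Per-state channel geometry and closed-to-open deltas.

Four numbers summarize what membrane tension "sees" of a curved-TMD
mechanosensitive channel in each state:

* the midplane bending angle theta -- how strongly the transmembrane domain
  deflects the membrane midplane out of a plane (degrees);
* the in-plane radius R and cross-sectional area A of the transmembrane
  footprint (nm, nm^2);
* the axial height of the TMD (Angstrom);
* optionally the diameter of the periplasmic ring (Angstrom).

The closed-to-open differences of these quantities (``StateDelta``) are the
structural inputs of the gating energetics model: a reduced bending angle
and an expanded in-plane area together make the flattened, open state
favorable under tension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .errors import ConventionError, InsufficientDataError, SelectionError
from .structio import ChannelStructure, MembraneSlab

A2_PER_NM2 = 100.0  # Angstrom^2 per nm^2


@dataclass(frozen=True)
class GeometryProfile:
    """Geometric measurements of one channel state.

    ``slab`` records the (z_min, z_max) convention the numbers were measured
    under, so that two profiles can only be differenced consistently.
    """

    theta: float  # midplane bending angle, degrees
    R_inplane: float  # effective in-plane radius, nm
    area: float  # in-plane cross-sectional area, nm^2
    tmd_height: float  # Angstrom
    ring_diameter: float | None = None  # Angstrom
    slab: tuple[float, float] | None = None
    slab_convention: str = "explicit"

    def __post_init__(self):
        if not (0.0 <= self.theta < 90.0):
            raise ValueError(f"theta out of range: {self.theta}")
        if self.R_inplane <= 0 or self.area <= 0 or self.tmd_height <= 0:
            raise ValueError("R_inplane, area and tmd_height must be positive")


@dataclass(frozen=True)
class StateDelta:
    """Closed-to-open geometry differences in model units.

    Angles in radians, lengths in nm, areas in nm^2, height in Angstrom.
    ``annular`` is True when the measured area change is consistent with the
    thin-annulus approximation delta_A ~ 2*pi*R_c*delta_R (15% tolerance).
    """

    theta_c: float
    theta_o: float
    R_c: float
    R_o: float
    delta_R: float
    delta_A: float
    delta_height: float
    annular: bool = True


# ---------------------------------------------------------------------------
# TM-segment decomposition (shared by the bending-angle fit)


def tm_segments(
    s: ChannelStructure,
    slab: MembraneSlab,
    min_atoms: int = 4,
    residue_gap: int = 1,
) -> list[np.ndarray]:
    """Split each chain's in-slab atoms into contiguous-residue segments.

    A segment is a run of consecutive author residue numbers (gaps larger
    than ``residue_gap`` split it) with at least ``min_atoms`` atoms in the
    slab; each run approximates one membrane crossing of one helix.  Returns
    the per-segment atom index arrays.
    """
    z = s.positions[:, 2]
    in_slab = slab.contains(z)
    segments: list[np.ndarray] = []
    for chain in s.subunit_chains:
        idx = np.flatnonzero(in_slab & s.chain_mask(chain))
        if len(idx) == 0:
            continue
        order = np.argsort(s.residue_numbers[idx], kind="stable")
        idx = idx[order]
        resnums = s.residue_numbers[idx]
        breaks = np.flatnonzero(np.diff(resnums) > residue_gap) + 1
        for part in np.split(idx, breaks):
            if len(part) >= min_atoms:
                segments.append(part)
    return segments


def midplane_bending_angle(
    s: ChannelStructure, slab: MembraneSlab, min_points: int = 4
) -> float:
    """Midplane bending angle in degrees.

    Each TM segment (helix crossing) is reduced to the centroid of its
    in-slab atoms; z is fit as a linear function of the radial distance r
    pooled over all segments, and the angle is arctan(|dz/dr|).  For a
    cone-shaped midplane this recovers the cone half-deflection exactly, and
    by construction the measurement is invariant under rotation about z and
    translation along z.
    """
    if not s.frame_aligned:
        raise InsufficientDataError("structure must be frame-aligned")
    segments = tm_segments(s, slab)
    points = np.array([s.positions[seg].mean(axis=0) for seg in segments]) if segments else np.empty((0, 3))
    if len(points) < min_points:
        raise InsufficientDataError(
            f"only {len(points)} TM segment points in slab (need >= {min_points})"
        )
    r = np.hypot(points[:, 0], points[:, 1])
    z = points[:, 2]
    if np.ptp(r) < 1e-9:
        raise InsufficientDataError("degenerate radial spread among TM segments")
    slope = np.polyfit(r, z, 1)[0]
    return float(np.degrees(np.arctan(abs(slope))))


def inplane_radius_area(
    s: ChannelStructure, slab: MembraneSlab, band: float | None = None
) -> tuple[float, float]:
    """Effective in-plane radius (nm) and convex-hull area (nm^2).

    Atoms within ``band`` Angstrom of the slab midplane (default: the whole
    slab, i.e. the full transmembrane footprint) are projected onto the xy
    plane; A is the area of their 2D convex hull and R = sqrt(A/pi).
    """
    z = s.positions[:, 2]
    if band is None:
        mask = slab.contains(z)
    else:
        mask = np.abs(z - slab.z_mid) <= band / 2.0
    pts = s.positions[mask][:, :2]
    if len(pts) < 3:
        raise InsufficientDataError("fewer than 3 atoms in the midplane band")
    area_nm2 = ConvexHull(pts).volume / A2_PER_NM2  # 2D hull: .volume is area
    return float(np.sqrt(area_nm2 / np.pi)), float(area_nm2)


def tmd_height(
    s: ChannelStructure,
    selection: str | None = None,
    percentile_trim: float = 2.5,
) -> float:
    """Robust axial extent of the (selected) structure in Angstrom.

    The raw z-span is sensitive to single stray atoms, so the span between
    the ``percentile_trim`` and ``100 - percentile_trim`` percentiles is
    measured and rescaled by ``100 / (100 - 2*trim)``, which is exact for a
    uniform axial atom density and still robust to a small fraction of
    outliers.  Translation-invariant by construction.
    """
    mask = s.select(selection) if selection else np.ones(len(s), dtype=bool)
    z = s.positions[mask, 2]
    if len(z) == 0:
        raise SelectionError("height selection matched no atoms")
    lo, hi = np.percentile(z, [percentile_trim, 100.0 - percentile_trim])
    span = float(hi - lo) * 100.0 / (100.0 - 2.0 * percentile_trim)
    return span


def ring_diameter(s: ChannelStructure, selection: str) -> float:
    """Outer diameter (Angstrom) of a residue selection: twice the maximum
    radial distance of its atoms from the z-axis."""
    mask = s.select(selection)
    if not mask.any():
        raise SelectionError(f"ring selection {selection!r} matched no atoms")
    r = np.hypot(s.positions[mask, 0], s.positions[mask, 1])
    return float(2.0 * r.max())


def measure_geometry(
    s: ChannelStructure,
    slab: MembraneSlab,
    ring_selection: str | None = None,
    height_selection: str | None = None,
    slab_convention: str = "explicit",
) -> GeometryProfile:
    """Convenience: all per-state measurements in one profile.

    ``slab_convention`` names how the slab was chosen (e.g. ``"explicit"``,
    ``"tm-extent"``, ``"hydrophobic-belt"``); closed/open profiles can only
    be differenced when measured under the same convention, though the
    numeric bounds may differ between states (the membrane boundaries of a
    curved and a flattened conformation genuinely do).
    """
    theta = midplane_bending_angle(s, slab)
    R, A = inplane_radius_area(s, slab)
    height = tmd_height(s, height_selection)
    ring = ring_diameter(s, ring_selection) if ring_selection else None
    return GeometryProfile(
        theta=theta,
        R_inplane=R,
        area=A,
        tmd_height=height,
        ring_diameter=ring,
        slab=(slab.z_min, slab.z_max),
        slab_convention=slab_convention,
    )


def compare_states(
    closed: GeometryProfile, open: GeometryProfile, annular_tolerance: float = 0.15
) -> StateDelta:
    """Closed-to-open differences in model units (radians, nm, nm^2).

    Raises :class:`ConventionError` if the two profiles were measured under
    different slab conventions.  ``delta_A`` is by definition
    A_open - A_closed; the ``annular`` flag records whether it also matches
    the thin-annulus form 2*pi*R_c*delta_R within ``annular_tolerance``.
    """
    if closed.slab_convention != open.slab_convention:
        raise ConventionError(
            "profiles measured under different slab conventions: "
            f"{closed.slab_convention!r} vs {open.slab_convention!r}"
        )
    theta_c = float(np.radians(closed.theta))
    theta_o = float(np.radians(open.theta))
    R_c, R_o = closed.R_inplane, open.R_inplane
    delta_R = R_o - R_c
    delta_A = open.area - closed.area
    annulus = 2.0 * np.pi * R_c * delta_R
    annular = (
        abs(delta_A) > 0
        and abs(delta_A - annulus) / abs(delta_A) <= annular_tolerance
    )
    return StateDelta(
        theta_c=theta_c,
        theta_o=theta_o,
        R_c=R_c,
        R_o=R_o,
        delta_R=float(delta_R),
        delta_A=float(delta_A),
        delta_height=float(closed.tmd_height - open.tmd_height),
        annular=bool(annular),
    )
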