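"""Sphere-probe pore-radius profiling and gate location.

At each axial position z the pore radius is the radius of the largest
sphere, centered within a bounded distance ("wander") of the pore axis,
that touches no atom: probe_radius(z) = max over centers c of
[min over atoms (|c - atom| - vdw_radius)], clamped at zero.  The
maximization uses a deterministic grid search over probe centers (classic
HOLE-style profilers use simulated annealing; a grid is reproducible and
directly checkable against a brute-force oracle).

Constrictions ("gates") are local minima of the smoothed profile with
sufficient radial prominence; each is attributed to the residues whose
atoms lie within a contact cutoff of the probe sphere.  Diameters are
reported as twice the probe radius with no solvent offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InsufficientDataError, RangeError
from .structio import ChannelStructure


@dataclass(frozen=True)
class PoreProfile:
    """Maximal probe radius along the pore axis.

    z (Angstrom, strictly increasing), radius (Angstrom, >= 0), offsets
    ((x, y) probe-center wander per sample, Angstrom), step (Angstrom).
    """

    z: np.ndarray
    radius: np.ndarray
    offsets: np.ndarray
    step: float

    def __post_init__(self):
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z samples must be strictly increasing")
        if np.any(self.radius < -1e-12):
            raise ValueError("negative probe radius")

    @property
    def min_diameter(self) -> float:
        return float(2.0 * self.radius.min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_A": self.z,
                "radius_A": self.radius,
                "x_offset_A": self.offsets[:, 0],
                "y_offset_A": self.offsets[:, 1],
            }
        )


@dataclass(frozen=True)
class Constriction:
    """A located gate: axial position, diameter (= 2x local minimum probe
    radius) and the residues lining the probe sphere."""

    z: float
    diameter: float
    lining_residues: tuple[tuple[str, str, int], ...]


def _candidate_centers(wander: float, resolution: float) -> np.ndarray:
    """Grid of probe-center (x, y) offsets within the wander disc; always
    contains the on-axis point."""
    if wander <= 0:
        return np.zeros((1, 2))
    ticks = np.arange(-wander, wander + 0.5 * resolution, resolution)
    xx, yy = np.meshgrid(ticks, ticks)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= wander + 1e-9]
    if not np.any(np.all(np.abs(pts) < 1e-12, axis=1)):
        pts = np.vstack([[0.0, 0.0], pts])
    return pts


def pore_profile(
    s: ChannelStructure,
    z_range: tuple[float, float] | None = None,
    step: float = 0.5,
    wander: float = 5.0,
    center_resolution: float | None = None,
) -> PoreProfile:
    """Sphere-probe radius profile along the z axis.

    ``z_range`` defaults to the structure's atom z-range trimmed by 2 A at
    both ends.  Probe centers are searched on a grid of resolution
    ``center_resolution`` (default step/2) within ``wander`` of the axis.
    Deterministic.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    z_atoms = s.positions[:, 2]
    z_lo_struct, z_hi_struct = float(z_atoms.min()), float(z_atoms.max())
    if z_range is None:
        z_range = (z_lo_struct + 2.0, z_hi_struct - 2.0)
    z_lo, z_hi = map(float, z_range)
    if z_lo >= z_hi or z_hi < z_lo_struct or z_lo > z_hi_struct:
        raise RangeError(
            f"z range ({z_lo}, {z_hi}) outside structure ({z_lo_struct:.1f}, "
            f"{z_hi_struct:.1f})"
        )
    if center_resolution is None:
        center_resolution = step / 2.0
    centers = _candidate_centers(wander, center_resolution)  # (M, 2)
    z_samples = np.arange(z_lo, z_hi + 0.5 * step, step)

    xy = s.positions[:, :2]  # (N, 2)
    radii = s.vdw_radii
    # Planar distances from every candidate center to every atom are
    # z-independent; precompute their squares once.
    d_planar_sq = (
        (centers[:, 0, None] - xy[None, :, 0]) ** 2
        + (centers[:, 1, None] - xy[None, :, 1]) ** 2
    )  # (M, N)

    out_r = np.empty(len(z_samples))
    out_off = np.empty((len(z_samples), 2))
    for i, z in enumerate(z_samples):
        dz_sq = (z_atoms - z) ** 2  # (N,)
        gaps = np.sqrt(d_planar_sq + dz_sq[None, :]) - radii[None, :]
        per_center = gaps.min(axis=1)  # (M,)
        j = int(np.argmax(per_center))
        out_r[i] = max(per_center[j], 0.0)
        out_off[i] = centers[j]
    return PoreProfile(z=z_samples, radius=out_r, offsets=out_off, step=float(step))


def _smooth(radius: np.ndarray, window_samples: int) -> np.ndarray:
    if window_samples <= 1:
        return radius
    kernel = np.ones(window_samples) / window_samples
    padded = np.pad(radius, window_samples // 2, mode="edge")
    sm = np.convolve(padded, kernel, mode="valid")
    return sm[: len(radius)]


def find_gates(
    profile: PoreProfile,
    s: ChannelStructure,
    smoothing_window: float = 1.5,
    prominence: float = 0.5,
    contact: float = 1.0,
) -> list[Constriction]:
    """Locate constrictions and attribute them to pore-lining residues.

    Local minima of the moving-average-smoothed profile with radial
    prominence >= ``prominence`` (Angstrom) are reported, ordered by z;
    boundary minima (e.g. the narrow end of a funnel) count.  A residue
    lines a gate if any of its atoms comes within ``contact`` Angstrom of
    touching the probe sphere.
    """
    if len(profile.z) == 0:
        raise InsufficientDataError("empty pore profile")
    window_samples = max(1, int(round(smoothing_window / profile.step)))
    if window_samples % 2 == 0:
        window_samples += 1
    sm = _smooth(profile.radius, window_samples)
    # Pad with a high shoulder so minima at the profile ends are found too.
    pad = sm.max() + 10.0
    padded = np.concatenate([[pad], sm, [pad]])
    minima, _ = find_peaks(-padded, prominence=prominence)
    minima = minima - 1  # undo padding shift

    gates: list[Constriction] = []
    for idx in minima:
        z = float(profile.z[idx])
        r = float(profile.radius[idx])
        cx, cy = profile.offsets[idx]
        center = np.array([cx, cy, z])
        gap = np.linalg.norm(s.positions - center, axis=1) - s.vdw_radii - r
        lining_mask = gap <= contact
        lining = sorted(
            {
                (
                    str(s.chain_ids[k]),
                    str(s.residue_names[k]),
                    int(s.residue_numbers[k]),
                )
                for k in np.flatnonzero(lining_mask)
            }
        )
        gates.append(Constriction(z=z, diameter=2.0 * r, lining_residues=tuple(lining)))
    gates.sort(key=lambda g: g.z)
    return gates


def constrictions_to_intervals(
    gates: list[Constriction], half_width: float = 1.0
) -> pd.DataFrame:
    """BED-like interval table of gates: one row per constriction with a
    +/- half_width z-window, the diameter and the lining residues."""
    return pd.DataFrame(
        {
            "name": [f"gate_{i+1}" for i in range(len(gates))],
            "z_start_A": [g.z - half_width for g in gates],
            "z_end_A": [g.z + half_width for g in gates],
            "diameter_A": [g.diameter for g in gates],
            "lining_residues": [
                ";".join(f"{c}:{rn}{num}" for c, rn, num in g.lining_residues)
                for g in gates
            ],
        }
    )


def plot_profile(profile: PoreProfile, gates: list[Constriction] | None = None, ax=None):
    """Quick matplotlib view of the radius profile (convenience only)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.z, profile.radius, lw=1.5)
    if gates:
        for g in gates:
            ax.axvline(g.z, color="0.6", ls="--", lw=0.8)
            ax.plot([g.z], [g.diameter / 2.0], "o", color="crimson", ms=4)
    ax.set_xlabel("z (A)")
    ax.set_ylabel("probe radius (A)")
    return ax
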