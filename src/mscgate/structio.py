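"""Structure input/output, symmetry detection and canonical-frame alignment.

A :class:`ChannelStructure` stores one homo-oligomeric channel as parallel
numpy arrays (positions, radii, identifiers) plus per-structure annotation
(subunit chains, symmetry order, whether the canonical frame has been
established).  The canonical analysis frame puts the rotational symmetry
axis on z through the origin, the periplasmic/extracellular side at +z, and
the first subunit's centroid at azimuth 0, so that every downstream
measurement (bending angle, in-plane area, pore profile) is deterministic
and comparable between states.

File reading and writing go through gemmi; van der Waals radii follow the
Bondi compilation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    FormatError,
    OrientationError,
    SlabError,
    SymmetryError,
)

# Bondi van der Waals radii (Angstrom).  Hydrogens are excluded by default
# because deposited cryo-EM models lack them; the radius is kept for
# completeness.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

# Apolar residues used by the hydrophobic-belt slab heuristic.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "TRP", "CYS"}
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, author-numbered residue, position (Angstrom)."""

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    vdw_radius: float


@dataclass(frozen=True)
class SymmetryInfo:
    """Detected Cn symmetry: order, unit axis, a point on the axis, and the
    self-agreement RMSD under rotation by 2*pi/order (Angstrom)."""

    order: int
    axis: np.ndarray
    center: np.ndarray
    rmsd: float


@dataclass(frozen=True)
class MembraneSlab:
    """Axial membrane bounds in the canonical frame (Angstrom)."""

    z_min: float
    z_max: float
    z_mid: float | None = None

    def __post_init__(self):
        if self.z_min >= self.z_max:
            raise SlabError(f"empty slab: z_min={self.z_min} >= z_max={self.z_max}")
        if self.z_mid is None:
            object.__setattr__(self, "z_mid", 0.5 * (self.z_min + self.z_max))

    @property
    def thickness(self) -> float:
        return self.z_max - self.z_min

    def contains(self, z: np.ndarray) -> np.ndarray:
        return (z >= self.z_min) & (z <= self.z_max)


class ChannelStructure:
    """Symmetry-annotated atomic coordinate set.

    Parameters
    ----------
    positions : (N, 3) float array, Angstrom.
    atom_names, elements, residue_names : length-N string arrays.
    residue_numbers : length-N int array (author numbering, 1-based).
    chain_ids : length-N string array.
    vdw_radii : length-N float array, Angstrom; looked up from the Bondi
        table when omitted.
    symmetry_order : assumed rotational order (1 = unknown/asymmetric).
    frame_aligned : True once the structure sits in the canonical frame.
    """

    def __init__(
        self,
        positions,
        atom_names,
        elements,
        residue_names,
        residue_numbers,
        chain_ids,
        vdw_radii=None,
        symmetry_order: int = 1,
        frame_aligned: bool = False,
    ):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        if vdw_radii is None:
            vdw_radii = [
                BONDI_RADII.get(str(e).upper(), DEFAULT_VDW) for e in self.elements
            ]
        self.vdw_radii = np.asarray(vdw_radii, dtype=float)
        for arr in (
            self.atom_names,
            self.elements,
            self.residue_names,
            self.residue_numbers,
            self.chain_ids,
            self.vdw_radii,
        ):
            if len(arr) != n:
                raise ValueError("field length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if np.any(self.vdw_radii <= 0):
            raise ValueError("non-positive vdW radius")
        self.symmetry_order = int(symmetry_order)
        self.frame_aligned = bool(frame_aligned)

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def subunit_chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                self.atom_names[i],
                self.elements[i],
                self.residue_names[i],
                int(self.residue_numbers[i]),
                self.chain_ids[i],
                self.positions[i].copy(),
                float(self.vdw_radii[i]),
            )
            for i in range(len(self))
        ]

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id

    def copy(self) -> "ChannelStructure":
        return ChannelStructure(
            self.positions.copy(),
            self.atom_names.copy(),
            self.elements.copy(),
            self.residue_names.copy(),
            self.residue_numbers.copy(),
            self.chain_ids.copy(),
            self.vdw_radii.copy(),
            self.symmetry_order,
            self.frame_aligned,
        )

    def subset(self, mask: np.ndarray) -> "ChannelStructure":
        mask = np.asarray(mask, dtype=bool)
        return ChannelStructure(
            self.positions[mask],
            self.atom_names[mask],
            self.elements[mask],
            self.residue_names[mask],
            self.residue_numbers[mask],
            self.chain_ids[mask],
            self.vdw_radii[mask],
            self.symmetry_order,
            self.frame_aligned,
        )

    def transformed(
        self, rotation: np.ndarray, translation=np.zeros(3), frame_aligned=None
    ) -> "ChannelStructure":
        """Apply the rigid map x -> R x + t and return a new structure."""
        out = self.copy()
        out.positions = self.positions @ np.asarray(rotation).T + np.asarray(
            translation, dtype=float
        )
        if frame_aligned is not None:
            out.frame_aligned = bool(frame_aligned)
        return out

    # -- selections --------------------------------------------------------

    def select(self, selection: str) -> np.ndarray:
        """Boolean mask for a ``[chain:]lo[-hi]`` residue-range selection.

        ``"914"`` picks residue 914 on all chains, ``"900-950"`` a range,
        ``"A:900-950"`` restricts to chain A.
        """
        selection = selection.strip()
        chain = None
        if ":" in selection:
            chain, selection = selection.split(":", 1)
            chain = chain.strip()
        mask = np.ones(len(self), dtype=bool)
        if chain:
            mask &= self.chain_ids == chain
        selection = selection.strip()
        if selection:
            if "-" in selection:
                lo_s, hi_s = selection.split("-", 1)
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(selection)
            mask &= (self.residue_numbers >= lo) & (self.residue_numbers <= hi)
        return mask


# ---------------------------------------------------------------------------
# Reading / writing


def _detect_format(path: Path, fmt: str) -> gemmi.CoorFormat:
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    if fmt == "mmcif":
        return gemmi.CoorFormat.Mmcif
    if fmt == "auto":
        return gemmi.CoorFormat.Detect
    raise FormatError(f"unknown format {fmt!r}")


def read_structure(
    path, fmt: str = "auto", include_het: bool = False, include_hydrogens: bool = False
) -> ChannelStructure:
    """Read a PDB or mmCIF file into a :class:`ChannelStructure`.

    Waters and heteroatoms are excluded by default; hydrogens likewise
    (deposited models lack them, and the Bondi radii below are heavy-atom
    radii).  Chain and author residue identifiers are preserved verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_detect_format(path, fmt))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()
    rows: list[tuple] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name in ("HOH", "WAT", "DOD"):
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if not is_aa and not include_het:
                continue
            for atom in res:
                if atom.element.is_hydrogen and not include_hydrogens:
                    continue
                el = atom.element.name.upper()
                rows.append(
                    (
                        atom.name,
                        el,
                        res.name,
                        res.seqid.num,
                        chain.name,
                        (atom.pos.x, atom.pos.y, atom.pos.z),
                        BONDI_RADII.get(el, DEFAULT_VDW),
                    )
                )
    if not rows:
        raise EmptyStructureError(f"{path} contains no protein atoms")
    names, elements, resnames, resnums, chains, xyz, radii = zip(*rows)
    return ChannelStructure(
        np.array(xyz, dtype=float),
        names,
        elements,
        resnames,
        resnums,
        chains,
        radii,
    )


def write_pdb(s: ChannelStructure, path) -> None:
    """Write the structure as a PDB file (ATOM records, verbatim identifiers)."""
    st = gemmi.Structure()
    st.name = "mscgate"
    model = gemmi.Model("1")
    for chain_id in s.subunit_chains:
        chain = gemmi.Chain(chain_id)
        idx = np.flatnonzero(s.chain_mask(chain_id))
        # add_residue copies, so each residue must be complete before adding
        groups: list[list[int]] = []
        last = None
        for i in idx:
            key = (int(s.residue_numbers[i]), s.residue_names[i])
            if key != last:
                groups.append([])
                last = key
            groups[-1].append(i)
        for group in groups:
            first = group[0]
            res = gemmi.Residue()
            res.name = s.residue_names[first]
            res.seqid = gemmi.SeqId(int(s.residue_numbers[first]), " ")
            res.het_flag = "A"
            for i in group:
                atom = gemmi.Atom()
                atom.name = s.atom_names[i]
                atom.element = gemmi.Element(s.elements[i])
                x, y, z = s.positions[i]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Symmetry detection


def _chain_arrays(s: ChannelStructure) -> dict[str, np.ndarray]:
    return {c: s.positions[s.chain_mask(c)] for c in s.subunit_chains}


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through ``points`` (smallest
    principal axis of their covariance)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    return normal / np.linalg.norm(normal)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def _cyclic_mapping(
    centroids: np.ndarray, rot: np.ndarray, center: np.ndarray
) -> np.ndarray | None:
    """Map each chain index to the chain nearest its rotated centroid;
    None unless the map is a fixed-point-free permutation."""
    rotated = (centroids - center) @ rot.T + center
    d = np.linalg.norm(rotated[:, None, :] - centroids[None, :, :], axis=2)
    mapping = np.argmin(d, axis=1)
    if len(set(mapping)) != len(mapping) or np.any(mapping == np.arange(len(mapping))):
        return None
    return mapping


def _kabsch(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Least-squares rotation taking centered point set p onto centered q."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def detect_symmetry(
    s: ChannelStructure, max_order: int = 12, rmsd_threshold: float = 5.0
) -> SymmetryInfo:
    """Detect the rotational (Cn) symmetry of a homo-oligomer.

    Candidate orders 2..max_order are scanned exhaustively: the trial axis is
    the normal of the best-fit plane through the chain centroids, each order
    is scored by the all-atom RMSD between the structure rotated by
    2*pi/order and its cyclically mapped self, and the winning order is
    refined by a least-squares (Kabsch) fit of the cyclic-permutation map,
    whose rotation axis is the reported symmetry axis.  Ties in RMSD are
    broken toward the higher order.  Deterministic.
    """
    chains = s.subunit_chains
    if len(chains) < 2:
        warnings.warn("single-chain structure: assuming C1", stacklevel=2)
        return SymmetryInfo(1, np.array([0.0, 0.0, 1.0]), s.positions.mean(axis=0), 0.0)
    arrays = _chain_arrays(s)
    counts = {len(a) for a in arrays.values()}
    if len(counts) != 1:
        warnings.warn(
            "chains differ in atom count: assuming symmetry = chain count",
            stacklevel=2,
        )
        centroids = np.array([arrays[c].mean(axis=0) for c in chains])
        return SymmetryInfo(
            len(chains), _plane_normal(centroids), s.positions.mean(axis=0), float("nan")
        )
    centroids = np.array([arrays[c].mean(axis=0) for c in chains])
    axis = _plane_normal(centroids)
    center = centroids.mean(axis=0)
    stacked = np.concatenate([arrays[c] for c in chains])
    per_chain = len(next(iter(arrays.values())))

    results: dict[int, tuple[float, np.ndarray]] = {}
    for order in range(2, max_order + 1):
        rot = _rotation_about(axis, 2.0 * np.pi / order)
        mapping = _cyclic_mapping(centroids, rot, center)
        if mapping is None:
            continue
        rotated = (stacked - center) @ rot.T + center
        target = np.concatenate([arrays[chains[j]] for j in mapping])
        rmsd = float(np.sqrt(np.mean(np.sum((rotated - target) ** 2, axis=1))))
        results[order] = (rmsd, mapping)
    if not results:
        raise SymmetryError("no candidate rotation maps chains onto chains", best=None)

    best_rmsd = min(r for r, _ in results.values())
    # Divisor orders of the true symmetry score equally well; prefer the
    # highest order among near-ties.
    tol = best_rmsd * 1.1 + 0.05
    order = max(o for o, (r, _) in results.items() if r <= tol)
    rmsd, mapping = results[order]

    # Least-squares refinement: fit the rotation carrying each chain onto its
    # cyclic image, then recover axis and on-axis point from that rotation.
    target = np.concatenate([arrays[chains[j]] for j in mapping])
    p_mean, q_mean = stacked.mean(axis=0), target.mean(axis=0)
    rot = _kabsch(stacked - p_mean, target - q_mean)
    w, v = np.linalg.eig(rot)
    axis_ref = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis_ref = axis_ref / np.linalg.norm(axis_ref)
    if np.dot(axis_ref, axis) < 0:
        axis_ref = -axis_ref
    # Fixed point of x -> R(x - p_mean) + q_mean, solved in the plane
    # perpendicular to the axis (least squares; the axial component is free).
    t = q_mean - rot @ p_mean
    center_ref, *_ = np.linalg.lstsq(np.eye(3) - rot, t, rcond=None)
    # Pin the free axial component to the structure centroid.
    centroid = s.positions.mean(axis=0)
    center_ref = center_ref + np.dot(centroid - center_ref, axis_ref) * axis_ref
    rotated = (stacked - center_ref) @ _rotation_about(
        axis_ref, 2.0 * np.pi / order
    ).T + center_ref
    rmsd_ref = float(np.sqrt(np.mean(np.sum((rotated - target) ** 2, axis=1))))
    if rmsd_ref > rmsd:  # refinement should never hurt; keep the better one
        axis_ref, center_ref, rmsd_ref = axis, center, rmsd
    info = SymmetryInfo(order, axis_ref, center_ref, rmsd_ref)
    if rmsd_ref > rmsd_threshold:
        raise SymmetryError(
            f"best candidate C{order} has RMSD {rmsd_ref:.2f} A > "
            f"threshold {rmsd_threshold} A",
            best=info,
        )
    return info


# ---------------------------------------------------------------------------
# Canonical frame


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(axis, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # Antiparallel: rotate pi about x.
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(axis, z)
    angle = np.arccos(np.clip(c, -1.0, 1.0))
    return _rotation_about(v / np.linalg.norm(v), angle)


def align_to_axis(
    s: ChannelStructure,
    sym: SymmetryInfo,
    periplasmic_marker: str | None = None,
) -> ChannelStructure:
    """Place the structure in the canonical frame.

    The symmetry axis is mapped onto z through the origin, the overall
    centroid is moved to z = 0, and the structure is rotated about z so the
    first subunit chain's centroid sits at azimuth 0 (making the frame
    unique, hence alignment idempotent).  If ``periplasmic_marker`` names a
    residue selection, the frame is flipped so those atoms end up at mean
    z > 0; with no marker the current polarity is kept.

    Purely rigid: pairwise distances are preserved to machine precision.
    """
    if sym.order < 2:
        raise SymmetryError("alignment requires symmetry order >= 2")
    marker_mask = None
    if periplasmic_marker is not None:
        marker_mask = s.select(periplasmic_marker)
        if not marker_mask.any():
            raise OrientationError(
                f"marker selection {periplasmic_marker!r} matched no atoms"
            )

    rot = _rotation_to_z(sym.axis)
    pos = (s.positions - sym.center) @ rot.T
    pos[:, 2] -= pos[:, 2].mean()

    if marker_mask is not None and pos[marker_mask, 2].mean() < 0:
        pos = pos @ np.diag([1.0, -1.0, -1.0]).T  # flip pi about x

    first = s.chain_mask(s.subunit_chains[0])
    cx, cy = pos[first, 0].mean(), pos[first, 1].mean()
    phi = np.arctan2(cy, cx)
    pos = pos @ _rotation_about(np.array([0.0, 0.0, 1.0]), -phi).T

    out = s.copy()
    out.positions = pos
    out.frame_aligned = True
    out.symmetry_order = sym.order
    return out


# ---------------------------------------------------------------------------
# Membrane slab


def assign_membrane_slab(
    s: ChannelStructure,
    mode: str = "explicit",
    z_min: float | None = None,
    z_max: float | None = None,
    width: float = 32.0,
    min_hydrophobic_fraction: float = 0.25,
) -> MembraneSlab:
    """Assign membrane z-bounds in the canonical frame.

    ``explicit`` returns the user bounds unchanged.  ``hydrophobic-belt``
    slides a window of ``width`` along z and returns the window maximizing
    the fraction of atoms in apolar residues; it fails if no window reaches
    ``min_hydrophobic_fraction`` (e.g. an all-polar structure).
    """
    if not s.frame_aligned:
        raise SlabError("structure must be frame-aligned before slab assignment")
    z = s.positions[:, 2]
    if mode == "explicit":
        if z_min is None or z_max is None:
            raise SlabError("explicit mode requires z_min and z_max")
        slab = MembraneSlab(float(z_min), float(z_max))
    elif mode == "hydrophobic-belt":
        hydro = np.isin(
            np.asarray(s.residue_names, dtype=str), list(HYDROPHOBIC_RESIDUES)
        )
        lo, hi = float(z.min()), float(z.max())
        if hi - lo <= width:
            starts = np.array([0.5 * (lo + hi) - width / 2.0])
        else:
            starts = np.arange(lo, hi - width + 1e-9, 0.5)
        best_frac, best_start = -1.0, starts[0]
        for start in starts:
            in_win = (z >= start) & (z <= start + width)
            n = int(in_win.sum())
            if n == 0:
                continue
            frac = float(hydro[in_win].mean())
            if frac > best_frac:
                best_frac, best_start = frac, start
        if best_frac < min_hydrophobic_fraction:
            raise SlabError(
                f"no {width} A window reaches hydrophobic fraction "
                f"{min_hydrophobic_fraction} (best {best_frac:.2f})"
            )
        slab = MembraneSlab(float(best_start), float(best_start + width))
    else:
        raise SlabError(f"unknown slab mode {mode!r}")
    if slab.thickness < 10.0:
        raise SlabError(f"slab thinner than 10 A ({slab.thickness:.1f} A)")
    if slab.z_max < z.min() or slab.z_min > z.max():
        raise SlabError("slab lies outside the structure z-range")
    return slab
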