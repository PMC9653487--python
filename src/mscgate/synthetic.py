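"""Ground-truthed synthetic inputs: bent Cn helix bundles and tension-gated
patch recordings.

The structure generator builds idealized pseudo-atom channels, not real
proteins: per subunit, helical axes sit on a cone of known bending angle,
pore-lining atoms are placed analytically so requested constriction radii
are realized exactly, and an apolar/polar residue labeling makes the
hydrophobic-belt and gate-attribution logic exercisable.  Because every
quantity the measurement modules report exists in closed form at generation
time, the generator doubles as the package's regression oracle: every
downstream module must recover the embedded ground truth within its
documented tolerance.

The recording simulator produces single-channel current traces under a
linear suction ramp (or a pressure hold): each channel population opens
when the ramp crosses its activation pressure, either sharply or with
Boltzmann-smoothed stochastic flicker, carries its unitary current g*V, and
rides on seeded Gaussian noise.  All randomness flows through one seeded
generator, and the seed is recorded in the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import SpecError
from .structio import ChannelStructure
from .ephys import Recording

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_HYDROPHOBIC_CYCLE = ("LEU", "ILE", "VAL", "PHE", "ALA", "MET")
#: Default gate labels, topmost ring first (mimicking the periplasmic
#: tryptophan ring and the V/F cytoplasmic gate of MscK).
_DEFAULT_RING_LABELS = (("TRP", 914), ("VAL", 921), ("PHE", 925))
_HELIX_TUBE_RADIUS = 2.3  # Angstrom, pseudo-helical spiral radius
_RISE_PER_ATOM = 1.5  # Angstrom
_TWIST_PER_ATOM = np.radians(100.0)
_CAP_RESIDUE_START = 1401


@dataclass(frozen=True)
class ToyChannelSpec:
    """Parameters of one synthetic Cn channel.

    ``inplane_radius`` is the axis radius of the outermost helix (Angstrom);
    ``constriction_radii`` lists (z, radius) pore constrictions realized
    exactly by analytic ring placement; ``ring_labels`` optionally names the
    ring residues (default: W914 for the topmost, then V921, F925);
    ``cap_radius`` sets the periplasmic marker/ring radius.  ``jitter_sd``
    Gaussian coordinate noise is applied last, seeded.
    """

    n_subunits: int = 7
    cone_angle: float = 30.0  # degrees
    inplane_radius: float = 78.1  # Angstrom
    tm_span: float = 32.0  # Angstrom, helix length
    helices_per_subunit: int = 4
    constriction_radii: tuple[tuple[float, float], ...] = ((-10.0, 2.5), (10.0, 4.0))
    ring_labels: tuple[tuple[str, int], ...] | None = None
    pore_lining_atom_radius: float = 1.7
    cap_radius: float = 77.0
    periplasmic_cap: bool = True
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subunits < 3:
            raise SpecError("need at least 3 subunits")
        if self.jitter_sd < 0:
            raise SpecError("jitter_sd must be >= 0")
        if self.inplane_radius <= 0 or self.tm_span <= 0:
            raise SpecError("radii and spans must be positive")
        if any(r <= 0 for _, r in self.constriction_radii):
            raise SpecError("constriction radii must be positive")
        if self.ring_labels is not None and len(self.ring_labels) != len(
            self.constriction_radii
        ):
            raise SpecError("ring_labels must match constriction_radii in length")


@dataclass(frozen=True)
class GroundTruth:
    """Exact generation values serialized alongside every artifact."""

    spec: dict
    true_cone_angle_deg: float
    true_hull_radius_nm: float
    true_hull_area_nm2: float
    true_height_A: float
    true_constriction_diameters_A: tuple[tuple[float, float], ...]  # (z, diameter)
    true_ring_diameter_A: float | None
    tm_slab: tuple[float, float]
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _ring_labels(spec: ToyChannelSpec) -> list[tuple[str, int]]:
    if spec.ring_labels is not None:
        return list(spec.ring_labels)
    order = np.argsort([-z for z, _ in spec.constriction_radii])  # topmost first
    labels: list[tuple[str, int] | None] = [None] * len(order)
    for rank, idx in enumerate(order):
        if rank < len(_DEFAULT_RING_LABELS):
            labels[idx] = _DEFAULT_RING_LABELS[rank]
        else:
            labels[idx] = ("GLY", 930 + rank)
    return labels  # type: ignore[return-value]


def make_toy_channel(spec: ToyChannelSpec) -> tuple[ChannelStructure, GroundTruth]:
    """Generate a Cn pseudo-atom channel with exact ground truth.

    Helix axes are placed on a cone of ``cone_angle``: a helix at radial
    distance r has its midpoint at z = -tan(angle) * (r - r_mean), so the
    midplane deflection per unit radius is exactly tan(angle).  Pore rings
    put one atom per subunit at distance (radius + atom_radius) from the
    axis, so a centered probe sphere of exactly the requested radius
    touches them.  Deterministic per seed; bit-identical across runs.
    """
    rng = np.random.default_rng(spec.seed)
    theta = np.radians(spec.cone_angle)
    n = spec.n_subunits
    max_constr = max((r for _, r in spec.constriction_radii), default=0.0)
    r_inner = max(15.0, max_constr + spec.pore_lining_atom_radius + 4.0)
    if r_inner >= spec.inplane_radius:
        raise SpecError("inplane_radius too small for the requested constrictions")
    helix_radii = np.linspace(r_inner, spec.inplane_radius, spec.helices_per_subunit)
    r_pivot = float(helix_radii.mean())
    n_res = int(round(spec.tm_span / _RISE_PER_ATOM)) + 1

    names, elements, resnames, resnums, chains, xyz = [], [], [], [], [], []

    def add_atom(pos, resname, resnum, chain, name="CA", element="C"):
        names.append(name)
        elements.append(element)
        resnames.append(resname)
        resnums.append(int(resnum))
        chains.append(chain)
        xyz.append(pos)

    # Helix z-extents are analytic (helix axes are parallel to z; the cone
    # lives entirely in the radial profile of the midpoints, so the in-plane
    # footprint is set by the helix radii alone and closed/open footprint
    # differences track the generator radii exactly).
    mid_z = -np.tan(theta) * (helix_radii - r_pivot)
    z_tm_min = float(mid_z.min() - spec.tm_span / 2.0)
    z_tm_max = float(mid_z.max() + spec.tm_span / 2.0)
    labels = _ring_labels(spec)
    for zc, _ in spec.constriction_radii:
        if not (z_tm_min - 1.0 <= zc <= z_tm_max + 1.0):
            raise SpecError(
                f"constriction z={zc} outside the TM span "
                f"[{z_tm_min:.1f}, {z_tm_max:.1f}]"
            )
    cap_z0 = z_tm_max + 4.0

    for k in range(n):  # atoms grouped per chain (round-trip stable order)
        chain = _CHAIN_IDS[k]
        phi0 = 2.0 * np.pi * k / n
        for h, r_h in enumerate(helix_radii, start=1):
            # Stagger helices within the subunit wedge.
            phi = phi0 + (h - 1) * (2.0 * np.pi / n) / spec.helices_per_subunit
            radial = np.array([np.cos(phi), np.sin(phi), 0.0])
            center = r_h * radial + np.array(
                [0.0, 0.0, -np.tan(theta) * (r_h - r_pivot)]
            )
            axis = np.array([0.0, 0.0, 1.0])
            u = np.array([-np.sin(phi), np.cos(phi), 0.0])
            v = np.cross(axis, u)
            for i, t in enumerate(
                np.linspace(-spec.tm_span / 2.0, spec.tm_span / 2.0, n_res)
            ):
                ang = i * _TWIST_PER_ATOM
                pos = (
                    center
                    + t * axis
                    + _HELIX_TUBE_RADIUS * (np.cos(ang) * u + np.sin(ang) * v)
                )
                add_atom(
                    pos,
                    _HYDROPHOBIC_CYCLE[(h + i) % len(_HYDROPHOBIC_CYCLE)],
                    h * 100 + i + 1,
                    chain,
                )
        for (zc, rc), (resname, resnum) in zip(spec.constriction_radii, labels):
            ring_r = rc + spec.pore_lining_atom_radius
            add_atom(
                np.array([ring_r * np.cos(phi0), ring_r * np.sin(phi0), zc]),
                resname,
                resnum,
                chain,
            )
        if spec.periplasmic_cap:
            for j in range(8):
                add_atom(
                    np.array(
                        [
                            spec.cap_radius * np.cos(phi0),
                            spec.cap_radius * np.sin(phi0),
                            cap_z0 + j * _RISE_PER_ATOM,
                        ]
                    ),
                    "SER",
                    _CAP_RESIDUE_START + j,
                    chain,
                )

    positions = np.array(xyz, dtype=float)
    # Exact values before jitter.
    from scipy.spatial import ConvexHull  # local: avoid import cost at module load

    ring_z = [zc for zc, _ in spec.constriction_radii]
    tm_slab = (
        min([z_tm_min] + ring_z) - 2.0,
        max([z_tm_max] + ring_z) + 2.0,
    )
    in_slab = (positions[:, 2] >= tm_slab[0]) & (positions[:, 2] <= tm_slab[1])
    hull_area_nm2 = ConvexHull(positions[in_slab][:, :2]).volume / 100.0
    truth = GroundTruth(
        spec=asdict(spec),
        true_cone_angle_deg=float(spec.cone_angle),
        true_hull_radius_nm=float(np.sqrt(hull_area_nm2 / np.pi)),
        true_hull_area_nm2=float(hull_area_nm2),
        true_height_A=float(positions[:, 2].max() - positions[:, 2].min()),
        true_constriction_diameters_A=tuple(
            (float(z), float(2.0 * r)) for z, r in spec.constriction_radii
        ),
        true_ring_diameter_A=2.0 * spec.cap_radius if spec.periplasmic_cap else None,
        tm_slab=(float(tm_slab[0]), float(tm_slab[1])),
        seed=spec.seed,
    )
    if spec.jitter_sd > 0:
        positions = positions + rng.normal(0.0, spec.jitter_sd, positions.shape)
    structure = ChannelStructure(
        positions,
        names,
        elements,
        resnames,
        resnums,
        chains,
        symmetry_order=n,
        frame_aligned=True,
    )
    return structure, truth


def mscK_mimic_closed_spec(jitter_sd: float = 0.25, seed: int = 0) -> ToyChannelSpec:
    """Closed-state MscK mimic: cone 30 deg, ~7.8 nm in-plane radius, a
    2.5 A-radius cytoplasmic gate (V921/F925) and a 4 A periplasmic W914
    ring, 154 A periplasmic ring."""
    return ToyChannelSpec(
        cone_angle=30.0,
        # Outermost helix-axis radius chosen so the convex-hull footprint
        # radius of the generated bundle is 7.81 nm (the helix tube width
        # and the 7-fold azimuthal sampling shrink the hull slightly).
        inplane_radius=81.2,
        cap_radius=77.0,
        constriction_radii=((-9.0, 2.5), (-6.5, 2.5), (10.0, 4.0)),
        ring_labels=(("VAL", 921), ("PHE", 925), ("TRP", 914)),
        jitter_sd=jitter_sd,
        seed=seed,
    )


def mscK_mimic_open_spec(jitter_sd: float = 0.25, seed: int = 1) -> ToyChannelSpec:
    """Open-state mimic: cone 15 deg, in-plane radius +11 A, single wide
    10 A-radius pore, ring dilated to 178 A."""
    return ToyChannelSpec(
        cone_angle=15.0,
        inplane_radius=93.0,  # hull footprint radius 8.92 nm (+1.1 nm)
        cap_radius=89.0,
        constriction_radii=((0.0, 10.0),),
        ring_labels=(("GLY", 924),),
        jitter_sd=jitter_sd,
        seed=seed,
    )


def make_state_pair(
    closed_spec: ToyChannelSpec | None = None,
    open_spec: ToyChannelSpec | None = None,
) -> tuple[ChannelStructure, ChannelStructure, dict]:
    """Generate a closed/open structure pair with paired ground truth.

    Defaults to the MscK mimic: 30 deg -> 15 deg bending, +11 A in-plane
    (hull-radius) expansion, 2.5 A -> 10 A minimal pore radius, 154 -> 178 A
    periplasmic ring.
    """
    if closed_spec is None:
        closed_spec = mscK_mimic_closed_spec()
    if open_spec is None:
        open_spec = mscK_mimic_open_spec()
    if closed_spec.n_subunits != open_spec.n_subunits:
        raise SpecError("closed and open specs must share the subunit count")
    closed, closed_truth = make_toy_channel(closed_spec)
    open_, open_truth = make_toy_channel(open_spec)
    pair_truth = {
        "closed": closed_truth,
        "open": open_truth,
        "delta_theta_deg": closed_truth.true_cone_angle_deg
        - open_truth.true_cone_angle_deg,
        "delta_R_nm": open_truth.true_hull_radius_nm - closed_truth.true_hull_radius_nm,
        "delta_A_nm2": open_truth.true_hull_area_nm2 - closed_truth.true_hull_area_nm2,
    }
    return closed, open_, pair_truth


# ---------------------------------------------------------------------------
# Patch-clamp recording simulation


@dataclass(frozen=True)
class ChannelPopulation:
    """One population of identical channels in the simulated patch.

    ``gating="sharp"`` opens each channel permanently once the suction
    magnitude crosses ``activation_pressure``; ``gating="flicker"`` runs a
    seeded two-state Markov chain whose equilibrium open probability is a
    Boltzmann function of pressure (width ``boltzmann_width`` mmHg) and
    whose transition attempt rate is ``flicker_rate`` (Hz).
    """

    conductance_ps: float
    activation_pressure: float  # mmHg (magnitude)
    count: int = 1
    gating: str = "sharp"
    boltzmann_width: float = 2.0
    flicker_rate: float = 5.0

    def __post_init__(self):
        if self.count < 1:
            raise SpecError("channel count must be >= 1")
        if self.conductance_ps <= 0:
            raise SpecError("conductance must be positive")
        if self.gating not in ("sharp", "flicker"):
            raise SpecError(f"unknown gating mode {self.gating!r}")


@dataclass(frozen=True)
class RecordingSpec:
    """Simulated patch: duration (s), sampling (Hz), holding voltage (mV),
    Gaussian current noise (pA), suction ramp rate (mmHg/s) or a constant
    hold, and the channel populations present."""

    duration: float = 30.0
    sample_rate: float = 5000.0
    voltage: float = -30.0
    noise_sd: float = 2.0
    ramp_rate: float = 4.0
    pressure_mode: str = "ramp"  # "ramp" | "hold"
    hold_pressure: float | None = None
    channels: tuple[ChannelPopulation, ...] = (
        ChannelPopulation(conductance_ps=895.0, activation_pressure=40.0),
    )
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.sample_rate <= 0:
            raise SpecError("duration and sample_rate must be positive")
        if self.pressure_mode not in ("ramp", "hold"):
            raise SpecError(f"unknown pressure mode {self.pressure_mode!r}")
        if self.pressure_mode == "hold" and self.hold_pressure is None:
            raise SpecError("hold mode requires hold_pressure")


def _flicker_state(
    rng: np.random.Generator,
    pressure: np.ndarray,
    pop: ChannelPopulation,
    sample_rate: float,
    tick: float = 1e-3,
) -> np.ndarray:
    """Open/closed state per sample for one flickering channel.

    Quasi-static two-state Markov chain evaluated on a 1 ms tick grid:
    opening rate = flicker_rate * P(p), closing rate = flicker_rate *
    (1 - P(p)), with P the Boltzmann open probability at the current
    pressure.  Expanded back to the sampling grid.
    """
    stride = max(1, int(round(tick * sample_rate)))
    p_tick = pressure[::stride]
    if pop.boltzmann_width > 0:
        p_open = 1.0 / (
            1.0
            + np.exp(-(np.abs(p_tick) - pop.activation_pressure) / pop.boltzmann_width)
        )
    else:
        p_open = (np.abs(p_tick) >= pop.activation_pressure).astype(float)
    dt = stride / sample_rate
    u = rng.random(len(p_tick))
    state = np.zeros(len(p_tick), dtype=bool)
    current = False
    for i in range(len(p_tick)):
        rate = pop.flicker_rate * ((1.0 - p_open[i]) if current else p_open[i])
        if u[i] < rate * dt:
            current = not current
        state[i] = current
    return np.repeat(state, stride)[: len(pressure)]


def simulate_patch_recording(spec: RecordingSpec) -> Recording:
    """Simulate a single-channel recording under a suction ramp or hold.

    Pressure is reported as negative (suction applied to the pipette);
    currents are signed (i = g * V).  Ground truth embeds the per-population
    unitary steps, thresholds, realized opening-event counts and the seed.
    Reproducible bit-for-bit per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    if spec.pressure_mode == "ramp":
        p_mag = spec.ramp_rate * t
    else:
        p_mag = np.full(n, float(spec.hold_pressure))
    current = np.zeros(n)
    truth_channels = []
    amplitudes = []
    for pop in spec.channels:
        step = pop.conductance_ps * spec.voltage / 1000.0  # pA, signed
        amplitudes.append(abs(step))
        n_events = 0
        for _ in range(pop.count):
            if pop.gating == "sharp":
                state = p_mag >= pop.activation_pressure
                n_events += int(state.any())
            else:
                state = _flicker_state(rng, p_mag, pop, spec.sample_rate)
                n_events += int(
                    np.count_nonzero(np.diff(state.astype(int)) == 1)
                    + (1 if state[0] else 0)
                )
            current = current + step * state
        truth_channels.append(
            {
                "conductance_ps": pop.conductance_ps,
                "step_pA": step,
                "activation_pressure_mmHg": pop.activation_pressure,
                "count": pop.count,
                "gating": pop.gating,
                "n_opening_events": n_events,
            }
        )
    overlap_warning = False
    amplitudes.sort()
    for a, b in zip(amplitudes, amplitudes[1:]):
        if b - a < 3.0 * spec.noise_sd:
            overlap_warning = True
    if spec.noise_sd > 0:
        current = current + rng.normal(0.0, spec.noise_sd, n)
    truth = {
        "seed": spec.seed,
        "voltage_mV": spec.voltage,
        "noise_sd_pA": spec.noise_sd,
        "ramp_rate_mmHg_per_s": spec.ramp_rate,
        "pressure_mode": spec.pressure_mode,
        "channels": truth_channels,
        "amplitude_classes_overlap": overlap_warning,
    }
    return Recording(
        time=t,
        current=current,
        pressure=-p_mag,
        voltage=spec.voltage,
        sample_rate=spec.sample_rate,
        ground_truth=truth,
    )
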