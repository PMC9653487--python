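"""End-to-end orchestration: structures -> geometry -> pore -> energetics,
and recordings -> conductance/sensitivity, with machine-readable reports.

A run is described by a :class:`RunConfig` (loadable from JSON or YAML),
executed by :func:`run_state_comparison` or :func:`run_ephys`, and produces
a :class:`Report`: a JSON document plus CSV tables in the output directory.
Every number in the report names the operation that produced it, the config
hash is stable under re-run, and identical config + seed give identical
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .energetics import (
    energetics_curve,
    midpoint_tension_closed_form,
    midpoint_tension_root,
    mscK_parameters,
    params_from_states,
)
from .ephys import (
    Recording,
    amplitude_class_for,
    estimate_unitary_conductance,
    tension_sensitivity_ratio,
)
from .errors import MscgateError
from .geometry import compare_states, measure_geometry
from .pore import constrictions_to_intervals, find_gates, pore_profile
from .structio import (
    MembraneSlab,
    align_to_axis,
    assign_membrane_slab,
    detect_symmetry,
    read_structure,
)
from .synthetic import (
    ChannelPopulation,
    RecordingSpec,
    make_state_pair,
    simulate_patch_recording,
)

log = logging.getLogger("mscgate")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Structures come either from ``closed_path``/``open_path`` (PDB/mmCIF)
    or from the named synthetic ``preset``.  ``energetics_profile`` selects
    the gating-parameter source: ``"from-measurements"`` builds them from
    the measured state delta, ``"canonical-parameters"`` uses the canonical
    MscK set.  Units: slab in Angstrom, K_b and dG0 in kBT.
    """

    preset: str | None = "mscK-mimic"
    closed_path: str | None = None
    open_path: str | None = None
    recording_path: str | None = None
    periplasmic_marker: str | None = "1401-1499"
    slab_mode: str = "auto"  # "auto" | "explicit" | "hydrophobic-belt"
    slab_z: tuple[float, float] | None = None
    ring_selection: str | None = "1401-1499"
    pore_step: float = 0.5
    pore_wander: float = 2.0
    energetics_profile: str = "from-measurements"
    K_b: float = 20.0
    dG0: float = 0.0
    output_dir: str = "mscgate_out"
    seed: int = 0
    verbosity: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a RunConfig from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if "slab_z" in data and data["slab_z"] is not None:
        data["slab_z"] = tuple(data["slab_z"])
    return RunConfig(**data)


@dataclass
class Report:
    """Machine-readable run report; ``values`` maps result names to
    {value, units, produced_by} entries."""

    kind: str
    values: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "values": self.values, "provenance": self.provenance},
            indent=2,
            default=_jsonable,
        )

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _provenance(cfg: RunConfig) -> dict:
    return {
        "package": "mscgate",
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": cfg.seed,
    }


def _load_state_structures(cfg: RunConfig):
    """Return (closed, open, per-state slabs, convention, truth_or_None)."""
    if cfg.closed_path and cfg.open_path:
        states = []
        for path in (cfg.closed_path, cfg.open_path):
            s = read_structure(path)
            sym = detect_symmetry(s)
            s = align_to_axis(s, sym, cfg.periplasmic_marker)
            states.append(s)
        closed, open_ = states
        if cfg.slab_mode == "explicit" or (cfg.slab_mode == "auto" and cfg.slab_z):
            if cfg.slab_z is None:
                raise MscgateError("explicit slab mode requires slab_z")
            slabs = tuple(
                assign_membrane_slab(s, "explicit", z_min=cfg.slab_z[0], z_max=cfg.slab_z[1])
                for s in states
            )
            convention = "explicit"
        else:
            slabs = tuple(assign_membrane_slab(s, "hydrophobic-belt") for s in states)
            convention = "hydrophobic-belt"
        return closed, open_, slabs, convention, None
    if cfg.preset == "mscK-mimic":
        from .synthetic import mscK_mimic_closed_spec, mscK_mimic_open_spec

        closed, open_, truth = make_state_pair(
            mscK_mimic_closed_spec(seed=cfg.seed),
            mscK_mimic_open_spec(seed=cfg.seed + 1),
        )
        # Each state is measured over its own TM extent (the membrane
        # boundaries of the curved and flattened conformations differ).
        slabs = (
            MembraneSlab(*truth["closed"].tm_slab),
            MembraneSlab(*truth["open"].tm_slab),
        )
        return closed, open_, slabs, "tm-extent", truth
    raise MscgateError(
        f"no input structures: preset {cfg.preset!r} unknown and no paths given"
    )


def run_state_comparison(cfg: RunConfig) -> Report:
    """Structure pair -> geometry -> pore -> energetics -> report.

    With ``energetics_profile="canonical-parameters"`` the gating parameters are
    the canonical MscK set and no structures are needed; otherwise they are
    built from the measured closed/open deltas.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    values: dict = {}

    if cfg.energetics_profile == "canonical-parameters":
        gp = mscK_parameters(K_b=cfg.K_b, dG0=cfg.dG0)
    else:
        closed, open_, slabs, convention, truth = _load_state_structures(cfg)
        profiles = {}
        for (name, s), slab in zip((("closed", closed), ("open", open_)), slabs):
            log.info(
                "measuring %s geometry (slab %.1f..%.1f A)", name, slab.z_min, slab.z_max
            )
            prof = measure_geometry(
                s, slab, ring_selection=cfg.ring_selection, slab_convention=convention
            )
            profiles[name] = prof
            values[f"{name}_geometry"] = {
                "value": dataclasses.asdict(prof),
                "units": {
                    "theta": "deg",
                    "R_inplane": "nm",
                    "area": "nm2",
                    "tmd_height": "A",
                    "ring_diameter": "A",
                },
                "produced_by": "geometry.measure_geometry",
            }
            log.info(
                "%s: theta=%.1f deg R=%.2f nm A=%.1f nm2", name, prof.theta, prof.R_inplane, prof.area
            )
            profile = pore_profile(
                s, step=cfg.pore_step, wander=cfg.pore_wander
            )
            profile.to_frame().to_csv(out / f"pore_{name}.csv", index=False)
            gates = find_gates(profile, s)
            constrictions_to_intervals(gates).to_csv(
                out / f"gates_{name}.csv", index=False
            )
            values[f"{name}_pore"] = {
                "value": {
                    "min_diameter": profile.min_diameter,
                    "gates": [dataclasses.asdict(g) for g in gates],
                },
                "units": {"min_diameter": "A", "gate_diameter": "A", "z": "A"},
                "produced_by": "pore.pore_profile+find_gates",
            }
        delta = compare_states(profiles["closed"], profiles["open"])
        values["state_delta"] = {
            "value": dataclasses.asdict(delta),
            "units": {
                "theta": "rad",
                "R": "nm",
                "delta_A": "nm2",
                "delta_height": "A",
            },
            "produced_by": "geometry.compare_states",
        }
        gp = params_from_states(delta, K_b=cfg.K_b, dG0=cfg.dG0)

    sigma_half = midpoint_tension_closed_form(gp)
    sigma_half_root = midpoint_tension_root(gp)
    curve = energetics_curve(gp)
    curve.to_frame().to_csv(out / "energetics_curve.csv", index=False)
    values["gating_parameters"] = {
        "value": dataclasses.asdict(gp),
        "units": {"theta": "rad", "R": "nm", "delta_A": "nm2", "K_b": "kBT", "dG0": "kBT"},
        "produced_by": (
            "energetics.mscK_parameters"
            if cfg.energetics_profile == "canonical-parameters"
            else "energetics.params_from_states"
        ),
    }
    values["sigma_half"] = {
        "value": sigma_half,
        "units": "kBT/nm2",
        "produced_by": "energetics.midpoint_tension_closed_form",
    }
    values["sigma_half_root"] = {
        "value": sigma_half_root,
        "units": "kBT/nm2",
        "produced_by": "energetics.midpoint_tension_root",
    }
    values["p_open_curve_csv"] = {
        "value": "energetics_curve.csv",
        "units": "sigma: kBT/nm2",
        "produced_by": "energetics.energetics_curve",
    }
    report = Report("state_comparison", values, _provenance(cfg))
    report.write(out / "report.json")
    log.info("sigma_1/2 = %.4f kBT/nm2", sigma_half)
    return report


# Ephys presets: a wild-type-like MscK patch held near threshold (flickery,
# many unitary events) and a two-population ramp with the endogenous MscL
# calibrator.
_EPHYS_PRESETS = {
    "wt-mimic": lambda seed: RecordingSpec(
        pressure_mode="hold",
        hold_pressure=40.0,
        channels=(
            ChannelPopulation(
                conductance_ps=895.0,
                activation_pressure=40.0,
                gating="flicker",
                flicker_rate=6.0,
            ),
        ),
        seed=seed,
    ),
    "ramp-two-pop": lambda seed: RecordingSpec(
        duration=30.0,
        pressure_mode="ramp",
        channels=(
            ChannelPopulation(conductance_ps=895.0, activation_pressure=40.0),
            ChannelPopulation(conductance_ps=3650.0, activation_pressure=100.0),
        ),
        seed=seed,
    ),
}


def run_ephys(cfg: RunConfig, preset: str | None = None) -> Report:
    """Recording -> conductance and tension-sensitivity report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.recording_path:
        rec = Recording.from_csv(cfg.recording_path)
    else:
        name = preset or "wt-mimic"
        if name not in _EPHYS_PRESETS:
            raise MscgateError(f"unknown ephys preset {name!r}")
        rec = simulate_patch_recording(_EPHYS_PRESETS[name](cfg.seed))
    values: dict = {}
    est = estimate_unitary_conductance(rec)
    values["unitary_conductance"] = {
        "value": {
            "g": est.g,
            "se": est.se,
            "n_events": est.n_events,
            "open_level": est.open_level,
            "baseline": est.baseline,
        },
        "units": {"g": "pS", "se": "pS", "open_level": "pA", "baseline": "pA"},
        "produced_by": "ephys.estimate_unitary_conductance",
    }
    truth = rec.ground_truth or {}
    populations = truth.get("channels", [])
    if len(populations) >= 2 and truth.get("pressure_mode") == "ramp":
        test_pop, cal_pop = populations[0], populations[1]
        sens = tension_sensitivity_ratio(
            rec,
            amplitude_class_for(test_pop["conductance_ps"], rec.voltage),
            amplitude_class_for(cal_pop["conductance_ps"], rec.voltage),
        )
        values["tension_sensitivity"] = {
            "value": {
                "p_first_test": sens.p_first_test,
                "p_first_calibrator": sens.p_first_calibrator,
                "ratio": sens.ratio,
            },
            "units": {"p_first_test": "mmHg", "p_first_calibrator": "mmHg", "ratio": "1"},
            "produced_by": "ephys.tension_sensitivity_ratio",
        }
    report = Report("ephys", values, _provenance(cfg))
    report.write(out / "ephys_report.json")
    return report
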