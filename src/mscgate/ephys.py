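"""Single-channel patch-clamp trace analysis.

Implements the three measurements the tension-sensitivity assay needs:

* unitary conductance from the two dominant modes of the current-amplitude
  histogram (baseline and first open level), with a standard error from
  event-level spread;
* the pressure at which the first channel of a given amplitude class
  activates on a slow suction ramp;
* the calibrator/test first-activation pressure ratio (e.g. P_MscL/P_MscK),
  the assay's tension-sensitivity readout -- the endogenous large-conductance
  channel MscL opens at a high, reproducible tension and serves as an
  in-patch calibrator, so a larger ratio means the test channel opens at a
  lower tension.

Traces are lowpass filtered with a 4-pole Bessel-equivalent filter (500 Hz
default, matching common acquisition practice) before event detection;
openings are idealized by half-amplitude threshold crossing.  Recordings are
plain CSV (time, current, pressure) with a JSON sidecar for metadata, so no
proprietary acquisition formats are involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import bessel, find_peaks, sosfiltfilt

from .errors import NoActivationError, NoEventsError


@dataclass
class Recording:
    """A (simulated) patch-clamp recording.

    time in s (uniform), current in pA, pressure in mmHg (negative values
    are suction; analyses use the magnitude), voltage in mV (constant),
    plus the generation ground truth when the trace is synthetic.
    """

    time: np.ndarray
    current: np.ndarray
    pressure: np.ndarray
    voltage: float
    sample_rate: float
    ground_truth: dict | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if not (len(self.time) == len(self.current) == len(self.pressure)):
            raise ValueError("time/current/pressure length mismatch")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    # -- CSV + JSON sidecar IO -------------------------------------------

    def to_csv(self, path) -> None:
        path = Path(path)
        pd.DataFrame(
            {
                "time_s": self.time,
                "current_pA": self.current,
                "pressure_mmHg": self.pressure,
            }
        ).to_csv(path, index=False)
        sidecar = {
            "voltage_mV": self.voltage,
            "sample_rate_Hz": self.sample_rate,
            "ground_truth": self.ground_truth,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "Recording":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            time=df["time_s"].to_numpy(),
            current=df["current_pA"].to_numpy(),
            pressure=df["pressure_mmHg"].to_numpy(),
            voltage=float(meta["voltage_mV"]),
            sample_rate=float(meta["sample_rate_Hz"]),
            ground_truth=meta.get("ground_truth"),
        )


@dataclass(frozen=True)
class ConductanceEstimate:
    """Unitary conductance (pS) with event-level standard error."""

    g: float
    se: float
    n_events: int
    open_level: float  # pA
    baseline: float  # pA


@dataclass(frozen=True)
class SensitivityResult:
    """First-activation pressures (mmHg, magnitudes) and their
    calibrator/test ratio."""

    p_first_test: float
    p_first_calibrator: float
    ratio: float


def lowpass(
    x: np.ndarray, sample_rate: float, cutoff: float = 500.0, order: int = 4
) -> np.ndarray:
    """Zero-phase 4-pole Bessel-equivalent lowpass."""
    if cutoff >= 0.49 * sample_rate:
        return np.asarray(x, dtype=float)
    sos = bessel(order, cutoff, fs=sample_rate, output="sos")
    return sosfiltfilt(sos, x)


def _noise_sd(x: np.ndarray) -> float:
    """Robust noise estimate from first differences (MAD-based)."""
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def amplitude_modes(
    x: np.ndarray,
    bandwidth: float | None = None,
    min_height_fraction: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Modes of the current-amplitude density (kernel-density estimate on a
    fine histogram).  Returns (levels, densities) sorted by level."""
    if bandwidth is None:
        bandwidth = max(0.5, _noise_sd(x))
    lo, hi = float(x.min()), float(x.max())
    bin_width = min(0.1, bandwidth / 5.0)
    edges = np.arange(lo - 3 * bandwidth, hi + 3 * bandwidth + bin_width, bin_width)
    hist, edges = np.histogram(x, bins=edges)
    density = gaussian_filter1d(hist.astype(float), bandwidth / bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    distance = max(1, int(round(4 * bandwidth / bin_width)))
    peaks, _ = find_peaks(
        density, height=min_height_fraction * density.max(), distance=distance
    )
    # Refine each mode to sub-bin precision by iterating the local centroid
    # (mean of samples within +/- 1.5 bandwidths); the fixed point is
    # independent of the histogram grid, so estimates are invariant under
    # sign flips and offsets of the trace.
    levels = []
    for p in peaks:
        c = centers[p]
        for _ in range(4):
            near = x[np.abs(x - c) <= 1.5 * bandwidth]
            if len(near) == 0:
                break
            c = float(near.mean())
        levels.append(float(c))
    return np.asarray(levels), density[peaks]


def _half_amplitude_events(
    xf: np.ndarray,
    baseline: float,
    open_level: float,
    min_duration_samples: int,
) -> list[tuple[int, int]]:
    """Contiguous sample ranges where the filtered trace is past the
    half-amplitude threshold toward the open level."""
    frac = (xf - baseline) / (open_level - baseline)
    above = frac > 0.5
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    return [
        (a, b) for a, b in zip(starts, ends) if (b - a) >= min_duration_samples
    ]


def estimate_unitary_conductance(
    r: Recording,
    filter_cutoff: float = 500.0,
    min_separation: float | None = None,
    min_event_duration: float = 1e-3,
) -> ConductanceEstimate:
    """Unitary conductance from the amplitude histogram.

    The baseline is the highest-density mode; the unitary open level is the
    mode nearest the baseline among those separated by more than
    ``min_separation`` pA (default 4x the noise SD), i.e. the *first*
    conductance step, so stacked multi-channel levels do not bias the
    estimate.  g = |open - baseline| / |V| converted to pS.  The standard
    error comes from per-event amplitudes of half-amplitude-idealized
    openings.
    """
    if r.voltage == 0:
        raise ValueError("conductance undefined at 0 mV")
    xf = lowpass(r.current, r.sample_rate, filter_cutoff)
    noise = _noise_sd(r.current)
    if min_separation is None:
        min_separation = 4.0 * max(noise, 0.25)
    levels, dens = amplitude_modes(xf)
    if len(levels) < 2:
        raise NoEventsError("current-amplitude histogram is unimodal")
    # Dominant mode is the baseline; among near-ties (within 20% density)
    # the level closest to zero current wins.
    contenders = levels[dens >= 0.8 * dens.max()]
    baseline = float(contenders[np.argmin(np.abs(contenders))])
    others = levels[np.abs(levels - baseline) > min_separation]
    if len(others) == 0:
        raise NoEventsError(
            "no amplitude mode separated from baseline; no resolvable openings"
        )
    open_level = float(others[np.argmin(np.abs(others - baseline))])
    step = open_level - baseline
    g_ns = abs(step) / abs(r.voltage)  # pA/mV = nS
    g_ps = 1000.0 * g_ns

    min_dur = max(1, int(round(min_event_duration * r.sample_rate)))
    events = _half_amplitude_events(xf, baseline, open_level, min_dur)
    # Per-event amplitudes from interior samples only: within one filter
    # settle time of a transition the filtered trace has not reached the
    # open level, which would bias short events low.
    margin = max(1, int(round(r.sample_rate / filter_cutoff)))
    g_events = []
    for a, b in events:
        if b - a <= 3 * margin:
            continue
        amp = np.mean(xf[a + margin : b - margin]) - baseline
        # Skip stacked openings (beyond ~1.5 unitary steps).
        if abs(amp) <= 1.5 * abs(step):
            g_events.append(1000.0 * abs(amp) / abs(r.voltage))
    n_events = max(len(g_events), 1)
    se = float(np.std(g_events, ddof=1) / np.sqrt(len(g_events))) if len(g_events) > 1 else float("nan")
    return ConductanceEstimate(
        g=float(g_ps),
        se=se,
        n_events=n_events,
        open_level=open_level,
        baseline=baseline,
    )


def amplitude_class_for(
    conductance_ps: float, voltage_mv: float, fraction: float = 0.3
) -> tuple[float, float]:
    """Amplitude band (pA, magnitudes) for events of a given conductance at
    the recording voltage: g*|V| widened by +/- ``fraction``."""
    amp = conductance_ps * abs(voltage_mv) / 1000.0  # pA
    return (amp * (1.0 - fraction), amp * (1.0 + fraction))


def _detect_steps(
    xf: np.ndarray, sample_rate: float, filter_cutoff: float, min_amplitude: float
) -> list[tuple[int, float]]:
    """Current steps (index, signed amplitude) from a two-sided moving
    difference with a settle window matched to the filter."""
    w = max(2, int(round(2.0 * sample_rate / filter_cutoff)))
    if len(xf) < 4 * w:
        raise NoActivationError("trace too short for step detection")
    d = np.empty_like(xf)
    d[:] = 0.0
    d[w:-w] = xf[2 * w :] - xf[: -2 * w]
    candidates = np.abs(d) >= 0.5 * min_amplitude
    edges = np.diff(candidates.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if candidates[0]:
        starts.insert(0, 0)
    if candidates[-1]:
        ends.append(len(candidates))
    steps = []
    for a, b in zip(starts, ends):
        idx = a + int(np.argmax(np.abs(d[a:b])))
        lo = max(0, idx - 3 * w)
        hi = min(len(xf), idx + 3 * w)
        before = np.median(xf[lo : max(lo + 1, idx - w)])
        after = np.median(xf[min(idx + w, hi - 1) : hi])
        steps.append((idx, float(after - before)))
    return steps


def first_activation_pressure(
    r: Recording,
    amplitude_class: tuple[float, float],
    filter_cutoff: float = 500.0,
    ramp_tolerance: float = 0.05,
) -> float:
    """Suction magnitude (mmHg) at the first opening in an amplitude class.

    Requires a monotone pressure ramp (within ``ramp_tolerance`` mmHg of
    backsliding).  Openings are current steps whose amplitude magnitude
    falls in ``amplitude_class`` (pA); the first one's pressure is returned.
    """
    p = np.abs(r.pressure)
    if np.any(np.maximum.accumulate(p) - p > ramp_tolerance):
        raise NoActivationError("pressure is not a monotone ramp")
    lo, hi = amplitude_class
    xf = lowpass(r.current, r.sample_rate, filter_cutoff)
    # Channel already open at the trace start: the initial level sits a full
    # class amplitude away from the closed level.  On a ramp the closed
    # level need not be the dominant mode (channels may spend most of the
    # trace open), so take the amplitude mode nearest zero current.
    levels, _ = amplitude_modes(xf)
    baseline = float(levels[np.argmin(np.abs(levels))])
    w = max(2, int(round(2.0 * r.sample_rate / filter_cutoff)))
    initial = float(np.median(xf[: 2 * w]))
    if lo <= abs(initial - baseline) <= hi:
        return float(p[0])
    steps = _detect_steps(xf, r.sample_rate, filter_cutoff, min_amplitude=lo)
    for idx, amp in steps:
        if lo <= abs(amp) <= hi:
            return float(p[idx])
    raise NoActivationError(
        f"no opening with amplitude in [{lo:.1f}, {hi:.1f}] pA on the ramp"
    )


def tension_sensitivity_ratio(
    r: Recording,
    test_class: tuple[float, float],
    calibrator_class: tuple[float, float],
    filter_cutoff: float = 500.0,
) -> SensitivityResult:
    """Calibrator/test first-activation pressure ratio (e.g. P_MscL/P_MscK).

    Higher ratio = higher tension sensitivity of the test channel relative
    to the in-patch calibrator.
    """
    p_test = first_activation_pressure(r, test_class, filter_cutoff)
    p_cal = first_activation_pressure(r, calibrator_class, filter_cutoff)
    return SensitivityResult(
        p_first_test=p_test,
        p_first_calibrator=p_cal,
        ratio=p_cal / p_test,
    )
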