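"""Membrane-tension gating energetics for curved-TMD channels.

Model
-----
A channel whose transmembrane domain is curved in the closed state bends the
surrounding membrane midplane into a cone (angle theta_c, in-plane radius
R_c); opening flattens it (theta_o < theta_c) and expands the in-plane
footprint by delta_A.  At lateral tension sigma the free-energy difference
between the flattened (open) and curved (closed) conformations is

    dG(sigma) = dG0 + dG_bending(sigma) - sigma * delta_A,

with the midplane-bending contribution approximated by

    dG_bending = pi * (theta_c^2 R_c - theta_o^2 R_o) * sqrt(sigma * K_b),

where K_b is the bilayer bending modulus (~20 kBT for a bacterial inner
membrane).  Setting dG = 0 with dG0 = 0 defines the midpoint tension
sigma_1/2 at which the open probability is 0.5; with the thin-annulus area
change delta_A = 2 pi R_c delta_R this has the closed form

    sigma_1/2 = (theta_c^2 R_c - theta_o^2 R_o)^2 K_b / (4 R_c^2 delta_R^2).

All energies are in units of kBT (so kB and T never appear separately),
tensions in kBT/nm^2 and lengths in nm.  The full open-probability curve is
the two-state Boltzmann completion P_open = 1 / (1 + exp(dG)).

Note on the sign structure: dG_bending grows like sqrt(sigma), so dG(sigma)
first rises from dG0 before the -sigma*delta_A term wins; with dG0 = 0 the
model has exactly one positive zero (the midpoint) and P_open dips slightly
below 1/2 at very low tension before rising.  This is a property of the
bending approximation, reported as-is rather than smoothed away.

Hydrophobic-mismatch contributions and the intrinsic conformational energy
dG0 are not part of the midpoint estimate (dG0 defaults to 0 and is an
explicit argument everywhere else).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import IncompleteDeltaError, MidpointError
from .geometry import StateDelta

#: 1 kBT/nm^2 in mN/m at T = 298 K (for reporting only; the model itself is
#: unit-free in kBT).
KBT_PER_NM2_IN_MN_PER_M = 4.114


def tension_to_mn_per_m(sigma_kbt_nm2: float) -> float:
    """Convert a tension from kBT/nm^2 to mN/m at 298 K."""
    return sigma_kbt_nm2 * KBT_PER_NM2_IN_MN_PER_M


@dataclass(frozen=True)
class GatingParameters:
    """Structural inputs of the gating model.

    theta_c, theta_o in radians; R_c, delta_R in nm; delta_A in nm^2
    (defaults to the thin-annulus value 2*pi*R_c*delta_R); K_b and dG0 in
    kBT.  ``R_o`` is derived as R_c + delta_R.
    """

    theta_c: float
    theta_o: float
    R_c: float
    delta_R: float
    delta_A: float | None = None
    K_b: float = 20.0
    dG0: float = 0.0

    def __post_init__(self):
        if not (self.theta_c >= self.theta_o >= 0.0):
            raise ValueError("require theta_c >= theta_o >= 0")
        if self.R_c <= 0 or self.K_b <= 0:
            raise ValueError("R_c and K_b must be positive")
        if self.delta_A is None:
            object.__setattr__(
                self, "delta_A", 2.0 * math.pi * self.R_c * self.delta_R
            )
        # delta_A == 0 (identical states) is representable but flagged
        # ill-posed; only a negative area change is rejected outright.
        if self.delta_A < 0:
            raise ValueError("delta_A must be non-negative")

    @property
    def R_o(self) -> float:
        return self.R_c + self.delta_R

    @property
    def shape_factor(self) -> float:
        """theta_c^2 R_c - theta_o^2 R_o (nm); must be positive for a
        well-posed midpoint."""
        return self.theta_c**2 * self.R_c - self.theta_o**2 * self.R_o

    @property
    def well_posed(self) -> bool:
        return self.shape_factor > 0 and self.delta_R > 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GatingParameters":
        return cls(**json.loads(text))


def mscK_parameters(K_b: float = 20.0, dG0: float = 0.0) -> GatingParameters:
    """Canonical MscK parameter set deduced from the closed/open structures.

    theta_c = pi/6, theta_o = pi/12, delta_A = 54 nm^2, delta_R = 1.1 nm
    (half the 22 A in-plane expansion), hence R_c = delta_A/(2 pi delta_R)
    ~ 7.813 nm, with K_b = 20 kBT.  Reproduces the midpoint tension
    0.16 kBT/nm^2.
    """
    delta_A = 54.0
    delta_R = 1.1
    return GatingParameters(
        theta_c=math.pi / 6.0,
        theta_o=math.pi / 12.0,
        R_c=delta_A / (2.0 * math.pi * delta_R),
        delta_R=delta_R,
        delta_A=delta_A,
        K_b=K_b,
        dG0=dG0,
    )


#: Literature midpoint tension of MscL (kBT/nm^2), for sensitivity comparisons.
MSCL_MIDPOINT_TENSION = 2.5


def _check_sigma(sigma) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("tension must be non-negative")
    return sigma


def bending_energy(gp: GatingParameters, sigma) -> np.ndarray | float:
    """Midplane-bending free-energy difference (kBT) at tension sigma.

    pi * (theta_c^2 R_c - theta_o^2 R_o) * sqrt(sigma * K_b); vectorized
    over sigma.
    """
    sigma = _check_sigma(sigma)
    out = math.pi * gp.shape_factor * np.sqrt(sigma * gp.K_b)
    return float(out) if out.ndim == 0 else out


def gating_energy(gp: GatingParameters, sigma, dG0: float | None = None):
    """Total open-minus-closed free energy (kBT):
    dG0 + bending - sigma * delta_A."""
    sigma = _check_sigma(sigma)
    if dG0 is None:
        dG0 = gp.dG0
    out = dG0 + bending_energy(gp, sigma) - sigma * gp.delta_A
    return float(out) if np.ndim(out) == 0 else out


def midpoint_tension_closed_form(gp: GatingParameters) -> float:
    """Closed-form midpoint tension (kBT/nm^2).

    (theta_c^2 R_c - theta_o^2 R_o)^2 K_b / (4 R_c^2 delta_R^2); valid for
    the thin-annulus area change.  dG0 is not part of the midpoint estimate.
    """
    x = gp.shape_factor
    if x <= 0 or gp.delta_R <= 0:
        raise MidpointError(
            f"no positive midpoint: shape factor {x:.4g} nm, delta_R {gp.delta_R:.4g} nm"
        )
    return x**2 * gp.K_b / (4.0 * gp.R_c**2 * gp.delta_R**2)


def midpoint_tension_root(gp: GatingParameters, rtol: float = 1e-10) -> float:
    """Midpoint tension as the unique positive root of
    pi*X*sqrt(sigma*K_b) - sigma*delta_A = 0, by bracketing bisection.

    Uses the structure's actual delta_A (which may deviate from the
    thin-annulus form); agrees with the closed form to ~1e-8 relative when
    delta_A = 2 pi R_c delta_R.
    """
    x = gp.shape_factor
    if x <= 0 or gp.delta_A <= 0:
        raise MidpointError(
            f"no positive midpoint: shape factor {x:.4g} nm, delta_A {gp.delta_A:.4g} nm^2"
        )
    c = math.pi * x * math.sqrt(gp.K_b)  # f(sigma) = c*sqrt(sigma) - sigma*dA
    sigma_star = (c / gp.delta_A) ** 2  # analytic root, used only to bracket
    lo, hi = sigma_star * 0.25, sigma_star * 4.0
    f = lambda s: c * math.sqrt(s) - s * gp.delta_A
    assert f(lo) > 0 and f(hi) < 0
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def open_probability(gp: GatingParameters, sigma, dG0: float | None = None):
    """Two-state Boltzmann open probability P = 1 / (1 + exp(dG(sigma))).

    Exactly 0.5 at the midpoint tension when dG0 = 0.
    """
    dg = gating_energy(gp, sigma, dG0)
    out = 1.0 / (1.0 + np.exp(np.clip(dg, -700, 700)))
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class EnergeticsCurve:
    """Tension sweep: bending and total energies (kBT) and open probability
    on a sigma grid (kBT/nm^2), plus the midpoint tension."""

    sigma_grid: np.ndarray
    dG_bending: np.ndarray
    dG_total: np.ndarray
    P_open: np.ndarray
    sigma_half: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sigma_kBT_per_nm2": self.sigma_grid,
                "dG_bending_kBT": self.dG_bending,
                "dG_total_kBT": self.dG_total,
                "P_open": self.P_open,
            }
        )


def energetics_curve(
    gp: GatingParameters,
    sigma_max: float | None = None,
    n_points: int = 201,
    dG0: float | None = None,
) -> EnergeticsCurve:
    """Sweep tension from 0 to ``sigma_max`` (default 3x the midpoint)."""
    sigma_half = midpoint_tension_closed_form(gp)
    if sigma_max is None:
        sigma_max = 3.0 * sigma_half
    grid = np.linspace(0.0, sigma_max, n_points)
    return EnergeticsCurve(
        sigma_grid=grid,
        dG_bending=bending_energy(gp, grid),
        dG_total=gating_energy(gp, grid, dG0),
        P_open=open_probability(gp, grid, dG0),
        sigma_half=sigma_half,
    )


def params_from_states(
    delta: StateDelta, K_b: float = 20.0, dG0: float = 0.0
) -> GatingParameters:
    """Build :class:`GatingParameters` from measured closed/open geometry.

    The StateDelta already carries model units (radians, nm, nm^2); this
    validates completeness and attaches K_b and dG0.  The measured delta_A
    is kept as-is, so the root-found midpoint uses the true area change
    while the closed form uses the thin-annulus geometry.
    """
    for name in ("theta_c", "theta_o", "R_c", "delta_R", "delta_A"):
        value = getattr(delta, name, None)
        if value is None or not np.isfinite(value):
            raise IncompleteDeltaError(f"StateDelta field {name!r} missing")
    return GatingParameters(
        theta_c=delta.theta_c,
        theta_o=delta.theta_o,
        R_c=delta.R_c,
        delta_R=delta.delta_R,
        delta_A=delta.delta_A,
        K_b=K_b,
        dG0=dG0,
    )
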