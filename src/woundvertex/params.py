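"""Model parameters in a canonical {nN, um, s} unit system.

Published parameter tables for this class of model mix hours and seconds
(rates in hr^-1, speeds in um/hr, the timestep in s) and quote forces in uN
and moduli in kPa.  Everything here is converted once, at construction time,
to nanonewtons, micrometres and seconds:

    1 uN  = 1e3 nN
    1 kPa = 1 nN um^-2  (1 Pa = 1e-3 nN um^-2)
    1 hr  = 3600 s

Consistency check on the defaults: mu * v0 = 7.2e3 * 10/3600 = 20 nN, the
bulk self-propulsion force scale.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields, replace

HR = 3600.0  # seconds per hour

__all__ = ["ModelParams", "ConfigurationError", "convert_value", "HR"]


class ConfigurationError(ValueError):
    """Invalid or inconsistent model configuration."""


# unit suffix -> multiplicative factor into {nN, um, s}
_UNIT_FACTORS = {
    "/hr": 1.0 / HR,
    "/s": 1.0,
    "um/hr": 1.0 / HR,
    "um/s": 1.0,
    "un": 1e3,  # uN -> nN
    "nn": 1.0,
    "kpa": 1.0,  # kPa -> nN/um^2
    "pa": 1e-3,
    "um": 1.0,
    "s": 1.0,
    "hr": HR,
}


def convert_value(value) -> float:
    """Convert a number or a ``"<number><unit>"`` string to canonical units.

    Examples: ``"4/hr"`` -> 1.111e-3 (s^-1), ``"2uN"`` -> 2000.0 (nN),
    ``"4kPa"`` -> 4.0 (nN um^-2).
    """
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip().replace(" ", "")
    m = re.fullmatch(r"([-+0-9.eE]+)(.*)", s)
    if not m:
        raise ConfigurationError(f"cannot parse value {value!r}")
    num, unit = float(m.group(1)), m.group(2).lower()
    if not unit:
        return num
    if unit not in _UNIT_FACTORS:
        raise ConfigurationError(f"unknown unit suffix {m.group(2)!r} in {value!r}")
    return num * _UNIT_FACTORS[unit]


@dataclass
class ModelParams:
    """All model parameters, canonical {nN, um, s} units.

    Defaults are the published table of default values for the wound-healing
    model (after unit conversion).  Derived read-only quantities: ``gamma``
    (interfacial tension of the expanded energy form), ``p0`` (target shape
    index), ``k_s`` (substrate spring constant).
    """

    # --- cell mechanics ---
    K: float = 0.2            # area elastic modulus, nN um^-3
    A0: float = 100.0         # preferred area, um^2
    P0: float = 36.0          # preferred perimeter, um
    Gamma: float = 20.0       # contractility, nN um^-1
    L_star: float = 1.0       # T1 threshold edge length, um

    # --- motility ---
    f_p: float = 2000.0       # protrusion force, nN (2 uN)
    v0: float = 10.0 / HR     # internal motility speed, um s^-1 (10 um/hr)
    D_r: float = 5.0 / HR     # rotational diffusion, s^-1 (5 /hr)
    gamma_ps: float = 300.0   # purse-string line tension, nN
    k_p: float = 4.0 / HR     # crawl -> purse-string switching rate, s^-1
    kappa_star: float = 0.05  # curvature threshold for curvature sensing, um^-1
    curvature_sensing: bool = False

    # --- substrate ---
    rho: float = 0.6          # substrate node density, um^-2
    E_s: float = 4.0          # substrate Young's modulus, nN um^-2 (4 kPa)
    h_s: float = 5.0          # substrate thickness, um
    mu: float = 7.2e3         # friction, nN s um^-1
    substrate_margin: float = 20.0  # pinned-boundary margin beyond tissue, um

    # --- adhesion ---
    k_f: float = 80.0         # focal adhesion stiffness, nN um^-1
    k_on: float = 500.0 / HR  # binding rate, s^-1
    k_off: float = 25.0 / HR  # unbinding rate, s^-1
    catch_bond: bool = False
    catch_sign: int = 1       # +1: catch convention (second exponent +f/f1); -1: as-printed slip form
    k0: float = 25.0 / HR     # catch-bond pathway rates, s^-1
    k1: float = 0.006 / HR
    f0: float = 3125.0        # catch-bond force scales, nN (3.125 uN)
    f1: float = 694.4         # nN (0.6944 uN)

    # --- numerics / engine ---
    dt: float = 3.6           # timestep, s
    L_max: float = 2.0        # edge refinement upper bound, um
    L_min: float = 0.5        # edge refinement lower bound, um
    t1_enabled: bool = True
    A_close: float = 1.0      # wound-closure area threshold, um^2
    t_max: float = 5.0 * HR   # simulation cutoff, s
    snapshot_every: float = 60.0  # snapshot cadence, s

    # --- fixture defaults ---
    n_cells: int = 150
    wound_radius: float = 15.0  # um
    wound_aspect: float = 1.0

    def __post_init__(self):
        self.validate()

    # derived quantities -------------------------------------------------
    @property
    def gamma(self) -> float:
        """Interfacial tension of the expanded energy form: gamma = -2*Gamma*P0 (nN)."""
        return -2.0 * self.Gamma * self.P0

    @property
    def p0(self) -> float:
        """Target dimensionless shape index P0/sqrt(A0)."""
        return self.P0 / math.sqrt(self.A0)

    @property
    def k_s(self) -> float:
        """Substrate spring constant sqrt(3)*E_s*h_s/2 (nN um^-1)."""
        return math.sqrt(3.0) * self.E_s * self.h_s / 2.0

    @property
    def node_spacing(self) -> float:
        """Triangular-lattice spacing for node density rho (um)."""
        return math.sqrt(2.0 / (math.sqrt(3.0) * self.rho))

    @property
    def capture_radius(self) -> float:
        """Maximum vertex-to-node distance for adhesion binding (um)."""
        return 2.0 * self.node_spacing

    @property
    def protrusion_delta(self) -> float:
        """Forward bias of protrusive adhesion binding at the wound edge (um)."""
        return self.node_spacing

    # construction / validation ------------------------------------------
    def validate(self) -> None:
        nonneg = ("K", "A0", "Gamma", "L_star", "f_p", "v0", "D_r", "gamma_ps",
                  "k_p", "rho", "E_s", "h_s", "mu", "k_f", "k_on", "k_off",
                  "k0", "k1", "f0", "f1", "A_close")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.rho <= 0 or self.h_s <= 0:
            raise ConfigurationError("rho and h_s must be positive")
        if self.L_max <= 2.0 * self.L_min:
            raise ConfigurationError(
                f"edge refinement requires L_max > 2*L_min, got L_max={self.L_max}, L_min={self.L_min}")
        if self.catch_sign not in (-1, 1):
            raise ConfigurationError("catch_sign must be +1 or -1")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        """Build parameters from a plain dict; unknown keys are rejected,
        values may carry unit suffixes (e.g. ``{"k_p": "4/hr"}``)."""
        valid = {f.name: f for f in fields(cls)}
        kwargs = {}
        for key, value in d.items():
            if key not in valid:
                raise ConfigurationError(f"unknown parameter key {key!r}")
            if valid[key].type in ("bool",) or isinstance(valid[key].default, bool):
                kwargs[key] = bool(value)
            elif isinstance(valid[key].default, int) and not isinstance(valid[key].default, bool):
                kwargs[key] = int(convert_value(value))
            else:
                kwargs[key] = convert_value(value)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)


def myosin_purse_string_tension(f_motor: float = 3e-3, n_motors: float = 1e5) -> float:
    """Order-of-magnitude purse-string tension from myosin numbers.

    A contractile actomyosin ring of ~15 um length and ~1 um thickness carries
    on the order of 1e5 myosin motors, each generating ~3 pN (= 3e-3 nN), which
    sets the cable line tension used as the model default.

    Returns tension in nN.
    """
    return f_motor * n_motors
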