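"""Physical and dimensionless parameters of the outer-hair-cell amplifier model.

An outer hair cell (OHC) is described here as N two-state piezoelectric
motors embedded in the lateral membrane (each contributing a length change
``a`` and a transmembrane charge movement ``q``), loaded by its own stiffness
``ko``, an external (basilar-membrane) spring ``Ke``, a drag ``eta`` and a
mass fixed by the mechanical resonance frequency.  The membrane electrical
circuit is an RC loop (capacitance ``C0``, steady conductance ``sigma``)
carrying a standing transducer current ``i0``; the hair bundle closes the
feedback loop by modulating its conductance in proportion to displacement
(sensitivity ``gx``).

Every frequency-domain equation of the model consumes a handful of
dimensionless groups derived from these SI quantities; :func:`derive_groups`
computes them.  Sign conventions are canonical throughout: ``q < 0`` and
``a > 0`` (depolarization shrinks the cell) and the closed-loop gain
``g = -|a N (1 - Kbar_e) gx|`` is negative so that cell shortening increases
the transducer current (the amplifying configuration).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PhysicalConstants",
    "MotorElement",
    "MembraneCircuit",
    "MechanicalSystem",
    "HairBundleCoupling",
    "OHCParameters",
    "DerivedGroups",
    "InvalidParameterError",
    "derive_groups",
    "steady_state_current",
    "stiffness_from_modulus",
    "motor_count_from_capacitance",
    "drag_from_subtectorial_geometry",
    "guinea_pig_4khz",
    "figure_mode_groups",
    "random_scenario",
    "load_scenario",
    "export_json",
]

#: kB*T at T = 300 K, in joules.  Chosen so that the dimensionless gating
#: groups computed from the guinea-pig fixture reproduce their reference
#: values; configurable per scenario.
KBT_300K = 4.142e-21
#: Elementary charge in coulombs (2 s.f. convention used by the fixture).
E_CHARGE = 1.6e-19


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates a physical invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermal energy scale and elementary charge."""

    kBT: float = KBT_300K  # J
    e_charge: float = E_CHARGE  # C

    def __post_init__(self) -> None:
        _require(self.kBT > 0, "kBT must be positive")
        _require(self.e_charge > 0, "e_charge must be positive")

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/kBT (1/J)."""
        return 1.0 / self.kBT


@dataclass(frozen=True)
class MotorElement:
    """Population of two-state piezoelectric motors in the lateral wall.

    Parameters
    ----------
    q : float
        Charge moved across the membrane per motor on the S->L transition (C).
        Negative: depolarization favours the short state.
    a : float
        Length contributed per motor in the long state (m). Positive.
    N : float
        Number of motors in the cell.
    P0 : float
        Resting open (long-state) fraction, in [0, 1].  The operating-point
        activity gamma = 4 P0 (1 - P0) is maximal (1) at P0 = 0.5.
    """

    q: float
    a: float
    N: float
    P0: float = 0.5

    def __post_init__(self) -> None:
        _require(self.q < 0, "motor charge q must be negative (canonical sign)")
        _require(self.a > 0, "motor displacement a must be positive")
        _require(self.N >= 1, "motor count N must be >= 1")
        _require(0.0 <= self.P0 <= 1.0, "resting open fraction P0 must lie in [0, 1]")

    @property
    def gamma(self) -> float:
        """Operating-point activity 4 P0 (1 - P0), in [0, 1]."""
        return 4.0 * self.P0 * (1.0 - self.P0)


@dataclass(frozen=True)
class MembraneCircuit:
    """Membrane RC circuit with a standing transducer current.

    Either supply ``i0``/``sigma`` directly (as the guinea-pig fixture does)
    or give enough of (V0, eK, Rm) / (eep, eK, R0, Rm) for
    :func:`steady_state_current` and ``sigma = 1/R0 + 1/Rm`` to be derived.
    """

    C0: float  # structural capacitance, F
    sigma: float | None = None  # steady-state conductance, S
    i0: float | None = None  # steady-state (baseline) current, A
    Rm: float | None = None  # basolateral resistance, Ohm
    R0: float | None = None  # resting hair-bundle resistance, Ohm
    eep: float | None = None  # endocochlear potential, V
    eK: float | None = None  # basolateral reversal potential, V
    V0: float | None = None  # resting membrane potential, V

    def __post_init__(self) -> None:
        # C0 = 0 is the degenerate resistance-dominated circuit that defines
        # the low-frequency approximation; it then needs sigma > 0.
        _require(self.C0 >= 0, "capacitance C0 must be non-negative")
        if self.sigma is None:
            sig = 0.0
            if self.R0:
                sig += 1.0 / self.R0
            if self.Rm:
                sig += 1.0 / self.Rm
            _require(sig > 0, "sigma not given and no resistances to derive it from")
            object.__setattr__(self, "sigma", sig)
        _require(self.sigma >= 0, "conductance sigma must be non-negative")
        if self.i0 is None:
            object.__setattr__(self, "i0", steady_state_current(self))
        _require(self.i0 >= 0, "baseline current i0 must be non-negative")
        _require(self.C0 > 0 or self.sigma > 0,
                 "C0 = 0 requires a conducting membrane (sigma > 0)")


def steady_state_current(circuit: MembraneCircuit) -> float:
    """Standing transducer current i0 through the membrane at rest (A).

    Two documented modes:

    * resting-potential mode (preferred when ``V0`` is given):
      ``i0 = (V0 - eK) / Rm`` — the current that holds the resting potential
      V0 above the basolateral reversal potential eK across Rm;
    * divider mode: ``i0 = (eep - eK) / (R0 + Rm)`` — the endocochlear
      potential driving the series bundle + basolateral resistances.
    """
    c = circuit
    if c.V0 is not None and c.eK is not None and c.Rm:
        return (c.V0 - c.eK) / c.Rm
    if c.eep is not None and c.eK is not None and c.R0 and c.Rm:
        return (c.eep - c.eK) / (c.R0 + c.Rm)
    raise InvalidParameterError(
        "steady_state_current needs (V0, eK, Rm) or (eep, eK, R0, Rm)"
    )


Connectivity = Literal["series", "parallel"]


@dataclass(frozen=True)
class MechanicalSystem:
    """Mechanical load: springs, drag, and a mass set by the resonance frequency.

    The mass is never specified directly; the model is parameterized by the
    resonance frequency, ``m = (ko + Ke) / omega_r**2`` with
    ``omega_r = 2 pi fr``.
    """

    ko: float  # OHC stiffness, N/m
    Ke: float  # external (basilar-membrane) stiffness, N/m
    eta: float  # drag coefficient, N s/m
    fr: float  # mechanical resonance frequency, Hz
    connectivity: Connectivity = "series"

    def __post_init__(self) -> None:
        _require(self.ko > 0, "OHC stiffness ko must be positive")
        _require(self.Ke >= 0, "external stiffness Ke must be non-negative")
        _require(self.eta > 0, "drag coefficient eta must be positive")
        _require(self.fr > 0, "resonance frequency fr must be positive")
        _require(self.connectivity in ("series", "parallel"), "unknown connectivity")

    @property
    def omega_r(self) -> float:
        """Angular resonance frequency 2 pi fr (rad/s)."""
        return 2.0 * math.pi * self.fr

    @property
    def m(self) -> float:
        """Mass (ko + Ke) / omega_r**2 (kg)."""
        return (self.ko + self.Ke) / self.omega_r**2


@dataclass(frozen=True)
class HairBundleCoupling:
    """Hair-bundle transduction feedback.

    ``gx`` is the magnitude of the bundle-resistance sensitivity to
    displacement (1/m).  The dimensionless closed-loop gain defaults to the
    amplifying sign, ``g = -|a N (1 - Kbar_e) gx|`` (negative, because q < 0);
    set ``amplifying=False`` to flip it and explore the non-amplifying case,
    or supply ``g`` explicitly to bypass the derivation.
    """

    gx: float  # 1/m, magnitude
    amplifying: bool = True
    g: float | None = None  # explicit dimensionless gain override

    def __post_init__(self) -> None:
        _require(self.gx >= 0, "gx is stored as a magnitude; use 'amplifying' for sign")


@dataclass(frozen=True)
class OHCParameters:
    """Complete physical description of one OHC plus its load."""

    motor: MotorElement
    circuit: MembraneCircuit
    mech: MechanicalSystem
    bundle: HairBundleCoupling
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    name: str = "unnamed"

    @property
    def gain(self) -> float:
        """Signed closed-loop feedback gain g (dimensionless)."""
        if self.bundle.g is not None:
            return self.bundle.g
        kbar_e = self.mech.Ke / (self.mech.ko + self.mech.Ke)
        mag = abs(self.motor.a * self.motor.N * (1.0 - kbar_e) * self.bundle.gx)
        return -mag if self.bundle.amplifying else mag


@dataclass(frozen=True)
class DerivedGroups:
    """Dimensionless groups every frequency-domain equation consumes.

    Attributes
    ----------
    ua : float
        Gating-compliance parameter ``beta a^2 N ko / 4``; measures how
        strongly external force biases the motors.
    Kbar_e : float
        Impedance-mismatch factor ``Ke / (ko + Ke)`` in [0, 1).
    alpha_c : float
        External-force transmission factor: 1 for series connectivity,
        ``1 - Kbar_e`` for parallel.
    omega_bar_eta : float
        Viscoelastic roll-off frequency ``(ko + Ke)/eta`` over ``omega_r``.
    omega_bar_m : float
        Membrane RC crossover ``sigma / C0`` over ``omega_r``.
    g : float
        Signed closed-loop hair-bundle gain ``a N (1 - Kbar_e) gx``.
    ah1 : float
        Bundle-feedback anti-damping strength
        ``beta q i0 g / (4 omega_r C0)`` (positive when amplifying).
    bh2 : float
        Strain-induced-polarization stiffness ``beta N q^2 / (4 C0)``.
    """

    ua: float
    Kbar_e: float
    alpha_c: float
    omega_bar_eta: float
    omega_bar_m: float
    g: float = 0.0
    ah1: float = 0.0
    bh2: float = 0.0
    beta: float = 1.0 / KBT_300K

    def __post_init__(self) -> None:
        _require(self.ua >= 0, "ua must be non-negative")
        _require(0.0 <= self.Kbar_e < 1.0, "Kbar_e must lie in [0, 1)")
        _require(self.omega_bar_eta > 0, "omega_bar_eta must be positive")
        _require(self.omega_bar_m >= 0, "omega_bar_m must be non-negative")

    def replace(self, **kw) -> "DerivedGroups":
        """Return a copy with some fields overridden (e.g. figure-mode omega_bar_eta)."""
        return dataclasses.replace(self, **kw)


def derive_groups(params: OHCParameters) -> DerivedGroups:
    """Compute all dimensionless groups of a physical parameter set.

    Pure and deterministic.  The ``/4`` in ``ua`` and in ``ah1``/``bh2``
    comes from the first-order expansion of the two-state Boltzmann function,
    whose slope at the operating point carries a factor 1/4.
    """
    m, c, me = params.motor, params.circuit, params.mech
    beta = params.constants.beta
    _require(me.ko + me.Ke > 0, "ko + Ke must be positive")
    wr = me.omega_r
    kbar_e = me.Ke / (me.ko + me.Ke)
    g = params.gain
    if c.C0 > 0:
        omega_bar_m = c.sigma / (wr * c.C0)
        ah1 = beta * m.q * c.i0 * g / (4.0 * wr * c.C0)
        bh2 = beta * m.N * m.q**2 / (4.0 * c.C0)
    else:  # resistance-dominated degenerate circuit (low-frequency limit)
        omega_bar_m = math.inf
        ah1 = math.inf
        bh2 = math.inf
    return DerivedGroups(
        ua=beta * m.a**2 * m.N * me.ko / 4.0,
        Kbar_e=kbar_e,
        alpha_c=1.0 if me.connectivity == "series" else 1.0 - kbar_e,
        omega_bar_eta=(me.ko + me.Ke) / me.eta / wr,
        omega_bar_m=omega_bar_m,
        g=g,
        ah1=ah1,
        bh2=bh2,
        beta=beta,
    )


# ---------------------------------------------------------------------------
# Parameter derivations from morphological / electrical measurements
# ---------------------------------------------------------------------------

def stiffness_from_modulus(modulus: float, exposed_length: float) -> float:
    """Axial stiffness (N/m) of the exposed cell body.

    ``modulus`` is the elastic modulus expressed as force per unit strain (N);
    dividing by the exposed length converts strain to displacement.
    """
    _require(exposed_length > 0, "exposed length must be positive")
    _require(modulus >= 0, "modulus must be non-negative")
    return modulus / exposed_length


def motor_count_from_capacitance(
    peak_excess_capacitance: float,
    q: float,
    kBT: float = KBT_300K,
    sig_figs: int | None = None,
) -> float:
    """Motor count N from the peak excess (nonlinear) capacitance.

    The voltage-dependent charge movement of N two-state motors contributes a
    bell-shaped excess capacitance peaking at ``beta q^2 N / 4``; solving for
    N gives ``N = 4 Cpeak kBT / q^2``.  ``sig_figs`` optionally rounds the
    result to that many significant figures.
    """
    _require(q != 0, "motor charge q must be non-zero")
    _require(peak_excess_capacitance > 0 and kBT > 0, "inputs must be positive")
    n = 4.0 * peak_excess_capacitance * kBT / q**2
    if sig_figs is not None:
        exp = math.floor(math.log10(n))
        n = round(n, -exp + sig_figs - 1)
    return n


def drag_from_subtectorial_geometry(
    gap_area: float, gap_height: float, viscosity: float
) -> float:
    """Shear drag coefficient (N s/m) of the subtectorial gap.

    Plane-shear estimate ``eta = viscosity * S / d`` for a gap of area ``S``
    and height ``d`` (the tallest stereocilia row).
    """
    _require(gap_height > 0, "gap height must be positive")
    _require(gap_area >= 0 and viscosity >= 0, "area and viscosity must be non-negative")
    return viscosity * gap_area / gap_height


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def guinea_pig_4khz() -> OHCParameters:
    """Reference scenario: a 40 um guinea-pig OHC at the 4 kHz place.

    All values are the standard published set for this location: motor charge
    0.8 e, unit displacement 0.67e-4 nm, 3e7 motors, 30 pF capacitance, 10 nS
    conductance, 0.3 nA standing current (resting potential -50 mV over a
    -80 mV reversal through 100 MOhm), 17 mN/m cell stiffness, 20 mN/m
    basilar-membrane stiffness per OHC, bundle sensitivity 1/(25 nm), drag
    0.8e-7 N s/m, resonance 4 kHz.
    """
    return OHCParameters(
        motor=MotorElement(q=-0.8 * E_CHARGE, a=0.67e-13, N=3e7, P0=0.5),
        circuit=MembraneCircuit(
            C0=30e-12, sigma=10e-9, Rm=100e6, V0=-50e-3, eK=-80e-3
        ),
        mech=MechanicalSystem(
            ko=17e-3, Ke=20e-3, eta=0.8e-7, fr=4000.0, connectivity="series"
        ),
        bundle=HairBundleCoupling(gx=1.0 / 25e-9),
        name="guinea-pig-4khz",
    )


#: Normalized viscoelastic roll-off frequency used by the reference plots.
#: The SI-derived value for the guinea-pig fixture is (ko+Ke)/eta/omega_r
#: ~= 18.4, but the reference frequency-response curves were generated with
#: omega_eta/omega_r = 10; figure mode pins that value.
FIGURE_MODE_OMEGA_BAR_ETA = 10.0


def figure_mode_groups() -> DerivedGroups:
    """Dimensionless groups used by the reference frequency-response plots.

    Table values of the guinea-pig fixture, with the roll-off frequency
    pinned at ``omega_bar_eta = 10`` and unit external-force transmission
    (``alpha_c = 1``, series).
    """
    gr = derive_groups(guinea_pig_4khz())
    return gr.replace(omega_bar_eta=FIGURE_MODE_OMEGA_BAR_ETA, alpha_c=1.0)


def random_scenario(seed: int) -> OHCParameters:
    """Physically valid randomized scenario for property tests.

    Each Table-value parameter is drawn log-uniformly from a one-decade-wide
    band centred on the guinea-pig fixture (factor 10**U(-1/2, 1/2)), with a
    random connectivity.  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    ref = guinea_pig_4khz()

    def jitter(x: float) -> float:
        return x * 10.0 ** rng.uniform(-0.5, 0.5)

    return OHCParameters(
        motor=MotorElement(
            q=-abs(jitter(ref.motor.q)), a=jitter(ref.motor.a), N=jitter(ref.motor.N)
        ),
        circuit=MembraneCircuit(
            C0=jitter(ref.circuit.C0),
            sigma=jitter(ref.circuit.sigma),
            i0=jitter(ref.circuit.i0),
        ),
        mech=MechanicalSystem(
            ko=jitter(ref.mech.ko),
            Ke=jitter(ref.mech.Ke),
            eta=jitter(ref.mech.eta),
            fr=jitter(ref.mech.fr),
            connectivity=str(rng.choice(["series", "parallel"])),
        ),
        bundle=HairBundleCoupling(gx=jitter(ref.bundle.gx)),
        name=f"random-{seed}",
    )


# ---------------------------------------------------------------------------
# Scenario I/O
# ---------------------------------------------------------------------------

_PHYSICAL_KEYS = {"q", "a", "N", "P0", "C0", "sigma", "i0", "Rm", "R0", "eep",
                  "eK", "V0", "ko", "Ke", "eta", "fr", "connectivity", "gx",
                  "amplifying", "kBT"}
_DIMENSIONLESS_KEYS = {"ua", "Kbar_e", "alpha_c", "omega_bar_eta",
                       "omega_bar_m", "g", "ah1", "bh2", "beta"}

UNITS = {
    "q": "C", "a": "m", "N": "", "P0": "", "C0": "F", "sigma": "S", "i0": "A",
    "Rm": "Ohm", "R0": "Ohm", "eep": "V", "eK": "V", "V0": "V", "ko": "N/m",
    "Ke": "N/m", "eta": "N s/m", "fr": "Hz", "gx": "1/m", "kBT": "J",
}


def load_scenario(path: str | Path) -> OHCParameters | DerivedGroups:
    """Load a YAML scenario file.

    The file holds up to two top-level blocks, ``physical:`` (SI floats, see
    :data:`UNITS` for the unit of each key) and ``dimensionless:`` (direct
    dimensionless groups).  If only ``physical`` is present an
    :class:`OHCParameters` is returned; if ``dimensionless`` is present the
    groups win (a warning is logged when both blocks are given) and a
    :class:`DerivedGroups` is returned, with any missing group filled in from
    the physical block when possible.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or not ({"physical", "dimensionless"} & doc.keys()):
        raise InvalidParameterError(
            f"{path}: expected top-level 'physical:' and/or 'dimensionless:' blocks"
        )
    phys = doc.get("physical") or {}
    dim = doc.get("dimensionless") or {}
    for k in phys:
        _require(k in _PHYSICAL_KEYS, f"unknown physical key {k!r}")
    for k in dim:
        _require(k in _DIMENSIONLESS_KEYS, f"unknown dimensionless key {k!r}")

    params = _params_from_dict(phys) if phys else None
    if not dim:
        return params
    if phys:
        logger.warning(
            "%s: both physical and dimensionless blocks given; "
            "dimensionless values take precedence", path
        )
        base = dataclasses.asdict(derive_groups(params))
        base.update(dim)
        return DerivedGroups(**base)
    defaults = {"alpha_c": 1.0, "omega_bar_m": 0.0}
    defaults.update(dim)
    return DerivedGroups(**defaults)


def _params_from_dict(d: dict) -> OHCParameters:
    d = dict(d)
    constants = PhysicalConstants(kBT=d.pop("kBT", KBT_300K))
    motor = MotorElement(
        q=d.pop("q"), a=d.pop("a"), N=d.pop("N"), P0=d.pop("P0", 0.5)
    )
    circuit = MembraneCircuit(
        C0=d.pop("C0"),
        **{k: d.pop(k) for k in ("sigma", "i0", "Rm", "R0", "eep", "eK", "V0") if k in d},
    )
    mech = MechanicalSystem(
        ko=d.pop("ko"), Ke=d.pop("Ke"), eta=d.pop("eta"), fr=d.pop("fr"),
        connectivity=d.pop("connectivity", "series"),
    )
    bundle = HairBundleCoupling(gx=d.pop("gx"), amplifying=d.pop("amplifying", True))
    return OHCParameters(motor=motor, circuit=circuit, mech=mech, bundle=bundle,
                         constants=constants)


def export_json(params: OHCParameters | None, groups: DerivedGroups,
                path: str | Path | None = None) -> dict:
    """Flat JSON export of a parameter set and its dimensionless groups."""
    out: dict = {"units": dict(UNITS)}
    if params is not None:
        out.update({
            "name": params.name,
            "q": params.motor.q, "a": params.motor.a, "N": params.motor.N,
            "P0": params.motor.P0, "gamma0": params.motor.gamma,
            "C0": params.circuit.C0, "sigma": params.circuit.sigma,
            "i0": params.circuit.i0,
            "ko": params.mech.ko, "Ke": params.mech.Ke, "eta": params.mech.eta,
            "fr": params.mech.fr, "m": params.mech.m,
            "connectivity": params.mech.connectivity,
            "gx": params.bundle.gx, "kBT": params.constants.kBT,
        })
    else:
        out["name"] = "dimensionless"
    out["groups"] = {k: v for k, v in dataclasses.asdict(groups).items()}
    if path is not None:
        Path(path).write_text(json.dumps(out, indent=2))
    return out
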