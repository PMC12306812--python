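"""Closed-form high- and low-frequency approximations of the closed loop.

Above the membrane crossover frequency (omega >> sigma/C0) the capacitive
conductance dominates and expanding 1/(sigma + i omega C0) to first order in
sigma/(i omega C0) collapses the electrical feedback into an anti-damping
factor Ah and a stiffness factor Bh:

    [ -wb^2 + i (wb/wbar_eta - gamma Ah / wb) + 1 + gamma Bh(wb) ] p
        = (1 + alpha_c gamma ua) fbar

    Ah      = ah1 - bh2 * wbar_m
    Bh(wb)  = -ua Kbar_e + bh2 + ah1 * wbar_m / wb^2

with ah1 = beta q i0 g / (4 omega_r C0) (bundle-feedback strength) and
bh2 = beta N q^2 / (4 C0) (strain-induced polarization stiffness).  The
wb-dependent third summand of Bh carries the small factor sigma/(omega C0)
and is ignorable away from the low edge of the validity region.

Below the crossover the capacitance is simply nullified (C0 -> 0), giving a
damping factor Al = bh2/wbar_m = beta omega_r N q^2 / (4 sigma) and a
stiffness factor Bl = -ua Kbar_e + ah1/wbar_m: at low frequencies the roles
reverse — strain-induced polarization produces drag, and bundle
sensitivity stiffens the cell.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .params import DerivedGroups, InvalidParameterError, OHCParameters, derive_groups
from .response import ComplexResponse, FrequencyGrid

__all__ = [
    "HFCoefficients",
    "LFCoefficients",
    "hf_coefficients",
    "hf_response",
    "lf_coefficients",
    "lf_response",
    "gating_compliance",
    "effectiveness_gap",
    "required_anti_damping",
    "strain_stiffness_toggle",
]

#: hf_response warns below this reduced frequency (figure-mode threshold).
HF_VALIDITY_THRESHOLD = 0.3


@dataclass(frozen=True)
class HFCoefficients:
    """Anti-damping factor Ah and stiffness factor Bh with their summands.

    ``ah = ah_term1 - ah_term2`` where ``ah_term1`` is the hair-bundle
    feedback gain and ``ah_term2 = bh2 * wbar_m`` the conductance correction.
    ``bh_at(wb) = bh_term1 + bh_term2 + bh_term3_at(wb)`` where
    ``bh_term1 = -ua Kbar_e`` (gating compliance, <= 0), ``bh_term2`` the
    strain-induced polarization stiffness (> 0) and the third summand the
    small sigma-dependent correction (dropped when ``include_sigma_correction``
    is False).  The scalar :attr:`bh` excludes the third summand.
    """

    ah_term1: float
    ah_term2: float
    bh_term1: float
    bh_term2: float
    _term3_scale: float  # ah_term1 * wbar_m; bh_term3_at(wb) = scale / wb^2
    include_sigma_correction: bool = True

    @property
    def ah(self) -> float:
        return self.ah_term1 - self.ah_term2

    @property
    def bh(self) -> float:
        """Scalar stiffness factor (wb-independent summands only)."""
        return self.bh_term1 + self.bh_term2

    def bh_term3_at(self, omega_bar) -> np.ndarray | float:
        wb = np.asarray(omega_bar, dtype=float)
        t3 = self._term3_scale / wb**2 if self.include_sigma_correction else wb * 0.0
        return t3 if t3.ndim else float(t3)

    def bh_at(self, omega_bar) -> np.ndarray | float:
        return self.bh_term1 + self.bh_term2 + self.bh_term3_at(omega_bar)


@dataclass(frozen=True)
class LFCoefficients:
    """Damping factor Al and stiffness factor Bl of the C0 -> 0 limit."""

    al: float
    bl_term1: float  # -ua Kbar_e (gating compliance)
    bl_term2: float  # beta g i0 q / (4 sigma); positive for amplifying signs

    @property
    def bl(self) -> float:
        return self.bl_term1 + self.bl_term2


def _as_groups(model: OHCParameters | DerivedGroups) -> DerivedGroups:
    return model if isinstance(model, DerivedGroups) else derive_groups(model)


def hf_coefficients(
    model: OHCParameters | DerivedGroups, include_sigma_correction: bool = True
) -> HFCoefficients:
    """High-frequency coefficients from a physical or dimensionless scenario.

    The conductance summand of Ah uses the total motile charge N q
    (``ah_term2 = (beta |q| / (4 omega_r C0)) sigma N |q| / C0
    = bh2 * wbar_m``), the reading consistent with the first-order expansion
    of the exact equation.
    """
    gr = _as_groups(model)
    return HFCoefficients(
        ah_term1=gr.ah1,
        ah_term2=gr.bh2 * gr.omega_bar_m,
        bh_term1=-gr.ua * gr.Kbar_e,
        bh_term2=gr.bh2,
        _term3_scale=gr.ah1 * gr.omega_bar_m,
        include_sigma_correction=include_sigma_correction,
    )


def nullify_conductance(coeffs: HFCoefficients) -> HFCoefficients:
    """Coefficients with the membrane conductance removed (sigma = 0).

    Zeroes both sigma-carrying summands (Ah's conductance correction and
    Bh's third term); used for the conductance-free reference curves.
    """
    return dataclasses.replace(coeffs, ah_term2=0.0, _term3_scale=0.0)


def strain_stiffness_toggle(coeffs: HFCoefficients, enabled: bool = True) -> HFCoefficients:
    """Return coefficients with the strain-induced polarization stiffness
    (the second summand of Bh) zeroed when ``enabled`` is False."""
    return coeffs if enabled else dataclasses.replace(coeffs, bh_term2=0.0)


def hf_response(
    coeffs: HFCoefficients,
    groups: DerivedGroups,
    gamma: float,
    grid: FrequencyGrid,
    *,
    f_bar: float = 1.0,
) -> ComplexResponse:
    """High-frequency approximate response on a grid.

    Singular at wb = 0 (the anti-damping term carries 1/wb); warns when
    evaluated below the validity threshold wb < 0.3 but still computes, as
    the reference curves do.
    """
    if not 0.0 <= gamma <= 1.0:
        raise InvalidParameterError("gamma must lie in [0, 1]")
    wb = grid.omega_bar
    if np.any(wb == 0):
        raise InvalidParameterError("hf_response is singular at omega_bar = 0")
    if wb[0] < HF_VALIDITY_THRESHOLD * (1.0 - 1e-9):
        warnings.warn(
            f"hf_response evaluated below omega_bar = {HF_VALIDITY_THRESHOLD}; "
            "the expansion parameter sigma/(omega C0) is no longer small",
            stacklevel=2,
        )
    # Same summation order as the exact denominator so that gamma = 0
    # reproduces the passive resonator bit for bit.
    denom = -wb**2 + 1j * wb / groups.omega_bar_eta + 1.0 \
        - 1j * gamma * coeffs.ah / wb + gamma * coeffs.bh_at(wb)
    rhs = (1.0 + groups.alpha_c * gamma * groups.ua) * f_bar
    p = rhs / denom

    def evaluator(wb1: float) -> complex:
        return rhs / (-wb1**2 + 1j * wb1 / groups.omega_bar_eta + 1.0
                      - 1j * gamma * coeffs.ah / wb1 + gamma * coeffs.bh_at(wb1))

    return ComplexResponse(grid=grid, p=p, gamma=gamma, model_tag="hf",
                           f_bar=f_bar, evaluator=evaluator)


def lf_coefficients(model: OHCParameters | DerivedGroups) -> LFCoefficients:
    """Low-frequency coefficients; requires a conducting membrane (sigma > 0).

    From SI parameters, ``Al = beta omega_r N q^2 / (4 sigma)`` and
    ``Bl_term2 = beta g i0 q / (4 sigma)`` directly (well defined even for
    the degenerate C0 = 0 circuit); from dimensionless groups, the
    equivalent ``bh2 / wbar_m`` and ``ah1 / wbar_m``.
    """
    if isinstance(model, OHCParameters):
        mo, ci, me = model.motor, model.circuit, model.mech
        if ci.sigma <= 0:
            raise InvalidParameterError("lf_coefficients requires sigma > 0")
        beta = model.constants.beta
        gr = derive_groups(model)
        return LFCoefficients(
            al=beta * me.omega_r * mo.N * mo.q**2 / (4.0 * ci.sigma),
            bl_term1=-gr.ua * gr.Kbar_e,
            bl_term2=beta * model.gain * ci.i0 * mo.q / (4.0 * ci.sigma),
        )
    gr = model
    if not 0.0 < gr.omega_bar_m < float("inf"):
        raise InvalidParameterError(
            "lf_coefficients from groups requires finite omega_bar_m > 0"
        )
    return LFCoefficients(
        al=gr.bh2 / gr.omega_bar_m,
        bl_term1=-gr.ua * gr.Kbar_e,
        bl_term2=gr.ah1 / gr.omega_bar_m,
    )


def lf_response(
    coeffs: LFCoefficients,
    groups: DerivedGroups,
    gamma: float,
    grid: FrequencyGrid,
    *,
    f_bar: float = 1.0,
) -> ComplexResponse:
    """Low-frequency approximate response (the C0 -> 0 limit of the exact loop).

    Warns above wbar_m / 3, where the nullified capacitance is no longer
    negligible, but still computes.
    """
    if not 0.0 <= gamma <= 1.0:
        raise InvalidParameterError("gamma must lie in [0, 1]")
    wb = grid.omega_bar
    if groups.omega_bar_m > 0 and wb[-1] > groups.omega_bar_m / 3.0:
        warnings.warn(
            "lf_response evaluated above omega_bar_m / 3; the C0 -> 0 "
            "approximation degrades there", stacklevel=2,
        )
    denom = -wb**2 + 1j * wb * (1.0 / groups.omega_bar_eta + gamma * coeffs.al) \
        + 1.0 + gamma * coeffs.bl
    rhs = (1.0 + groups.alpha_c * gamma * groups.ua) * f_bar
    p = rhs / denom

    def evaluator(wb1: float) -> complex:
        return rhs / (-wb1**2 + 1j * wb1 * (1.0 / groups.omega_bar_eta + gamma * coeffs.al)
                      + 1.0 + gamma * coeffs.bl)

    return ComplexResponse(grid=grid, p=p, gamma=gamma, model_tag="lf",
                           f_bar=f_bar, evaluator=evaluator)


def gating_compliance(params: OHCParameters, gamma: float) -> float:
    """Zero-frequency compliance x/Fext (m/N) of the isolated, voltage-clamped cell.

    With no external load (Kbar_e = 0, alpha_c = 1) and the membrane
    potential held fixed, the closed loop reduces to
    ``x / Fext = (1 + gamma ua) / ko``: the motors soften the cell the same
    way gating compliance softens the hair bundle, maximally at P0 = 0.5.
    """
    if not 0.0 <= gamma <= 1.0:
        raise InvalidParameterError("gamma must lie in [0, 1]")
    ko = params.mech.ko
    if ko == 0:
        raise InvalidParameterError("ko must be non-zero")
    ua = params.constants.beta * params.motor.a**2 * params.motor.N * ko / 4.0
    return (1.0 + gamma * ua) / ko


def required_anti_damping(coeffs: HFCoefficients, groups: DerivedGroups) -> float:
    """Anti-damping (1 + Bh) / wbar_eta needed to null net drag at resonance."""
    return (1.0 + coeffs.bh) / groups.omega_bar_eta


def effectiveness_gap(coeffs: HFCoefficients, groups: DerivedGroups) -> float:
    """Signed amplifier-effectiveness gap Ah - (1 + Bh)/wbar_eta.

    Evaluated at the shifted resonance wb^2 = 1 + Bh (where Ah is constant, the
    evaluation point only fixes which Bh enters).  A non-negative gap means
    the bundle-driven anti-damping can null the net damping at resonance at
    gamma = 1; exposed as a signed quantity so sweeps can locate the failure
    point as load or frequency grows.
    """
    return coeffs.ah - required_anti_damping(coeffs, groups)
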