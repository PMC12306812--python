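"""Exact closed-loop frequency response of the OHC–load system.

The cell is a forced damped oscillator in the motor-fraction amplitude ``p``
(the small sinusoidal deviation of the open fraction of the motors), coupled
to the membrane RC circuit through piezoelectric reciprocity and closed by
the hair-bundle feedback ``r_hat = g p``.  Per reduced frequency
``wb = omega/omega_r`` the response solves a single complex linear equation

    [ -wb^2 + i wb / wbar_eta + 1 - gamma ua Kbar_e
      + gamma (ah1 + i wb bh2) / (wbar_m + i wb) ] p = (1 + alpha_c gamma ua) fbar

where the last left-hand term is the electrical feedback
``(beta gamma q / 4) (i omega N q + i0 g) / (sigma + i omega C0)`` written in
dimensionless groups.  The time convention is exp(+i omega t); phases are
reported as unwrapped arg(p) along the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .params import DerivedGroups, InvalidParameterError, OHCParameters, derive_groups

__all__ = [
    "FrequencyGrid",
    "ComplexResponse",
    "closed_loop_denominator",
    "exact_response",
    "pure_piezo_response",
    "voltage_response",
]

ModelTag = Literal["exact", "hf", "lf", "piezo"]


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of reduced frequencies omega/omega_r (> 0)."""

    omega_bar: np.ndarray
    spacing: Literal["log", "linear"] = "log"

    def __post_init__(self) -> None:
        wb = np.asarray(self.omega_bar, dtype=float)
        object.__setattr__(self, "omega_bar", wb)
        if wb.ndim != 1 or wb.size == 0:
            raise InvalidParameterError("frequency grid must be a non-empty 1-D array")
        if not np.all(wb > 0):
            raise InvalidParameterError("all reduced frequencies must be positive")
        if not np.all(np.diff(wb) > 0):
            raise InvalidParameterError("frequency grid must be strictly increasing")

    @classmethod
    def log(cls, lo: float, hi: float, n: int = 400) -> "FrequencyGrid":
        return cls(np.logspace(np.log10(lo), np.log10(hi), n), "log")

    @classmethod
    def linear(cls, lo: float, hi: float, n: int = 400) -> "FrequencyGrid":
        return cls(np.linspace(lo, hi, n), "linear")

    def __len__(self) -> int:
        return len(self.omega_bar)


#: Default high-frequency figure grid: 400 log-spaced points on [0.3, 3].
def hf_grid(n: int = 400) -> FrequencyGrid:
    return FrequencyGrid.log(0.3, 3.0, n)


#: Default low-frequency figure grid: 400 log-spaced points on [1e-3, 1e-1].
def lf_grid(n: int = 400) -> FrequencyGrid:
    return FrequencyGrid.log(1e-3, 1e-1, n)


@dataclass
class ComplexResponse:
    """Complex amplitudes on a frequency grid, with amplitude/phase views.

    ``p`` is the motor-fraction amplitude per unit dimensionless drive fbar
    (the external force divided by a N ko).  ``x`` is the displacement in
    metres per unit fbar (``x = a N (1 - Kbar_e) p``) and ``v`` the membrane
    potential amplitude in volts per unit fbar; both are None when the
    response was computed from dimensionless groups alone.
    """

    grid: FrequencyGrid
    p: np.ndarray
    gamma: float
    model_tag: ModelTag = "exact"
    x: np.ndarray | None = None
    v: np.ndarray | None = None
    f_bar: float = 1.0
    #: optional continuous evaluator wb -> complex p, used for peak refinement
    evaluator: Callable[[float], complex] | None = field(default=None, repr=False)

    @property
    def omega_bar(self) -> np.ndarray:
        return self.grid.omega_bar

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.p)

    @property
    def phase(self) -> np.ndarray:
        """Unwrapped arg(p) along the grid, first point in (-pi, pi]."""
        return np.unwrap(np.angle(self.p))

    def to_dataframe(self) -> pd.DataFrame:
        def amp_phase(z):
            if z is None:
                nan = np.full(len(self.grid), np.nan)
                return nan, nan
            return np.abs(z), np.unwrap(np.angle(z))

        amp_x, ph_x = amp_phase(self.x)
        amp_v, ph_v = amp_phase(self.v)
        return pd.DataFrame({
            "omega_bar": self.omega_bar,
            "gamma": self.gamma,
            "model": self.model_tag,
            "amp_p": self.amplitude,
            "phase_p_rad": self.phase,
            "amp_x_m": amp_x,
            "phase_x_rad": ph_x,
            "amp_v_V": amp_v,
            "phase_v_rad": ph_v,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _as_groups(model: OHCParameters | DerivedGroups) -> DerivedGroups:
    return model if isinstance(model, DerivedGroups) else derive_groups(model)


def closed_loop_denominator(
    groups: DerivedGroups, gamma: float, omega_bar, *, g_scale: float = 1.0
):
    """Left-hand coefficient of the closed-loop equation at each frequency.

    ``g_scale`` scales the hair-bundle feedback gain (0 removes the
    mechanotransducer, giving the pure piezoelectric system).  Built so that
    every gamma-dependent term carries an explicit factor gamma: at gamma = 0
    the passive resonator coefficient is recovered exactly.
    """
    wb = np.asarray(omega_bar, dtype=float)
    if groups.omega_bar_eta == 0:
        raise InvalidParameterError("omega_bar_eta must be non-zero")
    if groups.omega_bar_m == 0 and np.any(wb == 0):
        raise InvalidParameterError("sigma = 0 and omega = 0 simultaneously")
    elec = gamma * (g_scale * groups.ah1 + 1j * wb * groups.bh2) / (
        groups.omega_bar_m + 1j * wb
    )
    return -wb**2 + 1j * wb / groups.omega_bar_eta + 1.0 \
        - gamma * groups.ua * groups.Kbar_e + elec


def exact_response(
    model: OHCParameters | DerivedGroups,
    gamma: float,
    grid: FrequencyGrid,
    *,
    f_bar: float = 1.0,
    g_scale: float = 1.0,
    model_tag: ModelTag = "exact",
) -> ComplexResponse:
    """Exact closed-loop response p(wb) (and x, v when SI parameters are known).

    With an :class:`OHCParameters` input the electrical term is evaluated in
    SI, ``(beta gamma q / 4)(i omega N q + i0 g)/(sigma + i omega C0)``, which
    remains well defined for the degenerate circuits C0 = 0 (the
    resistance-dominated limit) and sigma = 0; with a :class:`DerivedGroups`
    input the equivalent dimensionless form is used.
    """
    if not 0.0 <= gamma <= 1.0:
        raise InvalidParameterError("gamma must lie in [0, 1]")
    wb = grid.omega_bar

    if isinstance(model, OHCParameters):
        gr = derive_groups(model)
        mo, ci, me = model.motor, model.circuit, model.mech
        beta, g = model.constants.beta, model.gain * g_scale
        w = wb * me.omega_r
        zc = ci.sigma + 1j * w * ci.C0
        if np.any(zc == 0):
            raise InvalidParameterError("sigma + i omega C0 vanishes on the grid")
        elec = (beta * gamma * mo.q / 4.0) * (1j * w * mo.N * mo.q + ci.i0 * g) / zc
        denom = -wb**2 + 1j * wb / gr.omega_bar_eta + 1.0 \
            - gamma * gr.ua * gr.Kbar_e + elec
        rhs = (1.0 + gr.alpha_c * gamma * gr.ua) * f_bar
        p = rhs / denom
        x = mo.a * mo.N * (1.0 - gr.Kbar_e) * p
        v = -(ci.i0 * g + 1j * w * mo.N * mo.q) * p / zc

        def evaluator(wb1: float) -> complex:
            w1 = wb1 * me.omega_r
            zc1 = ci.sigma + 1j * w1 * ci.C0
            e1 = (beta * gamma * mo.q / 4.0) * (1j * w1 * mo.N * mo.q + ci.i0 * g) / zc1
            d1 = -wb1**2 + 1j * wb1 / gr.omega_bar_eta + 1.0 \
                - gamma * gr.ua * gr.Kbar_e + e1
            return rhs / d1

        return ComplexResponse(grid=grid, p=p, gamma=gamma, model_tag=model_tag,
                               x=x, v=v, f_bar=f_bar, evaluator=evaluator)

    gr = model
    denom = closed_loop_denominator(gr, gamma, wb, g_scale=g_scale)
    rhs = (1.0 + gr.alpha_c * gamma * gr.ua) * f_bar
    p = rhs / denom

    def evaluator(wb1: float) -> complex:
        return rhs / closed_loop_denominator(gr, gamma, wb1, g_scale=g_scale)

    return ComplexResponse(grid=grid, p=p, gamma=gamma, model_tag=model_tag,
                           f_bar=f_bar, evaluator=evaluator)


def pure_piezo_response(
    model: OHCParameters | DerivedGroups, gamma: float, grid: FrequencyGrid,
    *, f_bar: float = 1.0,
) -> ComplexResponse:
    """Response with the mechanotransducer removed (r_hat = 0, i.e. g = 0).

    Isolates pure piezoelectric resonance: the only gamma-dependent gain left
    is the gating-compliance factor on the drive, which cannot amplify
    because strain-induced polarization stiffness shifts the peak up and away
    from the mechanical resonance.
    """
    return exact_response(model, gamma, grid, f_bar=f_bar, g_scale=0.0,
                          model_tag="piezo")


def voltage_response(response: ComplexResponse, params: OHCParameters) -> np.ndarray:
    """Membrane-potential amplitude v(omega) = -(i0 g + i omega N q) p / (sigma + i omega C0).

    Recomputes v from a response's p using the circuit equation; volts per
    unit fbar.
    """
    mo, ci, me = params.motor, params.circuit, params.mech
    g = params.gain if response.model_tag != "piezo" else 0.0
    w = response.omega_bar * me.omega_r
    return -(ci.i0 * g + 1j * w * mo.N * mo.q) * response.p / (ci.sigma + 1j * w * ci.C0)
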