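"""Thermophysical properties and nonlinear source terms of the brain bioheat model.

The package solves the Pennes bioheat equation

    rho * Cp * dT/dt = div(kappa grad T) + rho_b * Cb * omega_b(T) * (Tb - T)
                       + Q_met(T) + Qv

for brain tissue around a cooled probe.  Cerebral blood perfusion and
metabolic heat generation are strong functions of the local tissue
temperature; both are modelled as exponentials fitted to in-vivo data:

    omega_b(T) = a_w * exp(b_w * T)      [1/s]
    Q_met(T)   = a_q * exp(b_q * T)      [W/m^3]

All temperatures in this package are degrees Celsius.  Evaluated at the
physiologic set point (37 degC) the defaults give omega_b ~ 8.9e-3 1/s and
Q_met ~ 9.9e3 W/m^3, i.e. realistic grey-matter magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import NoEquilibriumError, PhysiologyWarning

#: Range over which the perfusion/metabolism exponentials are considered
#: physiologically supported.  Values outside trigger a PhysiologyWarning but
#: are never clamped.
VALID_RANGE = (0.0, 45.0)


@dataclass(frozen=True)
class TissueProperties:
    """Homogeneous brain-tissue coefficients of the bioheat equation.

    Parameters
    ----------
    density : float
        Tissue density rho, kg/m^3.
    specific_heat : float
        Specific heat capacity Cp, J/(kg K).
    thermal_conductivity : float
        kappa, W/(m K).
    perfusion_coeff, perfusion_exp : float
        a_w (1/s) and b_w (1/degC) of omega_b(T) = a_w * exp(b_w * T).
    metabolic_coeff, metabolic_exp : float
        a_q (W/m^3) and b_q (1/degC) of Q_met(T) = a_q * exp(b_q * T).
        ``metabolic_coeff`` may be zero (metabolism switched off).
    """

    density: float = 1040.0
    specific_heat: float = 3250.0
    thermal_conductivity: float = 0.51
    perfusion_coeff: float = 0.0012
    perfusion_exp: float = 0.054
    metabolic_coeff: float = 342.45
    metabolic_exp: float = 0.091

    def __post_init__(self) -> None:
        for name in ("density", "specific_heat", "thermal_conductivity",
                     "perfusion_coeff", "perfusion_exp", "metabolic_exp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"TissueProperties.{name} must be strictly positive")
        if self.metabolic_coeff < 0:
            raise ValueError("TissueProperties.metabolic_coeff must be non-negative")

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * Cp, J/(m^3 K)."""
        return self.density * self.specific_heat


@dataclass(frozen=True)
class BloodProperties:
    """Arterial blood parameters of the perfusion heat-exchange term.

    The arterial temperature Tb defaults to 0.3 degC below the core
    temperature (37 degC), accounting for convective heat loss along the
    cerebral vasculature.
    """

    density: float = 1050.0
    specific_heat: float = 3600.0
    core_temperature: float = 37.0
    arterial_temperature: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0 or self.specific_heat <= 0:
            raise ValueError("blood density and specific heat must be positive")
        if self.arterial_temperature is None:
            object.__setattr__(self, "arterial_temperature",
                               self.core_temperature - 0.3)

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho_b * Cb, J/(m^3 K)."""
        return self.density * self.specific_heat


@dataclass(frozen=True)
class SourceTerms:
    """Evaluated volumetric source terms of the bioheat equation (W/m^3).

    ``perfusion_sink`` is rho_b*Cb*omega_b(T)*(T - Tb): positive where tissue
    is warmer than arterial blood (heat removed), negative where colder (the
    perfusion term rewarms cooled tissue).
    """

    volumetric_source: float = 0.0
    perfusion_sink: float | np.ndarray = 0.0
    metabolic_source: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.volumetric_source):
            raise ValueError("volumetric_source must be finite")


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    lo, hi = VALID_RANGE
    if np.any((T < lo) | (T > hi)):
        warnings.warn(
            f"temperature outside the fitted range {VALID_RANGE} degC; the "
            "perfusion/metabolism exponentials are extrapolations there",
            PhysiologyWarning, stacklevel=3)
    return T


def perfusion_rate(T, tissue: TissueProperties | None = None):
    """Temperature-dependent cerebral blood perfusion omega_b(T), 1/s.

    Strictly increasing in T: cooled tissue is progressively less perfused,
    which is what lets a cold probe's influence spread beyond the purely
    conductive penetration length.
    """
    tissue = tissue or TissueProperties()
    T = _check_temperature(T)
    out = tissue.perfusion_coeff * np.exp(tissue.perfusion_exp * T)
    return float(out) if out.ndim == 0 else out


def metabolic_rate(T, tissue: TissueProperties | None = None):
    """Temperature-dependent metabolic heat generation Q_met(T), W/m^3."""
    tissue = tissue or TissueProperties()
    T = _check_temperature(T)
    out = tissue.metabolic_coeff * np.exp(tissue.metabolic_exp * T)
    return float(out) if out.ndim == 0 else out


def source_terms(T, tissue: TissueProperties | None = None,
                 blood: BloodProperties | None = None,
                 volumetric_source: float = 0.0) -> SourceTerms:
    """Evaluate all volumetric source terms of the bioheat equation at T."""
    tissue = tissue or TissueProperties()
    blood = blood or BloodProperties()
    T = _check_temperature(T)
    sink = blood.volumetric_heat_capacity * perfusion_rate(T, tissue) \
        * (T - blood.arterial_temperature)
    return SourceTerms(volumetric_source=volumetric_source,
                       perfusion_sink=sink,
                       metabolic_source=metabolic_rate(T, tissue))


def equilibrium_temperature(tissue: TissueProperties | None = None,
                            blood: BloodProperties | None = None,
                            volumetric_source: float = 0.0,
                            bracket: tuple[float, float] = VALID_RANGE,
                            tol: float = 1e-6) -> float:
    """Far-field tissue temperature where perfusion exactly balances metabolism.

    Solves rho_b*Cb*omega_b(T)*(T - Tb) = Q_met(T) + Qv for T.  With default
    parameters the offset Q_met/(rho_b*Cb*omega_b) is about 0.3 degC above the
    arterial temperature, i.e. T* ~ 37.0 degC, consistent with a thermally
    autoregulated brain.

    Raises
    ------
    NoEquilibriumError
        If no root exists inside ``bracket``.
    """
    tissue = tissue or TissueProperties()
    blood = blood or BloodProperties()
    if tissue.metabolic_coeff == 0 and volumetric_source == 0:
        return float(blood.arterial_temperature)

    def balance(T: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PhysiologyWarning)
            sink = blood.volumetric_heat_capacity * perfusion_rate(T, tissue) \
                * (T - blood.arterial_temperature)
            return sink - metabolic_rate(T, tissue) - volumetric_source

    lo, hi = bracket
    if balance(lo) * balance(hi) > 0:
        raise NoEquilibriumError(
            f"perfusion-metabolism balance has no root in [{lo}, {hi}] degC")
    return float(brentq(balance, lo, hi, xtol=tol))
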