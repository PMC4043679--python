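"""Hydrodynamic sizing from solution diffusion coefficients.

FCS yields the diffusion coefficient D of a fluorescent species in
solution.  Two routes to a hydrodynamic radius R_H:

* *relative* calibration against a size standard measured in the same
  buffer — R_H = R_H(standard) · D(standard) / D(sample), which cancels
  temperature and viscosity; the reference standard here is Alexa488-
  labeled mouse IgG1 with R_H = 5.6 ± 0.2 nm;
* *absolute* conversion through the Stokes–Einstein relation
  D = k_B·T / (6π·η·R_H), with η = 1.04 cP at T = 293 K for the reference
  borate/BSA buffer.

Uncertainties are propagated to first order (relative errors add in
quadrature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: CODATA Boltzmann constant, J/K.
K_BOLTZMANN = 1.380649e-23
CENTIPOISE_TO_PA_S = 1e-3


@dataclass(frozen=True)
class SizingStandard:
    """A calibration species of known hydrodynamic radius (nm)."""

    name: str
    R_H: float            # nm
    uncertainty: float = 0.0   # nm

    def __post_init__(self) -> None:
        if self.R_H <= 0:
            raise ValueError("R_H must be > 0")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


#: Alexa488-labeled mouse IgG1, the reference size standard.
MS_IGG1 = SizingStandard("Ms IgG1", R_H=5.6, uncertainty=0.2)


@dataclass(frozen=True)
class SolutionConditions:
    """Buffer temperature (K) and dynamic viscosity (Pa·s)."""

    temperature: float = 293.0
    viscosity: float = 1.04 * CENTIPOISE_TO_PA_S

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.viscosity <= 0:
            raise ValueError("temperature and viscosity must be > 0")

    @classmethod
    def from_centipoise(cls, temperature: float,
                        viscosity_cp: float) -> "SolutionConditions":
        return cls(temperature, viscosity_cp * CENTIPOISE_TO_PA_S)


def relative_radius(
    D_sample: float,
    D_standard: float,
    standard: SizingStandard = MS_IGG1,
    D_sample_err: float = 0.0,
    D_standard_err: float = 0.0,
) -> tuple[float, float]:
    """Hydrodynamic radius by relative calibration, in nm.

    R_H = R_H(standard) · D_standard / D_sample, valid when both D values
    were measured under identical buffer conditions.  Returns (R_H, first-
    order propagated uncertainty).
    """
    if D_sample <= 0 or D_standard <= 0:
        raise ValueError("diffusion coefficients must be > 0")
    r = standard.R_H * D_standard / D_sample
    rel = np.sqrt(
        (standard.uncertainty / standard.R_H) ** 2
        + (D_standard_err / D_standard) ** 2
        + (D_sample_err / D_sample) ** 2
    )
    return float(r), float(r * rel)


def stokes_einstein_radius(
    D: float, cond: SolutionConditions = SolutionConditions()
) -> float:
    """Hydrodynamic radius (nm) of a sphere diffusing at D (µm²/s)."""
    if D <= 0:
        raise ValueError("D must be > 0")
    D_si = D * 1e-12                    # µm²/s -> m²/s
    r_m = K_BOLTZMANN * cond.temperature / (6.0 * np.pi * cond.viscosity
                                            * D_si)
    return float(r_m * 1e9)


def stokes_einstein_D(
    R_H: float, cond: SolutionConditions = SolutionConditions()
) -> float:
    """Diffusion coefficient (µm²/s) of a sphere of radius R_H (nm)."""
    if R_H <= 0:
        raise ValueError("R_H must be > 0")
    r_m = R_H * 1e-9
    D_si = K_BOLTZMANN * cond.temperature / (6.0 * np.pi * cond.viscosity
                                             * r_m)
    return float(D_si * 1e12)
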