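"""Seawater oxygen solubility.

Dissolved-oxygen optodes report %air-saturation; converting a DO decline into
an oxygen mass consumed requires the air-saturated O2 concentration of the
water at the measured temperature and salinity.  We evaluate the García &
Gordon (1992) combined fit to the Benson & Krause solubility data, the
standard choice in respirometry software, and convert mL(STP) L⁻¹ to mg L⁻¹
with the real-gas molar volume of O2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["WaterConditions", "o2_solubility"]

# García & Gordon (1992) combined Benson-Krause fit, mL(STP) L^-1 units.
_A = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_C0 = -4.88682e-7

# mg O2 per mL(STP): molar mass 31.9988 g/mol over molar volume 22.3916 L/mol
_MG_PER_ML = 31.9988 / 22.3916


@dataclass(frozen=True)
class WaterConditions:
    """Temperature (°C), salinity (practical) and pressure (atm) of the water."""

    temperature: float
    salinity: float
    pressure: float = 1.0

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise ValueError(
                f"temperature {self.temperature} °C outside the solubility "
                "fit's validity range [-2, 40]"
            )
        if not (0.0 <= self.salinity <= 42.0):
            raise ValueError(
                f"salinity {self.salinity} outside the solubility fit's "
                "validity range [0, 42]"
            )
        if self.pressure <= 0:
            raise ValueError("pressure must be positive")


def o2_solubility(conditions: WaterConditions) -> float:
    """Air-saturated O2 concentration in mg L⁻¹ at 100 %sat.

    Evaluates the scaled-temperature polynomial

        ln C* = Σ Aᵢ Tsⁱ + S Σ Bᵢ Tsⁱ + C0 S²,
        Ts = ln[(298.15 − t) / (273.15 + t)]

    with the combined-fit coefficients for mL(STP) L⁻¹, then converts to
    mg L⁻¹.  Pressure is assumed to be 1 atm (moist-air equilibrium); the
    `pressure` field scales the result linearly, adequate for the near-surface
    tanks this package targets.
    """
    t, s = conditions.temperature, conditions.salinity
    ts = math.log((298.15 - t) / (273.15 + t))
    ln_c = sum(a * ts**i for i, a in enumerate(_A))
    ln_c += s * sum(b * ts**i for i, b in enumerate(_B))
    ln_c += _C0 * s * s
    return math.exp(ln_c) * _MG_PER_ML * conditions.pressure
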