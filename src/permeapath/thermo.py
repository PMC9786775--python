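"""Thermodynamic state shared by all estimators.

Internal unit system throughout the package: length nm, time ps,
energy kJ/mol, temperature K.  The molar gas constant in these units is
R = 0.0083145 kJ mol⁻¹ K⁻¹; all Boltzmann factors are computed from it,
never from hidden conversions.
"""

from dataclasses import dataclass

from .errors import ValidationError

GAS_CONSTANT = 0.0083145  # kJ mol^-1 K^-1

#: Skin-physiological temperature (32 °C) used as the package default.
DEFAULT_TEMPERATURE = 305.0


@dataclass(frozen=True)
class ThermoState:
    """Temperature and gas constant bundle.

    Attributes
    ----------
    temperature:
        Absolute temperature in K (default 305 K, physiological skin).
    gas_constant:
        R in kJ mol⁻¹ K⁻¹.
    """

    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.gas_constant > 0:
            raise ValidationError("gas constant must be positive")

    @property
    def rt(self) -> float:
        """R·T in kJ/mol."""
        return self.gas_constant * self.temperature

    @property
    def beta(self) -> float:
        """1/(R·T) in mol/kJ."""
        return 1.0 / self.rt
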