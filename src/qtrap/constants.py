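"""Physical constants and unit helpers.

Internal units throughout the package are fixed: energies in kcal/mol,
distances in Å, times in ns, temperatures in K.  Quantities reported in
thermal units (kT) are always derived from these via ``kt(temperature)``.
"""

from __future__ import annotations

#: Boltzmann constant in kcal/mol/K.
KB: float = 0.0019872041

#: Simulation temperature used throughout the study (K).
DEFAULT_TEMPERATURE: float = 310.0

#: "Room temperature" used when quoting barriers in kT (K).
ROOM_TEMPERATURE: float = 298.0

#: The alchemical coupling-parameter schedule: 11 λ values defining the
#: 10 windows of the dual-topology A→T transformation.
LAMBDA_SCHEDULE: tuple[float, ...] = (
    0.0, 0.03125, 0.0625, 0.125, 0.25, 0.5, 0.75, 0.875, 0.9375, 0.96875, 1.0
)


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in kcal/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature


def beta(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse thermal energy 1/(k_B·T) in mol/kcal."""
    return 1.0 / kt(temperature)
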