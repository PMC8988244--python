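"""Thermodynamic context: temperature, Boltzmann constant, standard state.

Units throughout the package: lengths in Å, energies in kcal/mol, angles in
radians, charges in elementary charge units e.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 0.0019872041

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_KCAL = 332.0637


def standard_volume(concentration: float = 1.0) -> float:
    """Volume per molecule (Å³) at the given concentration (mol/L).

    At the 1 mol/L standard state this is 10²⁷/N_A ≈ 1660.5 Å³ — the volume
    that gives the binding constant of a bimolecular association a defined
    free energy.

    Raises
    ------
    ValueError
        If ``concentration`` is not positive.
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    return 1e27 / (AVOGADRO * concentration)


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and derived thermodynamic quantities.

    Attributes
    ----------
    temperature : float
        Absolute temperature in K (default 300 K).
    kB : float
        Boltzmann constant in kcal/mol/K.
    standard_concentration : float
        Standard-state concentration in mol/L (default 1 mol/L).
    """

    temperature: float = 300.0
    kB: float = KB_KCAL
    standard_concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy kB·T in kcal/mol."""
        return self.kB * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(kB·T) in mol/kcal."""
        return 1.0 / self.kT

    @property
    def standard_volume(self) -> float:
        """Standard-state volume v° per molecule in Å³."""
        return standard_volume(self.standard_concentration)
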