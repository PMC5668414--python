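"""Reduced-unit conventions and physical conversions.

The simulation works in reduced units: the charged-bead diameter sigma is the
length unit and k_B*T the energy unit.  A single scalar, the physical bead
diameter ``sigma_nm``, connects reduced number densities to molar
concentrations.  The default sigma of 0.3 nm corresponds to a compact, high charge density
monomer (one backbone repeat of ~3 Angstrom carrying a full charge); with it,
water at 25 C (Bjerrum length 0.7114 nm) has a reduced Bjerrum length of
~2.37 sigma, a contact coupling at which oppositely charged chains robustly
complex and coacervate.
"""

from __future__ import annotations

from dataclasses import dataclass

AVOGADRO = 6.02214076e23  # 1/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)
ROOM_T = 298.15  # K
BJERRUM_WATER_NM = 0.7114  # Bjerrum length of water at 25 C


@dataclass(frozen=True)
class UnitSystem:
    """Maps reduced simulation units onto laboratory units.

    Parameters
    ----------
    sigma_nm : physical diameter of one bead in nm.
    """

    sigma_nm: float = 0.3

    @property
    def sigma_liters(self) -> float:
        """Volume of one cubic sigma in liters."""
        return (self.sigma_nm * 1e-8) ** 3  # (nm -> dm)**3

    @property
    def mM_per_reduced_density(self) -> float:
        """Concentration in mM corresponding to one particle per sigma^3."""
        return 1e3 / (AVOGADRO * self.sigma_liters)

    def density_to_mM(self, rho: float) -> float:
        """Reduced number density (per sigma^3) -> concentration in mM."""
        return rho * self.mM_per_reduced_density

    def mM_to_density(self, c_mM: float) -> float:
        """Concentration in mM -> reduced number density (per sigma^3)."""
        return c_mM / self.mM_per_reduced_density

    @property
    def bjerrum_reduced(self) -> float:
        """Bjerrum length of water at 25 C in sigma units."""
        return BJERRUM_WATER_NM / self.sigma_nm


DEFAULT_UNITS = UnitSystem()


def entropy_to_kJ_per_mol(s_over_kB: float, T: float = ROOM_T) -> float:
    """Convert an entropy in units of k_B (per particle/site) to T*S in kJ/mol."""
    return GAS_CONSTANT * T * s_over_kB / 1e3
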