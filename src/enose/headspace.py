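"""Theoretical headspace concentration of an evaporated liquid aliquot.

A liquid volume ``V_l`` (L) of a chemical with density ``D`` (kg/L) and
molecular weight ``MW`` (g/mol), fully evaporated inside a sealed container
of volume ``V_c`` (L), yields a molar gas-phase mixing ratio of

    C [ppm] = 1e6 * V_m * V_l * D / (V_c * MW)

with ``V_m`` the molar volume of an ideal gas (24.45 L/mol at 25 C and
1 atm).  Complete evaporation is assumed — no vapor-pressure saturation
check, no temperature correction.

``builtin_chemicals`` ships constants for the six chemicals used in the
characterization experiments (four solvents plus the two onion sour-skin
disease markers).  The 2-nonanone density is the standard reference value
(0.821 kg/L); see docs/methods.md for a note on its concentration table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

__all__ = [
    "ChemicalSpec",
    "HeadspaceSetup",
    "UnknownChemicalError",
    "concentration_ppm",
    "builtin_chemicals",
    "MOLAR_VOLUME_25C_L_PER_MOL",
]

#: Molar volume of an ideal gas at 25 C, 1 atm (L/mol).
MOLAR_VOLUME_25C_L_PER_MOL = 24.45


class UnknownChemicalError(KeyError):
    """Requested chemical is not in the builtin constants table."""


@dataclass(frozen=True)
class ChemicalSpec:
    """Constants of one chemical: molecular weight (g/mol), density (kg/L)."""

    name: str
    molecular_weight_g_per_mol: float
    density_kg_per_L: float

    def __post_init__(self) -> None:
        if self.molecular_weight_g_per_mol <= 0:
            raise ValueError("molecular_weight_g_per_mol must be > 0")
        if self.density_kg_per_L <= 0:
            raise ValueError("density_kg_per_L must be > 0")


@dataclass(frozen=True)
class HeadspaceSetup:
    """Geometry of the evaporation jar: liquid aliquot and container volume."""

    liquid_volume_L: float
    container_volume_L: float = 0.5
    molar_volume_L_per_mol: float = MOLAR_VOLUME_25C_L_PER_MOL

    def __post_init__(self) -> None:
        if self.liquid_volume_L <= 0:
            raise ValueError("liquid_volume_L must be > 0")
        if self.container_volume_L <= 0:
            raise ValueError("container_volume_L must be > 0")
        if self.molar_volume_L_per_mol <= 0:
            raise ValueError("molar_volume_L_per_mol must be > 0")
        if self.liquid_volume_L >= self.container_volume_L:
            raise ValueError("liquid volume must be much smaller than the container")


def concentration_ppm(chem: ChemicalSpec, setup: HeadspaceSetup) -> float:
    """Headspace concentration in ppm (molar), unrounded.

    Linear in the liquid volume, inverse in the container volume.
    """
    density_g_per_L = chem.density_kg_per_L * 1000.0
    moles = setup.liquid_volume_L * density_g_per_L / chem.molecular_weight_g_per_mol
    vapor_L = moles * setup.molar_volume_L_per_mol
    return 1e6 * vapor_L / setup.container_volume_L


def builtin_chemicals() -> dict[str, ChemicalSpec]:
    """Constants table for the six characterization chemicals."""
    text = resources.files("enose.data").joinpath("chemicals.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    table: dict[str, ChemicalSpec] = {}
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        table[row["name"]] = ChemicalSpec(
            name=row["name"],
            molecular_weight_g_per_mol=float(row["molecular_weight_g_per_mol"]),
            density_kg_per_L=float(row["density_kg_per_L"]),
        )
    return table


def lookup_chemical(name: str) -> ChemicalSpec:
    """Builtin chemical by name; raises :class:`UnknownChemicalError`."""
    table = builtin_chemicals()
    try:
        return table[name]
    except KeyError:
        known = ", ".join(sorted(table))
        raise UnknownChemicalError(f"unknown chemical {name!r}; known: {known}") from None
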