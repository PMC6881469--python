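"""Fixed registries of the sensor array: bacteria, pollutants, groups, levels.

The array has three sensing channels (one bacterium each) and was
characterised against twelve pollutants spanning three chemical groups.
Concentrations are quantized to a five-level decade grid.  Pollutant order
matters: it defines the class enumeration behind the 6-bit codebook.
"""

from __future__ import annotations

from .errors import RegistryError

#: Sensing channels, in the column order used throughout (input order of the net).
BACTERIA: tuple[str, ...] = ("e_coli", "m_capsulatus", "s_oneidensis")

#: The twelve pollutants in codebook (table) order.
POLLUTANTS: tuple[str, ...] = (
    "Hg2+",
    "Pb2+",
    "Cd2+",
    "atrazine",
    "simazine",
    "DDVP",
    "hexane",
    "octane",
    "pentane",
    "toluene",
    "pyrene",
    "ethanol",
)

#: Quantized concentration grid (micromolar), one decade apart.
LEVELS_UM: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0)

#: Chemical groups in fixed (tie-break) order.
GROUPS: tuple[str, ...] = ("heavy_metals", "pesticides", "petrochemicals")

#: Pollutant -> group membership: 3 heavy metals, 3 pesticides, 6 petrochemicals.
POLLUTANT_GROUP: dict[str, str] = {
    "Hg2+": "heavy_metals",
    "Pb2+": "heavy_metals",
    "Cd2+": "heavy_metals",
    "atrazine": "pesticides",
    "simazine": "pesticides",
    "DDVP": "pesticides",
    "hexane": "petrochemicals",
    "octane": "petrochemicals",
    "pentane": "petrochemicals",
    "toluene": "petrochemicals",
    "pyrene": "petrochemicals",
    "ethanol": "petrochemicals",
}


def pollutant_index(name: str) -> int:
    """Index of ``name`` in the codebook ordering; RegistryError if unknown."""
    try:
        return POLLUTANTS.index(name)
    except ValueError:
        raise RegistryError(f"unknown pollutant {name!r}") from None


def bacterium_index(name: str) -> int:
    try:
        return BACTERIA.index(name)
    except ValueError:
        raise RegistryError(f"unknown bacterium {name!r}") from None


def level_index(level_um: float) -> int:
    """Index of a grid level; RegistryError if not a member of the grid."""
    for i, lv in enumerate(LEVELS_UM):
        if abs(level_um - lv) <= 1e-9 * lv:
            return i
    raise RegistryError(f"{level_um!r} is not a grid concentration level")


def group_of(pollutant: str) -> str:
    try:
        return POLLUTANT_GROUP[pollutant]
    except KeyError:
        raise RegistryError(f"unknown pollutant {pollutant!r}") from None
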