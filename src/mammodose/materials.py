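"""Material definitions and photon interaction coefficients.

Every material is a named elemental composition (mass fractions) with a
bulk density.  Photon mass attenuation and mass energy-absorption
coefficients for mixtures follow the standard additivity rule

    (mu/rho)_mix(E) = sum_i  w_i * (mu/rho)_i(E)

over per-element tables packaged with the library (1-50 keV, the
mammographic range).  Elemental values are interpolated log-log, which is
the conventional choice for photon cross sections away from absorption
edges; the shell edges of Rh, Ag and W are explicit nodes of the packaged
grids so no interpolation segment straddles an edge.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping

import numpy as np

__all__ = [
    "Material",
    "CoefficientTable",
    "MaterialError",
    "EnergyRangeError",
    "builtin_materials",
    "element_table",
    "mass_attenuation",
    "linear_attenuation",
    "mass_energy_absorption",
    "material_from_dict",
    "material_to_dict",
    "ENERGY_MIN_KEV",
    "ENERGY_MAX_KEV",
    "CHANNELS",
]

ENERGY_MIN_KEV = 1.0
ENERGY_MAX_KEV = 50.0

#: interaction channels available in the packaged tables
CHANNELS = ("photoelectric", "incoherent", "coherent", "total")
_COLUMN = {"photoelectric": 1, "incoherent": 2, "coherent": 3, "total": 4,
           "energy_absorption": 5}


class MaterialError(ValueError):
    """Invalid composition, density, or unknown element symbol."""


class EnergyRangeError(ValueError):
    """Photon energy outside the packaged 1-50 keV table range."""


@dataclass(frozen=True)
class Material:
    """A named mixture: element symbol -> mass fraction, plus density.

    Compositions are renormalized to sum exactly to 1 at construction
    (printed assay tables often total 99.9-100.1%); a sum further than
    1% from unity is rejected as a transcription error.
    """

    name: str
    composition: Mapping[str, float]
    density: float  # g/cm^3

    def __post_init__(self):
        if self.density <= 0:
            raise MaterialError(f"{self.name}: density must be positive")
        if not self.composition:
            raise MaterialError(f"{self.name}: empty composition")
        total = float(sum(self.composition.values()))
        if any(v < 0 for v in self.composition.values()):
            raise MaterialError(f"{self.name}: negative mass fraction")
        if not 0.99 <= total <= 1.01:
            raise MaterialError(
                f"{self.name}: mass fractions sum to {total:.4f}, not ~1")
        norm = {el: float(v) / total for el, v in self.composition.items()}
        object.__setattr__(self, "composition", norm)


@dataclass(frozen=True)
class CoefficientTable:
    """Per-element photon coefficients on a strictly increasing keV grid."""

    element: str
    energy_kev: np.ndarray
    columns: Dict[str, np.ndarray] = field(repr=False)

    def interpolate(self, energy_kev, channel: str) -> np.ndarray:
        """Log-log interpolated coefficient, cm^2/g."""
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
            raise EnergyRangeError(
                f"energy outside [{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV")
        y = self.columns[channel]
        out = np.exp(np.interp(np.log(e), np.log(self.energy_kev), np.log(y)))
        return out if out.shape else float(out)


@functools.lru_cache(maxsize=None)
def element_table(symbol: str) -> CoefficientTable:
    """Load the packaged coefficient table for one element."""
    try:
        ref = resources.files("mammodose.data.coeff") / f"{symbol}.txt"
        raw = np.loadtxt(str(ref))
    except (FileNotFoundError, OSError) as exc:
        raise MaterialError(f"no packaged coefficient table for element "
                            f"{symbol!r}") from exc
    cols = {name: raw[:, idx] for name, idx in _COLUMN.items()}
    return CoefficientTable(symbol, raw[:, 0], cols)


def _mixture(material: Material, energy_kev, column: str):
    acc = None
    for sym, w in material.composition.items():
        val = w * np.asarray(element_table(sym).interpolate(energy_kev, column))
        acc = val if acc is None else acc + val
    return acc if np.ndim(acc) else float(acc)


def mass_attenuation(material: Material, energy_kev, channel: str = "total"):
    """Mass attenuation coefficient of a mixture, cm^2/g."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; pick from {CHANNELS}")
    return _mixture(material, energy_kev, channel)


def linear_attenuation(material: Material, energy_kev, channel: str = "total"):
    """Linear attenuation coefficient, 1/cm."""
    return mass_attenuation(material, energy_kev, channel) * material.density


def mass_energy_absorption(material: Material, energy_kev):
    """Mass energy-absorption coefficient, cm^2/g."""
    return _mixture(material, energy_kev, "energy_absorption")


# ---------------------------------------------------------------------------
# Builtin material registry
# ---------------------------------------------------------------------------

def _pct(**fractions):
    return {el: v / 100.0 for el, v in fractions.items()}


def builtin_materials() -> Dict[str, Material]:
    """Registry of every material used by the dosimetry pipeline.

    Tissues are the standard compressed-breast components (skin,
    glandular, adipose); PLA/PC/WOOD are the printer-filament surrogates,
    entered exactly as assayed (the published filament assays report no
    hydrogen); the remaining entries are the tube/filter/support
    materials plus aluminum (beam-quality attenuator) and dry air.
    """
    reg = {}

    def add(name, composition, density):
        reg[name] = Material(name, composition, density)

    # breast tissue compositions (mass %), skin / glandular / adipose
    add("skin", _pct(H=10.0, C=20.4, N=4.2, O=64.5, Na=0.2, P=0.1,
                     S=0.2, Cl=0.3), 1.09)
    add("glandular", _pct(H=10.6, C=33.2, N=3.0, O=52.7, Na=0.1, P=0.1,
                          S=0.2, Cl=0.1), 1.02)
    add("adipose", _pct(H=11.4, C=59.8, N=0.7, O=27.8, Na=0.1,
                        S=0.1, Cl=0.1), 0.95)

    # printer filaments, as assayed (WOOD totals 100.01%; renormalized)
    add("PLA", _pct(C=54.76, O=44.99, S=0.13, K=0.12), 1.25)
    add("PC", _pct(C=76.28, O=22.79, S=0.11, Ti=0.82), 1.21)
    add("WOOD", _pct(C=61.48, O=37.65, Mg=0.26, Si=0.47, Cl=0.15), 1.00)

    # tube, filters, paddle/support, HVL attenuator
    add("tungsten", {"W": 1.0}, 19.25)
    add("beryllium", {"Be": 1.0}, 1.85)
    add("rhodium", {"Rh": 1.0}, 12.41)
    add("silver", {"Ag": 1.0}, 10.49)
    # stoichiometric polycarbonate (C16H14O3) for the paddle and support
    add("polycarbonate", {"H": 0.055491, "C": 0.755746, "O": 0.188764}, 1.2)
    add("aluminum", {"Al": 1.0}, 2.699)

    # standard dry air (needed for kerma; sea-level density)
    add("air", {"N": 0.755, "O": 0.232, "Ar": 0.013}, 1.205e-3)

    return reg


def blend(name: str, parts: Mapping[str, float],
          registry: Mapping[str, Material]) -> Material:
    """Homogeneous blend of registry materials by mass fraction.

    The blended density uses mass-weighted specific volumes,
    1/rho = sum_i w_i / rho_i, which conserves each component's mass.
    """
    total = sum(parts.values())
    comp: Dict[str, float] = {}
    inv_rho = 0.0
    for mat_name, w in parts.items():
        mat = registry[mat_name]
        w = w / total
        inv_rho += w / mat.density
        for el, f in mat.composition.items():
            comp[el] = comp.get(el, 0.0) + w * f
    return Material(name, comp, 1.0 / inv_rho)


def material_to_dict(material: Material) -> dict:
    """Human-editable config block for one material."""
    return {"name": material.name,
            "density": material.density,
            "composition": dict(material.composition)}


def material_from_dict(block: Mapping) -> Material:
    try:
        return Material(str(block["name"]), dict(block["composition"]),
                        float(block["density"]))
    except KeyError as exc:
        raise MaterialError(f"material block missing key {exc}") from exc
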